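study_id,trials,events,follow_up_weeks
huang_2008,234,0,128.5
panchenko_2016,69,0,132
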