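cohort_id,group,strain,trials,events,follow_up_weeks
bap1_mut_fvbn_aging,mutant,FVB/N,93,2,140
bap1_mut_fvbn_new,mutant,FVB/N,54,0,
bap1_mut_c57bl6,mutant,C57BL/6,62,0,
bap1_mut_129sv,mutant,129/Sv,59,0,
bap1_mut_c57bl6_gen,mutant,C57BL/6,61,0,
wt_fvbn_aging,wildtype,FVB/N,43,0,
wt_fvbn_new,wildtype,FVB/N,20,0,
wt_c57bl6,wildtype,C57BL/6,57,0,
wt_129sv,wildtype,129/Sv,43,0,
wt_c57bl6_gen,wildtype,C57BL/6,64,0,
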