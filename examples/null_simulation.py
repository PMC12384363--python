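"""How surprising are two cases in 329 mice if the mutant rate is the wild-type rate?

Replays the mutant-sized cohort 100,000 times at the wild-type posterior
mean rate and counts how often at least two mesothelioma cases appear;
the exact binomial tail serves as a cross-check.
"""

from histoprior import prob_at_least_k_exact, prob_at_least_k_sim

n, k, p = 329, 2, 0.00186  # wild-type posterior mean under the pooled prior

estimate, se = prob_at_least_k_sim(n, p, k, reps=100_000)
exact = prob_at_least_k_exact(n, p, k)
print(f"simulated P(>= {k} cases in {n} mice at rate {p}) = {estimate:.4f} (se {se:.4f})")
print(f"exact binomial tail                             = {exact:.4f}")
print(
    "\nSeeing two or more cases happens in roughly one of eight null"
    "\nreplicates, so the observed data are not unusual under equal rates."
)
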