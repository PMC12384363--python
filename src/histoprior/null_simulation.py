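"""Null-hypothesis event-count simulation.

How surprising is it to see at least ``k`` cases in a cohort of ``n``
animals when the true rate equals the wild-type rate?  The exact answer
is the binomial upper tail; the Monte-Carlo version replays the cohort
many times and reports the frequency, with its standard error.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["prob_at_least_k_exact", "prob_at_least_k_sim"]


def _check(n: int, p: float, k: int) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")


def prob_at_least_k_exact(n: int, p: float, k: int) -> float:
    """Exact binomial tail P(X >= k), X ~ Binomial(n, p)."""
    _check(n, p, k)
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def prob_at_least_k_sim(
    n: int, p: float, k: int, reps: int = 100_000, seed: int = 20250819
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(X >= k) with its standard error.

    Each replicate draws a Binomial(n, p) cohort; the estimate is the
    fraction of replicates with at least ``k`` events.
    """
    _check(n, p, k)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E756C6C]))
    hits = np.count_nonzero(rng.binomial(n, p, size=reps) >= k)
    phat = hits / reps
    se = float(np.sqrt(phat * (1.0 - phat) / reps))
    return float(phat), se
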