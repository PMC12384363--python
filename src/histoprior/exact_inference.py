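"""Exact frequentist baselines: Fisher's exact test and Clopper-Pearson intervals.

Both procedures are exact in the sense that they use the discrete
sampling distribution directly rather than a normal approximation,
which matters here because mesothelioma is rare and expected cell
counts are far below the chi-square rule of thumb.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data_model import EventCount

__all__ = ["fisher_exact_two_sided", "clopper_pearson_interval"]

# relative slack when comparing hypergeometric table probabilities, so a
# table tied with the observed one (up to float rounding) is counted
_TIE_RTOL = 1e-7


def fisher_exact_two_sided(a: EventCount, b: EventCount) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 table of events/trials.

    Conditions on both margins and uses the probability-mass rule: the
    p-value is the total hypergeometric probability of every table (with
    the same margins) whose probability does not exceed that of the
    observed table.  Ties are resolved with a small relative tolerance.
    """
    n_total = a.trials + b.trials
    if n_total == 0:
        raise ValueError("total number of trials must be positive")
    k_total = a.events + b.events

    # support of the first group's event count given fixed margins
    lo = max(0, k_total - b.trials)
    hi = min(k_total, a.trials)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, k_total, a.trials)
    p_obs = pmf[support == a.events][0]
    p_value = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p_value, 1.0)


def clopper_pearson_interval(x: EventCount, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial rate.

    Bounds invert the binomial tail tests via the beta quantile identity;
    the lower bound is exactly 0 when no events were seen and the upper
    bound exactly 1 when every trial was an event.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    k, n = x.events, x.trials
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lower, upper
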