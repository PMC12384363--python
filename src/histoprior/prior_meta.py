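"""Random-effects meta-analysis of historical proportions on the logit scale.

Each historical study's mesothelioma proportion is logit-transformed
and pooled by inverse-variance weighting; between-study variance is
estimated by the DerSimonian-Laird moment estimator.  Zero-event (or
all-event) studies get the standard 0.5 continuity correction, i.e.
``p_i = (x_i + 0.5) / (n_i + 1)`` with squared standard error
``1/(x_i + 0.5) + 1/(n_i - x_i + 0.5)``; otherwise the usual
``p_i = x_i / n_i`` and ``1/x_i + 1/(n_i - x_i)`` apply.  The pooled
logit and its Wald interval are back-transformed to the probability
scale, and a beta prior is fitted to that summary.

Because a Wald interval is symmetric on the logit scale, its
back-transformed point estimate is a median-type location; the beta
prior is therefore fitted by matching the beta's median to the pooled
point and its 97.5% quantile to the interval's upper bound.  (The lower
bound of a rare-event Wald interval is generally not jointly attainable
with those two targets by any beta distribution.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .beta_tools import IntervalSummary, fit_beta_to_interval
from .data_model import BetaSpec, EventCount, HistoricalSet, ValidationError

__all__ = [
    "StudyEffect",
    "MetaPoolResult",
    "corrected_proportion",
    "dersimonian_laird_tau2",
    "meta_pool",
    "meta_prior_for_wildtype",
]

logger = logging.getLogger(__name__)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(theta: float) -> float:
    return 1.0 / (1.0 + math.exp(-theta))


@dataclass(frozen=True)
class StudyEffect:
    label: str
    p: float
    theta: float
    se: float
    weight: float | None = None


@dataclass(frozen=True)
class MetaPoolResult:
    per_study: tuple[StudyEffect, ...]
    tau2: float
    theta_hat: float
    se_theta_hat: float
    pooled: IntervalSummary


def corrected_proportion(x: EventCount) -> tuple[float, float, float]:
    """Continuity-corrected proportion, logit and logit standard error.

    Returns ``(p_i, theta_i, se_i)``.  The 0.5 correction applies when
    the study has zero events (or, symmetrically, zero non-events).
    """
    k, n = x.events, x.trials
    if k == 0 or k == n:
        p = (k + 0.5) / (n + 1.0)
        se2 = 1.0 / (k + 0.5) + 1.0 / (n - k + 0.5)
    else:
        p = k / n
        se2 = 1.0 / k + 1.0 / (n - k)
    return p, _logit(p), math.sqrt(se2)


def dersimonian_laird_tau2(effects: list[tuple[float, float]]) -> float:
    """DerSimonian-Laird moment estimate of between-study variance.

    ``effects`` is a list of (theta_i, se_i).  With fewer than two
    studies heterogeneity is not estimable and 0 is returned.  The
    estimate is truncated at zero: tau2 = max(0, (Q - df) / c) with
    fixed-effect weights w_i = 1/se_i^2, Q the fixed-effect
    heterogeneity statistic and c = sum(w) - sum(w^2)/sum(w).
    """
    if len(effects) < 2:
        logger.info("fewer than 2 studies: between-study variance set to 0")
        return 0.0
    w = [1.0 / se**2 for _, se in effects]
    theta_fixed = sum(wi * th for wi, (th, _) in zip(w, effects)) / sum(w)
    q = sum(wi * (th - theta_fixed) ** 2 for wi, (th, _) in zip(w, effects))
    df = len(effects) - 1
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    return max(0.0, (q - df) / c)


def meta_pool(historical: HistoricalSet, level: float = 0.95) -> MetaPoolResult:
    """Inverse-variance random-effects pooling of historical proportions.

    Pooled logit ``theta_hat = sum(w_i theta_i) / sum(w_i)`` with
    random-effects weights ``w_i = 1 / (se_i^2 + tau2)``; its standard
    error is ``sum(w_i)^(-1/2)``.  Point and Wald interval are
    back-transformed to the probability scale.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0,1), got {level}")
    base = [
        (s.label, *corrected_proportion(s.event_count())) for s in historical.studies
    ]
    tau2 = dersimonian_laird_tau2([(th, se) for _, _, th, se in base])
    weights = [1.0 / (se**2 + tau2) for _, _, _, se in base]
    wsum = sum(weights)
    theta_hat = sum(wi * th for wi, (_, _, th, _) in zip(weights, base)) / wsum
    se_hat = wsum**-0.5
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    pooled = IntervalSummary(
        lower=_inv_logit(theta_hat - z * se_hat),
        upper=_inv_logit(theta_hat + z * se_hat),
        point=_inv_logit(theta_hat),
        level=level,
        point_type="median",
    )
    per_study = tuple(
        StudyEffect(label, p, th, se, wi)
        for (label, p, th, se), wi in zip(base, weights)
    )
    return MetaPoolResult(
        per_study=per_study, tau2=tau2, theta_hat=theta_hat, se_theta_hat=se_hat, pooled=pooled
    )


def meta_prior_for_wildtype(result: MetaPoolResult) -> BetaSpec:
    """Beta prior fitted to the pooled meta-analytic summary.

    Matches the beta median to the pooled point estimate and the upper
    quantile to the Wald upper bound (see module docstring for why the
    lower bound is excluded).
    """
    return fit_beta_to_interval(result.pooled, use_lower=False)
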