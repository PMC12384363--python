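"""Two-group posterior comparison of rare-event rates.

The mutant and wild-type event counts are binomial with rates ``Pm``
and ``Pw``; ``Pm`` carries a uniform Beta(1,1) prior and ``Pw`` the
informative prior derived from historical data (a single beta or a
beta mixture).  Both posteriors are conjugate:

* beta prior ``Beta(a, b)`` -> posterior ``Beta(a + x, b + n - x)``;
* mixture prior -> mixture posterior with the same updated components
  and weights rescaled by each component's marginal likelihood.

Draws are taken directly from these conjugate posteriors (independent
sampling targets exactly the same law as a converged MCMC chain; the
chain layout of :class:`~histoprior.data_model.McmcSettings` only fixes
the draw count).  Per-draw odds ratio, risk ratio and risk difference
summaries drive the interval-based decisions: the null (OR = RR = 1,
RD = 0) is rejected when the 95% equal-tailed credible interval
excludes the null value.
"""

from __future__ import annotations

from dataclasses import dataclass
import zlib

import numpy as np
from scipy import special

from .data_model import (
    BetaMixture,
    BetaSpec,
    EventCount,
    McmcSettings,
    ValidationError,
)

__all__ = [
    "ComparisonResult",
    "EffectSummary",
    "posterior_update",
    "mixture_posterior_weights",
    "posterior_draws",
    "compare_groups",
    "exceedance_probability",
    "McmcSettings",
]


def posterior_update(prior: BetaSpec | BetaMixture, data: EventCount) -> BetaSpec | BetaMixture:
    """Conjugate posterior for binomial data under a beta or beta-mixture prior."""
    x, n = data.events, data.trials
    if isinstance(prior, BetaSpec):
        return BetaSpec(prior.alpha + x, prior.beta + n - x)
    weights = mixture_posterior_weights(prior, data)
    comps = tuple(
        (float(w), BetaSpec(spec.alpha + x, spec.beta + n - x))
        for w, (_, spec) in zip(weights, prior.components)
    )
    return BetaMixture(comps)


def mixture_posterior_weights(prior: BetaMixture, data: EventCount) -> np.ndarray:
    """Updated mixture weights: prior weight times component marginal likelihood.

    For component ``Beta(a_k, b_k)`` the binomial marginal likelihood is
    ``B(a_k + x, b_k + n - x) / B(a_k, b_k)`` (binomial coefficient
    cancels in the normalization); computed in log space.
    """
    x, n = data.events, data.trials
    logw = np.array(
        [
            np.log(w)
            + special.betaln(s.alpha + x, s.beta + n - x)
            - special.betaln(s.alpha, s.beta)
            for w, s in prior.components
        ]
    )
    logw -= special.logsumexp(logw)
    return np.exp(logw)


def _sample(posterior: BetaSpec | BetaMixture, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(posterior, BetaSpec):
        return rng.beta(posterior.alpha, posterior.beta, size=size)
    weights = posterior.weights
    idx = rng.choice(len(weights), size=size, p=weights)
    draws = np.empty(size)
    for k, (_, spec) in enumerate(posterior.components):
        mask = idx == k
        draws[mask] = rng.beta(spec.alpha, spec.beta, size=int(mask.sum()))
    return draws


def posterior_draws(
    data: EventCount,
    prior: BetaSpec | BetaMixture,
    settings: McmcSettings | None = None,
    stream: int | None = None,
) -> np.ndarray:
    """Draws from the conjugate posterior of one group's rate.

    ``stream`` selects an independent substream of the seed; by default
    it is derived from the data label, so swapping the two groups'
    roles (with their priors) reuses each label's draws and maps
    OR -> 1/OR, RR -> 1/RR, RD -> -RD exactly draw by draw.
    """
    settings = settings or McmcSettings()
    if stream is None:
        stream = zlib.crc32(data.label.encode()) & 0x7FFFFFFF
    posterior = posterior_update(prior, data)
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 0x636D70, stream]))
    return _sample(posterior, settings.total_draws, rng)


@dataclass(frozen=True)
class EffectSummary:
    mean: float
    median: float
    lower: float
    upper: float

    def to_dict(self) -> dict:
        return {"mean": self.mean, "median": self.median, "lower": self.lower, "upper": self.upper}


def _summarize(draws: np.ndarray) -> EffectSummary:
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return EffectSummary(float(draws.mean()), float(med), float(lo), float(hi))


@dataclass(frozen=True)
class ComparisonResult:
    draws_pm: np.ndarray
    draws_pw: np.ndarray
    pm_summary: EffectSummary
    pw_summary: EffectSummary
    or_summary: EffectSummary
    rr_summary: EffectSummary
    rd_summary: EffectSummary
    exceedance: dict[float, float]
    decisions: dict[str, str]

    @property
    def draws_or(self) -> np.ndarray:
        return (self.draws_pm / (1.0 - self.draws_pm)) / (self.draws_pw / (1.0 - self.draws_pw))

    @property
    def draws_rr(self) -> np.ndarray:
        return self.draws_pm / self.draws_pw

    @property
    def draws_rd(self) -> np.ndarray:
        return self.draws_pm - self.draws_pw

    def to_dict(self) -> dict:
        return {
            "pm": self.pm_summary.to_dict(),
            "pw": self.pw_summary.to_dict(),
            "odds_ratio": self.or_summary.to_dict(),
            "risk_ratio": self.rr_summary.to_dict(),
            "risk_difference": self.rd_summary.to_dict(),
            "exceedance": {str(c): p for c, p in self.exceedance.items()},
            "decisions": dict(self.decisions),
        }


def _decision(summary: EffectSummary, null_value: float) -> str:
    return "reject" if not summary.lower <= null_value <= summary.upper else "fail to reject"


def compare_groups(
    mutant: EventCount,
    wildtype: EventCount,
    prior_w: BetaSpec | BetaMixture,
    prior_m: BetaSpec | None = None,
    settings: McmcSettings | None = None,
    cutoffs: tuple[float, ...] = (2.0, 5.0),
) -> ComparisonResult:
    """Joint posterior comparison of the mutant and wild-type rates.

    The mutant prior defaults to the uniform Beta(1,1).  Returns paired
    posterior draws, OR/RR/RD summaries with 95% equal-tailed intervals,
    exceedance probabilities P(OR > c) for each cutoff, and the
    interval-based reject / fail-to-reject decision per measure.
    """
    if any(c < 0 for c in cutoffs):
        raise ValidationError("cutoffs must be non-negative")
    prior_m = prior_m or BetaSpec(1.0, 1.0)
    settings = settings or McmcSettings()
    if mutant.label == wildtype.label:  # degenerate: fall back to positional streams
        stream_m, stream_w = 0, 1
    else:
        stream_m = stream_w = None
    draws_pm = posterior_draws(mutant, prior_m, settings, stream=stream_m)
    draws_pw = posterior_draws(wildtype, prior_w, settings, stream=stream_w)

    odds_ratio = (draws_pm / (1.0 - draws_pm)) / (draws_pw / (1.0 - draws_pw))
    risk_ratio = draws_pm / draws_pw
    risk_diff = draws_pm - draws_pw

    or_s = _summarize(odds_ratio)
    rr_s = _summarize(risk_ratio)
    rd_s = _summarize(risk_diff)
    decisions = {
        "odds_ratio": _decision(or_s, 1.0),
        "risk_ratio": _decision(rr_s, 1.0),
        "risk_difference": _decision(rd_s, 0.0),
    }
    exceedance = {float(c): float((odds_ratio > c).mean()) for c in cutoffs}
    return ComparisonResult(
        draws_pm=draws_pm,
        draws_pw=draws_pw,
        pm_summary=_summarize(draws_pm),
        pw_summary=_summarize(draws_pw),
        or_summary=or_s,
        rr_summary=rr_s,
        rd_summary=rd_s,
        exceedance=exceedance,
        decisions=decisions,
    )


def exceedance_probability(result: ComparisonResult, c: float) -> float:
    """Posterior probability that the odds ratio exceeds ``c``."""
    return float((result.draws_or > c).mean())
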