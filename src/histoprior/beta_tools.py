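"""Fitting beta distributions to posterior summaries and beta mixtures to draws.

Two fitting problems recur in every prior-derivation strategy:

* turn a posterior/confidence summary (point estimate plus an
  equal-tailed 95% interval) into a single ``Beta(alpha, beta)`` prior,
  by deterministic quantile matching;
* turn a cloud of predictive draws into a beta mixture, by
  expectation-maximization maximum likelihood with AIC model selection
  over the number of components.

Quantile matching minimizes the sum of squared *relative* errors of the
requested targets over ``(log alpha, log beta)``; relative errors keep
the tiny lower bound of a rare-event interval from being drowned out by
the upper bound.  The point estimate can be matched as the beta's mean
(appropriate for a posterior-mean summary) or as its median
(appropriate for the back-transformed center of a logit-scale Wald
interval, which is a median-type location).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data_model import BetaMixture, BetaSpec, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSummary",
    "FitError",
    "ConvergenceError",
    "beta_quantile",
    "fit_beta_to_interval",
    "fit_beta_mixture",
    "em_fit",
]


class FitError(RuntimeError):
    """A parametric fit could not satisfy its tolerance; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConvergenceError(FitError):
    """An iterative fit hit its iteration cap before converging."""


@dataclass(frozen=True)
class IntervalSummary:
    """Point estimate plus equal-tailed interval on the probability scale.

    ``point_type`` records whether the point estimate is a mean (e.g. a
    posterior mean computed from draws) or a median-type location (e.g.
    the back-transformed center of a symmetric logit-scale interval).
    """

    lower: float
    upper: float
    point: float | None = None
    level: float = 0.95
    point_type: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError(f"level must be in (0,1), got {self.level}")
        if not 0.0 <= self.lower < self.upper <= 1.0:
            raise ValidationError(
                f"need 0 <= lower < upper <= 1, got [{self.lower}, {self.upper}]"
            )
        if self.point is not None and not self.lower <= self.point <= self.upper:
            raise ValidationError("point estimate must lie inside the interval")
        if self.point_type not in ("mean", "median"):
            raise ValidationError(f"unknown point_type {self.point_type!r}")


def beta_quantile(spec: BetaSpec, q: float) -> float:
    """Inverse distribution function of ``Beta(spec.alpha, spec.beta)``."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0,1), got {q}")
    return float(stats.beta.ppf(q, spec.alpha, spec.beta))


def _moment_start(mean: float, sd: float) -> np.ndarray:
    mean = min(max(mean, 1e-8), 1 - 1e-8)
    kappa = max(mean * (1.0 - mean) / max(sd, 1e-12) ** 2 - 1.0, 1e-3)
    return np.log([max(mean * kappa, 1e-4), max((1.0 - mean) * kappa, 1e-4)])


def fit_beta_to_interval(
    summary: IntervalSummary,
    use_lower: bool = True,
    rtol: float = 0.01,
    rtol_mean: float = 0.05,
) -> BetaSpec:
    """Fit a beta distribution to a (point, interval) summary by quantile matching.

    Targets are the interval bounds at the summary's equal-tailed
    quantile levels plus, when present, the point estimate (matched as
    mean or median according to ``summary.point_type``).  A zero lower
    bound is unattainable by any beta quantile and is dropped from the
    target set, as is the lower bound when ``use_lower`` is False (a
    rare-event Wald interval's lower bound is often jointly infeasible
    with its center and upper bound).

    Deterministic Nelder-Mead over ``(log alpha, log beta)`` from a
    moment-matched start plus a small fixed grid of fallback starts.
    Raises :class:`FitError` if any matched quantile misses its target
    by more than ``rtol`` relative error, or a matched mean by more than
    ``rtol_mean`` (the looser mean tolerance absorbs the slight mutual
    inconsistency of a mean and empirical quantiles estimated from a
    finite posterior sample).
    """
    q_lo = (1.0 - summary.level) / 2.0
    q_hi = 1.0 - q_lo
    targets: list[tuple[object, float]] = []
    if use_lower and summary.lower > 0.0:
        targets.append((q_lo, summary.lower))
    targets.append((q_hi, summary.upper))
    if summary.point is not None and 0.0 < summary.point < 1.0:
        targets.append(("mean" if summary.point_type == "mean" else 0.5, summary.point))
    if len(targets) < 2:
        raise FitError("need at least two usable targets (interval bound(s) and/or point)")

    keys = [k for k, _ in targets]
    vals = np.array([v for _, v in targets])

    def predicted(a: float, b: float) -> np.ndarray:
        out = np.empty(len(keys))
        for i, k in enumerate(keys):
            out[i] = a / (a + b) if k == "mean" else stats.beta.ppf(k, a, b)
        return out

    def objective(x: np.ndarray) -> float:
        a, b = np.exp(x)
        rel = (predicted(a, b) - vals) / vals
        return float(rel @ rel)

    point_guess = summary.point if summary.point is not None else float(
        np.sqrt(max(summary.lower, summary.upper / 100.0) * summary.upper)
    )
    sd_guess = (summary.upper - max(summary.lower, 0.0)) / (2.0 * stats.norm.ppf(q_hi))
    starts = [_moment_start(point_guess, sd_guess)]
    starts += [np.log([a0, b0]) for a0, b0 in ((0.5, 50.0), (1.0, 100.0), (2.0, 500.0))]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-15, "maxiter": 8000, "maxfev": 8000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    rel = np.abs(predicted(a, b) - vals) / vals
    tols = np.array([rtol_mean if k == "mean" else rtol for k in keys])
    if np.any(rel > tols):
        raise FitError(
            f"no beta matches the summary within tolerance "
            f"(worst residual {rel.max():.3g} on targets {keys})",
            residual=float(rel.max()),
        )
    return BetaSpec(float(a), float(b))


# ---------------------------------------------------------------------------
# Beta mixture fitting by EM


def _weighted_beta_mle(x: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood beta parameters for draws x with weights r.

    Solves the digamma score equations psi(a) - psi(a+b) = E_r[log x],
    psi(b) - psi(a+b) = E_r[log(1-x)] in (log a, log b), which is the
    exact M-step of beta-mixture EM.
    """
    wsum = r.sum()
    s1 = float(r @ np.log(x)) / wsum
    s2 = float(r @ np.log1p(-x)) / wsum
    m = float(r @ x) / wsum
    v = float(r @ (x - m) ** 2) / wsum
    x0 = _moment_start(m, np.sqrt(max(v, 1e-16)))

    def score(lp: np.ndarray) -> np.ndarray:
        a, b = np.exp(lp)
        d = special.digamma(a + b)
        return np.array([special.digamma(a) - d - s1, special.digamma(b) - d - s2])

    sol = optimize.root(score, x0, method="hybr")
    if sol.success:
        a, b = np.exp(sol.x)
        return float(a), float(b)

    # fall back to direct likelihood maximization (same optimum)
    def nll(lp: np.ndarray) -> float:
        a, b = np.exp(lp)
        return float(special.betaln(a, b) - (a - 1.0) * s1 - (b - 1.0) * s2)

    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"maxfev": 4000})
    a, b = np.exp(res.x)
    return float(a), float(b)


def _slice_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-sliced moment initialization: deterministic given draws."""
    xs = np.sort(x)
    slices = np.array_split(xs, k)
    a0 = np.empty(k)
    b0 = np.empty(k)
    for j, s in enumerate(slices):
        m = float(s.mean())
        v = float(s.var()) if len(s) > 1 else m * (1 - m) / 10.0
        la, lb = _moment_start(m, np.sqrt(max(v, 1e-16)))
        a0[j], b0[j] = np.exp(la), np.exp(lb)
    return np.full(k, 1.0 / k), a0, b0


def em_fit(
    draws: np.ndarray,
    k: int,
    max_iter: int = 2000,
    tol: float = 1e-8,
    strict: bool = True,
) -> tuple[BetaMixture, float, list[float]]:
    """EM maximum-likelihood fit of a k-component beta mixture.

    Returns ``(mixture, loglik, loglik_trace)``.  The M-step is exact
    (digamma score equations), so the log-likelihood trace is
    non-decreasing.  If the relative log-likelihood change has not
    dropped below ``tol`` within ``max_iter`` iterations, a
    :class:`ConvergenceError` is raised when ``strict``; otherwise the
    plateaued fit is returned with a logged warning (an overparameterized
    mixture on unimodal data can crawl indefinitely while the likelihood
    is already flat, which is harmless for model comparison).
    """
    x = np.asarray(draws, dtype=float)
    w, a, b = _slice_init(x, k)
    trace: list[float] = []
    ll_prev = -np.inf
    for it in range(max_iter):
        # E-step in log space
        logp = np.log(w)[:, None] + stats.beta.logpdf(x[None, :], a[:, None], b[:, None])
        norm = special.logsumexp(logp, axis=0)
        ll = float(norm.sum())
        trace.append(ll)
        if ll - ll_prev < tol * (1.0 + abs(ll)):
            resp = np.exp(logp - norm)
            w = np.maximum(resp.mean(axis=1), 1e-12)
            w = w / w.sum()
            comps = tuple((float(w[j]), BetaSpec(float(a[j]), float(b[j]))) for j in range(k))
            return BetaMixture(comps), ll, trace
        ll_prev = ll
        resp = np.exp(logp - norm)
        for j in range(k):
            rj = resp[j]
            if rj.sum() < 1e-9 * len(x):
                continue  # moribund component: freeze parameters
            a[j], b[j] = _weighted_beta_mle(x, rj)
        w = np.maximum(resp.mean(axis=1), 1e-12)
        w = w / w.sum()
    delta = trace[-1] - trace[-2]
    if strict:
        raise ConvergenceError(
            f"beta-mixture EM (k={k}) did not converge in {max_iter} iterations; "
            f"last log-likelihood change {delta:.3g}",
            residual=delta,
        )
    logger.warning(
        "beta-mixture EM (k=%d) hit the %d-iteration cap (last LL change %.3g); "
        "returning the plateaued fit",
        k,
        max_iter,
        delta,
    )
    comps = tuple((float(w[j]), BetaSpec(float(a[j]), float(b[j]))) for j in range(k))
    return BetaMixture(comps), trace[-1], trace


def fit_beta_mixture(
    draws: np.ndarray,
    k_max: int = 3,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[BetaMixture, int, dict[int, float]]:
    """Fit beta mixtures with 1..k_max components and select by AIC.

    AIC counts ``3k - 1`` free parameters (two shapes per component plus
    ``k - 1`` free weights): ``AIC = 2(3k - 1) - 2 log L``.  Returns the
    AIC-best mixture, the selected ``k`` and the AIC per candidate ``k``.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("draws must be a 1-D array with at least 2 values")
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValidationError("all draws must lie strictly inside (0, 1)")
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")

    fits: dict[int, BetaMixture] = {}
    aic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        mixture, ll, _ = em_fit(x, k, max_iter=max_iter, tol=tol, strict=False)
        fits[k] = mixture
        aic[k] = 2.0 * (3 * k - 1) - 2.0 * ll
    selected = min(aic, key=lambda k: (aic[k], k))
    return fits[selected], selected, aic
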