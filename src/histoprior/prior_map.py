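"""Meta-analytic predictive (MAP) prior from a hierarchical binomial-logit model.

Historical study counts are modeled as ``x_i ~ Binomial(n_i, p_i)`` with
``logit(p_i) = beta0 + mu_i`` and study effects ``mu_i ~ N(0, tau^2)``.
The intercept carries a normal prior and the between-study SD ``tau`` a
half-normal prior.  The joint posterior of ``(beta0, tau, mu_1..mu_I)``
is sampled by an adaptive random-walk Metropolis-within-Gibbs sampler in
the non-centered parameterization ``mu_i = tau * eta_i`` (which avoids
the funnel that appears when tau is small).  Proposal scales adapt
during warmup only, so retained draws come from a fixed Markov kernel.

The predictive distribution for the rate in a *new* study adds a fresh
study effect per retained draw: ``p* = inv_logit(beta0 + tau * z)``,
``z ~ N(0,1)``.  A beta mixture is fitted to the predictive draws to
obtain a closed-form prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
from scipy import stats

from .beta_tools import (
    ConvergenceError,
    IntervalSummary,
    fit_beta_mixture,
)
from .data_model import BetaMixture, BetaSpec, HistoricalSet, McmcSettings, ValidationError

__all__ = ["MapHyperPriors", "MapResult", "map_sample", "map_prior_for_wildtype"]

RHAT_LIMIT = 1.01


@dataclass(frozen=True)
class MapHyperPriors:
    """Hyperpriors for the hierarchical model.

    ``tau_scale`` is the scale (standard-deviation parameter) of the
    half-normal prior on the between-study SD; the default 1/16 encodes
    low expected heterogeneity.  The intercept prior defaults to
    Normal(0, sd 2), i.e. variance 4 on the log-odds scale.
    """

    beta0_mean: float = 0.0
    beta0_sd: float = 2.0
    tau_scale: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if not self.beta0_sd > 0:
            raise ValidationError("beta0_sd must be positive")
        if not self.tau_scale > 0:
            raise ValidationError("tau_scale must be positive")


@dataclass
class MapResult:
    draws_beta0: np.ndarray  # (chains, draws)
    draws_tau: np.ndarray  # (chains, draws)
    predictive_draws: np.ndarray  # flat
    summary: IntervalSummary
    diagnostics: dict
    mixture: BetaMixture | None = None


def _adapt_delta(batch: int) -> float:
    return min(0.25, 2.0 / math.sqrt(batch))


def _run_chain(
    x: np.ndarray,
    n: np.ndarray,
    hyper: MapHyperPriors,
    iterations: int,
    warmup: int,
    thinning: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One chain of the non-centered adaptive MWG sampler.

    Returns retained (beta0, tau) draws.
    """
    n_stud = len(x)
    s0 = hyper.beta0_sd
    m0 = hyper.beta0_mean
    st2 = hyper.tau_scale**2

    def loglik(beta0: float, tau: float, eta: np.ndarray) -> float:
        theta = beta0 + tau * eta
        return float(x @ theta - n @ np.logaddexp(0.0, theta))

    def logprior(beta0: float, tau: float, eta: np.ndarray) -> float:
        return (
            -0.5 * ((beta0 - m0) / s0) ** 2
            - 0.5 * float(eta @ eta)
            - tau * tau / (2.0 * st2)
        )

    # random initial values
    beta0 = m0 + s0 * rng.standard_normal()
    eta = rng.standard_normal(n_stud)
    tau = abs(rng.normal(0.0, hyper.tau_scale)) + 1e-8
    lp = loglik(beta0, tau, eta) + logprior(beta0, tau, eta)

    # beta0, eta_1..eta_I, log tau, plus two likelihood-preserving moves
    # that keep every theta_i fixed: a translation of beta0 (compensated
    # by eta) and a rescaling of tau (compensated by eta); they break the
    # beta0/eta and tau/eta couplings when the studies are informative
    n_params = n_stud + 3
    scales = np.full(n_params, 0.5)
    scales[n_stud + 1] = hyper.tau_scale  # tau RW step starts at the prior scale
    accepted = np.zeros(n_params)
    batch = 0

    keep = (iterations - warmup) // thinning
    out_b0 = np.empty(keep)
    out_tau = np.empty(keep)
    k = 0

    for it in range(iterations):
        # beta0
        prop = beta0 + scales[0] * rng.standard_normal()
        lp_prop = loglik(prop, tau, eta) + logprior(prop, tau, eta)
        if math.log(rng.random()) < lp_prop - lp:
            beta0, lp = prop, lp_prop
            accepted[0] += 1
        # study effects (non-centered)
        for j in range(n_stud):
            prop_e = eta.copy()
            prop_e[j] = eta[j] + scales[1 + j] * rng.standard_normal()
            # only study j's likelihood term and eta_j's prior change
            th_old = beta0 + tau * eta[j]
            th_new = beta0 + tau * prop_e[j]
            dll = x[j] * (th_new - th_old) - n[j] * (
                np.logaddexp(0.0, th_new) - np.logaddexp(0.0, th_old)
            )
            dlp = dll - 0.5 * (prop_e[j] ** 2 - eta[j] ** 2)
            if math.log(rng.random()) < dlp:
                eta = prop_e
                lp += dlp
                accepted[1 + j] += 1
        # tau: reflected random walk on the original scale (the prior is
        # flat near 0, so no log transform is needed and none of the heavy
        # log-scale left tail has to be traversed)
        prop_t = abs(tau + scales[n_stud + 1] * rng.standard_normal())
        if prop_t > 0.0:
            lp_prop = loglik(beta0, prop_t, eta) + logprior(beta0, prop_t, eta)
            if math.log(rng.random()) < lp_prop - lp:
                tau, lp = prop_t, lp_prop
                accepted[n_stud + 1] += 1
        # translation: beta0 -> beta0 + d, eta_i -> eta_i - d/tau
        # (theta_i and hence the likelihood are unchanged; Jacobian 1)
        d = scales[-1] * rng.standard_normal()
        prop_b = beta0 + d
        prop_e = eta - d / tau
        dlp = (
            -0.5 * ((prop_b - m0) / s0) ** 2
            + 0.5 * ((beta0 - m0) / s0) ** 2
            - 0.5 * float(prop_e @ prop_e)
            + 0.5 * float(eta @ eta)
        )
        if math.log(rng.random()) < dlp:
            beta0, eta = prop_b, prop_e
            lp += dlp
            accepted[-1] += 1
        # interweaved (centered) Gibbs step for tau: holding the centered
        # effects mu_i = tau * eta_i fixed, tau^2 | mu is Generalized
        # Inverse Gaussian with lambda = (1 - I)/2, chi = sum(mu^2),
        # psi = 1/tau_scale^2; sampled exactly, then eta is rescaled.
        # This mixes tau when the studies are informative (where the
        # non-centered random walk stalls); the reflected walk above
        # covers the weak-data regime.
        mu = tau * eta
        chi = float(mu @ mu)
        if chi > 1e-290:
            lam = (1.0 - n_stud) / 2.0
            b = math.sqrt(chi / st2)
            v = math.sqrt(chi * st2) * stats.geninvgauss.rvs(lam, b, random_state=rng)
            tau = math.sqrt(v)
            eta = mu / tau
            lp = loglik(beta0, tau, eta) + logprior(beta0, tau, eta)

        if it < warmup and (it + 1) % 50 == 0:
            batch += 1
            rate = accepted / 50.0
            delta = _adapt_delta(batch)
            scales *= np.exp(np.where(rate > 0.44, delta, -delta))
            accepted[:] = 0.0

        if it >= warmup and (it - warmup) % thinning == 0:
            out_b0[k] = beta0
            out_tau[k] = tau
            k += 1

    return out_b0[:k], out_tau[:k]


def map_sample(
    historical: HistoricalSet,
    hyper: MapHyperPriors | None = None,
    mcmc: McmcSettings | None = None,
) -> MapResult:
    """Sample the hierarchical model and form the predictive distribution.

    Runs ``mcmc.chains`` independent chains, checks split-R-hat on
    ``beta0`` and ``tau`` (raising :class:`ConvergenceError` at R-hat >=
    1.01 with a suggestion to lengthen chains), then draws one new-study
    rate per retained posterior draw.
    """
    hyper = hyper or MapHyperPriors()
    mcmc = mcmc or McmcSettings()
    x = np.array([s.events for s in historical.studies], dtype=float)
    n = np.array([s.trials for s in historical.studies], dtype=float)

    b0_chains = []
    tau_chains = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 0x6D6170, c]))
        b0, tau = _run_chain(x, n, hyper, mcmc.iterations, mcmc.warmup, mcmc.thinning, rng)
        b0_chains.append(b0)
        tau_chains.append(tau)
    draws_b0 = np.vstack(b0_chains)
    draws_tau = np.vstack(tau_chains)

    diagnostics = {}
    for name, arr in (("beta0", draws_b0), ("tau", draws_tau)):
        rhat = float(az.rhat(arr)) if mcmc.chains > 1 else 1.0
        ess = float(az.ess(arr))
        diagnostics[name] = {"rhat": rhat, "ess": ess}
        if rhat >= RHAT_LIMIT:
            raise ConvergenceError(
                f"split-R-hat for {name} is {rhat:.4f} >= {RHAT_LIMIT}; "
                "run longer chains (increase McmcSettings.iterations)"
            )

    rng_pred = np.random.default_rng(np.random.SeedSequence([mcmc.seed, 0x70726564]))
    z = rng_pred.standard_normal(draws_b0.size)
    theta_star = draws_b0.ravel() + draws_tau.ravel() * z
    predictive = 1.0 / (1.0 + np.exp(-theta_star))

    lo, hi = np.quantile(predictive, [0.025, 0.975])
    summary = IntervalSummary(
        lower=float(lo), upper=float(hi), point=float(predictive.mean()), point_type="mean"
    )
    return MapResult(
        draws_beta0=draws_b0,
        draws_tau=draws_tau,
        predictive_draws=predictive,
        summary=summary,
        diagnostics=diagnostics,
    )


def map_prior_for_wildtype(
    result: MapResult, k_max: int = 3
) -> tuple[BetaMixture, BetaSpec | None]:
    """Beta-mixture approximation of the predictive draws.

    Fits mixtures with 1..k_max components by EM and selects by AIC.
    When a single component wins, it is also returned as a plain
    :class:`BetaSpec` directly usable as a conjugate prior.  The fitted
    mixture is attached to ``result.mixture``.
    """
    mixture, selected_k, _ = fit_beta_mixture(result.predictive_draws, k_max=k_max)
    result.mixture = mixture
    single = mixture.components[0][1] if selected_k == 1 else None
    return mixture, single
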