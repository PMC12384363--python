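"""End-to-end orchestration: exact tests, prior strategies, comparison, null simulation.

``run_pipeline`` executes the full analysis for a run configuration and
returns a consolidated, JSON-serializable report: Fisher/Clopper-Pearson
baselines, then for each requested prior strategy the derived wild-type
prior and the posterior OR/RR/RD comparison, and finally the null
event-count simulation at the wild-type posterior mean.  Reruns with the
same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import datasets
from .data_model import (
    BetaMixture,
    BetaSpec,
    CohortTable,
    HistoricalSet,
    McmcSettings,
    ValidationError,
    aggregate_groups,
    read_cohort_table,
    read_historical_table,
    write_report,
)
from .exact_inference import clopper_pearson_interval, fisher_exact_two_sided
from .null_simulation import prob_at_least_k_exact, prob_at_least_k_sim
from .posterior_compare import ComparisonResult, compare_groups
from .prior_map import MapHyperPriors, map_prior_for_wildtype, map_sample
from .prior_meta import meta_pool, meta_prior_for_wildtype
from .prior_pooled import pooled_posterior, pooled_prior_for_wildtype

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STRATEGIES = ("uniform", "pooled", "meta", "map")


@dataclass(frozen=True)
class RunConfig:
    cohort_path: str | None = None  # None -> bundled aging-study table
    historical_path: str | None = None  # None -> bundled historical controls
    strategies: tuple[str, ...] = ("pooled", "meta", "map")
    hyper: MapHyperPriors = field(default_factory=MapHyperPriors)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    cutoffs: tuple[float, ...] = (2.0, 5.0)
    null_sim_reps: int = 100_000
    mixture_k_max: int = 3
    output: str | None = None

    def __post_init__(self) -> None:
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValidationError(
                f"unknown strategy name(s) {unknown}; valid strategies: {list(STRATEGIES)}"
            )
        if not self.strategies:
            raise ValidationError("at least one strategy required")


def load_config(path: str | Path) -> RunConfig:
    """Build a :class:`RunConfig` from a JSON key-value file."""
    with open(path) as fh:
        raw = json.load(fh)
    kwargs: dict = {}
    for key in ("cohort_path", "historical_path", "output"):
        if key in raw:
            kwargs[key] = raw[key]
    if "strategies" in raw:
        kwargs["strategies"] = tuple(raw["strategies"])
    if "cutoffs" in raw:
        kwargs["cutoffs"] = tuple(float(c) for c in raw["cutoffs"])
    for key in ("null_sim_reps", "mixture_k_max"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "hyper" in raw:
        kwargs["hyper"] = MapHyperPriors(**raw["hyper"])
    if "mcmc" in raw:
        kwargs["mcmc"] = McmcSettings(**raw["mcmc"])
    if "seed" in raw:
        kwargs["mcmc"] = replace(kwargs.get("mcmc", McmcSettings()), seed=int(raw["seed"]))
    return RunConfig(**kwargs)


def _prior_to_dict(prior: BetaSpec | BetaMixture) -> dict:
    if isinstance(prior, BetaSpec):
        return {"alpha": prior.alpha, "beta": prior.beta}
    return {
        "components": [
            {"weight": w, "alpha": s.alpha, "beta": s.beta} for w, s in prior.components
        ]
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config`` and return the report."""
    table: CohortTable = (
        read_cohort_table(config.cohort_path) if config.cohort_path else datasets.load_bap1_cohorts()
    )
    historical: HistoricalSet = (
        read_historical_table(config.historical_path)
        if config.historical_path
        else datasets.load_historical_controls()
    )
    mutant, wildtype = aggregate_groups(table)
    logger.info("[data] mutant %d/%d, wildtype %d/%d, %d historical studies",
                mutant.events, mutant.trials, wildtype.events, wildtype.trials,
                len(historical.studies))

    report: dict = {
        "settings": {
            "strategies": list(config.strategies),
            "cutoffs": list(config.cutoffs),
            "null_sim_reps": config.null_sim_reps,
            "mixture_k_max": config.mixture_k_max,
            "seed": config.mcmc.seed,
            "mcmc": config.mcmc.to_dict(),
            "hyper": {
                "beta0_mean": config.hyper.beta0_mean,
                "beta0_sd": config.hyper.beta0_sd,
                "tau_scale": config.hyper.tau_scale,
            },
        },
        "data": {
            "mutant": {"events": mutant.events, "trials": mutant.trials},
            "wildtype": {"events": wildtype.events, "trials": wildtype.trials},
            "historical": [
                {"study": s.label, "events": s.events, "trials": s.trials,
                 "follow_up_weeks": s.follow_up_weeks}
                for s in historical.studies
            ],
        },
    }

    logger.info("[exact] Fisher's exact test and Clopper-Pearson intervals")
    report["exact"] = {
        "fisher_p": fisher_exact_two_sided(mutant, wildtype),
        "rate_mutant": mutant.rate,
        "ci_mutant": list(clopper_pearson_interval(mutant)),
        "rate_wildtype": wildtype.rate,
        "ci_wildtype": list(clopper_pearson_interval(wildtype)),
    }

    strategies_out: dict = {}
    pw_mean_for_null: float | None = None
    for name in config.strategies:
        logger.info("[%s] deriving wild-type prior", name)
        entry: dict = {}
        if name == "uniform":
            prior_w: BetaSpec | BetaMixture = BetaSpec(1.0, 1.0)
        elif name == "pooled":
            post = pooled_posterior(historical, config.mcmc)
            prior_w = pooled_prior_for_wildtype(post)
            entry["posterior"] = {
                "analytic_alpha": post.analytic.alpha,
                "analytic_beta": post.analytic.beta,
                "mean": post.summary.point,
                "interval": [post.summary.lower, post.summary.upper],
            }
        elif name == "meta":
            pooled = meta_pool(historical)
            prior_w = meta_prior_for_wildtype(pooled)
            entry["meta"] = {
                "tau2": pooled.tau2,
                "theta_hat": pooled.theta_hat,
                "se_theta_hat": pooled.se_theta_hat,
                "proportion": pooled.pooled.point,
                "interval": [pooled.pooled.lower, pooled.pooled.upper],
                "per_study": [
                    {"study": e.label, "p": e.p, "theta": e.theta, "se": e.se, "weight": e.weight}
                    for e in pooled.per_study
                ],
            }
        elif name == "map":
            result = map_sample(historical, config.hyper, config.mcmc)
            mixture, single = map_prior_for_wildtype(result, k_max=config.mixture_k_max)
            prior_w = single if single is not None else mixture
            entry["map"] = {
                "predictive_mean": result.summary.point,
                "predictive_interval": [result.summary.lower, result.summary.upper],
                "diagnostics": result.diagnostics,
                "selected_k": len(mixture.components),
                "mixture": _prior_to_dict(mixture)["components"],
            }
        entry["prior_wildtype"] = _prior_to_dict(prior_w)
        logger.info("[%s] posterior comparison", name)
        comparison: ComparisonResult = compare_groups(
            mutant, wildtype, prior_w, settings=config.mcmc, cutoffs=config.cutoffs
        )
        entry["comparison"] = comparison.to_dict()
        strategies_out[name] = entry
        if pw_mean_for_null is None and name != "uniform":
            pw_mean_for_null = float(comparison.draws_pw.mean())
    report["strategies"] = strategies_out

    if pw_mean_for_null is None:  # only the uniform strategy was run
        pw_mean_for_null = float(strategies_out["uniform"]["comparison"]["pw"]["mean"])
    logger.info("[null-sim] %d replicates at p=%.5g", config.null_sim_reps, pw_mean_for_null)
    estimate, se = prob_at_least_k_sim(
        n=mutant.trials,
        p=pw_mean_for_null,
        k=max(mutant.events, 1),
        reps=config.null_sim_reps,
        seed=config.mcmc.seed,
    )
    report["null_simulation"] = {
        "n": mutant.trials,
        "k": max(mutant.events, 1),
        "p": pw_mean_for_null,
        "reps": config.null_sim_reps,
        "estimate": estimate,
        "mc_standard_error": se,
        "exact": prob_at_least_k_exact(mutant.trials, pw_mean_for_null, max(mutant.events, 1)),
    }

    if config.output:
        write_report(report, config.output)
    return report
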