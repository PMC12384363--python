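"""Synthetic cohort tables and historical-study sets with known truth.

The generators emulate the statistical structure the analysis assumes:
cohort event counts are binomial at a per-row true rate, and historical
study rates vary on the log-odds scale around a common intercept with
between-study SD ``tau`` (the same generative model the MAP stage
fits).  The true parameters are returned (and optionally written)
alongside the data so parameter-recovery tests can score estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import (
    CohortRow,
    CohortTable,
    HistoricalSet,
    HistoricalStudy,
    ValidationError,
    write_cohort_table,
    write_historical_table,
)

__all__ = ["CohortSpec", "generate_cohorts", "generate_historical", "write_truth"]


@dataclass(frozen=True)
class CohortSpec:
    """Blueprint for one synthetic cohort row."""

    group: str
    strain: str
    n_mice: int
    true_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_rate <= 1.0:
            raise ValidationError(f"true_rate must be in [0,1], got {self.true_rate}")
        if self.n_mice < 1:
            raise ValidationError("n_mice must be >= 1")


def generate_cohorts(
    specs: Sequence[CohortSpec], seed: int = 20250819
) -> tuple[CohortTable, dict]:
    """Draw a cohort table with binomial event counts at each row's true rate.

    Deterministic given ``seed``.  Returns the table and a truth record
    mapping each generated cohort_id to its true rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x73796E63]))
    rows = []
    truth = {"seed": seed, "rows": {}}
    for i, spec in enumerate(specs):
        cid = f"synth_{spec.group}_{i:03d}"
        events = int(rng.binomial(spec.n_mice, spec.true_rate))
        rows.append(
            CohortRow(
                cohort_id=cid,
                group=spec.group,
                strain=spec.strain,
                trials=spec.n_mice,
                events=events,
            )
        )
        truth["rows"][cid] = {"true_rate": spec.true_rate, "n_mice": spec.n_mice}
    return CohortTable(tuple(rows)), truth


def generate_historical(
    n_studies: int,
    sizes: Sequence[int],
    base_logit: float,
    tau: float,
    seed: int = 20250819,
    follow_up_weeks: float = 130.0,
) -> tuple[HistoricalSet, dict]:
    """Draw a historical set from the binomial-logit random-effects model.

    Study ``i`` has rate ``inv_logit(base_logit + N(0, tau^2))`` and a
    binomial event count.  ``sizes`` is recycled to length ``n_studies``.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    if n_studies < 1:
        raise ValidationError("n_studies must be >= 1")
    sizes = list(sizes)
    if not sizes or any(s < 1 for s in sizes):
        raise ValidationError("sizes must be positive integers")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x73796E68]))
    studies = []
    truth = {"seed": seed, "base_logit": base_logit, "tau": tau, "studies": {}}
    for i in range(n_studies):
        n = int(sizes[i % len(sizes)])
        theta = base_logit + tau * rng.standard_normal()
        rate = 1.0 / (1.0 + np.exp(-theta))
        events = int(rng.binomial(n, rate))
        label = f"synth_study_{i:03d}"
        studies.append(
            HistoricalStudy(label=label, events=events, trials=n, follow_up_weeks=follow_up_weeks)
        )
        truth["studies"][label] = {"true_rate": float(rate), "n": n}
    return HistoricalSet(tuple(studies)), truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Write the truth record next to a generated table for test harnesses."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
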