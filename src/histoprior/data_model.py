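"""Domain types and table/report IO.

The analysis operates on event-count data: for each mouse cohort or
historical study we record how many animals were followed (``trials``)
and how many developed spontaneous mesothelioma (``events``).  Cohort
tables distinguish a ``mutant`` (germline Bap1-heterozygous) and a
``wildtype`` group; historical tables describe previously published
wild-type cohorts used to build an informative prior.

Tables are flat delimited text (comma or tab, auto-detected) with a
header row.  Analysis reports are JSON and round-trip losslessly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventCount",
    "CohortRow",
    "CohortTable",
    "HistoricalStudy",
    "HistoricalSet",
    "BetaSpec",
    "BetaMixture",
    "McmcSettings",
    "ValidationError",
    "read_cohort_table",
    "write_cohort_table",
    "read_historical_table",
    "write_historical_table",
    "aggregate_groups",
    "write_report",
    "read_report",
]

GROUPS = ("mutant", "wildtype")


class ValidationError(ValueError):
    """Raised when an input table or domain object violates its invariants."""


@dataclass(frozen=True)
class EventCount:
    """Events (cases) out of trials (animals) for one cohort or study."""

    label: str
    events: int
    trials: int

    def __post_init__(self) -> None:
        if not (isinstance(self.events, (int, np.integer)) and isinstance(self.trials, (int, np.integer))):
            raise ValidationError(f"{self.label!r}: events and trials must be integers")
        if self.trials < 1:
            raise ValidationError(f"{self.label!r}: trials must be >= 1, got {self.trials}")
        if not 0 <= self.events <= self.trials:
            raise ValidationError(
                f"{self.label!r}: events must satisfy 0 <= events <= trials, "
                f"got events={self.events}, trials={self.trials}"
            )

    @property
    def rate(self) -> float:
        return self.events / self.trials


@dataclass(frozen=True)
class CohortRow:
    cohort_id: str
    group: str
    strain: str
    trials: int
    events: int
    follow_up_weeks: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"row {self.cohort_id!r}: unknown group {self.group!r} (expected one of {GROUPS})"
            )
        EventCount(self.cohort_id, self.events, self.trials)  # reuse invariants
        if self.follow_up_weeks is not None and not self.follow_up_weeks > 0:
            raise ValidationError(f"row {self.cohort_id!r}: follow_up_weeks must be positive")

    def event_count(self) -> EventCount:
        return EventCount(self.cohort_id, self.events, self.trials)


@dataclass(frozen=True)
class CohortTable:
    rows: tuple[CohortRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("cohort table has no rows")
        ids = [r.cohort_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate cohort_id values: {dupes}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass(frozen=True)
class HistoricalStudy:
    """One historical wild-type study: counts plus follow-up duration."""

    label: str
    events: int
    trials: int
    follow_up_weeks: float

    def __post_init__(self) -> None:
        EventCount(self.label, self.events, self.trials)
        if not self.follow_up_weeks > 0:
            raise ValidationError(f"study {self.label!r}: follow_up_weeks must be positive")

    def event_count(self) -> EventCount:
        return EventCount(self.label, self.events, self.trials)


@dataclass(frozen=True)
class HistoricalSet:
    studies: tuple[HistoricalStudy, ...]

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValidationError("historical set must contain at least one study")

    @property
    def total_events(self) -> int:
        return sum(s.events for s in self.studies)

    @property
    def total_trials(self) -> int:
        return sum(s.trials for s in self.studies)

    def event_counts(self) -> list[EventCount]:
        return [s.event_count() for s in self.studies]


@dataclass(frozen=True)
class BetaSpec:
    """Parameters of a beta distribution used as a prior or posterior."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValidationError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValidationError(f"beta must be positive and finite, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


@dataclass(frozen=True)
class BetaMixture:
    """Finite mixture of beta distributions, sum_k w_k Beta(a_k, b_k)."""

    components: tuple[tuple[float, BetaSpec], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("mixture must have at least one component")
        weights = [w for w, _ in self.components]
        if any(w <= 0 for w in weights):
            raise ValidationError("mixture weights must be strictly positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError(f"mixture weights must sum to 1, got {sum(weights)}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for w, _ in self.components])

    @property
    def mean(self) -> float:
        return float(sum(w * s.mean for w, s in self.components))


@dataclass(frozen=True)
class McmcSettings:
    """Chain bookkeeping for posterior sampling.

    Defaults mirror a common four-chain setup: 4 chains of 4000
    iterations each, the first half discarded as warmup, no thinning,
    giving 8000 retained draws.
    """

    chains: int = 4
    iterations: int = 4000
    warmup_fraction: float = 0.5
    thinning: int = 1
    seed: int = 20250819

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValidationError("chains must be >= 1")
        if self.iterations < 4:
            raise ValidationError("iterations must be >= 4")
        if not 0.0 <= self.warmup_fraction < 1.0:
            raise ValidationError("warmup_fraction must be in [0, 1)")
        if self.thinning < 1:
            raise ValidationError("thinning must be >= 1")

    @property
    def warmup(self) -> int:
        return int(round(self.iterations * self.warmup_fraction))

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.warmup) // self.thinning

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "iterations": self.iterations,
            "warmup_fraction": self.warmup_fraction,
            "thinning": self.thinning,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Table IO

_COHORT_COLUMNS = ("cohort_id", "group", "strain", "trials", "events")
_HISTORICAL_COLUMNS = ("study_id", "trials", "events", "follow_up_weeks")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: file is empty")
    # sep=None lets pandas sniff comma vs tab
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read and validate a cohort count table (CSV or TSV with header).

    Required columns: cohort_id, group, strain, trials, events.
    Optional: follow_up_weeks.  Raises :class:`ValidationError` naming
    the offending row when a row violates the count invariants.
    """
    df = _read_delimited(path)
    _require_columns(df, _COHORT_COLUMNS, path)
    rows = []
    for _, rec in df.iterrows():
        fu = rec.get("follow_up_weeks")
        fu = None if fu is None or (isinstance(fu, float) and math.isnan(fu)) else float(fu)
        rows.append(
            CohortRow(
                cohort_id=str(rec["cohort_id"]),
                group=str(rec["group"]).strip().lower(),
                strain=str(rec["strain"]),
                trials=int(rec["trials"]),
                events=int(rec["events"]),
                follow_up_weeks=fu,
            )
        )
    return CohortTable(tuple(rows))


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_historical_table(path: str | Path) -> HistoricalSet:
    """Read a historical-study count table (study_id, trials, events, follow_up_weeks)."""
    df = _read_delimited(path)
    _require_columns(df, _HISTORICAL_COLUMNS, path)
    studies = tuple(
        HistoricalStudy(
            label=str(rec["study_id"]),
            events=int(rec["events"]),
            trials=int(rec["trials"]),
            follow_up_weeks=float(rec["follow_up_weeks"]),
        )
        for _, rec in df.iterrows()
    )
    return HistoricalSet(studies)


def write_historical_table(historical: HistoricalSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "study_id": s.label,
                "trials": s.trials,
                "events": s.events,
                "follow_up_weeks": s.follow_up_weeks,
            }
            for s in historical.studies
        ]
    ).to_csv(path, index=False)


def aggregate_groups(table: CohortTable) -> tuple[EventCount, EventCount]:
    """Sum cohort rows into per-group totals ``(mutant, wildtype)``.

    Raises :class:`ValidationError` if either group is absent.
    """
    totals: dict[str, list[int]] = {}
    for row in table.rows:
        ev, tr = totals.setdefault(row.group, [0, 0])
        totals[row.group] = [ev + row.events, tr + row.trials]
    missing = [g for g in GROUPS if g not in totals]
    if missing:
        raise ValidationError(f"group(s) missing from cohort table: {missing}")
    return tuple(EventCount(g, *totals[g]) for g in GROUPS)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Report IO


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize an analysis report (plain dict of results, seeds, settings) as JSON.

    Floats are written at full double precision so that a write/read
    cycle preserves every value exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
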