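"""Bundled count tables.

``load_bap1_cohorts`` returns the lifetime aging-study cohorts of
germline Bap1-heterozygous mice and wild-type littermates (totals
2/329 mutant, 0/227 wild-type).  ``load_historical_controls`` returns
the two published lifetime wild-type FVB/N studies (0/234 and 0/69)
used to derive the historical-control prior.
"""

from importlib import resources

from ..data_model import CohortTable, HistoricalSet, read_cohort_table, read_historical_table

__all__ = ["load_bap1_cohorts", "load_historical_controls"]


def _path(name: str):
    return resources.files(__package__) / name


def load_bap1_cohorts() -> CohortTable:
    with resources.as_file(_path("bap1_cohorts.csv")) as p:
        return read_cohort_table(p)


def load_historical_controls() -> HistoricalSet:
    with resources.as_file(_path("historical_controls.csv")) as p:
        return read_historical_table(p)
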