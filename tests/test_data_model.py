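import math

import numpy as np
import pytest

from histoprior import (
    BetaMixture,
    BetaSpec,
    CohortRow,
    CohortTable,
    EventCount,
    HistoricalStudy,
    McmcSettings,
    ValidationError,
    aggregate_groups,
    read_cohort_table,
    read_historical_table,
    read_report,
    write_cohort_table,
    write_report,
)


class TestEventCount:
    def test_invariants(self):
        ec = EventCount("c", 2, 329)
        assert ec.rate == pytest.approx(2 / 329)

    @pytest.mark.parametrize("events,trials", [(-1, 10), (11, 10), (0, 0), (1, 0)])
    def test_invalid_counts_rejected(self, events, trials):
        with pytest.raises(ValidationError):
            EventCount("bad", events, trials)

    def test_boundary_single_trial(self):
        assert EventCount("one", 1, 1).rate == 1.0


class TestBetaTypes:
    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.0), (math.inf, 1.0)])
    def test_beta_spec_requires_positive_finite_shapes(self, a, b):
        with pytest.raises(ValidationError):
            BetaSpec(a, b)

    def test_beta_spec_moments(self):
        s = BetaSpec(2.0, 50.0)
        assert s.mean == pytest.approx(2 / 52)
        assert s.variance == pytest.approx(2 * 50 / (52**2 * 53))

    def test_mixture_weights_must_normalize(self):
        with pytest.raises(ValidationError):
            BetaMixture(((0.5, BetaSpec(1, 1)), (0.6, BetaSpec(2, 2))))
        mix = BetaMixture(((0.25, BetaSpec(1, 3)), (0.75, BetaSpec(3, 1))))
        assert mix.mean == pytest.approx(0.25 * 0.25 + 0.75 * 0.75)


class TestCohortIO:
    def test_bundled_table_totals(self, cohort_table):
        mutant, wildtype = aggregate_groups(cohort_table)
        assert (mutant.events, mutant.trials) == (2, 329)
        assert (wildtype.events, wildtype.trials) == (0, 227)

    def test_tsv_dialect_autodetected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "cohort_id\tgroup\tstrain\ttrials\tevents\n"
            "a\tmutant\tX\t10\t1\nb\twildtype\tX\t20\t0\n"
        )
        table = read_cohort_table(path)
        mutant, wildtype = aggregate_groups(table)
        assert (mutant.events, mutant.trials, wildtype.trials) == (1, 10, 20)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValidationError):
            read_cohort_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("cohort_id,group,trials,events\na,mutant,10,1\n")
        with pytest.raises(ValidationError, match="strain"):
            read_cohort_table(path)

    def test_bad_row_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "cohort_id,group,strain,trials,events\nrow_bad,mutant,X,10,11\n"
        )
        with pytest.raises(ValidationError, match="row_bad"):
            read_cohort_table(path)

    def test_unknown_group_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("cohort_id,group,strain,trials,events\na,control,X,10,1\n")
        with pytest.raises(ValidationError, match="control"):
            read_cohort_table(path)

    def test_single_row_events_equal_trials(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("cohort_id,group,strain,trials,events\na,mutant,X,1,1\n")
        table = read_cohort_table(path)
        assert table.rows[0].events == table.rows[0].trials == 1

    def test_round_trip_preserves_counts(self, cohort_table, tmp_path):
        path = tmp_path / "rt.csv"
        write_cohort_table(cohort_table, path)
        again = read_cohort_table(path)
        assert [(r.cohort_id, r.events, r.trials) for r in again.rows] == [
            (r.cohort_id, r.events, r.trials) for r in cohort_table.rows
        ]


class TestAggregate:
    def test_missing_group_is_an_error(self):
        table = CohortTable((CohortRow("a", "mutant", "X", 54, 0),))
        with pytest.raises(ValidationError, match="wildtype"):
            aggregate_groups(table)

    def test_permutation_invariant(self, cohort_table):
        forward = aggregate_groups(cohort_table)
        reversed_ = aggregate_groups(CohortTable(tuple(reversed(cohort_table.rows))))
        assert forward == reversed_

    def test_duplicated_rows_double_the_sums(self, cohort_table):
        doubled_rows = cohort_table.rows + tuple(
            CohortRow(r.cohort_id + "_dup", r.group, r.strain, r.trials, r.events)
            for r in cohort_table.rows
        )
        mutant, wildtype = aggregate_groups(CohortTable(doubled_rows))
        assert (mutant.events, mutant.trials) == (4, 658)
        assert (wildtype.events, wildtype.trials) == (0, 454)


class TestHistoricalIO:
    def test_bundled_historical(self, historical):
        assert [(s.events, s.trials) for s in historical.studies] == [(0, 234), (0, 69)]
        assert historical.total_trials == 303
        assert all(s.follow_up_weeks > 0 for s in historical.studies)

    def test_follow_up_must_be_positive(self):
        with pytest.raises(ValidationError):
            HistoricalStudy("s", 0, 10, follow_up_weeks=0.0)


class TestReportIO:
    def test_round_trip_and_provenance(self, tmp_path):
        report = {
            "settings": McmcSettings(seed=99).to_dict(),
            "values": {"rd_mean": 0.007197131415926535, "p": 0.5159569641584031},
            "decisions": {"risk_difference": "fail to reject"},
        }
        path = tmp_path / "report.json"
        write_report(report, path)
        loaded = read_report(path)
        assert loaded["settings"]["seed"] == 99
        for key, val in report["values"].items():
            # full double precision survives the JSON round trip
            assert loaded["values"][key] == pytest.approx(val, rel=1e-12)
        assert loaded["decisions"]["risk_difference"] == "fail to reject"

    def test_numpy_scalars_serializable(self, tmp_path):
        path = tmp_path / "np.json"
        write_report({"x": np.float64(0.25), "arr": np.arange(3)}, path)
        assert read_report(path) == {"x": 0.25, "arr": [0, 1, 2]}


class TestMcmcSettings:
    def test_draw_bookkeeping(self):
        s = McmcSettings(chains=4, iterations=4000, warmup_fraction=0.5, thinning=1)
        assert s.warmup == 2000
        assert s.total_draws == 8000

    @pytest.mark.parametrize(
        "kwargs",
        [{"chains": 0}, {"iterations": 2}, {"warmup_fraction": 1.0}, {"thinning": 0}],
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValidationError):
            McmcSettings(**kwargs)
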