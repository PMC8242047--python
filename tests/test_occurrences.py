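import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fossilbd.occurrences import (
    CovariateCurve,
    FormatError,
    OccurrenceRecord,
    OccurrenceTable,
    StageGrid,
    ValidationError,
    default_stage_grid,
    read_occurrences,
    read_stage_table,
    rescale_covariate,
    resample_ages,
    summarize,
    write_occurrences,
)


class TestRecordInvariants:
    def test_age_order_enforced(self):
        with pytest.raises(ValidationError):
            OccurrenceRecord("X", 70.0, 66.0)

    def test_negative_age_rejected(self):
        with pytest.raises(ValidationError):
            OccurrenceRecord("X", -1.0, 5.0)

    def test_empty_taxon_rejected(self):
        with pytest.raises(ValidationError):
            OccurrenceRecord("", 1.0, 2.0)


class TestReadWrite:
    def _write(self, tmp_path, rows, header="taxon\tstatus\tmin_age\tmax_age"):
        p = tmp_path / "occ.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_three_rows_two_taxa_one_singleton(self, tmp_path):
        p = self._write(tmp_path, ["A\textinct\t66\t70",
                                   "A\textinct\t68\t71",
                                   "B\textinct\t70\t72"])
        t = read_occurrences(p)
        assert t.n_occurrences == 3
        assert t.n_taxa == 2
        assert t.singletons == ["B"]

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("name\tage\nA\t66\n")
        with pytest.raises(FormatError):
            read_occurrences(p)

    def test_inverted_ages_reported_with_row(self, tmp_path):
        p = self._write(tmp_path, ["A\textinct\t70\t66"])
        with pytest.raises(ValidationError, match="row 1"):
            read_occurrences(p)

    def test_round_trip(self, tmp_path, toy_table):
        p = tmp_path / "rt.tsv"
        write_occurrences(toy_table, p)
        back = read_occurrences(p, name=toy_table.name)
        assert back.records == toy_table.records

    def test_pyrate_style_columns(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("Species\tStatus\tmin_age\tmax_age\n"
                     "T_rex\textinct\t66\t68\n")
        t = read_occurrences(p, dialect="pyrate_style")
        assert t.taxa == ["T_rex"]


class TestSummaries:
    def test_single_taxon_four_records(self):
        t = OccurrenceTable([OccurrenceRecord("A", 60 + i, 61 + i)
                             for i in range(4)])
        s = summarize(t)
        assert s["n_occurrences"] == 4
        assert s["n_taxa"] == 1
        assert s["n_singletons"] == 0
        assert s["mean_occurrences_per_taxon"] == 4.0

    def test_empty_table_errors(self):
        with pytest.raises(ValidationError):
            summarize(OccurrenceTable([]))

    def test_region_filter_partitions(self, toy_table):
        parts = [len(toy_table.filter(region=r))
                 for r in ("new_world", "old_world", "other")]
        assert sum(parts) == len(toy_table)


class TestResampleAges:
    def test_degenerate_interval_fixed(self):
        t = OccurrenceTable([OccurrenceRecord("A", 67.5, 67.5)])
        for rep in resample_ages(t, 5, seed=0):
            assert rep.ages[0] == 67.5

    def test_bounds_respected(self):
        t = OccurrenceTable([OccurrenceRecord("A", 66.0, 72.1)])
        for rep in resample_ages(t, 50, seed=3):
            assert 66.0 <= rep.ages[0] <= 72.1

    def test_uniform_distribution_ks(self):
        t = OccurrenceTable([OccurrenceRecord("A", 66.0, 72.1)])
        draws = np.array([r.ages[0] for r in resample_ages(t, 1000, seed=7)])
        p = stats.kstest(draws, stats.uniform(66.0, 72.1 - 66.0).cdf).pvalue
        assert p > 0.01

    def test_seed_determinism_and_divergence(self, toy_table):
        a = resample_ages(toy_table, 3, seed=11)
        b = resample_ages(toy_table, 3, seed=11)
        c = resample_ages(toy_table, 3, seed=12)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.ages, y.ages)
        assert not np.allclose(a[0].ages, c[0].ages)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_bit_reproducible_property(self, seed):
        t = OccurrenceTable([OccurrenceRecord("A", 60.0, 70.0),
                             OccurrenceRecord("B", 65.0, 65.0)])
        x = resample_ages(t, 2, seed=seed)
        y = resample_ages(t, 2, seed=seed)
        for a, b in zip(x, y):
            np.testing.assert_array_equal(a.ages, b.ages)

    def test_per_taxon_mode_shares_quantile(self):
        t = OccurrenceTable([OccurrenceRecord("A", 60.0, 70.0),
                             OccurrenceRecord("A", 50.0, 60.0)])
        rep = resample_ages(t, 1, seed=4, per="taxon")[0]
        u0 = (rep.ages[0] - 60.0) / 10.0
        u1 = (rep.ages[1] - 50.0) / 10.0
        assert u0 == pytest.approx(u1)


class TestStageGrid:
    def test_boundary_goes_to_younger_stage(self, stage_grid):
        j = stage_grid.stage_index(72.1)
        assert stage_grid.labels[j] == "Maastrichtian"

    def test_interior_age(self, stage_grid):
        assert stage_grid.labels[stage_grid.stage_index(70.0)] \
            == "Maastrichtian"
        assert stage_grid.labels[stage_grid.stage_index(80.0)] == "Campanian"

    def test_oldest_bin_closed(self, stage_grid):
        assert stage_grid.stage_index(stage_grid.oldest) == 0

    def test_outside_span_errors(self, stage_grid):
        with pytest.raises(ValidationError):
            stage_grid.stage_index(stage_grid.oldest + 1.0)

    def test_overlaps_sum_to_interval(self, stage_grid):
        ov = stage_grid.overlaps(90.0, 70.0)
        assert ov.sum() == pytest.approx(20.0)

    def test_read_stage_table(self, tmp_path):
        p = tmp_path / "stages.tsv"
        p.write_text("stage\tbase_age\ttop_age\n"
                     "Camp\t83.6\t72.1\nMaas\t72.1\t66.0\n")
        g = read_stage_table(p)
        assert g.labels == ["Camp", "Maas"]
        np.testing.assert_allclose(g.boundaries, [83.6, 72.1, 66.0])


class TestCovariates:
    def test_constant_curve_zeroed(self):
        c = CovariateCurve(np.array([100.0, 80.0, 60.0]),
                           np.array([5.0, 5.0, 5.0]))
        z = rescale_covariate(c, (100, 60), 0.1)
        assert np.all(z.values == 0.0)

    def test_ramp_grid_size(self):
        c = CovariateCurve(np.array([100.0, 66.0]), np.array([0.0, 34.0]))
        z = rescale_covariate(c, (100, 66), 0.1)
        assert len(z.ages) == 341

    def test_zscore_definition(self):
        ages = np.arange(100.0, 59.9, -1.0)
        c = CovariateCurve(ages, np.sin(ages / 3.0))
        z = rescale_covariate(c, (95, 65), 0.1)
        assert abs(z.values.mean()) < 1e-12
        assert z.values.std() == pytest.approx(1.0)

    def test_window_outside_support(self):
        c = CovariateCurve(np.array([90.0, 70.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValidationError):
            rescale_covariate(c, (100, 60), 0.1)
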