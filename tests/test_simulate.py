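import numpy as np
import pytest
from scipy import stats

from fossilbd.occurrences import CovariateCurve, default_stage_grid
from fossilbd.preservation import PreservationModel
from fossilbd.simulate import (
    SimulationRegime,
    impose_age_uncertainty,
    read_truth,
    sample_fossils,
    simulate_history,
    write_truth,
)
from tests.conftest import find_history


class TestSimulateHistory:
    def test_zero_extinction_all_extant(self):
        reg = SimulationRegime(kind="piecewise", origin_age=80, end_age=60,
                               lam=[0.1], mu=[0.0], shift_times=[])
        h = simulate_history(reg, seed=4)
        assert h.extant.all()
        assert np.all(h.te == 60.0)

    def test_seed_determinism(self):
        reg = SimulationRegime(kind="piecewise", origin_age=90, end_age=60,
                               lam=[0.2], mu=[0.1], shift_times=[])
        a = simulate_history(reg, seed=42)
        b = simulate_history(reg, seed=42)
        np.testing.assert_array_equal(a.ts, b.ts)
        np.testing.assert_array_equal(a.te, b.te)

    def test_single_origin_conservation(self):
        reg = SimulationRegime(kind="piecewise", origin_age=90, end_age=50,
                               lam=[0.25], mu=[0.1], shift_times=[])
        h = find_history(reg, 20, 500)
        assert np.sum(h.parent >= 0) == h.n_species - 1
        assert np.sum(h.parent == -1) == 1

    def test_weibull_shape_one_is_exponential(self):
        reg = SimulationRegime(kind="age_dependent", origin_age=300,
                               end_age=0.0, lam0=0.08, weibull_shape=1.0,
                               weibull_scale=5.0, min_species=1)
        longs = []
        s = 0
        while len(longs) < 10_000:
            h = simulate_history(reg, seed=s)
            longs.extend(h.longevities()[~h.extant])
            s += 1
        longs = np.array(longs[:10_000])
        se = longs.std() / np.sqrt(len(longs))
        assert abs(longs.mean() - 5.0) < 3 * se

    def test_piecewise_trajectory_rises_then_falls(self):
        # mean diversity should rise before the 76 Ma shift and decline after
        reg = SimulationRegime(kind="piecewise", origin_age=96, end_age=56,
                               lam=[0.2, 0.1], mu=[0.05, 0.3],
                               shift_times=[76.0], min_species=1)
        pre, post = [], []
        for s in range(500):
            h = simulate_history(reg, seed=s)
            pre.append(h.diversity(77.0) - h.diversity(90.0))
            post.append(h.diversity(60.0) - h.diversity(75.0))
        # sign test: growth before the shift, decline after
        pre = np.array(pre)
        post = np.array(post)
        p_pre = stats.binomtest((pre > 0).sum(), (pre != 0).sum(),
                                alternative="greater").pvalue
        p_post = stats.binomtest((post < 0).sum(), (post != 0).sum(),
                                 alternative="greater").pvalue
        assert p_pre < 0.01
        assert p_post < 0.01

    def test_diversity_cap_aborts(self):
        reg = SimulationRegime(kind="piecewise", origin_age=500, end_age=0,
                               lam=[0.5], mu=[0.0], shift_times=[])
        with pytest.raises(RuntimeError, match="cap"):
            simulate_history(reg, seed=1)

    def test_covariate_g_zero_matches_piecewise(self):
        ages = np.arange(100.0, 59.9, -0.5)
        cov = CovariateCurve(ages, np.sin(ages / 3.0), "x")
        reg_cov = SimulationRegime(kind="covariate_linked", origin_age=95,
                                   end_age=65, lam0=0.2, mu0=0.15,
                                   g_lam=[0.0], g_mu=[0.0],
                                   covariates=[cov], min_species=1)
        reg_pw = SimulationRegime(kind="piecewise", origin_age=95,
                                  end_age=65, lam=[0.2], mu=[0.15],
                                  shift_times=[], min_species=1)
        a, b = [], []
        for s in range(400):
            a.extend(simulate_history(reg_cov, seed=s).longevities())
            b.extend(simulate_history(reg_pw, seed=10_000 + s).longevities())
        p = stats.ks_2samp(np.array(a)[:1000], np.array(b)[:1000]).pvalue
        assert p > 0.01

    def test_rejection_gives_min_species(self):
        reg = SimulationRegime(kind="piecewise", origin_age=90, end_age=80,
                               lam=[0.05], mu=[0.3], shift_times=[])
        h = simulate_history(reg, seed=0)
        assert h.n_species >= 2


class TestSampleFossils:
    def test_expected_count_hpp(self):
        # q=0.5, lifespan 10 -> Poisson mean 5 per species
        from fossilbd.simulate import TrueHistory
        n = 10_000
        h = TrueHistory(ts=np.full(n, 20.0), te=np.full(n, 10.0),
                        extant=np.zeros(n, bool), parent=np.full(n, -1))
        tab = sample_fossils(h, PreservationModel(kind="HPP", q=0.5), seed=3)
        counts = np.zeros(n)
        per = tab.counts_per_taxon()
        names = h.taxon_names()
        for i, nm in enumerate(names):
            counts[i] = per.get(nm, 0)
        se = counts.std() / np.sqrt(n)
        assert abs(counts.mean() - 5.0) < 3 * se

    def test_vanishing_rate_empty_table(self):
        from fossilbd.simulate import TrueHistory
        h = TrueHistory(ts=np.array([20.0]), te=np.array([10.0]),
                        extant=np.array([False]), parent=np.array([-1]))
        tab = sample_fossils(h, PreservationModel(kind="HPP", q=1e-9), seed=1)
        assert len(tab) == 0

    def test_tpp_zero_stage_has_no_occurrences(self, stage_grid):
        from fossilbd.simulate import TrueHistory
        q = np.full(stage_grid.n_stages, 2.0)
        dead = stage_grid.labels.index("Campanian")
        q[dead] = 0.0
        n = 300
        h = TrueHistory(ts=np.full(n, 95.0), te=np.full(n, 67.0),
                        extant=np.zeros(n, bool), parent=np.full(n, -1))
        tab = sample_fossils(h, PreservationModel(kind="TPP", q=q,
                                                  grid=stage_grid), seed=2)
        ages = tab.min_ages()
        in_camp = (ages <= 83.6) & (ages > 72.1)
        assert not in_camp.any()
        assert len(tab) > 0


class TestAgeUncertainty:
    def test_maastrichtian_interval(self, stage_grid):
        from fossilbd.occurrences import OccurrenceRecord, OccurrenceTable
        t = OccurrenceTable([OccurrenceRecord("A", 70.0, 70.0)])
        out = impose_age_uncertainty(t, stage_grid)
        assert out.records[0].max_age == pytest.approx(72.1)
        assert out.records[0].min_age == pytest.approx(66.0)

    def test_boundary_age_younger_stage(self, stage_grid):
        from fossilbd.occurrences import OccurrenceRecord, OccurrenceTable
        t = OccurrenceTable([OccurrenceRecord("A", 72.1, 72.1)])
        out = impose_age_uncertainty(t, stage_grid)
        # 72.1 is the Maastrichtian base: assigned to the younger stage
        assert out.records[0].max_age == pytest.approx(72.1)
        assert out.records[0].min_age == pytest.approx(66.0)

    def test_true_age_always_inside_interval(self, stage_grid):
        from fossilbd.occurrences import resample_ages
        reg = SimulationRegime(kind="piecewise", origin_age=100, end_age=66,
                               lam=[0.2], mu=[0.1], shift_times=[])
        h = find_history(reg, 20, 300)
        tab = sample_fossils(h, PreservationModel(kind="HPP", q=2.0), seed=8)
        true_ages = tab.min_ages()
        blurred = impose_age_uncertainty(tab, stage_grid)
        lo = blurred.min_ages()
        hi = blurred.max_ages()
        assert np.all((true_ages >= lo) & (true_ages <= hi))
        rep = resample_ages(blurred, 1, seed=1)[0]
        assert np.all((rep.ages >= lo) & (rep.ages <= hi))


class TestTruthIO:
    def test_round_trip(self, tmp_path, constant_clade):
        p = tmp_path / "truth.tsv"
        write_truth(constant_clade, p)
        df = read_truth(p)
        np.testing.assert_allclose(df["ts"].to_numpy(), constant_clade.ts)
        np.testing.assert_allclose(df["te"].to_numpy(), constant_clade.te)


class TestRecoveredDiversityIdentity:
    def test_trajectory_matches_simulator_counts(self, constant_clade):
        from fossilbd.episodic import LineageTimes, diversity_trajectory
        h = constant_clade
        lt = LineageTimes(h.ts, h.te, h.extant)
        grid_ages = np.arange(float(h.ts.max()), float(h.te.min()), -1.0)
        div = diversity_trajectory([lt], step=1.0,
                                   span=(float(h.ts.max()),
                                         float(h.te.min())))
        expected = h.diversity(div.ages)
        np.testing.assert_array_equal(div.counts[0], expected)
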