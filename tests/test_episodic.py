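import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fossilbd.episodic import (
    LineageTimes,
    ShiftConfiguration,
    _EpisodicSampler,
    _OccData,
    bd_log_likelihood,
    bdmcmc_sample,
    diversity_trajectory,
    rates_through_time,
    rjmcmc_sample,
    update_lineage_times,
)

# B=2, D=1, S=30 in a single interval with lam=0.2, mu=0.1
BD_ORACLE = 2 * np.log(0.2) + np.log(0.1) - (0.2 + 0.1) * 30.0


def _three_species_times():
    # root ts=14 (no speciation event); births at 10 and 8; one death at 2
    return LineageTimes([14.0, 10.0, 8.0], [0.0, 2.0, 0.0],
                        [True, False, True])


def _small_ages(n=12, k=3, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        lo = rng.uniform(55, 70)
        out[f"s{i}"] = np.sort(lo + rng.uniform(0, 8, size=k))[::-1]
    return out


class TestBdLogLikelihood:
    def test_closed_form(self):
        t = _three_species_times()
        c = ShiftConfiguration(np.array([]), [0.2], [0.1])
        assert bd_log_likelihood(t, c) == pytest.approx(BD_ORACLE, abs=1e-10)
        assert bd_log_likelihood(t, c) == pytest.approx(-14.5214, abs=1e-4)

    def test_equal_rates_identity(self):
        # lam = mu with B = D = 1: log L = B(log lam + log mu) - 2 lam S
        t = LineageTimes([14.0, 10.0], [2.0, 5.0], [False, True])
        lam = 0.3
        c = ShiftConfiguration(np.array([]), [lam], [lam])
        S = (14.0 - 2.0) + (10.0 - 5.0)
        expected = 1 * (np.log(lam) + np.log(lam)) - 2 * lam * S
        assert bd_log_likelihood(t, c) == pytest.approx(expected, abs=1e-10)

    @given(st.floats(min_value=3.0, max_value=11.0))
    @settings(max_examples=25, deadline=None)
    def test_refinement_invariance(self, split):
        t = _three_species_times()
        c0 = ShiftConfiguration(np.array([]), [0.23], [0.12])
        c1 = ShiftConfiguration(np.array([split]), [0.23, 0.23],
                                [0.12, 0.12])
        assert bd_log_likelihood(t, c1) == pytest.approx(
            bd_log_likelihood(t, c0), abs=1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ShiftConfiguration(np.array([]), [-0.1], [0.1])


class TestUpdateLineageTimes:
    def test_hard_constraints_hold(self):
        ages = _small_ages()
        data = _OccData(ages)
        t = LineageTimes(data.oldest + 0.5,
                         np.maximum(data.youngest - 0.5, 0.0))
        for sweep in range(30):
            t = update_lineage_times(t, ages, q=2.0, seed=sweep)
            assert np.all(t.ts >= data.oldest)
            assert np.all(t.te <= data.youngest)
            assert np.all(t.ts > t.te)

    def test_high_q_pins_ts_to_oldest_occurrence(self):
        ages = _small_ages()
        data = _OccData(ages)
        t = LineageTimes(data.oldest + 0.5,
                         np.maximum(data.youngest - 0.5, 0.0))
        samples = []
        for sweep in range(300):
            t = update_lineage_times(t, ages, q=100.0, seed=sweep,
                                     window=0.2)
            if sweep > 100:
                samples.append(t.ts.copy())
        gap = np.mean(samples, axis=0) - data.oldest
        assert np.all(gap < 0.05)


class TestSamplers:
    def test_seed_determinism(self):
        ages = _small_ages()
        a = rjmcmc_sample(ages, iterations=2000, sampling_freq=50, seed=9)
        b = rjmcmc_sample(ages, iterations=2000, sampling_freq=50, seed=9)
        assert a.log_post == b.log_post
        for x, y in zip(a.lam, b.lam):
            np.testing.assert_array_equal(x, y)

    def test_single_iteration_returns_initial_state(self):
        ages = _small_ages()
        tr = bdmcmc_sample(ages, iterations=1, sampling_freq=1, seed=3)
        assert tr.n_samples >= 1
        np.testing.assert_allclose(tr.lam[0], [0.2])
        np.testing.assert_allclose(tr.mu[0], [0.1])
        assert len(tr.shifts_l[0]) == 0

    def test_posterior_times_bracket_occurrences(self):
        ages = _small_ages()
        data = _OccData(ages)
        tr = rjmcmc_sample(ages, iterations=3000, sampling_freq=30, seed=2)
        for i in range(tr.n_samples):
            assert np.all(tr.ts[i] >= data.oldest)
            assert np.all(tr.te[i] <= data.youngest)

    @pytest.mark.parametrize("algorithm,iters", [("rjmcmc", 30_000),
                                                 ("bdmcmc", 8_000)])
    def test_prior_only_shift_count_is_poisson(self, algorithm, iters):
        ages = _small_ages(n=8, k=2)
        data = _OccData(ages)
        ft = LineageTimes(data.oldest + 0.5,
                          np.maximum(data.youngest - 0.5, 0.0))
        s = _EpisodicSampler(data, "HPP", None, iters, 10, 1, 1.0,
                             algorithm, fix_times=ft, prior_only=True)
        tr = s.run()
        b = tr.burn_in()
        k = np.concatenate([tr.k_lambda()[b:], tr.k_mu()[b:]])
        assert abs(k.mean() - 1.0) < 0.25
        p0 = np.mean(k == 0)
        assert abs(p0 - np.exp(-1)) < 0.1

    def test_constant_rate_recovery_and_coverage(self, constant_dataset):
        h, table, rep = constant_dataset
        tr = rjmcmc_sample(rep, iterations=15_000, sampling_freq=25, seed=6)
        b = tr.burn_in()
        kl, km = tr.k_lambda()[b:], tr.k_mu()[b:]
        assert np.bincount(kl).argmax() == 0
        assert np.bincount(km).argmax() == 0
        r = rates_through_time(tr)
        # posterior mean lambda within 20% of the true 0.15
        assert abs(r.lam_mean.mean() - 0.15) < 0.2 * 0.15
        # identity: net = lambda - mu at every grid point
        np.testing.assert_allclose(r.net_mean, r.lam_mean - r.mu_mean,
                                   atol=1e-12)
        # true Ts inside the 95% credible interval for >= 90% of species
        TS = np.array([tr.ts[i] for i in range(b, tr.n_samples)])
        lo = np.percentile(TS, 2.5, axis=0)
        hi = np.percentile(TS, 97.5, axis=0)
        truth = {f"{h.clade_id}_sp{i}": h.ts[i]
                 for i in range(h.n_species)}
        tv = np.array([truth[t] for t in tr.taxa])
        assert np.mean((tv >= lo) & (tv <= hi)) >= 0.9

    def test_samplers_agree_on_marginal_rates(self, constant_dataset):
        _, _, rep = constant_dataset
        t1 = rjmcmc_sample(rep, iterations=15_000, sampling_freq=25, seed=6)
        t2 = bdmcmc_sample(rep, iterations=15_000, sampling_freq=25, seed=7)
        span = (110.0, 15.0)
        r1 = rates_through_time(t1, span=span)
        r2 = rates_through_time(t2, span=span)
        diff = np.abs(r1.lam_mean - r2.lam_mean).mean()
        assert diff < 0.1 * r1.lam_mean.mean()

    def test_trace_tsv(self, tmp_path):
        ages = _small_ages()
        tr = rjmcmc_sample(ages, iterations=1000, sampling_freq=100, seed=1)
        p = tmp_path / "trace.tsv"
        tr.write(p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t")
        for col in ("iteration", "posterior", "likelihood",
                    "n_shifts_lambda", "n_shifts_mu"):
            assert col in df.columns
        assert len(df) == tr.n_samples


class TestDiversityTrajectory:
    def test_direct_count(self):
        # D(t) = #{i: Te_i <= t < Ts_i}; at t=73 the (72, 66) species is
        # not yet born, so two of three lineages are alive
        t = LineageTimes([80.0, 75.0, 72.0], [70.0, 66.0, 66.0])
        div = diversity_trajectory([t], step=1.0, span=(85.0, 66.0))
        at73 = div.counts[0][np.argmin(np.abs(div.ages - 73.0))]
        assert at73 == 2
        at71 = div.counts[0][np.argmin(np.abs(div.ages - 71.0))]
        assert at71 == 3

    def test_zero_before_origin(self):
        t = LineageTimes([80.0, 75.0], [70.0, 66.0])
        div = diversity_trajectory([t], step=1.0, span=(90.0, 66.0))
        assert div.counts[0][np.argmin(np.abs(div.ages - 88.0))] == 0

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            diversity_trajectory([])

    def test_decline_iff_excess_extinction(self):
        # count identity: D decreases over an interval iff extinctions
        # exceed speciations within it
        rng = np.random.default_rng(0)
        ts = np.sort(rng.uniform(60, 90, 40))[::-1]
        te = np.maximum(ts - rng.exponential(8, 40), 30.0)
        te = np.minimum(te, ts - 1e-3)
        t = LineageTimes(ts, te)
        a, b = 75.0, 65.0
        d_a = int(np.sum((te <= a) & (a < ts)))
        d_b = int(np.sum((te <= b) & (b < ts)))
        births = int(np.sum((ts <= a) & (ts > b)))
        deaths = int(np.sum((te <= a) & (te > b)))
        assert d_b - d_a == births - deaths
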