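"""Episodic (piecewise-constant) birth-death inference from occurrences.

Joint Bayesian estimation of per-species speciation/extinction times
(Ts, Te), preservation rates, and piecewise-constant speciation and
extinction rates with an unknown number of shifts.  Two trans-dimensional
samplers are provided over the shift configurations:

* ``rjmcmc_sample`` — reversible-jump MCMC with add/remove/move-shift
  moves and Green's acceptance ratio;
* ``bdmcmc_sample`` — a continuous-time birth-death process over shift
  points (Stephens-style jump process) with death rates derived from the
  likelihood ratio.

Rates are events / lineage / Myr; ages are Ma.  The first 10% of samples
are treated as burn-in by the summary helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .occurrences import AgeResampledDataset, StageGrid
from .preservation import _log1mexp, gamma_multipliers

__all__ = [
    "LineageTimes",
    "ShiftConfiguration",
    "EpisodicTrace",
    "bd_log_likelihood",
    "rjmcmc_sample",
    "bdmcmc_sample",
    "update_lineage_times",
    "rates_through_time",
    "diversity_trajectory",
    "DiversityTrajectory",
    "RateThroughTimeSummary",
]

# priors (documented defaults; see module docstring)
RATE_PRIOR_SHAPE = 1.1
RATE_PRIOR_RATE = 1.0
SHIFT_POISSON_MEAN = 1.0
Q_PRIOR_SHAPE = 1.01
Q_PRIOR_RATE = 0.1


@dataclass
class LineageTimes:
    """Per-species speciation/extinction ages (Ma), extant flags."""

    ts: np.ndarray
    te: np.ndarray
    extant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        if self.extant is None:
            self.extant = np.zeros(len(self.ts), dtype=bool)
        self.extant = np.asarray(self.extant, dtype=bool)
        if np.any(self.ts <= self.te):
            raise ValueError("require Ts > Te")
        if np.any(self.te < 0):
            raise ValueError("require Te >= 0")


@dataclass
class ShiftConfiguration:
    """Piecewise-constant rates: |lam| = |mu| = |shift_times| + 1."""

    shift_times: np.ndarray
    lam: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.shift_times = np.asarray(self.shift_times, dtype=float)
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        if np.any(np.diff(self.shift_times) >= 0):
            raise ValueError("shift times must be strictly decreasing")
        k = len(self.shift_times)
        if len(self.lam) != k + 1 or len(self.mu) != k + 1:
            raise ValueError("need |shift_times| + 1 rates")
        if np.any(self.lam <= 0) or np.any(self.mu <= 0):
            raise ValueError("rates must be > 0")

    def rates_at(self, ages) -> tuple[np.ndarray, np.ndarray]:
        j = np.searchsorted(-self.shift_times, -np.asarray(ages, float),
                            side="right")
        return self.lam[j], self.mu[j]


def _interval_index(ages: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Interval of each age; a boundary age belongs to the younger side."""
    # shifts decreasing; interval j spans (shifts[j], shifts[j-1]]
    return np.searchsorted(-shifts, -ages, side="right")


def _interval_stats(ts, te, extant, shifts):
    """(B, D, S) per interval for one rate dimension's shift set."""
    k = len(shifts)
    edges_old = np.concatenate([[np.inf], shifts])
    edges_yng = np.concatenate([shifts, [-np.inf]])
    root = int(np.argmax(ts))
    b_ages = np.delete(ts, root)
    B = np.bincount(_interval_index(b_ages, shifts), minlength=k + 1)
    d_ages = te[~extant]
    D = np.bincount(_interval_index(d_ages, shifts), minlength=k + 1)
    lo = np.maximum(edges_yng[None, :], te[:, None])
    hi = np.minimum(edges_old[None, :], ts[:, None])
    S = np.maximum(0.0, hi - lo).sum(axis=0)
    return B, D, S


def _bd_ll_one(ts, te, extant, shifts, rates, events_B):
    """Sum over intervals of B log r - r S for one rate dimension."""
    # computed jointly for lambda and mu in bd_log_likelihood; helper for
    # samplers that keep separate shift sets per dimension
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    k = len(shifts)
    edges_old = np.concatenate([[np.inf], shifts])
    edges_yng = np.concatenate([shifts, [-np.inf]])
    if events_B:
        root = int(np.argmax(ts))
        ages = np.delete(ts, root)
    else:
        ages = te[~extant]
    E = np.bincount(_interval_index(ages, shifts), minlength=k + 1)
    lo = np.maximum(edges_yng[None, :], te[:, None])
    hi = np.minimum(edges_old[None, :], ts[:, None])
    S = np.maximum(0.0, hi - lo).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = np.where(E > 0, E * np.log(rates), 0.0)
    return float(np.sum(ev - rates * S))


def bd_log_likelihood(times: LineageTimes,
                      config: ShiftConfiguration) -> float:
    """Augmented-data birth-death log-likelihood.

    Sum over intervals j of B_j log(lam_j) + D_j log(mu_j)
    - (lam_j + mu_j) S_j, with B_j the speciation events (the single
    origin excluded), D_j the extinction events of non-extant species and
    S_j the summed lineage duration in interval j.
    """
    B, D, S = _interval_stats(times.ts, times.te, times.extant,
                              config.shift_times)
    if np.any(config.lam <= 0) or np.any(config.mu <= 0):
        raise ValueError("rates must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = np.where(B > 0, B * np.log(config.lam), 0.0) \
            + np.where(D > 0, D * np.log(config.mu), 0.0)
    return float(np.sum(ev - (config.lam + config.mu) * S))


# ---------------------------------------------------------------------------
# internal vectorized preservation likelihood on augmented times
# ---------------------------------------------------------------------------

class _OccData:
    """Flattened per-taxon occurrence data for fast likelihood evaluation."""

    def __init__(self, ages_by_taxon: dict[str, np.ndarray],
                 extant: dict[str, bool] | None = None,
                 grid: StageGrid | None = None) -> None:
        self.taxa = list(ages_by_taxon)
        self.n = len(self.taxa)
        ages, tix = [], []
        for i, t in enumerate(self.taxa):
            a = np.asarray(ages_by_taxon[t], dtype=float)
            ages.append(a)
            tix.append(np.full(len(a), i))
        self.occ = np.concatenate(ages) if ages else np.array([])
        self.tix = np.concatenate(tix).astype(int) if tix else np.array([], int)
        self.k = np.bincount(self.tix, minlength=self.n).astype(float)
        if np.any(self.k < 1):
            raise ValueError("every taxon needs >= 1 occurrence")
        self.oldest = np.array([a.max() for a in ages])
        self.youngest = np.array([a.min() for a in ages])
        self.extant = np.array(
            [bool(extant.get(t, False)) if extant else False
             for t in self.taxa])
        self.grid = grid
        if grid is not None:
            j = grid.stage_index(self.occ)
            self.stage_counts = np.zeros((self.n, grid.n_stages))
            np.add.at(self.stage_counts, (self.tix, j), 1.0)

    def span(self) -> tuple[float, float]:
        return float(self.oldest.max()), float(max(self.youngest.min(), 0.0))


def _pres_ll_terms(data: _OccData, ts, te, kind, q, gamma_alpha=None,
                   n_categories: int = 4) -> np.ndarray:
    """Per-taxon preservation log-likelihood terms, vectorized."""
    d = ts - te
    if kind == "TPP":
        grid = data.grid
        base, top = grid.boundaries[:-1], grid.boundaries[1:]
        lo = np.maximum(top[None, :], te[:, None])
        hi = np.minimum(base[None, :], ts[:, None])
        ov = np.maximum(0.0, hi - lo)
        qv = np.asarray(q, dtype=float)
        Lam = ov @ qv
        with np.errstate(divide="ignore", invalid="ignore"):
            ev = data.stage_counts @ np.log(qv)
    else:
        Lam = q * d
        ev = data.k * np.log(q)
        if kind == "NHPP":
            u = (ts[data.tix] - data.occ) / d[data.tix]
            with np.errstate(divide="ignore", invalid="ignore"):
                sh = np.log(6.0 * u * (1.0 - u))
            ev = ev + np.bincount(data.tix, weights=sh, minlength=data.n)
    if gamma_alpha is None:
        return ev - Lam - _log1mexp(Lam)
    m = gamma_multipliers(gamma_alpha, n_categories)
    mat = (ev[:, None] + data.k[:, None] * np.log(m)[None, :]
           - Lam[:, None] * m[None, :]
           - _log1mexp(Lam[:, None] * m[None, :]))
    return special.logsumexp(mat, axis=1) - np.log(len(m))


def _pres_ll_vec(data: _OccData, ts, te, kind, q, gamma_alpha=None,
                 n_categories: int = 4) -> float:
    """Preservation log-likelihood summed over taxa."""
    return float(np.sum(_pres_ll_terms(data, ts, te, kind, q, gamma_alpha,
                                       n_categories)))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _log_rate_prior(rates: np.ndarray) -> float:
    return float(np.sum(stats.gamma.logpdf(rates, RATE_PRIOR_SHAPE,
                                           scale=1.0 / RATE_PRIOR_RATE)))


@dataclass
class EpisodicTrace:
    """Thinned posterior samples from an episodic birth-death run."""

    iterations: list[int] = field(default_factory=list)
    log_post: list[float] = field(default_factory=list)
    log_lik: list[float] = field(default_factory=list)
    shifts_l: list[np.ndarray] = field(default_factory=list)
    lam: list[np.ndarray] = field(default_factory=list)
    shifts_m: list[np.ndarray] = field(default_factory=list)
    mu: list[np.ndarray] = field(default_factory=list)
    q: list[np.ndarray] = field(default_factory=list)
    ts: list[np.ndarray] = field(default_factory=list)
    te: list[np.ndarray] = field(default_factory=list)
    taxa: list[str] = field(default_factory=list)
    algorithm: str = "rjmcmc"
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.iterations)

    def burn_in(self, fraction: float = 0.1) -> int:
        return int(np.floor(self.n_samples * fraction))

    def k_lambda(self) -> np.ndarray:
        return np.array([len(s) for s in self.shifts_l])

    def k_mu(self) -> np.ndarray:
        return np.array([len(s) for s in self.shifts_m])

    def post_burnin_indices(self, fraction: float = 0.1) -> range:
        return range(self.burn_in(fraction), self.n_samples)

    def mean_times(self, fraction: float = 0.1) -> LineageTimes:
        idx = list(self.post_burnin_indices(fraction))
        ts = np.mean([self.ts[i] for i in idx], axis=0)
        te = np.mean([self.te[i] for i in idx], axis=0)
        return LineageTimes(ts, te)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_samples):
            rows.append({
                "iteration": self.iterations[i],
                "posterior": self.log_post[i],
                "likelihood": self.log_lik[i],
                "n_shifts_lambda": len(self.shifts_l[i]),
                "n_shifts_mu": len(self.shifts_m[i]),
                "mean_lambda": float(np.mean(self.lam[i])),
                "mean_mu": float(np.mean(self.mu[i])),
                "mean_q": float(np.mean(self.q[i])),
                "root_age": float(np.max(self.ts[i])),
            })
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class _AdaptiveScale:
    """Multiplicative tuning toward a 20-40% acceptance window."""

    def __init__(self, scale: float, window: int = 50) -> None:
        self.scale = scale
        self.window = window
        self.tried = 0
        self.accepted = 0
        self.frozen = False

    def update(self, accepted: bool) -> None:
        self.update_batch(int(accepted), 1)

    def update_batch(self, accepted: int, tried: int) -> None:
        if self.frozen:
            return
        self.tried += tried
        self.accepted += accepted
        if self.tried >= self.window:
            rate = self.accepted / self.tried
            if rate < 0.2:
                self.scale *= 0.8
            elif rate > 0.4:
                self.scale *= 1.25
            self.tried = 0
            self.accepted = 0


class _CumRate:
    """Cumulative integral of a piecewise rate along the age axis."""

    def __init__(self, shifts: np.ndarray, rates: np.ndarray) -> None:
        # edges ascending in age; interval i has rate r_asc[i]
        self.edges = np.concatenate([[0.0], shifts[::-1]])
        self.r_asc = rates[::-1]
        steps = self.r_asc[:-1] * np.diff(self.edges)
        self.G = np.concatenate([[0.0], np.cumsum(steps)])

    def __call__(self, ages: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(self.edges, ages, side="right") - 1,
                    0, len(self.r_asc) - 1)
        return self.G[i] + self.r_asc[i] * (ages - self.edges[i])


class _EpisodicSampler:
    def __init__(self, data: _OccData, pres_kind: str, gamma_alpha,
                 iterations: int, sampling_freq: int, seed: int,
                 epsilon: float, algorithm: str,
                 fix_times: LineageTimes | None = None,
                 prior_only: bool = False) -> None:
        self.prior_only = prior_only
        if iterations < sampling_freq:
            raise ValueError("iterations must be >= sampling_freq")
        self.data = data
        self.kind = pres_kind
        self.gamma_alpha = gamma_alpha
        self.iterations = iterations
        self.sampling_freq = sampling_freq
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.epsilon = epsilon
        self.algorithm = algorithm
        self.fix_times = fix_times is not None

        old, yng = data.span()
        self.span = (old + 5.0, max(yng - 2.0, 0.0))
        self.span_len = self.span[0] - self.span[1]

        # state
        if fix_times is not None:
            self.ts = fix_times.ts.copy()
            self.te = fix_times.te.copy()
        else:
            self.ts = data.oldest + 0.5 + 0.1 * self.rng.random(data.n)
            self.te = np.where(data.extant, 0.0,
                               np.maximum(data.youngest - 0.5
                                          - 0.1 * self.rng.random(data.n),
                                          0.0))
            bad = self.te >= data.youngest
            self.te[bad] = data.youngest[bad] * 0.5
        self.shifts_l = np.array([])
        self.lam = np.array([0.2])
        self.shifts_m = np.array([])
        self.mu = np.array([0.1])
        if pres_kind == "TPP":
            self.q = np.full(data.grid.n_stages, 1.0)
        else:
            self.q = np.array([1.0])

        self.sc_times = _AdaptiveScale(1.0)
        self.sc_rate = _AdaptiveScale(0.5)
        self.sc_q = _AdaptiveScale(0.4)
        self.sc_shift = _AdaptiveScale(2.0)
        self.rj_sigma = 1.0
        self.low_accept_warned = False

    # -- likelihood pieces ---------------------------------------------------
    def pres_ll(self, ts=None, te=None, q=None) -> float:
        if self.prior_only:
            return 0.0
        ts = self.ts if ts is None else ts
        te = self.te if te is None else te
        q = self.q if q is None else q
        qq = q if self.kind == "TPP" else float(q[0])
        return _pres_ll_vec(self.data, ts, te, self.kind, qq,
                            self.gamma_alpha)

    def bd_ll(self, ts=None, te=None, shifts_l=None, lam=None,
              shifts_m=None, mu=None) -> float:
        if self.prior_only:
            return 0.0
        ts = self.ts if ts is None else ts
        te = self.te if te is None else te
        shifts_l = self.shifts_l if shifts_l is None else shifts_l
        lam = self.lam if lam is None else lam
        shifts_m = self.shifts_m if shifts_m is None else shifts_m
        mu = self.mu if mu is None else mu
        ext = self.data.extant
        return (_bd_ll_one(ts, te, ext, shifts_l, lam, True)
                + _bd_ll_one(ts, te, ext, shifts_m, mu, False))

    def log_prior(self) -> float:
        lp = _log_rate_prior(self.lam) + _log_rate_prior(self.mu)
        for k in (len(self.shifts_l), len(self.shifts_m)):
            lp += stats.poisson.logpmf(k, self.epsilon)
            lp += special.gammaln(k + 1) - k * np.log(self.span_len)
        lp += float(np.sum(stats.gamma.logpdf(self.q, Q_PRIOR_SHAPE,
                                              scale=1.0 / Q_PRIOR_RATE)))
        return lp

    # -- moves ---------------------------------------------------------------
    def move_times(self) -> None:
        """Element-wise MH over every species' (Ts, Te).

        Given the rate configurations, the augmented likelihood
        factorizes across species, so each species is accepted or
        rejected independently.  The species carrying the single origin
        is updated by a separate scalar step.
        """
        if self.prior_only:
            return
        n = self.data.n
        w = self.sc_times.scale
        rng = self.rng
        data = self.data
        ts, te = self.ts, self.te
        root = int(np.argmax(ts))
        Gl = _CumRate(self.shifts_l, self.lam)
        Gm = _CumRate(self.shifts_m, self.mu)

        ts_prop = ts + rng.uniform(-w, w, n)
        te_raw = te + rng.uniform(-w, w, n)
        te_prop = np.where(data.extant, te, np.maximum(te_raw, 0.0))
        ok = ((ts_prop >= data.oldest) & (te_prop <= data.youngest)
              & (ts_prop > te_prop) & (ts_prop < ts[root]))
        ok[root] = False
        ts_new = np.where(ok, ts_prop, ts)
        te_new = np.where(ok, te_prop, te)

        with np.errstate(divide="ignore", invalid="ignore"):
            d_birth = (np.log(self.lam[_interval_index(ts_new, self.shifts_l)])
                       - np.log(self.lam[_interval_index(ts, self.shifts_l)]))
            d_death = np.where(
                data.extant, 0.0,
                np.log(self.mu[_interval_index(te_new, self.shifts_m)])
                - np.log(self.mu[_interval_index(te, self.shifts_m)]))
        d_birth[root] = 0.0
        d_exp = -((Gl(ts_new) - Gl(te_new)) + (Gm(ts_new) - Gm(te_new))
                  - (Gl(ts) - Gl(te)) - (Gm(ts) - Gm(te)))
        qq = self.q if self.kind == "TPP" else float(self.q[0])
        pres_old = _pres_ll_terms(data, ts, te, self.kind, qq,
                                  self.gamma_alpha)
        pres_new = _pres_ll_terms(data, ts_new, te_new, self.kind, qq,
                                  self.gamma_alpha)
        delta = d_birth + d_death + d_exp + (pres_new - pres_old)
        accept = ok & (np.log(rng.random(n)) < delta)
        self.ts = np.where(accept, ts_new, ts)
        self.te = np.where(accept, te_new, te)
        self.sc_times.update_batch(int(accept.sum()), int(ok.sum()) or 1)

        # origin species: exposure + preservation only (no birth event)
        ts_r = float(self.ts[root])
        prop = ts_r + rng.uniform(-w, w)
        others_max = float(np.max(np.delete(self.ts, root))) \
            if n > 1 else -np.inf
        if prop >= data.oldest[root] and prop > max(others_max, te[root]):
            ts_try = self.ts.copy()
            ts_try[root] = prop
            d = -((Gl(np.array([prop])) - Gl(np.array([ts_r])))[0]
                  + (Gm(np.array([prop])) - Gm(np.array([ts_r])))[0])
            p_old = _pres_ll_terms(data, self.ts, self.te, self.kind, qq,
                                   self.gamma_alpha)[root]
            p_new = _pres_ll_terms(data, ts_try, self.te, self.kind, qq,
                                   self.gamma_alpha)[root]
            if np.log(rng.random()) < d + p_new - p_old:
                self.ts = ts_try

    def move_rate(self) -> None:
        which = self.rng.random() < 0.5
        rates = self.lam if which else self.mu
        j = int(self.rng.integers(len(rates)))
        u = self.rng.uniform(-self.sc_rate.scale, self.sc_rate.scale)
        new = rates.copy()
        new[j] = rates[j] * np.exp(u)
        if which:
            d = self.bd_ll(lam=new) - self.bd_ll()
        else:
            d = self.bd_ll(mu=new) - self.bd_ll()
        d += _log_rate_prior(new[j:j + 1]) - _log_rate_prior(rates[j:j + 1])
        d += u  # Hastings term of the multiplier proposal
        if np.log(self.rng.random()) < d:
            if which:
                self.lam = new
            else:
                self.mu = new
            self.sc_rate.update(True)
        else:
            self.sc_rate.update(False)

    def move_q(self) -> None:
        j = int(self.rng.integers(len(self.q)))
        u = self.rng.uniform(-self.sc_q.scale, self.sc_q.scale)
        new = self.q.copy()
        new[j] = self.q[j] * np.exp(u)
        d = self.pres_ll(q=new) - self.pres_ll()
        d += stats.gamma.logpdf(new[j], Q_PRIOR_SHAPE,
                                scale=1.0 / Q_PRIOR_RATE) \
            - stats.gamma.logpdf(self.q[j], Q_PRIOR_SHAPE,
                                 scale=1.0 / Q_PRIOR_RATE)
        d += u
        if np.log(self.rng.random()) < d:
            self.q = new
            self.sc_q.update(True)
        else:
            self.sc_q.update(False)

    # -- trans-dimensional machinery ----------------------------------------
    def _get(self, which):
        return (self.shifts_l, self.lam) if which else (self.shifts_m, self.mu)

    def _set(self, which, shifts, rates):
        if which:
            self.shifts_l, self.lam = shifts, rates
        else:
            self.shifts_m, self.mu = shifts, rates

    def _split(self, shifts, rates, t_star, v):
        """Insert a shift at t_star splitting its interval's rate."""
        j = int(_interval_index(np.array([t_star]), shifts)[0])
        edges_old = np.concatenate([[self.span[0]], shifts])
        edges_yng = np.concatenate([shifts, [self.span[1]]])
        d1 = edges_old[j] - t_star
        d2 = t_star - edges_yng[j]
        d = d1 + d2
        r = rates[j]
        r1 = r * np.exp(v * d2 / d)
        r2 = r * np.exp(-v * d1 / d)
        new_shifts = np.insert(shifts, j, t_star)
        new_rates = np.concatenate([rates[:j], [r1, r2], rates[j + 1:]])
        jac = r1 * r2 / r
        return new_shifts, new_rates, (r, r1, r2, jac)

    def _merge(self, shifts, rates, j):
        """Remove shift j, merging the flanking rates."""
        t_star = shifts[j]
        edges_old = np.concatenate([[self.span[0]], shifts])
        edges_yng = np.concatenate([shifts, [self.span[1]]])
        d1 = edges_old[j] - t_star
        d2 = t_star - edges_yng[j + 1]
        d = d1 + d2
        r1, r2 = rates[j], rates[j + 1]
        r = np.exp((d1 * np.log(r1) + d2 * np.log(r2)) / d)
        v = np.log(r1 / r2)
        new_shifts = np.delete(shifts, j)
        new_rates = np.concatenate([rates[:j], [r], rates[j + 2:]])
        jac = r1 * r2 / r
        return new_shifts, new_rates, (r, r1, r2, v, jac)

    def _bd_ll_dim(self, which, shifts, rates):
        if self.prior_only:
            return 0.0
        ext = self.data.extant
        return _bd_ll_one(self.ts, self.te, ext, shifts, rates, which)

    def move_rj(self) -> None:
        """Green reversible-jump add/remove/move for one rate dimension."""
        which = self.rng.random() < 0.5
        shifts, rates = self._get(which)
        k = len(shifts)
        u = self.rng.random()
        p_add, p_rem = 0.35, 0.35
        if u < p_add:
            t_star = self.rng.uniform(self.span[1], self.span[0])
            v = self.rng.normal(0.0, self.rj_sigma)
            new_shifts, new_rates, (r, r1, r2, jac) = \
                self._split(shifts, rates, t_star, v)
            dll = self._bd_ll_dim(which, new_shifts, new_rates) \
                - self._bd_ll_dim(which, shifts, rates)
            # the (k+1)! / k! of the ordered-times prior cancels the
            # Poisson's 1/(k+1); the span factors cancel against 1/span
            # in the position proposal
            lpr = (np.log(self.epsilon)
                   + _log_rate_prior(np.array([r1, r2]))
                   - _log_rate_prior(np.array([r])))
            lq = (np.log(p_rem) - np.log(k + 1)
                  - np.log(p_add)
                  - stats.norm.logpdf(v, 0.0, self.rj_sigma))
            a = dll + lpr + lq + np.log(jac)
            if np.log(self.rng.random()) < a:
                self._set(which, new_shifts, new_rates)
        elif u < p_add + p_rem:
            if k == 0:
                return
            j = int(self.rng.integers(k))
            new_shifts, new_rates, (r, r1, r2, v, jac) = \
                self._merge(shifts, rates, j)
            dll = self._bd_ll_dim(which, new_shifts, new_rates) \
                - self._bd_ll_dim(which, shifts, rates)
            lpr = (-np.log(self.epsilon)
                   + _log_rate_prior(np.array([r]))
                   - _log_rate_prior(np.array([r1, r2])))
            lq = (np.log(p_add)
                  + stats.norm.logpdf(v, 0.0, self.rj_sigma)
                  - np.log(p_rem) + np.log(k))
            a = dll + lpr + lq - np.log(jac)
            if np.log(self.rng.random()) < a:
                self._set(which, new_shifts, new_rates)
        else:
            if k == 0:
                return
            j = int(self.rng.integers(k))
            w = self.sc_shift.scale
            t_new = shifts[j] + self.rng.uniform(-w, w)
            lo = shifts[j + 1] if j + 1 < k else self.span[1]
            hi = shifts[j - 1] if j > 0 else self.span[0]
            if not (lo < t_new < hi):
                self.sc_shift.update(False)
                return
            new_shifts = shifts.copy()
            new_shifts[j] = t_new
            dll = self._bd_ll_dim(which, new_shifts, rates) \
                - self._bd_ll_dim(which, shifts, rates)
            if np.log(self.rng.random()) < dll:
                self._set(which, new_shifts, rates)
                self.sc_shift.update(True)
            else:
                self.sc_shift.update(False)

    def move_bdprocess(self) -> None:
        """One unit of virtual time of the shift birth-death process."""
        for which in (True, False):
            tau = 0.0
            guard = 0
            while guard < 50:
                guard += 1
                shifts, rates = self._get(which)
                k = len(shifts)
                cur_ll = self._bd_ll_dim(which, shifts, rates)
                birth = self.epsilon
                death = np.zeros(k)
                merged = []
                for j in range(k):
                    ns, nr, (r, r1, r2, v, jac) = self._merge(shifts, rates, j)
                    dll = self._bd_ll_dim(which, ns, nr) - cur_ll
                    ld = (dll
                          + stats.norm.logpdf(v, 0.0, self.rj_sigma)
                          + _log_rate_prior(np.array([r]))
                          - _log_rate_prior(np.array([r1, r2]))
                          - np.log(jac))
                    death[j] = np.exp(min(ld, 50.0))
                    merged.append((ns, nr))
                total = birth + death.sum()
                dt = self.rng.exponential(1.0 / total)
                if tau + dt > 1.0:
                    break
                tau += dt
                if self.rng.random() < birth / total:
                    t_star = self.rng.uniform(self.span[1], self.span[0])
                    v = self.rng.normal(0.0, self.rj_sigma)
                    ns, nr, _ = self._split(shifts, rates, t_star, v)
                    self._set(which, ns, nr)
                else:
                    j = int(self.rng.choice(k, p=death / death.sum()))
                    self._set(which, *merged[j])

    # -- main loop -----------------------------------------------------------
    def run(self) -> EpisodicTrace:
        trace = EpisodicTrace(taxa=list(self.data.taxa),
                              algorithm=self.algorithm, seed=self.seed)
        burn = int(0.1 * self.iterations)
        n_acc_window = [0, 0]
        for it in range(self.iterations + 1):
            if it == burn:
                for sc in (self.sc_times, self.sc_rate, self.sc_q,
                           self.sc_shift):
                    sc.frozen = True
            if it > 0:
                u = self.rng.random()
                if not self.fix_times and u < 0.35:
                    self.move_times()
                elif u < 0.55:
                    self.move_rate()
                elif u < 0.65:
                    self.move_q()
                else:
                    if self.algorithm == "rjmcmc":
                        self.move_rj()
                    else:
                        if self.rng.random() < 0.3:
                            self.move_bdprocess()
                        else:
                            self.move_rate()
            if it % self.sampling_freq == 0:
                ll = self.pres_ll() + self.bd_ll()
                lp = ll + self.log_prior()
                trace.iterations.append(it)
                trace.log_lik.append(ll)
                trace.log_post.append(lp)
                trace.shifts_l.append(self.shifts_l.copy())
                trace.lam.append(self.lam.copy())
                trace.shifts_m.append(self.shifts_m.copy())
                trace.mu.append(self.mu.copy())
                trace.q.append(np.atleast_1d(self.q).copy())
                trace.ts.append(self.ts.copy())
                trace.te.append(self.te.copy())
        if self.sc_times.tried > 200 and not self.low_accept_warned:
            if self.sc_times.accepted / self.sc_times.tried < 0.01:
                warnings.warn("time-update acceptance below 1%; "
                              "chain may not be mixing")
                self.low_accept_warned = True
        return trace


def _as_occdata(dataset, grid=None) -> _OccData:
    if isinstance(dataset, _OccData):
        return dataset
    if isinstance(dataset, AgeResampledDataset):
        ages = dataset.ages_by_taxon()
        ext = {r.taxon: r.extant for r in dataset.table.records}
        return _OccData(ages, ext, grid)
    if isinstance(dataset, dict):
        return _OccData({t: np.asarray(a, float) for t, a in dataset.items()},
                        grid=grid)
    raise TypeError("dataset must be an AgeResampledDataset or a "
                    "taxon -> ages mapping")


def rjmcmc_sample(dataset, iterations: int = 100_000,
                  sampling_freq: int = 100, seed: int = 0,
                  pres_kind: str = "HPP", grid: StageGrid | None = None,
                  gamma_alpha: float | None = None,
                  epsilon: float = SHIFT_POISSON_MEAN,
                  fix_times: LineageTimes | None = None) -> EpisodicTrace:
    """Reversible-jump MCMC over shift configurations and (Ts, Te).

    ``epsilon`` is the Poisson prior mean on the number of shifts per rate
    vector.  Deterministic given ``seed``.
    """
    data = _as_occdata(dataset, grid)
    s = _EpisodicSampler(data, pres_kind, gamma_alpha, iterations,
                         sampling_freq, seed, epsilon, "rjmcmc", fix_times)
    return s.run()


def bdmcmc_sample(dataset, iterations: int = 100_000,
                  sampling_freq: int = 100, seed: int = 0,
                  pres_kind: str = "HPP", grid: StageGrid | None = None,
                  gamma_alpha: float | None = None,
                  epsilon: float = SHIFT_POISSON_MEAN,
                  fix_times: LineageTimes | None = None) -> EpisodicTrace:
    """Birth-death process over shift points (Stephens-style sampler)."""
    data = _as_occdata(dataset, grid)
    s = _EpisodicSampler(data, pres_kind, gamma_alpha, iterations,
                         sampling_freq, seed, epsilon, "bdmcmc", fix_times)
    return s.run()


def update_lineage_times(times: LineageTimes, dataset,
                         pres_kind: str = "HPP", q: float = 1.0,
                         config: ShiftConfiguration | None = None,
                         window: float = 1.0, seed: int = 0,
                         grid: StageGrid | None = None,
                         gamma_alpha: float | None = None) -> LineageTimes:
    """One Metropolis-Hastings sweep over every species' (Ts, Te).

    Each species is updated in turn with a uniform sliding-window
    proposal, respecting Ts >= oldest occurrence and Te <= youngest
    occurrence; violating proposals are rejected, not raised.
    """
    data = _as_occdata(dataset, grid)
    rng = np.random.default_rng(seed)
    if config is None:
        config = ShiftConfiguration(np.array([]), [0.2], [0.1])
    ts = times.ts.copy()
    te = times.te.copy()
    ext = times.extant
    qq = np.asarray(q, float) if pres_kind == "TPP" else float(q)

    def total_ll(ts_, te_):
        bd = (_bd_ll_one(ts_, te_, ext, config.shift_times, config.lam, True)
              + _bd_ll_one(ts_, te_, ext, config.shift_times, config.mu,
                           False))
        return bd + _pres_ll_vec(data, ts_, te_, pres_kind, qq, gamma_alpha)

    cur = total_ll(ts, te)
    for i in range(data.n):
        ts_new = ts.copy()
        te_new = te.copy()
        ts_new[i] = ts[i] + rng.uniform(-window, window)
        if not ext[i]:
            te_new[i] = max(te[i] + rng.uniform(-window, window), 0.0)
        if (ts_new[i] < data.oldest[i] or te_new[i] > data.youngest[i]
                or ts_new[i] <= te_new[i]):
            continue
        new = total_ll(ts_new, te_new)
        if np.log(rng.random()) < new - cur:
            ts, te, cur = ts_new, te_new, new
    return LineageTimes(ts, te, ext)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class RateThroughTimeSummary:
    """Posterior mean and 95% CI of lambda(t), mu(t), r(t) on an age grid."""

    ages: np.ndarray
    lam_mean: np.ndarray
    lam_lo: np.ndarray
    lam_hi: np.ndarray
    mu_mean: np.ndarray
    mu_lo: np.ndarray
    mu_hi: np.ndarray
    net_mean: np.ndarray
    net_lo: np.ndarray
    net_hi: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages,
            "lambda_mean": self.lam_mean, "lambda_lo": self.lam_lo,
            "lambda_hi": self.lam_hi,
            "mu_mean": self.mu_mean, "mu_lo": self.mu_lo,
            "mu_hi": self.mu_hi,
            "net_mean": self.net_mean, "net_lo": self.net_lo,
            "net_hi": self.net_hi,
        })


def _curves_from_trace(trace: EpisodicTrace, ages: np.ndarray,
                       burn_fraction: float):
    idx = list(trace.post_burnin_indices(burn_fraction))
    L = np.empty((len(idx), len(ages)))
    M = np.empty((len(idx), len(ages)))
    for row, i in enumerate(idx):
        jl = _interval_index(ages, trace.shifts_l[i])
        jm = _interval_index(ages, trace.shifts_m[i])
        L[row] = trace.lam[i][jl]
        M[row] = trace.mu[i][jm]
    return L, M


def rates_through_time(trace: EpisodicTrace, step: float = 0.1,
                       span: tuple[float, float] | None = None,
                       burn_fraction: float = 0.1,
                       extra: list[EpisodicTrace] | None = None
                       ) -> RateThroughTimeSummary:
    """Evaluate each posterior sample's piecewise rates on a regular grid.

    ``extra`` traces (replicates) are pooled with the first.
    """
    traces = [trace] + list(extra or [])
    if span is None:
        old = max(float(np.max(t.ts[i]))
                  for t in traces for i in t.post_burnin_indices(burn_fraction))
        yng = min(float(np.min(t.te[i]))
                  for t in traces for i in t.post_burnin_indices(burn_fraction))
        span = (old, yng)
    n = int(np.floor((span[0] - span[1]) / step)) + 1
    ages = span[0] - step * np.arange(n)
    Ls, Ms = [], []
    for t in traces:
        L, M = _curves_from_trace(t, ages, burn_fraction)
        Ls.append(L)
        Ms.append(M)
    L = np.vstack(Ls)
    M = np.vstack(Ms)
    R = L - M
    pc = lambda X, p: np.percentile(X, p, axis=0)
    return RateThroughTimeSummary(
        ages=ages,
        lam_mean=L.mean(axis=0), lam_lo=pc(L, 2.5), lam_hi=pc(L, 97.5),
        mu_mean=M.mean(axis=0), mu_lo=pc(M, 2.5), mu_hi=pc(M, 97.5),
        net_mean=R.mean(axis=0), net_lo=pc(R, 2.5), net_hi=pc(R, 97.5),
    )


@dataclass
class DiversityTrajectory:
    """Lineage counts through time per replicate, with mean and 95% CI."""

    ages: np.ndarray
    counts: np.ndarray  # (n_replicates, n_ages)
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mean": self.mean,
                             "ci_low": self.lo, "ci_high": self.hi})


def diversity_trajectory(times_list: list[LineageTimes],
                         step: float = 0.1,
                         span: tuple[float, float] | None = None
                         ) -> DiversityTrajectory:
    """Count lineages with Te <= t < Ts on a regular age grid."""
    if len(times_list) < 1:
        raise ValueError("need at least one replicate")
    if span is None:
        old = max(float(t.ts.max()) for t in times_list)
        yng = min(float(t.te.min()) for t in times_list)
        span = (old, yng)
    n = int(np.floor((span[0] - span[1]) / step)) + 1
    ages = span[0] - step * np.arange(n)
    counts = np.empty((len(times_list), n), dtype=int)
    for r, t in enumerate(times_list):
        alive = (t.te[None, :] <= ages[:, None]) \
            & (ages[:, None] < t.ts[None, :])
        counts[r] = alive.sum(axis=1)
    mean = counts.mean(axis=0)
    lo = np.percentile(counts, 2.5, axis=0)
    hi = np.percentile(counts, 97.5, axis=0)
    return DiversityTrajectory(ages, counts, mean, lo, hi)
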