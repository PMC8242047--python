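"""Forward simulation of clade histories and fossil sampling.

Histories are simulated on the age axis from ``origin_age`` down to
``end_age`` under one of four generative regimes (piecewise-constant
rates, covariate-linked rates, diversity-dependent rates, or Weibull
age-dependent extinction).  Fossils are then sampled through a Poisson
preservation process and, optionally, exact ages are degraded to stage
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .occurrences import (CovariateCurve, OccurrenceRecord, OccurrenceTable,
                          StageGrid)
from .preservation import PreservationModel

__all__ = [
    "TrueHistory",
    "SimulationRegime",
    "simulate_history",
    "sample_fossils",
    "impose_age_uncertainty",
    "write_truth",
    "read_truth",
]

DIVERSITY_CAP = 10_000


@dataclass
class TrueHistory:
    """Simulated species with true speciation/extinction ages.

    ``te`` of a species still alive at ``end_age`` equals ``end_age`` and
    its ``extant`` flag is set.
    """

    ts: np.ndarray
    te: np.ndarray
    extant: np.ndarray
    parent: np.ndarray
    clade_id: str = "clade"
    seed: int = 0

    def __post_init__(self) -> None:
        self.ts = np.asarray(self.ts, dtype=float)
        self.te = np.asarray(self.te, dtype=float)
        self.extant = np.asarray(self.extant, dtype=bool)
        self.parent = np.asarray(self.parent, dtype=int)
        if np.any(self.ts <= self.te):
            raise ValueError("require Ts > Te for every species")
        if np.any(self.te < 0):
            raise ValueError("require Te >= 0")

    @property
    def n_species(self) -> int:
        return len(self.ts)

    def longevities(self) -> np.ndarray:
        return self.ts - self.te

    def diversity(self, ages) -> np.ndarray:
        """Number of species alive at each age: Te <= t < Ts."""
        t = np.atleast_1d(np.asarray(ages, dtype=float))
        alive = (self.te[None, :] <= t[:, None]) & (t[:, None] < self.ts[None, :])
        d = alive.sum(axis=1)
        return d if np.ndim(ages) else int(d[0])

    def taxon_names(self) -> list[str]:
        return [f"{self.clade_id}_sp{i}" for i in range(self.n_species)]


@dataclass
class SimulationRegime:
    """Generative regime for clade histories.

    kind='piecewise': ``shift_times`` (decreasing, inside the span) with
    per-interval ``lam``/``mu`` vectors of length len(shift_times)+1.

    kind='covariate_linked': baseline ``lam0``/``mu0`` with correlation
    vectors ``g_lam``/``g_mu`` against ``covariates`` (linear or
    exponential ``link``), rates refreshed on a 0.1-Myr grid.

    kind='diversity_dependent': baselines plus per-species coefficients
    ``dd_lam``/``dd_mu``: lam = lam0*max(0, 1 - dd_lam*N),
    mu = mu0*max(0, 1 + dd_mu*N).

    kind='age_dependent': speciation rate ``lam0``; longevities drawn at
    birth from Weibull(``weibull_shape``, ``weibull_scale``).
    """

    kind: str
    origin_age: float
    end_age: float
    lam: np.ndarray | None = None
    mu: np.ndarray | None = None
    shift_times: np.ndarray | None = None
    lam0: float = 0.2
    mu0: float = 0.1
    g_lam: np.ndarray | None = None
    g_mu: np.ndarray | None = None
    covariates: list[CovariateCurve] | None = None
    link: str = "exponential"
    dd_lam: float = 0.0
    dd_mu: float = 0.0
    weibull_shape: float = 1.0
    weibull_scale: float = 5.0
    step: float = 0.1
    min_species: int = 2
    condition_on_survival: bool = False

    def __post_init__(self) -> None:
        kinds = ("piecewise", "covariate_linked", "diversity_dependent",
                 "age_dependent")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if not self.origin_age > self.end_age >= 0:
            raise ValueError("require origin_age > end_age >= 0")
        if self.kind == "piecewise":
            self.shift_times = (np.array([]) if self.shift_times is None
                                else np.asarray(self.shift_times, dtype=float))
            self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
            self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
            k = len(self.shift_times)
            if len(self.lam) != k + 1 or len(self.mu) != k + 1:
                raise ValueError("need one rate per interval")
            if np.any(self.lam < 0) or np.any(self.mu < 0):
                raise ValueError("rates must be >= 0")
            inside = ((self.shift_times < self.origin_age)
                      & (self.shift_times > self.end_age))
            if not np.all(inside):
                raise ValueError("shift times must lie inside the span")
        if self.kind == "age_dependent":
            if self.weibull_shape <= 0 or self.weibull_scale <= 0:
                raise ValueError("Weibull shape/scale must be > 0")


def _piecewise_rates_at(regime: SimulationRegime, t: float) -> tuple[float, float]:
    st = regime.shift_times
    j = int(np.sum(st >= t))  # boundary age belongs to the younger interval
    return float(regime.lam[j]), float(regime.mu[j])


def _covariate_rates_at(regime: SimulationRegime, t: float) -> tuple[float, float]:
    v = np.array([c.at(t) for c in regime.covariates]) \
        if regime.covariates else np.zeros(0)
    gl = np.zeros(len(v)) if regime.g_lam is None else np.asarray(regime.g_lam)
    gm = np.zeros(len(v)) if regime.g_mu is None else np.asarray(regime.g_mu)
    if regime.link == "exponential":
        lam = regime.lam0 * float(np.exp(np.dot(gl, v)))
        mu = regime.mu0 * float(np.exp(np.dot(gm, v)))
    else:
        lam = regime.lam0 * max(0.0, 1.0 + float(np.dot(gl, v)))
        mu = regime.mu0 * max(0.0, 1.0 + float(np.dot(gm, v)))
    return lam, mu


class _AliveSet:
    """Uniform sampling and O(1) removal over living species indices."""

    def __init__(self) -> None:
        self._items: list[int] = []
        self._pos: dict[int, int] = {}

    def __len__(self) -> int:
        return len(self._items)

    def add(self, i: int) -> None:
        self._pos[i] = len(self._items)
        self._items.append(i)

    def remove(self, i: int) -> None:
        p = self._pos.pop(i)
        last = self._items.pop()
        if last != i:
            self._items[p] = last
            self._pos[last] = p

    def sample(self, rng: np.random.Generator) -> int:
        return self._items[int(rng.integers(len(self._items)))]

    def items(self) -> list[int]:
        return list(self._items)


def _simulate_once(regime: SimulationRegime, rng: np.random.Generator):
    """One unconditioned forward pass.  Returns (ts, te, extant, parent)."""
    t0, t_end = regime.origin_age, regime.end_age
    ts: list[float] = [t0]
    te: list[float] = [np.nan]
    parent: list[int] = [-1]
    alive = _AliveSet()
    alive.add(0)

    if regime.kind == "age_dependent":
        import heapq

        # non-Markovian extinction: draw each longevity at birth
        def draw_death(birth_age: float) -> float:
            lv = regime.weibull_scale * rng.weibull(regime.weibull_shape)
            return birth_age - lv

        deaths: list[tuple[float, int]] = []  # (-death_age, index)
        heapq.heappush(deaths, (-draw_death(t0), 0))
        t = t0
        while t > t_end and len(alive):
            total = regime.lam0 * len(alive)
            dt = rng.exponential(1.0 / total) if total > 0 else np.inf
            neg_d, di = deaths[0]
            next_death = -neg_d
            t_birth = t - dt
            if next_death >= t_birth and next_death > t_end:
                heapq.heappop(deaths)
                t = next_death
                alive.remove(di)
                te[di] = t
            elif t_birth > t_end:
                t = t_birth
                p = alive.sample(rng)
                ts.append(t)
                te.append(np.nan)
                parent.append(p)
                i = len(ts) - 1
                heapq.heappush(deaths, (-draw_death(t), i))
                alive.add(i)
                if len(alive) > DIVERSITY_CAP:
                    raise RuntimeError("diversity exceeded the configured cap")
            else:
                break
        extant = np.array([np.isnan(x) for x in te])
        te = [t_end if np.isnan(x) else x for x in te]
        return np.array(ts), np.array(te), extant, np.array(parent)

    if regime.kind == "piecewise":
        bounds = np.sort(np.asarray(regime.shift_times))[::-1]
        rate_fn = _piecewise_rates_at
    elif regime.kind == "covariate_linked":
        nsteps = int(np.ceil((t0 - t_end) / regime.step))
        bounds = t0 - regime.step * np.arange(1, nsteps)
        rate_fn = _covariate_rates_at
    else:
        bounds = np.array([])
        rate_fn = None

    t = t0
    bi = 0
    while t > t_end and len(alive):
        n = len(alive)
        if regime.kind == "diversity_dependent":
            lam = regime.lam0 * max(0.0, 1.0 - regime.dd_lam * n)
            mu = regime.mu0 * max(0.0, 1.0 + regime.dd_mu * n)
        else:
            lam, mu = rate_fn(regime, t)
        total = (lam + mu) * n
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        t_event = t - dt
        next_bound = bounds[bi] if bi < len(bounds) else -np.inf
        if t_event <= next_bound and next_bound > t_end:
            t = next_bound
            bi += 1
            continue
        if t_event <= t_end:
            break
        t = t_event
        if rng.random() < lam / (lam + mu):
            p = alive.sample(rng)
            ts.append(t)
            te.append(np.nan)
            parent.append(p)
            alive.add(len(ts) - 1)
            if len(alive) > DIVERSITY_CAP:
                raise RuntimeError("diversity exceeded the configured cap")
        else:
            i = alive.sample(rng)
            alive.remove(i)
            te[i] = t
    extant = np.array([np.isnan(x) for x in te])
    te = [t_end if np.isnan(x) else x for x in te]
    return np.array(ts), np.array(te), extant, np.array(parent)


def simulate_history(regime: SimulationRegime, seed: int,
                     max_attempts: int = 1000) -> TrueHistory:
    """Simulate one clade history, rejecting until >= ``min_species``.

    Optionally also conditions on the clade reaching ``end_age`` alive.
    Deterministic given (regime, seed).
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        ts, te, extant, parent = _simulate_once(regime, rng)
        if len(ts) < regime.min_species:
            continue
        if regime.condition_on_survival and not extant.any():
            continue
        return TrueHistory(ts, te, extant, parent,
                           clade_id=f"sim{seed}", seed=seed)
    raise RuntimeError(f"no acceptable history in {max_attempts} attempts")


def sample_fossils(history: TrueHistory, model: PreservationModel,
                   seed: int, clade: str | None = None) -> OccurrenceTable:
    """Sample fossil occurrence times for every species.

    Occurrence times are drawn from the model's Poisson process on each
    lifespan; species with zero occurrences are dropped.  With the gamma
    model each taxon gets a continuous Gamma(alpha, alpha) multiplier.
    Exact ages are stored with min_age == max_age.
    """
    rng = np.random.default_rng(seed)
    names = history.taxon_names()
    records: list[OccurrenceRecord] = []
    for i in range(history.n_species):
        ts_i, te_i = history.ts[i], history.te[i]
        d = ts_i - te_i
        m = (rng.gamma(model.gamma_alpha, 1.0 / model.gamma_alpha)
             if model.gamma_alpha is not None else 1.0)
        if model.kind == "HPP":
            n = rng.poisson(model.q * m * d)
            ages = te_i + d * rng.random(n)
        elif model.kind == "NHPP":
            n = rng.poisson(model.q * m * d)
            u = rng.beta(2.0, 2.0, size=n)  # density 6u(1-u)
            ages = ts_i - u * d
        else:  # TPP
            ov = model.grid.overlaps(ts_i, te_i)
            ages_list = []
            for j, (qj, oj) in enumerate(zip(np.asarray(model.q), ov)):
                if oj <= 0 or qj <= 0:
                    continue
                nj = rng.poisson(qj * m * oj)
                base, top = model.grid.bin_edges(j)
                lo = max(top, te_i)
                hi = min(base, ts_i)
                ages_list.append(lo + (hi - lo) * rng.random(nj))
            ages = (np.concatenate(ages_list) if ages_list
                    else np.array([]))
        for a in np.sort(ages)[::-1]:
            records.append(OccurrenceRecord(
                taxon=names[i], min_age=float(a), max_age=float(a),
                clade=clade or history.clade_id,
                extant=bool(history.extant[i]),
            ))
    return OccurrenceTable(records, name=f"{history.clade_id}_fossils")


def impose_age_uncertainty(table: OccurrenceTable,
                           grid: StageGrid) -> OccurrenceTable:
    """Replace exact ages by the containing stage's (base, top) interval."""
    records = []
    for r in table.records:
        if r.min_age != r.max_age:
            raise ValueError("expected exact ages (min_age == max_age)")
        j = grid.stage_index(r.min_age)
        base, top = grid.bin_edges(j)
        records.append(OccurrenceRecord(
            taxon=r.taxon, min_age=top, max_age=base,
            specimen_id=r.specimen_id, region=r.region, clade=r.clade,
            extant=r.extant,
        ))
    return OccurrenceTable(records, name=table.name)


def write_truth(history: TrueHistory, path: str | Path) -> None:
    """Ground-truth TSV (taxon, Ts, Te, extant) for recovery tests."""
    pd.DataFrame({
        "taxon": history.taxon_names(),
        "ts": history.ts,
        "te": history.te,
        "extant": history.extant.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"taxon", "ts", "te"}
    if not need.issubset(df.columns):
        raise ValueError(f"truth table needs columns {sorted(need)}")
    return df
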