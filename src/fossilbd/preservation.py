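"""Poisson preservation-process likelihoods and model comparison.

Three sampling processes for fossil occurrence times on a species'
lifespan (Ts, Te), each conditioned on observing at least one occurrence:

* HPP  — homogeneous rate q (occurrences / species / Myr)
* NHPP — hump-shaped rate q * 6u(1-u) with u the relative position on the
  lifespan (zero at both endpoints, lifespan integral q * duration)
* TPP  — piecewise-constant rate per geological stage

Across-taxon rate heterogeneity is modelled with mean-one discretized
gamma multipliers (category medians, equal weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .occurrences import StageGrid

__all__ = [
    "PreservationModel",
    "gamma_multipliers",
    "log_likelihood",
    "table_log_likelihood",
    "pp_model_test",
    "preservation_rate_through_time",
]


def _log1mexp(x: np.ndarray | float) -> np.ndarray | float:
    """log(1 - exp(-x)) for x > 0, numerically stable."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0.693, np.log(-np.expm1(-np.maximum(x, 1e-300))),
        np.log1p(-np.exp(-x)),
    )
    return out if out.ndim else float(out)


def gamma_multipliers(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean-one multipliers from a discretized Gamma(alpha, alpha).

    Category medians at quantiles (c + 0.5)/K, renormalized to mean one.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    qs = (np.arange(n_categories) + 0.5) / n_categories
    m = stats.gamma.ppf(qs, a=alpha, scale=1.0 / alpha)
    return m / m.mean()


@dataclass
class PreservationModel:
    """Preservation process specification.

    ``q`` is a scalar rate for HPP/NHPP or a per-stage rate vector for TPP
    (aligned with ``grid``).  ``gamma_alpha`` switches on across-taxon
    gamma rate heterogeneity.
    """

    kind: str = "HPP"
    q: float | np.ndarray = 1.0
    grid: StageGrid | None = None
    gamma_alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("HPP", "NHPP", "TPP"):
            raise ValueError(f"unknown preservation kind {self.kind!r}")
        if self.kind == "TPP":
            if self.grid is None:
                raise ValueError("TPP requires a stage grid")
            self.q = np.asarray(self.q, dtype=float)
            if self.q.shape != (self.grid.n_stages,):
                raise ValueError("TPP needs one rate per stage")
            if np.any(self.q < 0):
                raise ValueError("rates must be >= 0")
        else:
            self.q = float(self.q)
            if self.q <= 0:
                raise ValueError("rate must be > 0")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be > 0")

    def multipliers(self) -> np.ndarray:
        if self.gamma_alpha is None:
            return np.array([1.0])
        return gamma_multipliers(self.gamma_alpha, self.n_categories)


def _core_loglik(occ_ages: np.ndarray, ts: float, te: float,
                 model: PreservationModel, m: float) -> float:
    """Log-likelihood of one taxon's occurrence ages at multiplier m."""
    k = len(occ_ages)
    d = ts - te
    if model.kind == "HPP":
        q = model.q * m
        lam = q * d
        return k * np.log(q) - lam - _log1mexp(lam)
    if model.kind == "NHPP":
        q = model.q * m
        lam = q * d
        u = (ts - occ_ages) / d
        with np.errstate(divide="ignore"):
            shape = np.log(6.0 * u * (1.0 - u))
        return k * np.log(q) + float(np.sum(shape)) - lam - _log1mexp(lam)
    # TPP
    rates = np.asarray(model.q) * m
    grid = model.grid
    ov = grid.overlaps(ts, te)
    lam = float(np.sum(rates * ov))
    j = grid.stage_index(occ_ages)
    with np.errstate(divide="ignore"):
        ev = float(np.sum(np.log(rates[j])))
    return ev - lam - _log1mexp(lam)


def log_likelihood(occ_ages, ts: float, te: float,
                   model: PreservationModel) -> float:
    """Log-probability of one taxon's occurrence ages given (Ts, Te).

    Conditioned on >= 1 occurrence.  With the gamma model the likelihood
    is averaged over the discretized multipliers with equal weights.
    """
    occ_ages = np.asarray(occ_ages, dtype=float)
    if occ_ages.size < 1:
        raise ValueError("need at least one occurrence")
    if ts <= te:
        raise ValueError("require Ts > Te")
    if np.any(occ_ages > ts) or np.any(occ_ages < te):
        raise ValueError("occurrences must lie within [Te, Ts]")
    ms = model.multipliers()
    if len(ms) == 1:
        return float(_core_loglik(occ_ages, ts, te, model, ms[0]))
    lls = np.array([_core_loglik(occ_ages, ts, te, model, m) for m in ms])
    return float(special.logsumexp(lls) - np.log(len(ms)))


def table_log_likelihood(ages_by_taxon: dict[str, np.ndarray],
                         ts: dict[str, float], te: dict[str, float],
                         model: PreservationModel) -> float:
    """Sum of per-taxon log-likelihoods."""
    return float(sum(
        log_likelihood(a, ts[t], te[t], model)
        for t, a in ages_by_taxon.items()
    ))


def _aicc(loglik: float, k: int, n: int) -> float:
    aic = 2.0 * k - 2.0 * loglik
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def _fit_scalar_rate(ages_by_taxon, ts, te, kind, gamma_alpha=None,
                     grid=None):
    """Profile over q (and optionally gamma alpha) for HPP/NHPP."""

    def nll(params):
        q = np.exp(params[0])
        al = np.exp(params[1]) if gamma_alpha == "fit" else None
        try:
            m = PreservationModel(kind=kind, q=q, grid=grid, gamma_alpha=al)
            return -table_log_likelihood(ages_by_taxon, ts, te, m)
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = [0.0] if gamma_alpha != "fit" else [0.0, 0.0]
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 2000})
    return -res.fun, res.x


def _fit_tpp(ages_by_taxon, ts, te, grid, gamma_alpha=None):
    """Maximize the TPP likelihood over per-stage rates (log scale)."""
    # stages with no lineage overlap carry no information: drop from count
    ov = np.zeros(grid.n_stages)
    for t in ages_by_taxon:
        ov += grid.overlaps(ts[t], te[t])
    active = ov > 0
    n_active = int(active.sum())

    def build(params):
        q = np.full(grid.n_stages, 1e-8)
        q[active] = np.exp(params[:n_active])
        al = np.exp(params[n_active]) if gamma_alpha == "fit" else None
        return PreservationModel(kind="TPP", q=q, grid=grid, gamma_alpha=al)

    def nll(params):
        try:
            return -table_log_likelihood(ages_by_taxon, ts, te, build(params))
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = np.zeros(n_active + (1 if gamma_alpha == "fit" else 0))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-5,
                                     "fatol": 1e-7})
    return -res.fun, res.x, n_active


def pp_model_test(ages_by_taxon: dict[str, np.ndarray],
                  ts: dict[str, float], te: dict[str, float],
                  grid: StageGrid,
                  include_gamma: bool = False) -> list[dict]:
    """Rank preservation models by AICc on fixed (Ts, Te).

    Returns a list of dicts (model, loglik, k, aicc, delta_aicc, aic)
    sorted best first.  n = total number of occurrences.
    """
    n = int(sum(len(a) for a in ages_by_taxon.values()))
    rows = []
    variants = [("HPP", None), ("NHPP", None), ("TPP", None)]
    if include_gamma:
        variants += [("HPP", "fit"), ("NHPP", "fit"), ("TPP", "fit")]
    for kind, gam in variants:
        if kind == "TPP":
            ll, _, n_active = _fit_tpp(ages_by_taxon, ts, te, grid, gam)
            k = n_active + (1 if gam else 0)
        else:
            ll, _ = _fit_scalar_rate(ages_by_taxon, ts, te, kind, gam)
            k = 1 + (1 if gam else 0)
        label = kind + ("+G" if gam else "")
        rows.append({"model": label, "loglik": ll, "k": k,
                     "aic": 2 * k - 2 * ll, "aicc": _aicc(ll, k, n)})
    rows.sort(key=lambda r: r["aicc"])
    best = rows[0]["aicc"]
    for r in rows:
        r["delta_aicc"] = r["aicc"] - best
    return rows


def preservation_rate_through_time(samples: np.ndarray,
                                   grid: StageGrid) -> "pd.DataFrame":
    """Per-stage posterior mean and 95% CI of TPP rates.

    ``samples`` is (n_samples, n_stages).
    """
    import pandas as pd

    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != grid.n_stages:
        raise ValueError("samples must be (n_samples, n_stages)")
    mean = samples.mean(axis=0)
    lo = np.percentile(samples, 2.5, axis=0)
    hi = np.percentile(samples, 97.5, axis=0)
    return pd.DataFrame({
        "stage": grid.labels,
        "base_age": grid.boundaries[:-1],
        "top_age": grid.boundaries[1:],
        "mean_q": mean,
        "ci_low": lo,
        "ci_high": hi,
    })
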