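"""Multi-clade diversity-dependence: clade interactions on diversification.

Each clade's rates are shifted linearly, per living species of every
clade (including itself), by interaction coefficients:

    lam_i(t) = lam0_i * max(0, 1 - sum_j g_lam[i][j] * D_j(t))
    mu_i(t)  = mu0_i  * max(0, 1 + sum_j g_mu[i][j]  * D_j(t))

Positive g means competition (speciation suppressed / extinction
boosted), negative g a positive interaction.  The probability of
competition (positive interaction) for a pair is the posterior sampling
frequency of positive (negative) coefficient values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .episodic import LineageTimes

__all__ = [
    "InteractionMatrix",
    "MCDDTrace",
    "interaction_rates",
    "mcdd_log_likelihood",
    "mcdd_sample",
    "interaction_network_summary",
]

G_PRIOR_SD = 0.25


@dataclass
class InteractionMatrix:
    """Baselines plus per-species fractional interaction coefficients."""

    lam0: np.ndarray
    mu0: np.ndarray
    g_lam: np.ndarray  # (n_clades, n_clades): effect of j on i
    g_mu: np.ndarray

    def __post_init__(self) -> None:
        self.lam0 = np.atleast_1d(np.asarray(self.lam0, float))
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, float))
        self.g_lam = np.atleast_2d(np.asarray(self.g_lam, float))
        self.g_mu = np.atleast_2d(np.asarray(self.g_mu, float))
        c = len(self.lam0)
        if self.g_lam.shape != (c, c) or self.g_mu.shape != (c, c):
            raise ValueError("interaction matrices must be (n_clades,)^2")
        if np.any(self.lam0 <= 0) or np.any(self.mu0 <= 0):
            raise ValueError("baseline rates must be > 0")


def interaction_rates(matrix: InteractionMatrix,
                      diversities: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-clade rates given diversity trajectories.

    ``diversities`` is (n_times, n_clades) of D_j(t); returns
    (lam, mu) each (n_times, n_clades), truncated at zero.
    """
    D = np.atleast_2d(np.asarray(diversities, float))
    lam = matrix.lam0[None, :] * np.maximum(
        0.0, 1.0 - D @ matrix.g_lam.T)
    mu = matrix.mu0[None, :] * np.maximum(
        0.0, 1.0 + D @ matrix.g_mu.T)
    return lam, mu


class _MCDDData:
    """Grid quantities for a set of clades with fixed (Ts, Te)."""

    def __init__(self, times_by_clade: dict[str, LineageTimes],
                 step: float = 0.1) -> None:
        self.names = list(times_by_clade)
        self.clades = [times_by_clade[n] for n in self.names]
        c = len(self.clades)
        for n, t in zip(self.names, self.clades):
            if len(t.ts) < 3:
                warnings.warn(f"clade {n!r} has < 3 species; expect wide "
                              "posteriors")
        old = max(float(t.ts.max()) for t in self.clades)
        yng = min(float(t.te.min()) for t in self.clades)
        m = int(np.ceil((old - yng) / step))
        self.edges = old - step * np.arange(m + 1)
        self.edges[-1] = yng
        cell_old = self.edges[:-1]
        cell_yng = self.edges[1:]
        mid = 0.5 * (cell_old + cell_yng)
        # diversity of every clade at cell midpoints (includes all living)
        self.D = np.column_stack([_div_at(t, mid) for t in self.clades])
        self.B = np.zeros((m, c))
        self.Dd = np.zeros((m, c))
        self.T = np.zeros((m, c))
        for i, t in enumerate(self.clades):
            root = int(np.argmax(t.ts))
            births = np.delete(t.ts, root)
            deaths = t.te[~t.extant]
            self.B[:, i] = _cell_counts(births, cell_old, m)
            self.Dd[:, i] = _cell_counts(deaths, cell_old, m)
            lo = np.maximum(cell_yng[None, :], t.te[:, None])
            hi = np.minimum(cell_old[None, :], t.ts[:, None])
            self.T[:, i] = np.maximum(0.0, hi - lo).sum(axis=0)

    def loglik_clade(self, i: int, matrix: InteractionMatrix) -> float:
        lam = matrix.lam0[i] * np.maximum(
            0.0, 1.0 - self.D @ matrix.g_lam[i])
        mu = matrix.mu0[i] * np.maximum(
            0.0, 1.0 + self.D @ matrix.g_mu[i])
        with np.errstate(divide="ignore", invalid="ignore"):
            ev = (np.where(self.B[:, i] > 0,
                           self.B[:, i] * np.log(lam), 0.0)
                  + np.where(self.Dd[:, i] > 0,
                             self.Dd[:, i] * np.log(mu), 0.0))
        return float(np.sum(ev - (lam + mu) * self.T[:, i]))

    def loglik(self, matrix: InteractionMatrix) -> float:
        return sum(self.loglik_clade(i, matrix)
                   for i in range(len(self.clades)))


def _div_at(t: LineageTimes, ages: np.ndarray) -> np.ndarray:
    alive = (t.te[None, :] <= ages[:, None]) & (ages[:, None] < t.ts[None, :])
    return alive.sum(axis=1).astype(float)


def _cell_counts(ages, cell_old, m):
    j = np.searchsorted(-cell_old, -np.asarray(ages), side="right") - 1
    j = np.clip(j, 0, m - 1)
    return np.bincount(j, minlength=m).astype(float)


def mcdd_log_likelihood(times_by_clade: dict[str, LineageTimes],
                        matrix: InteractionMatrix,
                        step: float = 0.1) -> float:
    """Joint log-likelihood of all clades under the interaction model."""
    return _MCDDData(times_by_clade, step).loglik(matrix)


@dataclass
class MCDDTrace:
    """Posterior samples of baselines and interaction coefficients."""

    names: list[str]
    lam0: np.ndarray  # (n_samples, C)
    mu0: np.ndarray
    g_lam: np.ndarray  # (n_samples, C, C)
    g_mu: np.ndarray
    seed: int = 0

    def _post(self, x: np.ndarray) -> np.ndarray:
        b = int(np.floor(len(x) * 0.1))
        return x[b:]

    def summary(self) -> pd.DataFrame:
        rows = []
        c = len(self.names)
        gl = self._post(self.g_lam)
        gm = self._post(self.g_mu)
        for i in range(c):
            for j in range(c):
                rows.append({
                    "clade_i": self.names[i],
                    "clade_j": self.names[j],
                    "g_lambda_median": np.median(gl[:, i, j]),
                    "g_lambda_lo": np.percentile(gl[:, i, j], 2.5),
                    "g_lambda_hi": np.percentile(gl[:, i, j], 97.5),
                    "p_competition_lambda": float(np.mean(gl[:, i, j] > 0)),
                    "p_positive_lambda": float(np.mean(gl[:, i, j] < 0)),
                    "g_mu_median": np.median(gm[:, i, j]),
                    "g_mu_lo": np.percentile(gm[:, i, j], 2.5),
                    "g_mu_hi": np.percentile(gm[:, i, j], 97.5),
                    "p_competition_mu": float(np.mean(gm[:, i, j] > 0)),
                    "p_positive_mu": float(np.mean(gm[:, i, j] < 0)),
                })
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def mcdd_sample(times_by_clade: dict[str, LineageTimes],
                iterations: int = 20_000, sampling_freq: int = 20,
                seed: int = 0, step: float = 0.1,
                g_prior_sd: float = G_PRIOR_SD) -> MCDDTrace:
    """Joint MCMC over baselines and all interaction coefficients.

    Baselines get multiplier updates (Gamma(1.1, 1) prior); coefficients
    get random-walk updates with a Normal(0, g_prior_sd^2) prior.
    Deterministic given ``seed``.
    """
    if len(times_by_clade) < 1:
        raise ValueError("need at least one clade")
    data = _MCDDData(times_by_clade, step)
    c = len(data.names)
    rng = np.random.default_rng(seed)

    mat = InteractionMatrix(np.full(c, 0.2), np.full(c, 0.1),
                            np.zeros((c, c)), np.zeros((c, c)))
    ll_i = np.array([data.loglik_clade(i, mat) for i in range(c)])
    scale_g = 0.02
    burn = int(0.1 * iterations)
    acc = tried = 0

    out_l0, out_m0, out_gl, out_gm = [], [], [], []
    for it in range(iterations + 1):
        # baselines
        for i in range(c):
            for which in (0, 1):
                u = rng.uniform(-0.3, 0.3)
                vec = mat.lam0 if which == 0 else mat.mu0
                old = vec[i]
                vec[i] = old * np.exp(u)
                new = data.loglik_clade(i, mat)
                d = (new - ll_i[i] + u
                     + stats.gamma.logpdf(vec[i], 1.1, scale=1.0)
                     - stats.gamma.logpdf(old, 1.1, scale=1.0))
                if np.log(rng.random()) < d:
                    ll_i[i] = new
                else:
                    vec[i] = old
        # interaction coefficients
        for i in range(c):
            for j in range(c):
                for which in (0, 1):
                    G = mat.g_lam if which == 0 else mat.g_mu
                    old = G[i, j]
                    G[i, j] = old + rng.normal(0.0, scale_g)
                    new = data.loglik_clade(i, mat)
                    d = (new - ll_i[i]
                         + stats.norm.logpdf(G[i, j], 0.0, g_prior_sd)
                         - stats.norm.logpdf(old, 0.0, g_prior_sd))
                    tried += 1
                    if np.log(rng.random()) < d:
                        ll_i[i] = new
                        acc += 1
                    else:
                        G[i, j] = old
        if it < burn and tried >= 200:
            r = acc / tried
            if r < 0.2:
                scale_g *= 0.8
            elif r > 0.4:
                scale_g *= 1.25
            acc = tried = 0
        if it % sampling_freq == 0:
            out_l0.append(mat.lam0.copy())
            out_m0.append(mat.mu0.copy())
            out_gl.append(mat.g_lam.copy())
            out_gm.append(mat.g_mu.copy())

    return MCDDTrace(names=data.names, lam0=np.array(out_l0),
                     mu0=np.array(out_m0), g_lam=np.array(out_gl),
                     g_mu=np.array(out_gm), seed=seed)


def interaction_network_summary(trace: MCDDTrace,
                                threshold: float = 0.95) -> pd.DataFrame:
    """Edges whose sign-frequency probability exceeds ``threshold``.

    Effect magnitude is the posterior median coefficient, reported as a
    percentage of the baseline rate per added species.
    """
    summ = trace.summary()
    rows = []
    for _, r in summ.iterrows():
        for rate, med_col, pc, pp in (
            ("speciation", "g_lambda_median", "p_competition_lambda",
             "p_positive_lambda"),
            ("extinction", "g_mu_median", "p_competition_mu",
             "p_positive_mu"),
        ):
            if r[pc] > threshold or r[pp] > threshold:
                kind = "competition" if r[pc] > threshold else "positive"
                rows.append({
                    "clade_i": r["clade_i"], "clade_j": r["clade_j"],
                    "rate": rate, "interaction": kind,
                    "probability": max(r[pc], r[pp]),
                    "effect_pct_per_species": 100.0 * abs(r[med_col]),
                    "g_median": r[med_col],
                })
    cols = ["clade_i", "clade_j", "rate", "interaction", "probability",
            "effect_pct_per_species", "g_median"]
    return pd.DataFrame(rows, columns=cols)
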