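"""Multivariate birth-death model: rates tied to time-series covariates.

Speciation and extinction rates are linked to standardized covariate
curves by either a linear or an exponential link:

    linear:       rate(t) = baseline * max(0, 1 + sum_j G_j v_j(t))
    exponential:  rate(t) = baseline * exp(sum_j G_j v_j(t))

The correlation parameters G carry a horseshoe prior
G_j ~ Normal(0, tau^2 psi_j^2), psi_j ~ HalfCauchy(1),
tau ~ HalfCauchy(1); the per-covariate shrinkage weight is the
posterior mean of omega_j = 1 - 1/(1 + psi_j^2).  The local scale
psi_j must escape the globally shrunk tau to accommodate a real effect,
so omega > 0.5 is read as significant.  (Ts, Te) are taken as fixed
input, normally the posterior means from an episodic run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .episodic import LineageTimes
from .occurrences import CovariateCurve, rescale_covariate

__all__ = [
    "CovariateModelState",
    "MBDTrace",
    "rate_at_time",
    "mbd_log_likelihood",
    "mbd_sample",
]

HS_GLOBAL_SCALE = 1.0  # HalfCauchy scale of tau


@dataclass
class CovariateModelState:
    """Parameters of the covariate-linked birth-death model."""

    lambda0: float
    mu0: float
    g_lambda: np.ndarray
    g_mu: np.ndarray
    link: str = "exponential"
    psi: np.ndarray | None = None
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.g_lambda = np.atleast_1d(np.asarray(self.g_lambda, float))
        self.g_mu = np.atleast_1d(np.asarray(self.g_mu, float))
        if self.link not in ("linear", "exponential"):
            raise ValueError("link must be 'linear' or 'exponential'")
        if self.lambda0 <= 0 or self.mu0 <= 0:
            raise ValueError("baseline rates must be > 0")

    def omega(self) -> np.ndarray:
        """Shrinkage weight per correlation parameter (lambda then mu)."""
        if self.psi is None:
            raise ValueError("no horseshoe scales attached")
        return 1.0 - 1.0 / (1.0 + self.psi ** 2)


def rate_at_time(baseline: float, g, values, link: str = "linear"):
    """Rate implied by covariate values at one time (or a grid).

    ``values`` may be (n_cov,) or (n_times, n_cov).
    """
    g = np.atleast_1d(np.asarray(g, float))
    v = np.asarray(values, float)
    s = v @ g if v.ndim > 1 else float(np.dot(v, g))
    if link == "linear":
        return baseline * np.maximum(0.0, 1.0 + s)
    if link == "exponential":
        return baseline * np.exp(s)
    raise ValueError("link must be 'linear' or 'exponential'")


class _MBDData:
    """Precomputed grid quantities for fixed (Ts, Te) and covariates."""

    def __init__(self, times: LineageTimes,
                 covariates: list[CovariateCurve],
                 step: float = 0.1) -> None:
        self.times = times
        self.step = step
        old = float(times.ts.max())
        yng = float(times.te.min())
        for c in covariates:
            lo, hi = min(c.ages.min(), c.ages.max()), max(c.ages)
            if hi < old or lo > yng:
                raise ValueError(f"covariate {c.name!r} does not cover the "
                                 "clade span")
        n = int(np.ceil((old - yng) / step))
        # cell m spans (edges[m+1], edges[m]]
        self.edges = old - step * np.arange(n + 1)
        self.edges[-1] = yng
        self.cell_old = self.edges[:-1]
        self.cell_yng = self.edges[1:]
        self.mid = 0.5 * (self.cell_old + self.cell_yng)
        std = [rescale_covariate(c, (old, yng), step) for c in covariates]
        self.names = [c.name for c in covariates]
        self.V = np.column_stack([c.at(self.mid) for c in std]) \
            if covariates else np.zeros((n, 0))
        # exposure: summed lineage duration per cell
        lo = np.maximum(self.cell_yng[None, :], times.te[:, None])
        hi = np.minimum(self.cell_old[None, :], times.ts[:, None])
        self.T = np.maximum(0.0, hi - lo).sum(axis=0)
        # event counts per cell
        root = int(np.argmax(times.ts))
        births = np.delete(times.ts, root)
        deaths = times.te[~times.extant]
        self.B = self._cell_counts(births, n)
        self.D = self._cell_counts(deaths, n)

    def _cell_counts(self, ages: np.ndarray, n: int) -> np.ndarray:
        # cell m spans (cell_old[m+1], cell_old[m]]; boundary ages go to
        # the cell whose older edge they sit on (the younger cell)
        j = np.searchsorted(-self.cell_old, -np.asarray(ages), side="right") - 1
        j = np.clip(j, 0, n - 1)
        return np.bincount(j, minlength=n).astype(float)

    def loglik(self, state: CovariateModelState) -> float:
        lam = rate_at_time(state.lambda0, state.g_lambda, self.V, state.link)
        mu = rate_at_time(state.mu0, state.g_mu, self.V, state.link)
        with np.errstate(divide="ignore", invalid="ignore"):
            ev = (np.where(self.B > 0, self.B * np.log(lam), 0.0)
                  + np.where(self.D > 0, self.D * np.log(mu), 0.0))
        return float(np.sum(ev - (lam + mu) * self.T))


def mbd_log_likelihood(times: LineageTimes, state: CovariateModelState,
                       covariates: list[CovariateCurve],
                       step: float = 0.1) -> float:
    """Birth-death log-likelihood with stepwise covariate-linked rates."""
    return _MBDData(times, covariates, step).loglik(state)


@dataclass
class MBDTrace:
    """Posterior samples from an MBD run."""

    names: list[str]
    link: str
    lambda0: np.ndarray = field(default_factory=lambda: np.array([]))
    mu0: np.ndarray = field(default_factory=lambda: np.array([]))
    g_lambda: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    g_mu: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    omega_lambda: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    omega_mu: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.lambda0)

    def _post(self, x: np.ndarray) -> np.ndarray:
        b = int(np.floor(len(x) * 0.1))
        return x[b:]

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.names):
            gl = self._post(self.g_lambda[:, j])
            gm = self._post(self.g_mu[:, j])
            rows.append({
                "covariate": name,
                "G_lambda_mean": gl.mean(),
                "G_lambda_lo": np.percentile(gl, 2.5),
                "G_lambda_hi": np.percentile(gl, 97.5),
                "omega_lambda": self._post(self.omega_lambda[:, j]).mean(),
                "G_mu_mean": gm.mean(),
                "G_mu_lo": np.percentile(gm, 2.5),
                "G_mu_hi": np.percentile(gm, 97.5),
                "omega_mu": self._post(self.omega_mu[:, j]).mean(),
            })
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def _inv_gamma(rng, shape, rate):
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def mbd_sample(times: LineageTimes, covariates: list[CovariateCurve],
               iterations: int = 20_000, sampling_freq: int = 20,
               seed: int = 0, link: str = "exponential", step: float = 0.1,
               prior_only: bool = False) -> MBDTrace:
    """Gibbs-within-Metropolis sampler for the MBD model.

    Baselines get multiplier updates with a vague Gamma(1.1, 1) prior;
    each G_j gets a random-walk update under the horseshoe; the local and
    global horseshoe scales are Gibbs-updated via their inverse-gamma
    auxiliary representation.  Deterministic given ``seed``.
    """
    import warnings

    p = len(covariates)
    if p < 2:
        warnings.warn("fewer than 2 covariates: shrinkage is degenerate")
    data = _MBDData(times, covariates, step)
    rng = np.random.default_rng(seed)

    lam0, mu0 = 0.2, 0.1
    G = np.zeros(2 * p)  # lambda block then mu block
    psi2 = np.ones(2 * p)
    nu = np.ones(2 * p)
    tau2 = HS_GLOBAL_SCALE ** 2
    xi = 1.0
    scale_g = np.full(2 * p, 0.05)
    acc_g = np.zeros(2 * p)
    try_g = np.zeros(2 * p)

    def state() -> CovariateModelState:
        return CovariateModelState(lam0, mu0, G[:p], G[p:], link,
                                   psi=np.sqrt(psi2), tau=np.sqrt(tau2))

    def ll() -> float:
        return 0.0 if prior_only else data.loglik(state())

    dead_col = np.array([np.all(data.V[:, j] == 0.0) for j in range(p)]) \
        if p else np.zeros(0, bool)

    cur = ll()
    names = [c.name for c in covariates]
    out = {"lambda0": [], "mu0": [], "G": [], "omega": []}
    burn = int(0.1 * iterations)

    for it in range(iterations + 1):
        # baselines
        for which in (0, 1):
            u = rng.uniform(-0.3, 0.3)
            old = (lam0, mu0)
            if which == 0:
                lam0_new = lam0 * np.exp(u)
                lam0, prev = lam0_new, old[0]
            else:
                mu0_new = mu0 * np.exp(u)
                mu0, prev = mu0_new, old[1]
            new = ll()
            val = lam0 if which == 0 else mu0
            d = (new - cur + u
                 + stats.gamma.logpdf(val, 1.1, scale=1.0)
                 - stats.gamma.logpdf(prev, 1.1, scale=1.0))
            if np.log(rng.random()) < d:
                cur = new
            else:
                if which == 0:
                    lam0 = prev
                else:
                    mu0 = prev
        # correlation parameters; a zero (constant) covariate column
        # carries no likelihood, so its conditional is the prior exactly
        for j in range(2 * p):
            if prior_only or dead_col[j % p]:
                G[j] = rng.normal(0.0, np.sqrt(tau2 * psi2[j]))
                continue
            gj = G[j]
            G[j] = gj + rng.normal(0.0, scale_g[j])
            new = ll()
            sd2 = tau2 * psi2[j]
            d = (new - cur
                 - G[j] ** 2 / (2 * sd2) + gj ** 2 / (2 * sd2))
            try_g[j] += 1
            if np.log(rng.random()) < d:
                cur = new
                acc_g[j] += 1
            else:
                G[j] = gj
        # horseshoe scales (Gibbs)
        psi2 = _inv_gamma(rng, 1.0, 1.0 / nu + G ** 2 / (2 * tau2))
        nu = _inv_gamma(rng, 1.0, 1.0 + 1.0 / psi2)
        tau2 = _inv_gamma(rng, (2 * p + 1) / 2.0,
                          1.0 / xi + float(np.sum(G ** 2 / (2 * psi2))))
        xi = _inv_gamma(rng, 1.0, 1.0 / HS_GLOBAL_SCALE ** 2 + 1.0 / tau2)
        # adapt during burn-in
        if it < burn and it % 100 == 99:
            r = np.divide(acc_g, np.maximum(try_g, 1))
            scale_g = np.where(r < 0.2, scale_g * 0.8,
                               np.where(r > 0.45, scale_g * 1.25, scale_g))
            acc_g[:] = 0
            try_g[:] = 0
        if it % sampling_freq == 0:
            omega = 1.0 - 1.0 / (1.0 + psi2)
            out["lambda0"].append(lam0)
            out["mu0"].append(mu0)
            out["G"].append(G.copy())
            out["omega"].append(omega.copy())

    Gs = np.array(out["G"])
    Os = np.array(out["omega"])
    return MBDTrace(
        names=names, link=link,
        lambda0=np.array(out["lambda0"]), mu0=np.array(out["mu0"]),
        g_lambda=Gs[:, :p], g_mu=Gs[:, p:],
        omega_lambda=Os[:, :p], omega_mu=Os[:, p:], seed=seed,
    )
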