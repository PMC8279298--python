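"""Hierarchical Poisson-lognormal model and its MCMC sampler.

Model, per stratum cell i:

    C_i ~ Poisson(theta_i * E_i)
    theta_i ~ Lognormal(x_i' beta, sigma^2)
    beta_j ~ Normal(0, 1e4)          (vague)
    sigma^2 ~ Inverse-Gamma(1, 0.001)

The latent log-rate eta_i = log theta_i has a Normal(x_i'beta, sigma^2)
prior, which makes beta and sigma^2 conditionally conjugate given eta.
The sampler is therefore Metropolis-within-Gibbs: a vectorised random-walk
Metropolis step on every eta_i (their full conditionals are independent
given beta, sigma^2), an exact multivariate-normal draw for beta, and an
exact inverse-gamma draw for sigma^2. The eta proposal scales adapt toward
0.44 acceptance during burn-in only, preserving ergodicity afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp

from .data_io import CountTable
from .design import DesignMatrix

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "FittedRates",
    "log_joint",
    "fit_mcmc",
    "marginal_moments",
    "marginal_loglik",
    "poisson_loglik",
]

BETA_PRIOR_VAR = 1.0e4
SIGMA2_PRIOR_SHAPE = 1.0
SIGMA2_PRIOR_SCALE = 0.001


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and adaptation settings.

    Defaults give a production-length chain; tests and selection passes use
    shorter chains via replace().
    """

    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    adapt_interval: int = 50
    target_accept: float = 0.44
    init_step: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass
class PosteriorDraws:
    """Retained MCMC draws.

    beta is draws x p, sigma2 draws, eta draws x cells (latent log-rates).
    """

    beta: np.ndarray
    sigma2: np.ndarray
    eta: np.ndarray
    design: DesignMatrix
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 draws must be positive")
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("eta draws must be finite")

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def beta_mean(self) -> np.ndarray:
        return self.beta.mean(axis=0)

    @property
    def sigma2_mean(self) -> float:
        return float(self.sigma2.mean())

    def beta_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed credible intervals, (p, 2)."""
        a = (1.0 - level) / 2.0
        return np.quantile(self.beta, [a, 1.0 - a], axis=0).T

    def fitted_rates(self) -> "FittedRates":
        """Latent-rate draws theta = exp(eta) for the observed cells."""
        return FittedRates(theta=np.exp(self.eta), strata=self.design.strata)

    @classmethod
    def degenerate(cls, beta: np.ndarray, sigma2: float, design: DesignMatrix,
                   n_draws: int = 1) -> "PosteriorDraws":
        """A point-mass 'posterior' at fixed parameters (for plug-in use)."""
        beta = np.asarray(beta, dtype=float)
        B = np.tile(beta, (n_draws, 1))
        s2 = np.full(n_draws, float(sigma2))
        eta = B @ design.X.T
        return cls(beta=B, sigma2=s2, eta=eta, design=design,
                   meta={"degenerate": True})


@dataclass
class FittedRates:
    """Per-cell rate draws (draws x cells) with stratum labels."""

    theta: np.ndarray
    strata: "object"  # pandas DataFrame of KEY_COLUMNS

    def __post_init__(self) -> None:
        if np.any(self.theta <= 0):
            raise ValueError("rates must be positive")

    def summary(self):
        import pandas as pd

        q = np.quantile(self.theta, [0.025, 0.975], axis=0)
        out = self.strata.copy()
        out["mean"] = self.theta.mean(axis=0)
        out["lo95"] = q[0]
        out["hi95"] = q[1]
        return out


# ---------------------------------------------------------------------------
# densities


def poisson_loglik(counts: np.ndarray, mean: np.ndarray) -> float:
    """Plain Poisson log-likelihood at the given cell means."""
    counts = np.asarray(counts, dtype=float)
    mean = np.asarray(mean, dtype=float)
    return float(np.sum(counts * np.log(mean) - mean - gammaln(counts + 1.0)))


def log_joint(beta: np.ndarray, sigma2: float, eta: np.ndarray,
              design: DesignMatrix, table: CountTable) -> float:
    """Unnormalised log posterior of (beta, sigma2, eta).

    Sum of the Poisson log-pmf of the counts at rate exp(eta)*E, the
    Normal(eta | X beta, sigma2) latent prior, the vague Normal prior on
    beta, and the Inverse-Gamma(1, 0.001) prior on sigma2. Returns -inf for
    sigma2 <= 0 (rejected state).
    """
    if sigma2 <= 0:
        return -np.inf
    C = table.counts.astype(float)
    E = table.exposures
    mu = design.X @ np.asarray(beta, dtype=float)
    eta = np.asarray(eta, dtype=float)
    lp = np.sum(C * eta + C * np.log(E) - E * np.exp(eta) - gammaln(C + 1.0))
    resid = eta - mu
    n = eta.size
    lp += -0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * np.sum(resid ** 2) / sigma2
    b = np.asarray(beta, dtype=float)
    lp += -0.5 * b.size * np.log(2.0 * np.pi * BETA_PRIOR_VAR) - 0.5 * np.sum(b ** 2) / BETA_PRIOR_VAR
    a0, b0 = SIGMA2_PRIOR_SHAPE, SIGMA2_PRIOR_SCALE
    lp += a0 * np.log(b0) - gammaln(a0) - (a0 + 1.0) * np.log(sigma2) - b0 / sigma2
    return float(lp)


def marginal_moments(linpred, sigma2, exposure):
    """Marginal mean and variance of a Poisson-lognormal count.

    With theta ~ Lognormal(linpred, sigma2) and C | theta ~ Poisson(theta E):

        m = E * exp(linpred + sigma2/2)
        Var = m * (1 + m * (exp(sigma2) - 1))

    The overdispersion factor is (exp(sigma2) - 1), the squared coefficient
    of variation of the lognormal rate.
    """
    linpred = np.asarray(linpred, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    m = exposure * np.exp(linpred + sigma2 / 2.0)
    var = m * (1.0 + m * np.expm1(sigma2))
    return m, var


def marginal_loglik(beta: np.ndarray, sigma2: float, design: DesignMatrix,
                    table: CountTable, n_nodes: int = 25) -> float:
    """Poisson-lognormal marginal log-likelihood by adaptive quadrature.

    Integrates the latent log-rate out of each cell's likelihood with
    Gauss-Hermite quadrature centred and scaled at the mode of the per-cell
    integrand (adaptive quadrature); the prior-centred rule badly
    undersamples the likelihood when counts are large, since its width in
    eta shrinks like 1/sqrt(C). Everything is kept in log space.
    sigma2 = 0 degenerates to the plain Poisson log-likelihood at rate
    exp(mu) * E.
    """
    if n_nodes < 5:
        raise ValueError("n_nodes must be >= 5")
    beta = np.asarray(beta, dtype=float)
    mu = design.X @ beta if beta.ndim == 1 else design.X @ beta.T  # cells or cells x draws
    return _marginal_loglik_mu(mu, sigma2, table, n_nodes)


def _latent_mode(C: np.ndarray, E: np.ndarray, mu: np.ndarray,
                 sigma2: np.ndarray, n_iter: int = 100) -> np.ndarray:
    """Mode of log[Poisson(C | e^eta E) Normal(eta | mu, sigma2)] per cell.

    Damped Newton on the strictly concave objective
    f(eta) = C eta - E e^eta - (eta - mu)^2 / (2 sigma2).
    """
    eta = np.where(C > 0, np.log((C + 0.5) / E), mu)
    for _ in range(n_iter):
        expo = E * np.exp(eta)
        grad = C - expo - (eta - mu) / sigma2
        hess = expo + 1.0 / sigma2
        step = np.clip(grad / hess, -2.0, 2.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return eta


def _marginal_loglik_mu(mu: np.ndarray, sigma2, table: CountTable,
                        n_nodes: int = 25) -> float | np.ndarray:
    """Marginal log-likelihood given per-cell linear predictors.

    mu may be (cells,) for a scalar result or (cells, m) for m parameter
    sets evaluated at once (sigma2 then scalar or length m).
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be >= 0")
    C = np.broadcast_to(table.counts.astype(float)[(...,) + (None,) * (mu.ndim - 1)], mu.shape)
    E = np.broadcast_to(table.exposures[(...,) + (None,) * (mu.ndim - 1)], mu.shape)
    s2 = np.broadcast_to(sigma2, mu.shape)
    cell_ll = np.empty(mu.shape)
    pos = s2 > 0
    if np.any(~pos):
        m0, C0, E0 = mu[~pos], C[~pos], E[~pos]
        cell_ll[~pos] = C0 * (m0 + np.log(E0)) - E0 * np.exp(m0) - gammaln(C0 + 1.0)
    if np.any(pos):
        m, s, Cp, Ep = mu[pos], s2[pos], C[pos], E[pos]
        mode = _latent_mode(Cp, Ep, m, s)
        s_hat = 1.0 / np.sqrt(Ep * np.exp(mode) + 1.0 / s)
        z, w = hermgauss(n_nodes)
        # adaptive rule: int g = sqrt(2) s_hat sum_k w_k exp(z_k^2) g(mode + sqrt(2) s_hat z_k)
        eta = mode[:, None] + np.sqrt(2.0) * s_hat[:, None] * z
        log_g = (Cp[:, None] * (eta + np.log(Ep)[:, None]) - Ep[:, None] * np.exp(eta)
                 - gammaln(Cp + 1.0)[:, None]
                 - 0.5 * np.log(2.0 * np.pi * s)[:, None]
                 - (eta - m[:, None]) ** 2 / (2.0 * s[:, None]))
        cell_ll[pos] = (logsumexp(log_g + np.log(w) + z ** 2, axis=-1)
                        + 0.5 * np.log(2.0) + np.log(s_hat))
    if np.any(np.isnan(cell_ll)):
        raise FloatingPointError("NaN in quadrature marginal likelihood")
    out = cell_ll.sum(axis=0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Gibbs building blocks (exposed for direct verification)


def beta_conditional(X: np.ndarray, eta: np.ndarray, sigma2: float,
                     prior_var: float = BETA_PRIOR_VAR) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of beta | eta, sigma2.

    The latent stage eta ~ N(X beta, sigma2 I) with prior beta ~ N(0, v I)
    gives a conjugate normal posterior with precision X'X/sigma2 + I/v.
    """
    p = X.shape[1]
    A = X.T @ X / sigma2 + np.eye(p) / prior_var
    cov = np.linalg.inv(A)
    mean = cov @ (X.T @ eta / sigma2)
    return mean, cov


def draw_beta(rng: np.random.Generator, XtX: np.ndarray, Xt_eta: np.ndarray,
              sigma2: float, prior_var: float = BETA_PRIOR_VAR) -> np.ndarray:
    p = XtX.shape[0]
    A = XtX / sigma2 + np.eye(p) / prior_var
    L = np.linalg.cholesky(A)
    b = Xt_eta / sigma2
    # mean = A^{-1} b; draw = mean + A^{-1/2} z  via two triangular solves
    tmp = np.linalg.solve(L, b)
    mean_t = np.linalg.solve(L.T, tmp)
    z = rng.standard_normal(p)
    return mean_t + np.linalg.solve(L.T, z)


def draw_sigma2(rng: np.random.Generator, resid: np.ndarray,
                prior_shape: float = SIGMA2_PRIOR_SHAPE,
                prior_scale: float = SIGMA2_PRIOR_SCALE) -> float:
    """Inverse-gamma full-conditional draw of sigma2 given eta - X beta.

    With zero residuals (no data) this samples the prior itself.
    """
    n = resid.size
    shape = prior_shape + 0.5 * n
    scale = prior_scale + 0.5 * float(resid @ resid)
    return scale / rng.gamma(shape)


def _init_beta(X: np.ndarray, C: np.ndarray, E: np.ndarray,
               ridge: float = 1e-6, n_iter: int = 25) -> np.ndarray:
    """Ridge-stabilised Poisson ML fit with offset log E (Newton/IRLS)."""
    n, p = X.shape
    eta0 = np.log((C + 0.5) / E)
    beta = np.linalg.solve(X.T @ X + ridge * np.eye(p), X.T @ eta0)
    for _ in range(n_iter):
        lin = np.clip(X @ beta + np.log(E), -30, 30)
        mu = np.exp(lin)
        W = mu
        grad = X.T @ (C - mu) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if np.max(np.abs(step)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def fit_mcmc(design: DesignMatrix, table: CountTable,
             config: MCMCConfig | None = None, seed: int = 0) -> PosteriorDraws:
    """Fit the Poisson-lognormal model by Metropolis-within-Gibbs.

    Parameters
    ----------
    design
        Output of :func:`cancerineq.design.encode_design`; rows must align
        with the table's canonical cell order.
    config
        Chain settings; defaults to :class:`MCMCConfig`.
    seed
        Seeds the whole chain; identical seed and config reproduce the
        draws bit for bit.
    """
    config = config or MCMCConfig()
    X = design.X
    n, p = X.shape
    if len(table) != n:
        raise ValueError("design and table are misaligned")
    if p >= n:
        import warnings

        warnings.warn(f"p={p} >= cells={n}: model is rank-deficient", stacklevel=2)
    C = table.counts.astype(float)
    E = table.exposures
    rng = np.random.default_rng(seed)

    beta = _init_beta(X, C, E)
    eta = np.log((C + 0.5) / E)
    sigma2 = 0.1
    if not np.isfinite(log_joint(beta, sigma2, eta, design, table)):
        raise RuntimeError("non-finite log posterior at the initial state")

    XtX = X.T @ X
    step = np.full(n, config.init_step)
    acc_count = np.zeros(n)
    acc_total = np.zeros(n)
    expo_eta = np.exp(eta)

    n_keep = config.n_draws
    beta_out = np.empty((n_keep, p))
    sigma2_out = np.empty(n_keep)
    eta_out = np.empty((n_keep, n))
    k = 0

    for it in range(config.iterations):
        mu = X @ beta
        # --- eta: vectorised random-walk Metropolis (cells independent given beta, sigma2)
        prop = eta + step * rng.standard_normal(n)
        expo_prop = np.exp(prop)
        log_ratio = (
            C * (prop - eta)
            - E * (expo_prop - expo_eta)
            - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * sigma2)
        )
        accept = np.log(rng.random(n)) < log_ratio
        eta[accept] = prop[accept]
        expo_eta[accept] = expo_prop[accept]
        acc_count += accept
        acc_total += 1

        # --- adapt proposal scales during burn-in only
        if it < config.burn_in and (it + 1) % config.adapt_interval == 0:
            rate = acc_count / acc_total
            step *= np.exp(np.clip(rate - config.target_accept, -0.5, 0.5) * 0.5)
            step = np.clip(step, 1e-3, 10.0)
            acc_count[:] = 0
            acc_total[:] = 0

        # --- beta | eta, sigma2 (conjugate normal)
        beta = draw_beta(rng, XtX, X.T @ eta, sigma2)

        # --- sigma2 | eta, beta (conjugate inverse-gamma)
        sigma2 = draw_sigma2(rng, eta - X @ beta)

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0 and k < n_keep:
            beta_out[k] = beta
            sigma2_out[k] = sigma2
            eta_out[k] = eta
            k += 1

    acc_rate = float(np.mean(acc_count / np.maximum(acc_total, 1)))
    meta = {
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "thinning": config.thinning,
        "seed": seed,
        "eta_accept_rate": acc_rate,
        "columns": design.columns,
    }
    return PosteriorDraws(beta=beta_out[:k], sigma2=sigma2_out[:k], eta=eta_out[:k],
                          design=design, meta=meta)
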