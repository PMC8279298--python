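"""Forward variable selection and goodness-of-fit diagnostics.

Selection starts from the null (intercept-only) model and adds candidate
terms one at a time, in a fixed order with main effects before
interactions. A candidate is kept when the augmented model has a lower DIC
or a Bayes factor above 3 against the current model. The Bayes factor is a
Schwarz (BIC) approximation built on the quadrature-marginalised
Poisson-lognormal likelihood; DIC uses the same marginalised deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data_io import CountTable
from .design import DesignMatrix, ModelSpec, encode_design
from .model import (
    MCMCConfig,
    PosteriorDraws,
    _marginal_loglik_mu,
    fit_mcmc,
    marginal_moments,
)

__all__ = [
    "pearson_residuals",
    "dic",
    "bayes_factor_approx",
    "forward_select",
    "SelectionTrace",
    "SelectionConfig",
]


# ---------------------------------------------------------------------------
# Pearson residuals


def pearson_residuals(draws: PosteriorDraws, design: DesignMatrix,
                      table: CountTable, variance_mode: str = "corrected") -> pd.DataFrame:
    """Per-cell Pearson residuals r = (C - E[C]) / sqrt(Var[C]).

    The fitted rate uses the posterior means: E[C] = E exp(x'beta_bar +
    sigma2_bar/2). ``variance_mode`` selects the marginal-variance formula:

    - "corrected": Var = m (1 + m (exp(sigma2) - 1)), the Poisson-lognormal
      marginal variance;
    - "literal": Var = m (1 + m exp(sigma2 - 1)), an alternative
      printed form kept for comparison (dimensionally inconsistent with the
      marginal variance; see docs/methods.md).
    """
    if variance_mode not in ("corrected", "literal"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    beta_bar = draws.beta_mean
    s2_bar = draws.sigma2_mean
    linpred = design.X @ beta_bar
    C = table.counts.astype(float)
    E = table.exposures
    m, var = marginal_moments(linpred, s2_bar, E)
    if variance_mode == "literal":
        var = m * (1.0 + m * np.exp(s2_bar - 1.0))
    out = table.strata()
    out["fitted_mean"] = m
    out["residual"] = (C - m) / np.sqrt(var)
    return out


# ---------------------------------------------------------------------------
# DIC


def dic(draws: PosteriorDraws, design: DesignMatrix, table: CountTable,
        n_nodes: int = 25, max_draws: int = 400) -> tuple[float, float]:
    """Deviance Information Criterion on the marginalised likelihood.

    The deviance is D(beta, sigma2) = -2 log p(C | beta, sigma2) with the
    latent rates integrated out by Gauss-Hermite quadrature. DIC =
    D(posterior means) + 2 p_D where p_D = mean deviance - deviance at the
    posterior means. Returns (DIC, p_D).
    """
    idx = np.arange(draws.n_draws)
    if draws.n_draws > max_draws:
        idx = np.linspace(0, draws.n_draws - 1, max_draws).astype(int)
    beta = draws.beta[idx]
    sigma2 = draws.sigma2[idx]
    mu = design.X @ beta.T  # cells x draws
    ll = _marginal_loglik_mu(mu, sigma2, table, n_nodes)
    dev = -2.0 * np.asarray(ll)
    finite = np.isfinite(dev)
    if not finite.all():
        import warnings

        warnings.warn(f"{(~finite).sum()} non-finite deviance draws dropped", stacklevel=2)
        dev = dev[finite]
    d_bar = float(dev.mean())
    d_hat = -2.0 * _marginal_loglik_mu(design.X @ draws.beta_mean,
                                       draws.sigma2_mean, table, n_nodes)
    p_d = d_bar - d_hat
    return d_hat + 2.0 * p_d, p_d


# ---------------------------------------------------------------------------
# BIC-approximate Bayes factor


def _max_marginal_loglik(design: DesignMatrix, table: CountTable,
                         beta0: np.ndarray, sigma2_0: float,
                         n_nodes: int = 25) -> float:
    """Maximise the quadrature marginal log-likelihood over (beta, log sigma2)."""

    def negll(params: np.ndarray) -> float:
        beta = params[:-1]
        sigma2 = np.exp(params[-1])
        try:
            ll = _marginal_loglik_mu(design.X @ beta, sigma2, table, n_nodes)
        except FloatingPointError:
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.concatenate([beta0, [np.log(max(sigma2_0, 1e-6))]])
    res = optimize.minimize(negll, x0, method="L-BFGS-B",
                            options={"maxiter": 500})
    return -float(res.fun)


def bayes_factor_approx(fit1: tuple[PosteriorDraws, DesignMatrix],
                        fit0: tuple[PosteriorDraws, DesignMatrix],
                        table: CountTable, n_nodes: int = 25) -> float:
    """Schwarz-approximate Bayes factor of model 1 over model 0.

    BF = exp(-(BIC1 - BIC0)/2) with BIC = -2 max marginal log-likelihood +
    (p+1) log n, the +1 counting the overdispersion variance. This is a
    documented large-sample approximation, not an exact marginal-likelihood
    ratio.
    """
    draws1, design1 = fit1
    draws0, design0 = fit0
    if design1.n_cells != design0.n_cells:
        raise ValueError("models were fitted to different data")
    n = design1.n_cells
    ll1 = _max_marginal_loglik(design1, table, draws1.beta_mean, draws1.sigma2_mean, n_nodes)
    ll0 = _max_marginal_loglik(design0, table, draws0.beta_mean, draws0.sigma2_mean, n_nodes)
    bic1 = -2.0 * ll1 + (design1.p + 1) * np.log(n)
    bic0 = -2.0 * ll0 + (design0.p + 1) * np.log(n)
    # cap the exponent: beyond exp(700) the evidence is decisive anyway and
    # np.exp would overflow to inf with a warning
    return float(np.exp(min(-0.5 * (bic1 - bic0), 700.0)))


# ---------------------------------------------------------------------------
# forward selection


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for one forward-selection pass."""

    outcome: str = "incidence"
    mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        iterations=3_000, burn_in=1_000, thinning=2))
    seed: int = 0
    n_nodes: int = 25
    bf_threshold: float = 3.0


@dataclass
class SelectionRecord:
    term: str
    dic: float | None
    delta_dic: float | None
    bayes_factor: float | None
    accepted: bool
    note: str = ""


@dataclass
class SelectionTrace:
    """Audit trail of a forward-selection pass."""

    records: list[SelectionRecord]
    final_spec: ModelSpec
    null_dic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "term": r.term, "dic": r.dic, "delta_dic": r.delta_dic,
            "bayes_factor": r.bayes_factor, "accepted": r.accepted, "note": r.note,
        } for r in self.records])

    @property
    def accepted_terms(self) -> list[str]:
        return [r.term for r in self.records if r.accepted]


def _term_parents_present(term: str, spec: ModelSpec) -> bool:
    if ":" not in term or term.startswith("year^") or term in ("AAD", "AAD:region"):
        return True
    parents = term.split(":")
    return all(p.split("^")[0] in spec.main_terms for p in parents)


def forward_select(candidates: list[str], table: CountTable,
                   config: SelectionConfig | None = None,
                   aad=None) -> SelectionTrace:
    """Greedy single-pass forward selection from the null model.

    Candidates are visited in the given order (main effects are expected
    before the interactions that involve them). A candidate is accepted when
    the augmented model lowers the DIC or attains a Bayes factor above the
    threshold against the current model. Interactions whose parents were
    not retained are skipped with a note rather than fitted.
    """
    config = config or SelectionConfig()
    for term in candidates:
        if ":" in term and not term.startswith("year^") and term not in ("AAD", "AAD:region"):
            parents = [p.split("^")[0] for p in term.split(":")]
            for p in parents:
                if p not in candidates and p not in ("AAD",):
                    raise ValueError(f"interaction {term!r} parent {p!r} not among candidates")

    spec = ModelSpec(outcome=config.outcome, main_terms=(), year_max_power=1)
    design = encode_design(spec, table, aad=aad)
    fit = fit_mcmc(design, table, config.mcmc, seed=config.seed)
    cur_dic, _ = dic(fit, design, table, config.n_nodes)
    null_dic = cur_dic
    records: list[SelectionRecord] = []

    for i, term in enumerate(candidates):
        if not _term_parents_present(term, spec):
            records.append(SelectionRecord(term, None, None, None, False,
                                           note="skipped: parent terms not in model"))
            continue
        try:
            new_spec = spec.with_term(term)
        except ValueError as exc:
            records.append(SelectionRecord(term, None, None, None, False,
                                           note=f"invalid: {exc}"))
            continue
        new_design = encode_design(new_spec, table, aad=aad)
        new_fit = fit_mcmc(new_design, table, config.mcmc, seed=config.seed + i + 1)
        new_dic, _ = dic(new_fit, new_design, table, config.n_nodes)
        bf = bayes_factor_approx((new_fit, new_design), (fit, design), table,
                                 config.n_nodes)
        delta = new_dic - cur_dic
        accepted = (delta < 0.0) or (bf > config.bf_threshold)
        records.append(SelectionRecord(term, new_dic, delta, bf, accepted))
        if accepted:
            spec, design, fit, cur_dic = new_spec, new_design, new_fit, new_dic

    return SelectionTrace(records=records, final_spec=spec, null_dic=null_dic)
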