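"""Average age-at-diagnosis (AAD) and its mortality linkage.

AAD summarises, per stratum, the age profile of incidence: it is the
standard-population-weighted, incidence-weighted mean of band midpoint
ages,

    AAD_{t,d,g,r} = sum_a a * theta_{a,t,d,g,r} E_a^std
                    / sum_a theta_{a,t,d,g,r} E_a^std ,

computed from fitted incidence rates and ESP 2013 weights E_a^std, then
population-weighted over the study years to one cross-sectional value per
(decile, gender, region). Entered as a standardised numerical covariate in
the mortality model with slope gamma (plus sum-to-zero regional deviations
gamma_r when an AAD:region interaction is present), a delay of delta years
in diagnosis multiplies mortality rates by exp((gamma + gamma_r) delta / s)
where s is the standardisation scale in years; impacts are reported as
percentage increases with equal-tailed 95% credible intervals taken over
posterior draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .age_bands import AgeBandScheme
from .data_io import CountTable
from .design import DesignMatrix
from .model import FittedRates, PosteriorDraws
from .standardise import StandardPopulation

__all__ = [
    "AADTable",
    "DelayImpact",
    "aad_by_year",
    "aad_weighted",
    "standardise_aad",
    "aad_covariate",
    "delay_impact",
    "delay_impact_pooled",
    "region_contribution",
    "latency_scenario",
]


@dataclass
class AADTable:
    """AAD draws (draws x strata) with their stratum labels."""

    draws: np.ndarray
    index: pd.DataFrame

    def __post_init__(self) -> None:
        if self.draws.shape[1] != len(self.index):
            raise ValueError("draws and index are misaligned")

    @property
    def means(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        q = np.quantile(self.draws, [0.025, 0.975], axis=0)
        out = self.index.copy()
        out["mean"] = self.means
        out["lo95"] = q[0]
        out["hi95"] = q[1]
        return out


def aad_by_year(rates: FittedRates, std: StandardPopulation,
                scheme: AgeBandScheme) -> AADTable:
    """AAD per (year, decile, gender, region), per posterior draw.

    Weighted mean of band midpoints with weights theta_a * w_a; invariant
    to any rescaling of the rates. Raises if some stratum has all-zero
    weighted rates.
    """
    strata = rates.strata.reset_index(drop=True)
    w = strata["age_band"].map(std.weights).to_numpy(float)
    if np.any(~np.isfinite(w)):
        bad = strata.loc[~np.isfinite(w), "age_band"].unique()
        raise ValueError(f"no standard weights for bands: {sorted(bad)}")
    mids = strata["age_band"].map(scheme.midpoint).to_numpy(float)
    group_cols = ["year", "decile", "gender", "region"]
    groups = strata.groupby(group_cols, sort=True)
    cols, labels = [], []
    theta = rates.theta
    for key in sorted(groups.indices):
        idx = groups.indices[key]
        wk = w[idx]
        num = theta[:, idx] @ (mids[idx] * wk)
        den = theta[:, idx] @ wk
        if np.any(den <= 0):
            raise ValueError(f"all-zero weighted rates in stratum {key}")
        cols.append(num / den)
        labels.append(key)
    return AADTable(draws=np.column_stack(cols),
                    index=pd.DataFrame(labels, columns=group_cols))


def aad_weighted(aad: AADTable, exposures: CountTable | pd.DataFrame,
                 over_deciles: bool = False) -> AADTable:
    """Population-weighted AAD over years (optionally also over deciles).

    ``exposures`` supplies E_{t,d,g,r}: either a count table (exposures are
    summed over age bands) or a frame with columns year, decile, gender,
    region, exposure. When the mortality model omits deprivation, pass
    ``over_deciles=True`` to additionally average across deciles.
    """
    if isinstance(exposures, CountTable):
        pop = (exposures.data.groupby(["year", "decile", "gender", "region"],
                                      as_index=False)["exposure"].sum())
    else:
        pop = exposures.copy()
    merged = aad.index.reset_index().merge(
        pop, on=["year", "decile", "gender", "region"], how="left")
    if merged["exposure"].isna().any():
        missing = merged.loc[merged["exposure"].isna(),
                             ["year", "decile", "gender", "region"]]
        raise ValueError(f"missing exposures for strata:\n{missing.head()}")
    group_cols = ["gender", "region"] if over_deciles else ["decile", "gender", "region"]
    groups = merged.groupby(group_cols, sort=True)
    cols, labels = [], []
    for key in sorted(groups.indices):
        sub = merged.iloc[groups.indices[key]]
        wk = sub["exposure"].to_numpy(float)
        cols.append(aad.draws[:, sub["index"].to_numpy()] @ (wk / wk.sum()))
        labels.append(key if isinstance(key, tuple) else (key,))
    return AADTable(draws=np.column_stack(cols),
                    index=pd.DataFrame(labels, columns=group_cols))


def standardise_aad(values) -> tuple[np.ndarray, float, float]:
    """Zero-mean, unit-variance scaling of AAD values.

    Returns (scaled values, mean, scale s); population (divide-by-n)
    standard deviation, so a calendar delay of delta years corresponds to
    delta / s standardised units.
    """
    vals = np.asarray(values, dtype=float)
    if np.unique(vals).size < 2:
        raise ValueError("AAD values are all identical; covariate uninformative")
    mean = float(vals.mean())
    s = float(vals.std())
    return (vals - mean) / s, mean, s


def aad_covariate(table: CountTable, aad: AADTable,
                  values: np.ndarray | None = None) -> np.ndarray:
    """Per-cell AAD values (years) aligned with a mortality table's rows.

    By default the AAD table's posterior means are joined on its stratum
    columns; pass ``values`` (one value per AAD stratum, e.g. a single
    posterior draw) to join those instead. Every table row must match
    exactly one AAD stratum.
    """
    key_cols = [c for c in ["year", "decile", "gender", "region"] if c in aad.index.columns]
    lookup = aad.index.copy()
    lookup["aad"] = aad.means if values is None else np.asarray(values, dtype=float)
    merged = table.data.merge(lookup, on=key_cols, how="left")
    if merged["aad"].isna().any():
        missing = merged.loc[merged["aad"].isna(), key_cols].drop_duplicates()
        raise ValueError(f"no AAD value for strata:\n{missing.head()}")
    return merged["aad"].to_numpy(float)


@dataclass
class DelayImpact:
    """Percentage mortality increase for a diagnosis delay of delta years."""

    delta: float
    draws: np.ndarray          # percentage increases per posterior draw
    region: str | None = None
    has_region_interaction: bool = False

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.draws, [0.025, 0.975])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.interval
        return {"delta_years": self.delta, "region": self.region,
                "mean_pct": self.mean, "lo95_pct": lo, "hi95_pct": hi}


def _slope_draws(draws: PosteriorDraws, design: DesignMatrix,
                 region: str | None) -> np.ndarray:
    gamma, gamma_r = design.aad_slopes(draws.beta)
    if gamma_r is None:
        if region is not None:
            warnings.warn("model has no AAD:region interaction; region ignored",
                          stacklevel=3)
        return gamma
    if region is None:
        raise ValueError("model has an AAD:region interaction; region is required")
    levels = design.factor_levels["region"]
    if region not in levels:
        raise KeyError(f"unknown region {region!r}; have {levels}")
    return gamma + gamma_r[..., levels.index(region)]


def delay_impact(draws: PosteriorDraws, design: DesignMatrix, s: float,
                 delta: float, region: str | None = None) -> DelayImpact:
    """Mortality impact of a diagnosis delay of *delta* years.

    Per posterior draw the multiplicative factor on mortality rates is
    exp((gamma + gamma_region) * delta / s); the impact is 100 * (factor -
    1) percent. ``s`` is the AAD standardisation scale in years (from
    ``design.aad_params`` or :func:`standardise_aad`).
    """
    if delta < 0:
        raise ValueError("delay must be non-negative")
    if s <= 0:
        raise ValueError("scale s must be positive")
    slopes = _slope_draws(draws, design, region)
    pct = 100.0 * np.expm1(slopes * delta / s)
    return DelayImpact(delta=float(delta), draws=pct, region=region,
                       has_region_interaction="AAD:region" in design.blocks)


def region_contribution(draws: PosteriorDraws, design: DesignMatrix) -> pd.DataFrame:
    """Per-region AAD effect relative to the across-region average slope.

    Per draw, factor_r = (gamma + gamma_r) / gamma_bar where gamma_bar is
    the mean slope over regions (equal to gamma under the sum-to-zero
    constraint); a value of 1.1 marks a region where age-at-diagnosis has a
    10% larger impact than average. Flagged unstable when the average
    slope's sign varies in more than 5% of draws.
    """
    gamma, gamma_r = design.aad_slopes(draws.beta)
    if gamma_r is None:
        raise ValueError("model has no AAD:region interaction")
    slopes = gamma[:, None] + gamma_r
    gamma_bar = slopes.mean(axis=1)
    sign_frac = min((gamma_bar > 0).mean(), (gamma_bar < 0).mean())
    unstable = bool(sign_frac > 0.05)
    if unstable:
        warnings.warn("average AAD slope is sign-unstable across draws; "
                      "regional contribution factors are unreliable", stacklevel=2)
    factors = slopes / gamma_bar[:, None]
    q = np.quantile(factors, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "region": design.factor_levels["region"],
        "factor_mean": factors.mean(axis=0),
        "lo95": q[0],
        "hi95": q[1],
        "unstable": unstable,
    })


def delay_impact_pooled(mortality: CountTable, mort_spec, aad: AADTable,
                        mcmc_config, seed: int, delta: float,
                        region: str | None = None,
                        n_imputations: int = 5) -> DelayImpact:
    """Delay impact with AAD posterior uncertainty propagated.

    The AAD covariate is itself an estimate (a functional of the fitted
    incidence rates); plugging in its posterior mean understates the
    uncertainty of the delay impact. Here the mortality model is refitted
    for ``n_imputations`` AAD posterior draws (evenly spaced through the
    chain) and the per-draw impact percentages are pooled across fits —
    a multiple-imputation approximation to the joint posterior.
    """
    from .design import encode_design
    from .model import fit_mcmc

    if n_imputations < 1:
        raise ValueError("n_imputations must be >= 1")
    if aad.draws.shape[0] < n_imputations:
        raise ValueError("not enough AAD draws for the requested imputations")
    pick = np.linspace(0, aad.draws.shape[0] - 1, n_imputations).astype(int)
    pooled = []
    for m, j in enumerate(pick):
        vals = aad_covariate(mortality, aad, values=aad.draws[j])
        design = encode_design(mort_spec, mortality, aad=vals)
        fit = fit_mcmc(design, mortality, mcmc_config, seed=seed + m)
        imp = delay_impact(fit, design, design.aad_params[1], delta, region=region)
        pooled.append(imp.draws)
    return DelayImpact(delta=float(delta), draws=np.concatenate(pooled), region=region,
                       has_region_interaction="AAD:region" in mort_spec.aad_terms)


def latency_scenario(draws: PosteriorDraws, design: DesignMatrix, s: float,
                     per_year_increase: float, horizon: float,
                     region: str | None = None) -> DelayImpact:
    """Impact of a sustained latency increase.

    A drift of ``per_year_increase`` years in age-at-diagnosis per calendar
    year, over ``horizon`` years, aggregates to a shift of
    per_year_increase * horizon years; the impact is that of a single delay
    of the aggregate size.
    """
    if horizon < 0 or per_year_increase < 0:
        raise ValueError("latency increase and horizon must be non-negative")
    return delay_impact(draws, design, s, per_year_increase * horizon, region=region)
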