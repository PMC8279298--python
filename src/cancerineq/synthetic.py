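"""Synthetic stratified count data with known ground truth.

The generator emulates national registry extracts: one cell per (age band,
year, gender, deprivation decile, region) with a population exposure and a
count, produced under exactly the statistical structure the hierarchical
model assumes — log-linear covariate effects with lognormal cell-level
overdispersion and Poisson observation noise:

    theta = exp(x' beta_true + eps),  eps ~ Normal(0, sigma2_true)
    C ~ Poisson(theta * E)

Exposures follow a lognormal spread around an age-profile template
(flat to age 60, declining geometrically above), scaled by
``exposure_scale``. One global seed is expanded into independent
substreams for exposures, overdispersion noise and counts, so each stage
is individually reproducible.

``make_delay_scenario`` additionally plants a mortality dependence on the
average age-at-diagnosis derived from the incidence truth, for end-to-end
recovery tests of the delay-impact machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .age_bands import AgeBandScheme
from .data_io import GENDERS, CountTable
from .design import (
    DesignMatrix,
    ModelSpec,
    contrast_coefs_from_effects,
    encode_design,
)
from .model import FittedRates
from .standardise import StandardPopulation

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "DelayScenario",
    "generate_scenario",
    "simulate_counts",
    "make_delay_scenario",
    "default_scenario",
    "delay_scenario_config",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth description of one synthetic scenario.

    ``true_effects`` maps term names to their true values:

    - "intercept", "year", "year^2", "year^3": scalars;
    - factors ("age", "gender", "deprivation", "region"): full-level effect
      vectors summing to zero, ordered as the design orders levels (bands
      by age, genders male-first, deciles ascending, regions sorted);
    - interactions like "age:year": a pair (left value, right value) whose
      separable product is planted (factor sides as full-level vectors,
      year sides as scalars).
    """

    years: tuple[int, ...]
    regions: tuple[str, ...]
    deciles: tuple[int, ...]
    genders: tuple[str, ...]
    age_bands: tuple[str, ...]
    true_sigma2: float
    true_effects: dict
    exposure_scale: float
    seed: int
    age_mode: str = "categorical"
    exposure_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("years", "regions", "deciles", "genders", "age_bands"):
            if not getattr(self, name):
                raise ValueError(f"empty strata list: {name}")
        years = list(self.years)
        if years != list(range(min(years), max(years) + 1)):
            raise ValueError("years must be contiguous")
        if len(set(self.deciles)) != len(self.deciles):
            raise ValueError("deciles must be distinct")
        if any(not 1 <= d <= 10 for d in self.deciles):
            raise ValueError("deciles must lie in 1..10")
        if len(self.regions) > 9:
            raise ValueError("at most 9 regions")
        if any(g not in GENDERS for g in self.genders):
            raise ValueError(f"genders must be a subset of {GENDERS}")
        if self.true_sigma2 < 0:
            raise ValueError("true_sigma2 must be >= 0")
        if self.exposure_scale <= 0:
            raise ValueError("exposure_scale must be > 0")
        AgeBandScheme.from_labels(list(self.age_bands))  # validates ordering

    @property
    def scheme(self) -> AgeBandScheme:
        return AgeBandScheme.from_labels(list(self.age_bands))

    @property
    def n_cells(self) -> int:
        return (len(self.age_bands) * len(self.years) * len(self.genders)
                * len(self.deciles) * len(self.regions))

    def model_spec(self, outcome: str = "incidence") -> ModelSpec:
        """The ModelSpec implied by the keys of ``true_effects``."""
        mains, inters = [], []
        ypow = 0
        for term in self.true_effects:
            if term == "intercept":
                continue
            if term in ("year", "year^2", "year^3"):
                ypow = max(ypow, 1 if term == "year" else int(term[-1]))
            elif ":" in term:
                inters.append(term)
            else:
                mains.append(term)
        if ypow:
            mains.append("year")
        for term in inters:
            for parent in term.split(":"):
                base = parent.split("^")[0]
                if base not in mains:
                    raise ValueError(f"interaction {term!r} parent {base!r} has no main effect")
        order = {t: i for i, t in enumerate(("age", "year", "gender", "deprivation", "region"))}
        return ModelSpec(
            outcome=outcome,
            main_terms=tuple(sorted(set(mains), key=order.get)),
            age_mode=self.age_mode,
            year_max_power=max(ypow, 1),
            interactions=tuple(inters),
        )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated scenario."""

    config: ScenarioConfig
    spec: ModelSpec
    design: DesignMatrix
    table: CountTable            # grid with exposures; counts all zero
    beta_true: np.ndarray        # aligned with design.columns
    sigma2_true: float
    latent_rates: np.ndarray     # theta per cell
    exposures: np.ndarray
    counts_seed: np.random.SeedSequence = field(repr=False, default=None)

    def fitted_rates(self) -> FittedRates:
        """The true rates wrapped as a single-'draw' rate object."""
        return FittedRates(theta=self.latent_rates[None, :], strata=self.table.strata())


def _age_profile(midpoints: np.ndarray) -> np.ndarray:
    """Population template: flat to age 60, geometric decline above."""
    return np.where(midpoints <= 60.0, 1.0, np.exp(-0.05 * (midpoints - 60.0)))


def _beta_true_from_effects(config: ScenarioConfig, design: DesignMatrix) -> np.ndarray:
    beta = np.zeros(design.p)
    effects = config.true_effects

    def put(term: str, coefs: np.ndarray) -> None:
        sl = design.term_slice(term)
        coefs = np.atleast_1d(np.asarray(coefs, dtype=float)).ravel()
        if coefs.size != sl.stop - sl.start:
            raise ValueError(f"term {term!r}: expected {sl.stop - sl.start} "
                             f"coefficients, got {coefs.size}")
        beta[sl] = coefs

    def side_coefs(name: str, value) -> np.ndarray:
        if np.ndim(value) == 0:
            return np.array([float(value)])
        return contrast_coefs_from_effects(np.asarray(value, dtype=float))

    year_coefs = np.zeros(design.blocks["year"][1] - design.blocks["year"][0]) \
        if "year" in design.blocks else None
    for term, value in effects.items():
        if term == "intercept":
            put("intercept", value)
        elif term in ("year", "year^2", "year^3"):
            k = 1 if term == "year" else int(term[-1])
            year_coefs[k - 1] = float(value)
        elif ":" in term:
            f1, f2 = term.split(":")
            v1, v2 = value
            coefs = np.outer(side_coefs(f1, v1), side_coefs(f2, v2)).ravel()
            put(term, coefs)
        elif term == "age" and config.age_mode == "numerical":
            put("age", value)
        else:
            put(term, contrast_coefs_from_effects(np.asarray(value, dtype=float)))
    if year_coefs is not None:
        put("year", year_coefs)
    return beta


def generate_scenario(config: ScenarioConfig,
                      extra_linpred: np.ndarray | None = None) -> SyntheticTruth:
    """Lay out the stratum grid and draw exposures and latent rates.

    ``extra_linpred`` adds a fixed per-cell offset to the log-rate (used to
    plant AAD effects); it must align with the canonical cell order.
    """
    scheme = config.scheme
    grid = pd.DataFrame(
        itertools.product(config.age_bands, sorted(config.years),
                          config.genders, sorted(config.deciles),
                          sorted(config.regions)),
        columns=["age_band", "year", "gender", "decile", "region"],
    )
    ss = np.random.SeedSequence(config.seed)
    ss_expo, ss_eps, ss_counts = ss.spawn(3)

    mids = grid["age_band"].map(scheme.midpoint).to_numpy(float)
    rng_e = np.random.default_rng(ss_expo)
    jitter = rng_e.lognormal(mean=0.0, sigma=config.exposure_jitter_sd, size=len(grid))
    exposures = config.exposure_scale * _age_profile(mids) * jitter

    grid["count"] = 0
    grid["exposure"] = exposures
    table = CountTable(grid, scheme=scheme, regions=tuple(sorted(config.regions)))
    # CountTable sorts rows canonically; recover aligned exposures
    exposures = table.exposures

    spec = config.model_spec()
    design = encode_design(spec, table)
    beta_true = _beta_true_from_effects(config, design)

    rng_eps = np.random.default_rng(ss_eps)
    eps = (rng_eps.normal(0.0, np.sqrt(config.true_sigma2), size=len(table))
           if config.true_sigma2 > 0 else np.zeros(len(table)))
    linpred = design.X @ beta_true
    if extra_linpred is not None:
        extra_linpred = np.asarray(extra_linpred, dtype=float)
        if extra_linpred.shape != linpred.shape:
            raise ValueError("extra_linpred misaligned with the cell grid")
        linpred = linpred + extra_linpred
    theta = np.exp(linpred + eps)
    return SyntheticTruth(config=config, spec=spec, design=design, table=table,
                          beta_true=beta_true, sigma2_true=config.true_sigma2,
                          latent_rates=theta, exposures=exposures,
                          counts_seed=ss_counts)


def simulate_counts(truth: SyntheticTruth) -> CountTable:
    """Draw independent Poisson counts C ~ Poisson(theta * E) per cell."""
    rng = np.random.default_rng(truth.counts_seed)
    counts = rng.poisson(truth.latent_rates * truth.exposures)
    df = truth.table.data.copy()
    df["count"] = counts
    return CountTable(df, scheme=truth.table.scheme, regions=truth.table.regions)


@dataclass
class DelayScenario:
    """Linked incidence/mortality pair with a planted AAD effect."""

    incidence_truth: SyntheticTruth
    incidence: CountTable
    mortality_truth: SyntheticTruth
    mortality: CountTable
    aad_values: np.ndarray       # per mortality cell, years
    aad_mean: float
    aad_scale: float             # s: years per standardised unit
    gamma_true: float            # slope per standardised AAD unit
    gamma_region: np.ndarray     # per-region deviations, sum-to-zero


def make_delay_scenario(config: ScenarioConfig, gamma_true: float,
                        gamma_region: np.ndarray | None = None,
                        mortality_config: ScenarioConfig | None = None) -> DelayScenario:
    """Generate an incidence table and a mortality table that depends on AAD.

    The average age-at-diagnosis is computed from the incidence *truth*
    rates (ESP-weighted over bands, population-weighted over years),
    standardised over the mortality cells, and (gamma_true +
    gamma_region[r]) times the standardised value is added to the mortality
    log-rate. ``gamma_region`` must sum to zero (sum-to-zero convention)
    and align with the sorted region labels; None plants no regional
    variation.
    """
    from .aad import aad_by_year, aad_covariate, aad_weighted, standardise_aad

    regions = tuple(sorted(config.regions))
    if gamma_region is None:
        gamma_region = np.zeros(len(regions))
    gamma_region = np.asarray(gamma_region, dtype=float)
    if gamma_region.shape != (len(regions),):
        raise ValueError(f"gamma_region must have length {len(regions)}")
    if abs(gamma_region.sum()) > 1e-8 * max(1.0, np.abs(gamma_region).max()):
        raise ValueError("gamma_region must sum to zero")

    inc_truth = generate_scenario(config)
    inc_counts = simulate_counts(inc_truth)

    std = StandardPopulation.esp2013(config.scheme)
    by_year = aad_by_year(inc_truth.fitted_rates(), std, config.scheme)
    weighted = aad_weighted(by_year, inc_counts)

    mort_config = mortality_config or replace(config, seed=config.seed + 1)
    # grid layout only (exposures/eps drawn from the mortality seed)
    mort_grid_truth = generate_scenario(mort_config)
    aad_vals = aad_covariate(mort_grid_truth.table, weighted)
    z, aad_mean, s = standardise_aad(aad_vals)
    region_codes = mort_grid_truth.table.data["region"].map(
        {r: i for i, r in enumerate(regions)}).to_numpy()
    extra = (gamma_true + gamma_region[region_codes]) * z
    mort_truth = generate_scenario(mort_config, extra_linpred=extra)
    mort_counts = simulate_counts(mort_truth)
    return DelayScenario(
        incidence_truth=inc_truth, incidence=inc_counts,
        mortality_truth=mort_truth, mortality=mort_counts,
        aad_values=aad_vals, aad_mean=aad_mean, aad_scale=s,
        gamma_true=float(gamma_true), gamma_region=gamma_region,
    )


def delay_scenario_config(seed: int = 0, **overrides) -> ScenarioConfig:
    """Study conditions for the incidence->AAD->mortality linkage bench.

    Identification of the AAD slope needs the average age-at-diagnosis to
    vary across deprivation deciles and regions over and above their main
    effects, so this scenario plants age:deprivation and age:region
    interactions (steeper age gradients in more deprived and northern
    strata) across 4 regions x 6 deciles x 9 bands x 8 years; exposures
    around one million person-years give registry-scale counts so the AAD
    covariate is estimated with small error relative to its spread
    (roughly +-2 years across strata).
    """
    params = dict(
        regions=("East", "North", "South", "West"),
        deciles=(1, 2, 4, 6, 8, 10),
        exposure_scale=1.0e6,
    )
    params.update(overrides)
    n_bands = len(params.get("age_bands", AgeBandScheme.five_year(45, 80).labels))
    n_dec = len(params["deciles"])
    n_reg = len(params["regions"])
    if "true_effects" not in params and min(n_bands, n_dec, n_reg) > 1:
        age_eff = np.linspace(-1.2, 1.2, n_bands)
        age_eff -= age_eff.mean()
        dep_eff = np.linspace(0.25, -0.25, n_dec)
        dep_eff -= dep_eff.mean()
        if n_reg == 4:
            reg_eff = np.array([0.10, 0.03, -0.05, -0.08])
        else:
            reg_eff = np.linspace(0.10, -0.08, n_reg)
            reg_eff -= reg_eff.mean()
        params["true_effects"] = {
            "intercept": -7.0,
            "age": age_eff,
            "year": 0.10,
            "deprivation": dep_eff,
            "region": reg_eff,
            "age:deprivation": (age_eff * 0.6, dep_eff * 2.5),
            "age:region": (age_eff * 0.6, reg_eff * 2.5),
        }
    return default_scenario(seed=seed, **params)


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Desk-scale study conditions used throughout the test-bench.

    2 regions x 4 deciles x 9 five-year bands (45-49 ... 85+) x 8 years,
    one gender: 576 cells. Effects mimic a lifestyle-linked cancer: steep
    age gradient, mild secular trend, a deprivation gradient with the most
    deprived decile highest, and a modest north-south contrast; cell-level
    overdispersion sigma2 = 0.05 and exposures around 100,000 person-years
    give counts from a few dozen to a few hundred per cell.
    """
    params = dict(
        years=tuple(range(2001, 2009)),
        regions=("North", "South"),
        deciles=(1, 4, 7, 10),
        genders=("female",),
        age_bands=tuple(AgeBandScheme.five_year(45, 80).labels),
        true_sigma2=0.05,
        exposure_scale=1.0e5,
        seed=seed,
    )
    params.update(overrides)
    strata_ok = all(len(params[k]) > 0 for k in
                    ("age_bands", "deciles", "regions", "genders"))
    if "true_effects" not in params and not strata_ok:
        params["true_effects"] = {"intercept": -7.0}  # constructor rejects empty strata
    if "true_effects" not in params:

        def _centred(span: float, n: int) -> np.ndarray:
            v = np.linspace(span, -span, n)
            return v - v.mean()

        effects = {
            "intercept": -7.0,
            "age": -_centred(1.2, len(params["age_bands"])),
            "year": 0.10,
            "deprivation": _centred(0.19, len(params["deciles"])),
            "region": _centred(0.08, len(params["regions"])),
        }
        if len(params["genders"]) > 1:
            effects["gender"] = _centred(0.05, len(params["genders"]))
        params["true_effects"] = effects
    return ScenarioConfig(**params)
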