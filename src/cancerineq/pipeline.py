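"""End-to-end pipeline: simulate/load -> fit -> standardise -> link -> report.

A single :class:`PipelineConfig` (usually loaded from YAML) drives all
stages; every stage writes tidy CSV artifacts plus a JSON manifest holding
the seed, a config hash and the file list, so any stage can be re-run and
audited. All randomness flows from the one configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .aad import (
    aad_by_year,
    aad_covariate,
    aad_weighted,
    delay_impact,
    latency_scenario,
    region_contribution,
)
from .age_bands import AgeBandScheme
from .data_io import CountTable, read_count_table, write_count_table
from .design import ModelSpec, encode_design
from .model import MCMCConfig, fit_mcmc
from .selection import SelectionConfig, forward_select
from .standardise import (
    StandardPopulation,
    age_standardise,
    deprivation_gap_AD,
    relative_gap_RD,
    temporal_change_AC,
)
from .synthetic import ScenarioConfig, generate_scenario, make_delay_scenario, simulate_counts

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("cancerineq")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings."""

    seed: int
    output_dir: Path
    scenario: ScenarioConfig | None = None
    incidence_path: Path | None = None
    mortality_path: Path | None = None
    age_bands: tuple[str, ...] = ()
    incidence_model: ModelSpec | None = None
    mortality_model: ModelSpec | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    delays: tuple[float, ...] = (1.0, 0.5, 0.25)
    latency: dict | None = None
    gamma_true: float = 0.0
    gamma_region: tuple[float, ...] | None = None
    select_candidates: tuple[str, ...] = ()
    gap_years: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        self.output_dir = Path(self.output_dir)
        if self.scenario is None and self.incidence_path is None:
            raise ValueError("config needs either a synthetic scenario or input paths")


def _spec_from_dict(d: dict, outcome: str) -> ModelSpec:
    return ModelSpec(
        outcome=outcome,
        main_terms=tuple(d.get("main_terms", ())),
        age_mode=d.get("age_mode", "categorical"),
        year_max_power=int(d.get("year_max_power", 1)),
        interactions=tuple(d.get("interactions", ())),
        aad_terms=tuple(d.get("aad_terms", ())),
        cancer_type=d.get("cancer_type", "all"),
    )


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError(f"{path}: config must set a seed")
    scenario = None
    if "scenario" in raw:
        sc = dict(raw["scenario"])
        sc.setdefault("seed", raw["seed"])
        for key in ("years", "regions", "deciles", "genders", "age_bands"):
            if key in sc:
                sc[key] = tuple(sc[key])
        if "true_effects" in sc:
            sc["true_effects"] = {
                k: (np.asarray(v, dtype=float) if isinstance(v, (list, tuple)) else v)
                for k, v in sc["true_effects"].items()
            }
            scenario = ScenarioConfig(**sc)
        else:
            # no planted effects given: fill them in from the strata sizes
            from .synthetic import default_scenario

            scenario = default_scenario(seed=sc.pop("seed"), **sc)
    mcmc_kw = raw.get("mcmc", {})
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw.get("output_dir", "cancerineq_out")),
        scenario=scenario,
        incidence_path=Path(raw["incidence"]) if "incidence" in raw else None,
        mortality_path=Path(raw["mortality"]) if "mortality" in raw else None,
        age_bands=tuple(raw.get("age_bands", ())),
        incidence_model=_spec_from_dict(raw["incidence_model"], "incidence")
        if "incidence_model" in raw else None,
        mortality_model=_spec_from_dict(raw["mortality_model"], "mortality")
        if "mortality_model" in raw else None,
        mcmc=MCMCConfig(**mcmc_kw) if mcmc_kw else MCMCConfig(),
        delays=tuple(raw.get("delays", (1.0, 0.5, 0.25))),
        latency=raw.get("latency"),
        gamma_true=float(raw.get("gamma_true", 0.0)),
        gamma_region=tuple(raw["gamma_region"]) if "gamma_region" in raw else None,
        select_candidates=tuple(raw.get("select_candidates", ())),
        gap_years=tuple(raw["gap_years"]) if "gap_years" in raw else None,
    )


def _config_hash(config: PipelineConfig) -> str:
    payload = repr(config).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and return the artifact manifest.

    Stages: data (simulate or load), incidence fit (or forward selection),
    age-standardisation with deprivation gaps, AAD derivation, mortality
    fit with AAD, and delay-impact tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config_hash": _config_hash(config),
                      "stages": {}, "files": [], "complete": False}

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def _emit(name: str, frame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest["files"].append(str(path))

    try:
        # ------------------------------------------------------------ data
        stage = "data"
        if config.scenario is not None:
            log.info("stage %s: simulating synthetic scenario", stage)
            delay = make_delay_scenario(
                config.scenario, config.gamma_true,
                np.asarray(config.gamma_region, dtype=float)
                if config.gamma_region is not None else None,
            )
            incidence, mortality = delay.incidence, delay.mortality
            scheme = config.scenario.scheme
            write_count_table(incidence, out / "incidence.csv")
            write_count_table(mortality, out / "mortality.csv")
            truth = {
                "beta_true": delay.incidence_truth.beta_true.tolist(),
                "columns": delay.incidence_truth.design.columns,
                "sigma2_true": delay.incidence_truth.sigma2_true,
                "gamma_true": delay.gamma_true,
                "gamma_region": delay.gamma_region.tolist(),
                "aad_scale_years": delay.aad_scale,
                "seed": config.scenario.seed,
            }
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
            manifest["files"] += [str(out / "incidence.csv"), str(out / "mortality.csv"),
                                  str(out / "truth.json")]
        else:
            log.info("stage %s: loading %s", stage, config.incidence_path)
            scheme = AgeBandScheme.from_labels(list(config.age_bands))
            incidence = read_count_table(config.incidence_path, scheme)
            mortality = (read_count_table(config.mortality_path, scheme)
                         if config.mortality_path else None)
        manifest["stages"][stage] = "ok"

        # ------------------------------------------------- incidence model
        stage = "fit_incidence"
        if config.select_candidates:
            log.info("stage %s: forward selection over %d candidates",
                     stage, len(config.select_candidates))
            trace = forward_select(
                list(config.select_candidates), incidence,
                SelectionConfig(outcome="incidence", seed=config.seed))
            _emit("selection_trace.csv", trace.to_frame())
            inc_spec = trace.final_spec
        elif config.incidence_model is not None:
            inc_spec = config.incidence_model
        else:
            inc_spec = (config.scenario.model_spec("incidence")
                        if config.scenario is not None else None)
        if inc_spec is None:
            raise PipelineError("no incidence model specified")
        inc_design = encode_design(inc_spec, incidence)
        log.info("stage %s: MCMC on %d cells, p=%d", stage, len(incidence), inc_design.p)
        inc_fit = fit_mcmc(inc_design, incidence, config.mcmc, seed=config.seed)
        rates = inc_fit.fitted_rates()
        _emit("incidence_rates.csv", rates.summary())
        manifest["stages"][stage] = "ok"

        # --------------------------------------------- standardise + gaps
        stage = "standardise"
        std = StandardPopulation.esp2013(scheme)
        asr = age_standardise(rates, std)
        _emit("asr.csv", asr.summary())
        years = incidence.years
        t0, t1 = config.gap_years or (years[0], years[-1])
        gap_rows = []
        deciles = sorted(incidence.data["decile"].unique())
        if len(deciles) >= 2:
            for region in incidence.regions:
                for year in (t0, t1):
                    for gender in sorted(incidence.data["gender"].unique()):
                        ad = deprivation_gap_AD(asr, year, region, gender)
                        rd = relative_gap_RD(asr, year, region, gender)
                        gap_rows.append({"stat": "AD", "year": year, "region": region,
                                         "gender": gender, "mean": ad["mean"],
                                         "lo95": ad["lo95"], "hi95": ad["hi95"]})
                        gap_rows.append({"stat": "RD", "year": year, "region": region,
                                         "gender": gender, "mean": rd["mean"],
                                         "lo95": rd["lo95"], "hi95": rd["hi95"]})
                for d in deciles:
                    for gender in sorted(incidence.data["gender"].unique()):
                        ac = temporal_change_AC(asr, d, region, gender, t0=t0, t1=t1)
                        gap_rows.append({"stat": "AC", "decile": d, "region": region,
                                         "gender": gender, "mean": ac["mean"],
                                         "lo95": ac["lo95"], "hi95": ac["hi95"]})
            import pandas as pd

            _emit("gaps.csv", pd.DataFrame(gap_rows))
        manifest["stages"][stage] = "ok"

        # ------------------------------------------------------------- AAD
        stage = "aad"
        by_year = aad_by_year(rates, std, scheme)
        _emit("aad_by_year.csv", by_year.summary())
        weighted = aad_weighted(by_year, incidence)
        _emit("aad_weighted.csv", weighted.summary())
        manifest["stages"][stage] = "ok"

        # ------------------------------------------------- mortality + AAD
        if mortality is not None:
            stage = "fit_mortality"
            mort_spec = config.mortality_model
            if mort_spec is None and config.scenario is not None:
                base = config.scenario.model_spec("mortality")
                aad_terms = ("AAD",) if config.gamma_region is None else ("AAD", "AAD:region")
                mort_spec = ModelSpec(
                    outcome="mortality", main_terms=base.main_terms,
                    age_mode=base.age_mode, year_max_power=base.year_max_power,
                    interactions=base.interactions, aad_terms=aad_terms)
            if mort_spec is None:
                raise PipelineError("no mortality model specified")
            aad_vals = aad_covariate(mortality, weighted)
            mort_design = encode_design(mort_spec, mortality, aad=aad_vals)
            mort_fit = fit_mcmc(mort_design, mortality, config.mcmc, seed=config.seed + 1)
            manifest["stages"][stage] = "ok"

            stage = "impact"
            import pandas as pd

            s = mort_design.aad_params[1]
            regions = (mort_design.factor_levels.get("region", [None])
                       if "AAD:region" in mort_design.blocks else [None])
            rows = []
            for delta in config.delays:
                for region in regions:
                    imp = delay_impact(mort_fit, mort_design, s, delta, region=region)
                    rows.append(imp.summary())
            if config.latency:
                for region in regions:
                    imp = latency_scenario(
                        mort_fit, mort_design, s,
                        per_year_increase=float(config.latency["per_year_increase"]),
                        horizon=float(config.latency["horizon"]), region=region)
                    row = imp.summary()
                    row["scenario"] = "latency"
                    rows.append(row)
            _emit("delay_impacts.csv", pd.DataFrame(rows))
            if "AAD:region" in mort_design.blocks:
                _emit("region_contributions.csv",
                      region_contribution(mort_fit, mort_design))
            manifest["stages"][stage] = "ok"

        manifest["complete"] = True
        _write_manifest()
        manifest["files"].append(str(out / "manifest.json"))
        return manifest
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
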