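"""Average age-at-diagnosis, delay impacts and regional contributions."""

import numpy as np
import pandas as pd
import pytest

from cancerineq import (
    CountTable,
    ModelSpec,
    StandardPopulation,
    aad_by_year,
    aad_covariate,
    aad_weighted,
    delay_impact,
    encode_design,
    latency_scenario,
    region_contribution,
    standardise_aad,
)
from cancerineq.aad import AADTable
from cancerineq.age_bands import AgeBandScheme
from cancerineq.model import FittedRates, PosteriorDraws


def rates_frame(bands, deciles=(1,), years=(2001,), regions=("N",)):
    rows = [{"age_band": b, "year": y, "gender": "male", "decile": d, "region": r}
            for y in years for d in deciles for r in regions for b in bands]
    return pd.DataFrame(rows)


class TestAADByYear:
    def test_concentrated_rate_gives_midpoint(self):
        # all incidence in one band: AAD equals that band's midpoint
        scheme = AgeBandScheme.five_year(45, 80)
        std = StandardPopulation.esp2013(scheme)
        df = rates_frame(scheme.labels)
        theta = np.full((2, len(df)), 1e-12)
        j = list(scheme.labels).index("60-64")
        theta[:, j] = 1.0
        aad = aad_by_year(FittedRates(theta=theta, strata=df), std, scheme)
        assert np.allclose(aad.draws, 62.0, atol=1e-6)

    def test_uniform_rates_give_weighted_midpoint(self):
        scheme = AgeBandScheme.five_year(45, 80)
        std = StandardPopulation.esp2013(scheme)
        df = rates_frame(scheme.labels)
        theta = np.full((1, len(df)), 2e-4)
        aad = aad_by_year(FittedRates(theta=theta, strata=df), std, scheme)
        w = np.array([std.weight(b) for b in scheme.labels])
        mids = np.array([scheme.midpoint(b) for b in scheme.labels])
        assert aad.draws[0, 0] == pytest.approx((mids * w).sum() / w.sum())

    def test_rate_doubling_invariance(self):
        rng = np.random.default_rng(2)
        scheme = AgeBandScheme.five_year(45, 80)
        std = StandardPopulation.esp2013(scheme)
        df = rates_frame(scheme.labels)
        theta = rng.uniform(1e-5, 1e-3, size=(3, len(df)))
        a1 = aad_by_year(FittedRates(theta=theta, strata=df), std, scheme)
        a2 = aad_by_year(FittedRates(theta=2.0 * theta, strata=df), std, scheme)
        assert np.allclose(a1.draws, a2.draws)

    def test_bounded_by_midpoints(self):
        rng = np.random.default_rng(3)
        scheme = AgeBandScheme.five_year(45, 80)
        std = StandardPopulation.esp2013(scheme)
        df = rates_frame(scheme.labels, deciles=(1, 5), years=(2001, 2002))
        theta = rng.uniform(1e-5, 1e-3, size=(4, len(df)))
        aad = aad_by_year(FittedRates(theta=theta, strata=df), std, scheme)
        assert aad.draws.min() >= 47.0
        assert aad.draws.max() <= 90.0


class TestAADWeighted:
    def test_two_year_hand_example(self):
        # AADs 60 and 70 with populations 1000 and 3000 -> 67.5
        index = pd.DataFrame({"year": [2001, 2002], "decile": 1,
                              "gender": "male", "region": "N"})
        aad = AADTable(draws=np.array([[60.0, 70.0]]), index=index)
        pop = pd.DataFrame({"year": [2001, 2002], "decile": 1, "gender": "male",
                            "region": "N", "exposure": [1000.0, 3000.0]})
        out = aad_weighted(aad, pop)
        assert out.draws[0, 0] == pytest.approx(67.5)

    def test_over_deciles_collapses_index(self):
        index = pd.DataFrame({"year": 2001, "decile": [1, 2],
                              "gender": "male", "region": "N"})
        aad = AADTable(draws=np.array([[60.0, 64.0]]), index=index)
        pop = pd.DataFrame({"year": 2001, "decile": [1, 2], "gender": "male",
                            "region": "N", "exposure": [500.0, 1500.0]})
        out = aad_weighted(aad, pop, over_deciles=True)
        assert list(out.index.columns) == ["gender", "region"]
        assert out.draws[0, 0] == pytest.approx((60 * 500 + 64 * 1500) / 2000)

    def test_missing_exposure_rejected(self):
        index = pd.DataFrame({"year": [2001, 2002], "decile": 1,
                              "gender": "male", "region": "N"})
        aad = AADTable(draws=np.array([[60.0, 70.0]]), index=index)
        pop = pd.DataFrame({"year": [2001], "decile": 1, "gender": "male",
                            "region": "N", "exposure": [1000.0]})
        with pytest.raises(ValueError, match="missing exposures"):
            aad_weighted(aad, pop)


class TestStandardiseAAD:
    def test_two_point_example(self):
        z, mean, s = standardise_aad([58.0, 62.0])
        assert mean == 60.0
        assert s == 2.0
        assert list(z) == [-1.0, 1.0]

    def test_inverse_transform(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(55, 75, size=40)
        z, mean, s = standardise_aad(vals)
        assert np.allclose(z * s + mean, vals)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            standardise_aad([60.0, 60.0, 60.0])


def mortality_table(regions=("N", "S"), years=(2001, 2002)):
    scheme = AgeBandScheme.five_year(60, 70)
    rows = [{"age_band": b, "year": y, "gender": "male", "decile": d,
             "region": r, "count": 5, "exposure": 1000.0}
            for b in scheme.labels for y in years for d in (1, 2) for r in regions]
    return CountTable(pd.DataFrame(rows), scheme=scheme, regions=regions), scheme


def degenerate_fit(table, gamma, gamma_region=None, aad_seed=7):
    """Point-mass posterior with known AAD slope(s) on a mortality design."""
    terms = ("AAD", "AAD:region") if gamma_region is not None else ("AAD",)
    spec = ModelSpec(outcome="mortality", main_terms=("age", "region"),
                     aad_terms=terms)
    rng = np.random.default_rng(aad_seed)
    aad = rng.uniform(58, 72, size=len(table))
    design = encode_design(spec, table, aad=aad)
    beta = np.zeros(design.p)
    beta[design.term_slice("AAD").start] = gamma
    if gamma_region is not None:
        sl = design.term_slice("AAD:region")
        beta[sl] = gamma_region[:-1]
    draws = PosteriorDraws.degenerate(beta, 1e-6, design, n_draws=3)
    return draws, design


class TestDelayImpact:
    def test_verified_identity_six_month(self):
        # yearly mortality factor 1.2356 -> 6-month delay = sqrt - 1 = 11.16%
        table, _ = mortality_table()
        _, d0 = degenerate_fit(table, gamma=0.0)
        s = d0.aad_params[1]
        draws, design = degenerate_fit(table, gamma=s * np.log(1.2356))
        imp = delay_impact(draws, design, s=s, delta=0.5)
        assert imp.mean == pytest.approx(100.0 * (np.sqrt(1.2356) - 1.0), abs=1e-9)
        assert imp.mean == pytest.approx(11.16, abs=0.01)

    def test_verified_identity_three_month(self):
        table, _ = mortality_table()
        _, d0 = degenerate_fit(table, gamma=0.0)
        s = d0.aad_params[1]
        draws, design = degenerate_fit(table, gamma=s * np.log(1.2356))
        imp = delay_impact(draws, design, s=s, delta=0.25)
        assert imp.mean == pytest.approx(100.0 * (1.2356 ** 0.25 - 1.0), abs=1e-9)
        assert imp.mean == pytest.approx(5.43, abs=0.01)

    def test_verified_identity_weak_effect(self):
        table, _ = mortality_table()
        _, d0 = degenerate_fit(table, gamma=0.0)
        s = d0.aad_params[1]
        draws, design = degenerate_fit(table, gamma=s * np.log(1.0339))
        imp = delay_impact(draws, design, s=s, delta=0.5)
        assert imp.mean == pytest.approx(100.0 * (np.sqrt(1.0339) - 1.0), abs=1e-9)
        assert imp.mean == pytest.approx(1.68, abs=0.01)

    def test_zero_delay_or_zero_slope_gives_zero(self):
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.3)
        s = design.aad_params[1]
        assert delay_impact(draws, design, s, delta=0.0).mean == 0.0
        draws0, design0 = degenerate_fit(table, gamma=0.0)
        assert delay_impact(draws0, design0, s, delta=2.0).mean == 0.0

    def test_half_step_compounding_per_draw(self):
        # impact(delta) relates to impact(delta/2) by squaring the factor
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.2)
        s = design.aad_params[1]
        full = delay_impact(draws, design, s, delta=1.0).draws / 100.0 + 1.0
        half = delay_impact(draws, design, s, delta=0.5).draws / 100.0 + 1.0
        assert np.allclose(full, half ** 2, rtol=1e-12)

    def test_negative_delay_rejected(self):
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.2)
        with pytest.raises(ValueError, match="non-negative"):
            delay_impact(draws, design, design.aad_params[1], delta=-1.0)

    def test_region_interaction_requires_region(self):
        table, _ = mortality_table()
        gr = np.array([0.05, -0.05])
        draws, design = degenerate_fit(table, gamma=0.2, gamma_region=gr)
        s = design.aad_params[1]
        with pytest.raises(ValueError, match="region is required"):
            delay_impact(draws, design, s, delta=1.0)
        imp_n = delay_impact(draws, design, s, delta=1.0, region="N")
        imp_s = delay_impact(draws, design, s, delta=1.0, region="S")
        expected_n = 100.0 * np.expm1(0.25 / s)
        expected_s = 100.0 * np.expm1(0.15 / s)
        assert imp_n.mean == pytest.approx(expected_n, rel=1e-10)
        assert imp_s.mean == pytest.approx(expected_s, rel=1e-10)

    def test_region_ignored_with_warning_when_no_interaction(self):
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.2)
        with pytest.warns(UserWarning, match="region ignored"):
            delay_impact(draws, design, design.aad_params[1], delta=1.0, region="N")


class TestRegionContribution:
    def test_contribution_algebra(self):
        # slopes (0.12, 0.08) around gamma = 0.10 -> factors 1.2 and 0.8
        table, _ = mortality_table()
        gr = np.array([0.02, -0.02])
        draws, design = degenerate_fit(table, gamma=0.10, gamma_region=gr)
        out = region_contribution(draws, design)
        got = dict(zip(out["region"], out["factor_mean"]))
        assert got["N"] == pytest.approx(1.2, rel=1e-10)
        assert got["S"] == pytest.approx(0.8, rel=1e-10)
        assert not out["unstable"].any()

    def test_factors_average_to_one_per_draw(self):
        table, _ = mortality_table()
        gr = np.array([0.03, -0.03])
        draws, design = degenerate_fit(table, gamma=0.07, gamma_region=gr)
        out = region_contribution(draws, design)
        assert out["factor_mean"].mean() == pytest.approx(1.0, rel=1e-10)

    def test_requires_interaction(self):
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.1)
        with pytest.raises(ValueError, match="AAD:region"):
            region_contribution(draws, design)


class TestLatencyScenario:
    def test_four_year_compounding(self):
        # 7% per year of latency drift over 4 years: 1.07^4 - 1 = 31.08%
        table, _ = mortality_table()
        _, d0 = degenerate_fit(table, gamma=0.0)
        s = d0.aad_params[1]
        draws, design = degenerate_fit(table, gamma=s * np.log(1.07))
        imp = latency_scenario(draws, design, s, per_year_increase=1.0, horizon=4.0)
        assert imp.mean == pytest.approx(100.0 * (1.07 ** 4 - 1.0), abs=1e-9)
        assert imp.mean == pytest.approx(31.08, abs=0.01)

    def test_negative_horizon_rejected(self):
        table, _ = mortality_table()
        draws, design = degenerate_fit(table, gamma=0.1)
        with pytest.raises(ValueError):
            latency_scenario(draws, design, design.aad_params[1], 0.1, -1.0)


class TestAADCovariate:
    def test_join_on_posterior_means(self):
        table, _ = mortality_table(years=(2001, 2002))
        index = pd.DataFrame([
            {"year": y, "decile": d, "gender": "male", "region": r}
            for y in (2001, 2002) for d in (1, 2) for r in ("N", "S")])
        draws = np.arange(2 * len(index), dtype=float).reshape(2, -1)
        aad = AADTable(draws=draws, index=index)
        vals = aad_covariate(table, aad)
        merged = table.data.merge(index.assign(aad=aad.means),
                                  on=["year", "decile", "gender", "region"])
        assert np.allclose(vals, merged["aad"])

    def test_explicit_draw_values(self):
        table, _ = mortality_table(years=(2001,))
        index = pd.DataFrame([
            {"year": 2001, "decile": d, "gender": "male", "region": r}
            for d in (1, 2) for r in ("N", "S")])
        aad = AADTable(draws=np.zeros((1, 4)), index=index)
        vals = aad_covariate(table, aad, values=[61.0, 62.0, 63.0, 64.0])
        assert set(np.unique(vals)) == {61.0, 62.0, 63.0, 64.0}

    def test_missing_stratum_rejected(self):
        table, _ = mortality_table(years=(2001, 2002))
        index = pd.DataFrame([
            {"year": 2001, "decile": d, "gender": "male", "region": r}
            for d in (1, 2) for r in ("N", "S")])
        aad = AADTable(draws=np.zeros((1, 4)), index=index)
        with pytest.raises(ValueError, match="no AAD value"):
            aad_covariate(table, aad)
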