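"""Model specifications and their numeric design matrices.

The log-rate of each cell is a linear predictor ``x'beta`` built from the
main covariates age, year, gender, deprivation and region plus selected
two-way interactions and, for mortality models, the average
age-at-diagnosis (AAD) covariate. Categorical factors are encoded with
sum-to-zero contrasts (the omitted level's effect is minus the sum of the
others), year enters as a standardised polynomial, and AAD as a
standardised numerical covariate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import GENDERS, CountTable

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "standardise_year",
    "encode_design",
    "sum_to_zero_columns",
    "full_level_effects",
    "MAIN_TERMS",
]

MAIN_TERMS = ("age", "year", "gender", "deprivation", "region")
_FACTORS = ("age", "gender", "deprivation", "region")
_INTER_RE = re.compile(r"^(\w+):(\w+?)(?:\^(\d))?$")


def _parse_interaction(term: str) -> tuple[str, str, int]:
    """Parse 'age:year', 'year:region', 'age:year^2' -> (f1, f2, year_power).

    The year power applies when one side is 'year'; it is 0 for
    factor-by-factor interactions.
    """
    m = _INTER_RE.match(term)
    if not m:
        raise ValueError(f"unparseable interaction term {term!r}")
    f1, f2, pow_ = m.group(1), m.group(2), m.group(3)
    power = int(pow_) if pow_ else (1 if "year" in (f1, f2) else 0)
    if pow_ and "year" not in (f1, f2):
        raise ValueError(f"power given in non-year interaction {term!r}")
    for f in (f1, f2):
        if f not in MAIN_TERMS:
            raise ValueError(f"unknown covariate {f!r} in interaction {term!r}")
    if f1 == f2:
        raise ValueError(f"degenerate interaction {term!r}")
    return f1, f2, power


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one incidence or mortality model.

    Parameters
    ----------
    outcome
        "incidence" or "mortality"; AAD terms are only valid for mortality.
    main_terms
        Subset of {age, year, gender, deprivation, region}.
    age_mode
        "categorical" (sum-to-zero over band levels) or "numerical"
        (standardised band midpoint).
    year_max_power
        Highest power of standardised year entering as a main effect (1-3).
    interactions
        Two-way terms like "age:year", "gender:region", "age:year^2";
        both parents must be main terms. Year interactions default to
        power 1.
    aad_terms
        Subset of {"AAD", "AAD:region"}; mortality only.
    """

    outcome: str = "incidence"
    main_terms: tuple[str, ...] = ()
    age_mode: str = "categorical"
    year_max_power: int = 1
    interactions: tuple[str, ...] = ()
    aad_terms: tuple[str, ...] = ()
    cancer_type: str = "all"

    def __post_init__(self) -> None:
        if self.outcome not in ("incidence", "mortality"):
            raise ValueError(f"outcome must be incidence|mortality, got {self.outcome!r}")
        unknown = set(self.main_terms) - set(MAIN_TERMS)
        if unknown:
            raise ValueError(f"unknown main terms {sorted(unknown)}")
        if self.age_mode not in ("categorical", "numerical"):
            raise ValueError(f"age_mode must be categorical|numerical")
        if not 1 <= self.year_max_power <= 3:
            raise ValueError("year_max_power must be 1, 2 or 3")
        for term in self.interactions:
            f1, f2, power = _parse_interaction(term)
            for f in (f1, f2):
                if f not in self.main_terms:
                    raise ValueError(f"interaction {term!r} parent {f!r} not a main term")
            if power > self.year_max_power:
                raise ValueError(
                    f"interaction {term!r} uses year power {power} > year_max_power")
        bad = set(self.aad_terms) - {"AAD", "AAD:region"}
        if bad:
            raise ValueError(f"unknown AAD terms {sorted(bad)}")
        if self.aad_terms and self.outcome != "mortality":
            raise ValueError("AAD terms are only valid in mortality models")
        if "AAD:region" in self.aad_terms:
            if "AAD" not in self.aad_terms:
                raise ValueError("AAD:region requires the AAD main term")
            if "region" not in self.main_terms:
                raise ValueError("AAD:region requires region as a main term")

    def with_term(self, term: str) -> "ModelSpec":
        """Return a spec augmented by one candidate term.

        Accepts main terms, "year^k" (raises the year power), interactions,
        and AAD terms; adding an existing term is a no-op.
        """
        kw = dict(
            outcome=self.outcome, main_terms=self.main_terms, age_mode=self.age_mode,
            year_max_power=self.year_max_power, interactions=self.interactions,
            aad_terms=self.aad_terms, cancer_type=self.cancer_type,
        )
        m = re.match(r"^year\^(\d)$", term)
        if m:
            kw["year_max_power"] = max(self.year_max_power, int(m.group(1)))
            if "year" not in self.main_terms:
                kw["main_terms"] = self.main_terms + ("year",)
        elif term in MAIN_TERMS:
            if term not in self.main_terms:
                kw["main_terms"] = self.main_terms + (term,)
        elif term in ("AAD", "AAD:region"):
            if term not in self.aad_terms:
                need = ("AAD",) if term == "AAD:region" and "AAD" not in self.aad_terms else ()
                kw["aad_terms"] = self.aad_terms + need + (term,)
        elif ":" in term:
            if term not in self.interactions:
                _, _, power = _parse_interaction(term)
                kw["year_max_power"] = max(self.year_max_power, power) if power else self.year_max_power
                kw["interactions"] = self.interactions + (term,)
        else:
            raise ValueError(f"unknown candidate term {term!r}")
        return ModelSpec(**kw)


def standardise_year(years) -> tuple[np.ndarray, float, float]:
    """Affine-standardise calendar years to zero mean, unit variance.

    The mapping is computed over the *distinct* year values (population,
    divide-by-n variance) so it does not depend on how deeply the table is
    stratified. Returns (transformed distinct values, mean, sd).
    """
    distinct = np.unique(np.asarray(years, dtype=float))
    if distinct.size < 2:
        raise ValueError("need at least two distinct years to standardise")
    mean = distinct.mean()
    sd = distinct.std()  # population sd
    return (distinct - mean) / sd, float(mean), float(sd)


def sum_to_zero_columns(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Sum-to-zero contrast encoding: L levels -> L-1 columns.

    Column j is 1 for level j, -1 for the last level, 0 otherwise, so the
    implied effect of the last level is minus the sum of the estimated
    ones.
    """
    if n_levels < 2:
        raise ValueError("factor needs at least 2 levels")
    X = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def full_level_effects(contrast_coefs: np.ndarray) -> np.ndarray:
    """Back-transform L-1 sum-to-zero coefficients to all L level effects."""
    coefs = np.atleast_1d(np.asarray(contrast_coefs, dtype=float))
    return np.concatenate([coefs, [-coefs.sum()]])


def contrast_coefs_from_effects(effects: np.ndarray) -> np.ndarray:
    """Inverse of :func:`full_level_effects`; effects must sum to ~0."""
    effects = np.asarray(effects, dtype=float)
    if abs(effects.sum()) > 1e-8 * max(1.0, np.abs(effects).max()):
        raise ValueError("level effects must sum to zero")
    return effects[:-1].copy()


@dataclass
class DesignMatrix:
    """Numeric encoding of a :class:`ModelSpec` over a count table.

    Attributes
    ----------
    X
        (cells x p) design including the intercept column.
    columns
        Column labels, e.g. ``age[22]``, ``year^2``, ``region[London]:year``.
    blocks
        term -> (start, stop) column slice.
    factor_levels
        factor -> ordered level labels used for contrasts.
    year_params, age_params, aad_params
        (mean, sd) standardisation parameters where applicable.
    """

    X: np.ndarray
    columns: list[str]
    blocks: dict[str, tuple[int, int]]
    factor_levels: dict[str, list]
    spec: ModelSpec
    year_params: tuple[float, float] | None = None
    age_params: tuple[float, float] | None = None
    aad_params: tuple[float, float] | None = None
    strata: pd.DataFrame | None = None

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    def term_slice(self, term: str) -> slice:
        start, stop = self.blocks[term]
        return slice(start, stop)

    def term_coefs(self, beta: np.ndarray, term: str) -> np.ndarray:
        """Coefficients of *term*; beta may be a draws x p matrix."""
        beta = np.asarray(beta)
        return beta[..., self.term_slice(term)]

    def factor_effects(self, beta: np.ndarray, factor: str) -> np.ndarray:
        """Full-level effects of a sum-to-zero factor (..., L)."""
        coefs = self.term_coefs(beta, factor)
        last = -coefs.sum(axis=-1, keepdims=True)
        return np.concatenate([coefs, last], axis=-1)

    def aad_slopes(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """AAD slope draws (gamma) and per-region deviations (gamma_r).

        gamma_r is None when the model has no AAD:region interaction;
        otherwise it is (..., R) with rows summing to zero.
        """
        gamma = self.term_coefs(np.asarray(beta), "AAD")[..., 0]
        if "AAD:region" not in self.blocks:
            return gamma, None
        return gamma, self.factor_effects(beta, "AAD:region")


def _factor_codes(table: CountTable, factor: str) -> tuple[np.ndarray, list]:
    df = table.data
    if factor == "age":
        levels = [lb for lb in table.scheme.labels if lb in set(df["age_band"])]
        codes = df["age_band"].map({lb: i for i, lb in enumerate(levels)}).to_numpy()
    elif factor == "gender":
        levels = [g for g in GENDERS if g in set(df["gender"])]
        codes = df["gender"].map({g: i for i, g in enumerate(levels)}).to_numpy()
    elif factor == "deprivation":
        levels = sorted(df["decile"].unique())
        codes = df["decile"].map({d: i for i, d in enumerate(levels)}).to_numpy()
    elif factor == "region":
        levels = sorted(df["region"].unique())
        codes = df["region"].map({r: i for i, r in enumerate(levels)}).to_numpy()
    else:
        raise ValueError(f"not a factor: {factor!r}")
    return codes.astype(int), list(levels)


def encode_design(spec: ModelSpec, table: CountTable,
                  aad: pd.Series | np.ndarray | None = None) -> DesignMatrix:
    """Encode *spec* over *table* into a numeric design matrix.

    Column order is deterministic: intercept, age, year powers, gender,
    deprivation, region (those present), interactions in spec order, then
    AAD and AAD:region. Row order follows the table's canonical cell
    ordering, so the encoding is invariant to the input row order.

    Parameters
    ----------
    aad
        Per-cell average age-at-diagnosis values (years), required when the
        spec has AAD terms; standardised internally, with the (mean, scale)
        recorded in ``aad_params``.
    """
    df = table.data
    n = len(df)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    labels: list[str] = ["intercept"]
    blocks: dict[str, tuple[int, int]] = {"intercept": (0, 1)}
    factor_levels: dict[str, list] = {}
    year_params = age_params = aad_params = None

    # main-effect encodings, kept for reuse by interactions
    main_enc: dict[str, np.ndarray] = {}
    main_labels: dict[str, list[str]] = {}

    def _add(term: str, mat: np.ndarray, lab: list[str]) -> None:
        blocks[term] = (sum(c.shape[1] for c in cols), 0)
        cols.append(mat)
        labels.extend(lab)
        start = blocks[term][0]
        blocks[term] = (start, start + mat.shape[1])

    # -- age
    if "age" in spec.main_terms:
        if spec.age_mode == "categorical":
            codes, levels = _factor_codes(table, "age")
            if len(levels) < 2:
                raise ValueError("age factor needs >= 2 band levels in the data")
            mat = sum_to_zero_columns(codes, len(levels))
            lab = [f"age[{table.scheme.midpoint(lb):g}]" for lb in levels[:-1]]
            factor_levels["age"] = levels
        else:
            mids = table.midpoints
            distinct = np.unique(mids)
            if distinct.size < 2:
                raise ValueError("numerical age needs >= 2 distinct midpoints")
            a_mean, a_sd = float(distinct.mean()), float(distinct.std())
            age_params = (a_mean, a_sd)
            mat = ((mids - a_mean) / a_sd)[:, None]
            lab = ["age"]
        _add("age", mat, lab)
        main_enc["age"], main_labels["age"] = mat, lab

    # -- year polynomial
    if "year" in spec.main_terms:
        _, y_mean, y_sd = standardise_year(df["year"].to_numpy())
        year_params = (y_mean, y_sd)
        z = ((df["year"].to_numpy(float)) - y_mean) / y_sd
        mats, labs = [], []
        for k in range(1, spec.year_max_power + 1):
            mats.append((z ** k)[:, None])
            labs.append("year" if k == 1 else f"year^{k}")
        mat = np.hstack(mats)
        _add("year", mat, labs)
        for k, m_, l_ in zip(range(1, spec.year_max_power + 1), mats, labs):
            main_enc[f"year^{k}"] = m_
            main_labels[f"year^{k}"] = [l_]

    # -- remaining factors
    for factor in ("gender", "deprivation", "region"):
        if factor not in spec.main_terms:
            continue
        codes, levels = _factor_codes(table, factor)
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels in the data")
        mat = sum_to_zero_columns(codes, len(levels))
        lab = [f"{factor}[{lv}]" for lv in levels[:-1]]
        factor_levels[factor] = levels
        _add(factor, mat, lab)
        main_enc[factor], main_labels[factor] = mat, lab

    # -- interactions: elementwise products of parent encodings
    for term in spec.interactions:
        f1, f2, power = _parse_interaction(term)

        def _enc(f: str) -> tuple[np.ndarray, list[str]]:
            if f == "year":
                key = f"year^{power}"
                if key not in main_enc:
                    raise ValueError(f"{term!r}: year power {power} not in design")
                return main_enc[key], main_labels[key]
            if f not in main_enc:
                raise ValueError(f"{term!r}: parent {f!r} not encoded")
            return main_enc[f], main_labels[f]

        m1, l1 = _enc(f1)
        m2, l2 = _enc(f2)
        prod = (m1[:, :, None] * m2[:, None, :]).reshape(n, -1)
        lab = [f"{a}:{b}" for a in l1 for b in l2]
        _add(term, prod, lab)

    # -- AAD covariate
    if spec.aad_terms:
        if aad is None:
            raise ValueError("spec has AAD terms but no aad values supplied")
        vals = np.asarray(aad, dtype=float)
        if vals.shape != (n,):
            raise ValueError(f"aad must have one value per cell ({n}), got {vals.shape}")
        distinct = np.unique(vals)
        if distinct.size < 2:
            raise ValueError("AAD covariate is constant over cells (uninformative)")
        mu, s = float(vals.mean()), float(vals.std())
        aad_params = (mu, s)
        z = (vals - mu) / s
        _add("AAD", z[:, None], ["aad"])
        if "AAD:region" in spec.aad_terms:
            mat_r, lab_r = main_enc["region"], main_labels["region"]
            prod = z[:, None] * mat_r
            _add("AAD:region", prod, [f"aad:{b}" for b in lab_r])

    X = np.hstack(cols)
    return DesignMatrix(
        X=X, columns=labels, blocks=blocks, factor_levels=factor_levels, spec=spec,
        year_params=year_params, age_params=age_params, aad_params=aad_params,
        strata=table.strata(),
    )
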