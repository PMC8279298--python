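"""Reading, validating and writing stratified count tables.

A count table has one record per (age_band, year, gender, decile, region)
cell holding the observed count ``C`` (registrations or deaths) and the
population exposure ``E``. Deprivation deciles run 1 (most deprived) to 10
(least deprived); regions are free labels declared up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_bands import AgeBandScheme, parse_band_label

__all__ = [
    "CountTable",
    "ValidationError",
    "read_count_table",
    "write_count_table",
    "aggregate_terminal_bands",
    "GENDERS",
    "KEY_COLUMNS",
    "REQUIRED_COLUMNS",
]

GENDERS = ("male", "female")
KEY_COLUMNS = ["age_band", "year", "gender", "decile", "region"]
REQUIRED_COLUMNS = KEY_COLUMNS + ["count", "exposure"]


class ValidationError(ValueError):
    """A count table violated a structural invariant."""


@dataclass
class CountTable:
    """Validated stratified counts with exposures.

    The backing frame always has columns
    ``age_band, year, gender, decile, region, count, exposure`` and a
    default RangeIndex; rows are sorted by the stratum key so that two
    tables with the same cells compare equal regardless of input order.
    """

    data: pd.DataFrame
    scheme: AgeBandScheme
    regions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = df[REQUIRED_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["decile"] = df["decile"].astype(int)
        df["count"] = df["count"].astype(np.int64)
        df["exposure"] = df["exposure"].astype(float)
        if not self.regions:
            self.regions = tuple(sorted(df["region"].unique()))
        _validate(df, self.scheme, self.regions)
        df = df.sort_values(KEY_COLUMNS, kind="mergesort").reset_index(drop=True)
        self.data = df

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def counts(self) -> np.ndarray:
        return self.data["count"].to_numpy()

    @property
    def exposures(self) -> np.ndarray:
        return self.data["exposure"].to_numpy()

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    @property
    def midpoints(self) -> np.ndarray:
        """Age midpoint per row."""
        return self.data["age_band"].map(self.scheme.midpoint).to_numpy(float)

    def strata(self) -> pd.DataFrame:
        """Key columns only (copy)."""
        return self.data[KEY_COLUMNS].copy()

    def equals(self, other: "CountTable") -> bool:
        return self.data.equals(other.data)


def _validate(df: pd.DataFrame, scheme: AgeBandScheme, regions: tuple[str, ...]) -> None:
    region_set = set(regions)
    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValidationError(f"negative count at row {bad[0]}: {df.loc[bad[0]].to_dict()}")
    bad = df.index[df["exposure"] <= 0]
    if len(bad):
        raise ValidationError(f"non-positive exposure at row {bad[0]}: {df.loc[bad[0]].to_dict()}")
    bad = df.index[~df["decile"].between(1, 10)]
    if len(bad):
        raise ValidationError(f"decile outside 1..10 at row {bad[0]}: {df.loc[bad[0]].to_dict()}")
    bad = df.index[~df["region"].isin(region_set)]
    if len(bad):
        raise ValidationError(f"unknown region at row {bad[0]}: {df.loc[bad[0]].to_dict()}")
    bad = df.index[~df["gender"].isin(GENDERS)]
    if len(bad):
        raise ValidationError(f"unknown gender at row {bad[0]}: {df.loc[bad[0]].to_dict()}")
    unknown = set(df["age_band"].unique()) - set(scheme.labels)
    if unknown:
        raise ValidationError(f"age bands not in scheme: {sorted(unknown)}")
    dup = df.duplicated(KEY_COLUMNS)
    if dup.any():
        row = df.index[dup][0]
        raise ValidationError(f"duplicate stratum key at row {row}: {df.loc[row, KEY_COLUMNS].to_dict()}")


def aggregate_terminal_bands(df: pd.DataFrame, cut: int = 85,
                             terminal_label: str = "85+") -> pd.DataFrame:
    """Merge all bands starting at or above *cut* into one open band.

    Registrations extend to "95+" while deaths and populations stop at
    "85+"; counts and exposures of the merged bands are summed.
    """
    df = df.copy()

    def _relabel(lb: str) -> str:
        return terminal_label if parse_band_label(lb).lower >= cut else lb

    df["age_band"] = df["age_band"].map(_relabel)
    grouped = (
        df.groupby(KEY_COLUMNS, as_index=False, sort=False)[["count", "exposure"]].sum()
    )
    return grouped


def read_count_table(path, scheme: AgeBandScheme, regions: tuple[str, ...] = (),
                     aggregate_from: int | None = 85) -> CountTable:
    """Read a CSV count table, merge terminal bands, and validate.

    Parameters
    ----------
    path
        CSV with header ``age_band,year,gender,decile,region,count,exposure``.
    scheme
        Age-band scheme the table must conform to *after* aggregation.
    regions
        Declared region labels; defaults to the labels present.
    aggregate_from
        Lower bound above which bands are merged into the scheme's terminal
        open band (None disables aggregation).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if aggregate_from is not None:
        terminal = scheme.bands[-1].label if scheme.bands[-1].is_open else "85+"
        df = aggregate_terminal_bands(df, cut=aggregate_from, terminal_label=terminal)
    return CountTable(df, scheme=scheme, regions=regions)


def write_count_table(table: CountTable, path) -> None:
    # %.17g guarantees exposures survive a write/read round trip bit-exactly
    table.data.to_csv(path, index=False, float_format="%.17g")
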