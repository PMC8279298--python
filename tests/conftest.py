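import numpy as np
import pandas as pd
import pytest

from cancerineq import CountTable
from cancerineq.age_bands import AgeBandScheme


@pytest.fixture(scope="session")
def scheme9() -> AgeBandScheme:
    """Nine five-year bands 45-49 ... 80-84, 85+."""
    return AgeBandScheme.five_year(45, 80)


@pytest.fixture()
def small_table(scheme9) -> CountTable:
    """A tiny deterministic count table: 2 bands x 2 years x 2 deciles."""
    rows = []
    rng = np.random.default_rng(42)
    for band in ("45-49", "85+"):
        for year in (2001, 2002):
            for decile in (1, 10):
                rows.append({
                    "age_band": band, "year": year, "gender": "female",
                    "decile": decile, "region": "North",
                    "count": int(rng.integers(0, 50)),
                    "exposure": float(rng.uniform(1e3, 1e4)),
                })
    return CountTable(pd.DataFrame(rows), scheme=scheme9, regions=("North",))
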