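"""Five-year age-band conventions used throughout the package.

Registration and death counts arrive in five-year bands ("20-24", "25-29",
...). For modelling, each closed band is represented by its integer midpoint
(e.g. "20-24" -> 22) and the open terminal band ("85+") by a conventional
age of 90, reflecting the concentration of the open-ended group just above
its lower bound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["AgeBand", "AgeBandScheme", "band_midpoint", "parse_band_label"]

TERMINAL_MIDPOINT = 90.0

_BAND_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")
_OPEN_RE = re.compile(r"^(\d+)\s*\+$")


@dataclass(frozen=True)
class AgeBand:
    """A single age band: closed ``lo-hi`` or open-ended ``lo+``."""

    label: str
    lower: int
    upper: int | None  # None for an open terminal band
    midpoint: float

    @property
    def is_open(self) -> bool:
        return self.upper is None


def parse_band_label(label: str, terminal_midpoint: float = TERMINAL_MIDPOINT) -> AgeBand:
    """Parse a band label like ``"20-24"``, ``"85+"`` or ``"0"``."""
    label = label.strip()
    m = _BAND_RE.match(label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if hi < lo:
            raise ValueError(f"invalid age band {label!r}: upper < lower")
        return AgeBand(label=label, lower=lo, upper=hi, midpoint=float((lo + hi) // 2))
    m = _OPEN_RE.match(label)
    if m:
        lo = int(m.group(1))
        return AgeBand(label=label, lower=lo, upper=None, midpoint=terminal_midpoint)
    if label.isdigit():
        a = int(label)
        return AgeBand(label=label, lower=a, upper=a, midpoint=float(a))
    raise ValueError(f"unrecognised age band label {label!r}")


@dataclass(frozen=True)
class AgeBandScheme:
    """An ordered, non-overlapping collection of age bands.

    Parameters
    ----------
    bands
        Bands in ascending age order. At most the last band may be open.
    """

    bands: tuple[AgeBand, ...]
    _index: dict[str, AgeBand] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("scheme needs at least one band")
        mids = [b.midpoint for b in self.bands]
        if any(b2 <= b1 for b1, b2 in zip(mids, mids[1:])):
            raise ValueError("band midpoints must be strictly increasing")
        for b in self.bands[:-1]:
            if b.is_open:
                raise ValueError("only the terminal band may be open-ended")
        lowers = [b.lower for b in self.bands]
        uppers = [b.upper for b in self.bands[:-1]]
        if any(u >= lo2 for u, lo2 in zip(uppers, lowers[1:])):
            raise ValueError("bands overlap")
        object.__setattr__(self, "_index", {b.label: b for b in self.bands})

    @classmethod
    def from_labels(cls, labels: list[str] | tuple[str, ...],
                    terminal_midpoint: float = TERMINAL_MIDPOINT) -> "AgeBandScheme":
        return cls(tuple(parse_band_label(lb, terminal_midpoint) for lb in labels))

    @classmethod
    def five_year(cls, start: int = 20, last_closed: int = 80,
                  terminal: str = "85+") -> "AgeBandScheme":
        """Standard scheme of closed five-year bands plus an open terminal band.

        ``five_year(20, 80)`` gives "20-24" ... "80-84", "85+" — the death /
        population layout; ``five_year(45, 80)`` starts at "45-49".
        """
        labels = [f"{lo}-{lo + 4}" for lo in range(start, last_closed + 1, 5)]
        labels.append(terminal)
        return cls.from_labels(labels)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def midpoints(self) -> list[float]:
        return [b.midpoint for b in self.bands]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self.bands)

    def band(self, label: str) -> AgeBand:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"age band {label!r} not in scheme {self.labels}") from None

    def midpoint(self, label: str) -> float:
        return self.band(label).midpoint


def band_midpoint(band: str, scheme: AgeBandScheme) -> float:
    """Midpoint age representing *band* under *scheme*.

    Closed five-year bands map to lower+2 ("20-24" -> 22, "45-49" -> 47);
    the open terminal band maps to 90.
    """
    return scheme.midpoint(band)
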