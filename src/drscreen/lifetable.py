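"""Age-banded all-cause mortality and its conversion to annual death probabilities.

A :class:`LifeTable` holds central mortality rates (deaths per person-year)
for contiguous, half-open age bands, WHO style. The model multiplies the
band rate by the diabetes-specific mortality relative risk and converts the
product to a 1-year death probability under a constant-hazard assumption,
``q = 1 - exp(-m * rr)``.

The packaged fixture (``data/malawi_synthetic_lifetable.csv``) is a
synthetic table: a Gompertz hazard tabulated in 5-year bands from age 25,
constructed so that general-population life expectancy is 25 years at age 50
and 38 years at age 30 — the remaining-lifetime figures the model horizons
are built on. It approximates the WHO Malawi life table of the study era but
is not that table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: ages are integrated up to this cap when computing life expectancy
_AGE_CAP = 110.0


@dataclass(frozen=True)
class LifeTable:
    """Ordered half-open age bands ``[age_low, age_high)`` with mortality rates.

    The final band may be open-ended (``age_high = inf``); lookups beyond the
    last closed band fall into it.
    """

    age_low: np.ndarray
    age_high: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "age_low", np.asarray(self.age_low, dtype=float))
        object.__setattr__(self, "age_high", np.asarray(self.age_high, dtype=float))
        object.__setattr__(self, "rate", np.asarray(self.rate, dtype=float))
        self._validate()

    def _validate(self) -> None:
        lo, hi, rate = self.age_low, self.age_high, self.rate
        if not (len(lo) == len(hi) == len(rate)) or len(lo) == 0:
            raise ValueError("life table: empty or ragged columns")
        if np.any(rate < 0):
            raise ValueError("life table: negative mortality rate")
        if np.any(hi[:-1] <= lo[:-1]) or (np.isfinite(hi[-1]) and hi[-1] <= lo[-1]):
            raise ValueError("life table: bands must satisfy age_low < age_high")
        if np.any(lo[1:] != hi[:-1]):
            raise ValueError("life table: bands must be contiguous and non-overlapping")
        if lo[0] > 25 or (np.isfinite(hi[-1]) and hi[-1] < 90):
            raise ValueError("life table: must cover at least ages 25-90")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        """Read ``age_low,age_high,mortality_rate`` (header required, UTF-8);
        a blank ``age_high`` in the last row marks the open-ended band."""
        df = pd.read_csv(path)
        required = ["age_low", "age_high", "mortality_rate"]
        if list(df.columns[:3]) != required:
            raise ValueError(f"life table CSV must have columns {required}, got {list(df.columns)}")
        hi = df["age_high"].to_numpy(dtype=float)
        hi = np.where(np.isnan(hi), np.inf, hi)
        return cls(df["age_low"].to_numpy(dtype=float), hi, df["mortality_rate"].to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_low": self.age_low, "age_high": self.age_high, "mortality_rate": self.rate}
        )

    def rate_at_age(self, age: float) -> float:
        """Mortality rate of the band containing ``age`` (half-open bands);
        ages beyond the last closed band use the final band's rate."""
        if age < self.age_low[0]:
            raise ValueError(
                f"age {age!r} is below the life table's first band (starts {self.age_low[0]!r})"
            )
        idx = int(np.searchsorted(self.age_low, age, side="right")) - 1
        idx = min(idx, len(self.rate) - 1)
        return float(self.rate[idx])

    def covers(self, age_from: float, age_to: float) -> bool:
        return age_from >= self.age_low[0]  # upper ages fall into the final band

    def life_expectancy(self, age: float) -> float:
        """Remaining life expectancy at ``age`` under piecewise-constant hazard."""
        edges = [age] + [float(a) for a in self.age_low if a > age] + [_AGE_CAP]
        edges = sorted(set(e for e in edges if e <= _AGE_CAP))
        e, survival = 0.0, 1.0
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = self.rate_at_age(lo)
            dt = hi - lo
            e += survival * ((1 - math.exp(-m * dt)) / m if m > 0 else dt)
            survival *= math.exp(-m * dt)
        return e


def annual_death_probability(rate: float, rr: float, method: str = "constant_hazard") -> float:
    """Convert a central mortality rate and relative risk to a 1-year death probability.

    ``constant_hazard`` (default) uses ``1 - exp(-rate * rr)``; ``product``
    uses ``min(rate * rr, 1)``. The relative risk multiplies the hazard, not
    the probability.
    """
    if rate < 0:
        raise ValueError(f"mortality rate must be >= 0, got {rate!r}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0, got {rr!r}")
    if method == "constant_hazard":
        return min(1.0 - math.exp(-rate * rr), math.nextafter(1.0, 0.0))
    if method == "product":
        return min(rate * rr, 1.0)
    raise ValueError(f"unknown conversion method {method!r}")


def bundled_life_table() -> LifeTable:
    """The packaged synthetic Malawi-style life table (see module docstring)."""
    with resources.as_file(
        resources.files("drscreen").joinpath("data/malawi_synthetic_lifetable.csv")
    ) as path:
        return LifeTable.from_csv(path)
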