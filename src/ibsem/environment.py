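"""Physical environment: river area and monthly water temperatures.

Two habitats are modelled — the natal river and the sea.  Each is described by
twelve monthly mean temperatures (°C) with optional Gaussian inter-annual
randomization.  The year is split into a warm growth season (March–October)
and a resting season (November–February); the seasonal calendar drives parr
growth and the seasonal mortality baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WARM_MONTHS = frozenset(range(3, 11))  # March .. October

# Default monthly climatologies: a small western-Norway river and Norwegian
# Sea surface temperatures.  Editable through the config file.
DEFAULT_RIVER_TEMP_MEAN = (3.0, 2.8, 3.9, 6.2, 9.4, 12.6, 15.0, 15.3, 12.6, 9.3, 6.1, 4.0)
DEFAULT_RIVER_TEMP_SD = (1.0,) * 12
DEFAULT_SEA_TEMP_MEAN = (6.2, 5.8, 5.7, 6.3, 7.8, 9.9, 11.9, 12.6, 11.6, 9.9, 8.4, 7.1)
DEFAULT_SEA_TEMP_SD = (0.6,) * 12


def season_of(month: int) -> str:
    """``"warm"`` for March–October, ``"resting"`` for November–February."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return "warm" if month in WARM_MONTHS else "resting"


@dataclass
class Environment:
    """River area plus monthly temperature climatology for river and sea."""

    river_area_m2: float = 250_000.0
    river_temp_mean: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_RIVER_TEMP_MEAN)
    )
    river_temp_sd: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_RIVER_TEMP_SD)
    )
    sea_temp_mean: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_SEA_TEMP_MEAN)
    )
    sea_temp_sd: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_SEA_TEMP_SD))
    randomize: bool = True

    def __post_init__(self) -> None:
        self.river_temp_mean = np.asarray(self.river_temp_mean, dtype=float)
        self.river_temp_sd = np.asarray(self.river_temp_sd, dtype=float)
        self.sea_temp_mean = np.asarray(self.sea_temp_mean, dtype=float)
        self.sea_temp_sd = np.asarray(self.sea_temp_sd, dtype=float)
        for name in ("river_temp_mean", "river_temp_sd", "sea_temp_mean", "sea_temp_sd"):
            arr = getattr(self, name)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly entries, got {arr.shape}")
        if self.river_area_m2 <= 0:
            raise ValueError("river_area_m2 must be positive")
        if (self.river_temp_sd < 0).any() or (self.sea_temp_sd < 0).any():
            raise ValueError("temperature SDs must be non-negative")

    def get_temperature(
        self, month: int, habitat: str, rng: np.random.Generator | None = None
    ) -> float:
        """Water temperature (°C) for one month and habitat.

        Returns the configured monthly mean, or a Gaussian draw around it when
        ``randomize`` is on (independent across months and years).
        """
        if not 1 <= int(month) <= 12:
            raise ValueError(f"month must be in 1..12, got {month}")
        if habitat == "river":
            mean, sd = self.river_temp_mean[month - 1], self.river_temp_sd[month - 1]
        elif habitat == "sea":
            mean, sd = self.sea_temp_mean[month - 1], self.sea_temp_sd[month - 1]
        else:
            raise ValueError(f"habitat must be 'river' or 'sea', got {habitat!r}")
        if not self.randomize or sd == 0:
            return float(mean)
        if rng is None:
            raise ValueError("rng required when randomize is on")
        return float(rng.normal(mean, sd))

    def scaled(self, scale: float) -> "Environment":
        """Copy with river area multiplied by ``scale`` (desk-scale runs)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return Environment(
            river_area_m2=self.river_area_m2 * scale,
            river_temp_mean=self.river_temp_mean.copy(),
            river_temp_sd=self.river_temp_sd.copy(),
            sea_temp_mean=self.sea_temp_mean.copy(),
            sea_temp_sd=self.sea_temp_sd.copy(),
            randomize=self.randomize,
        )
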