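"""Tidal immersion: empirical immersion fractions and the cubic height model.

A point at intertidal height h (m above LAT, the chart datum) is immersed
whenever the water height is at or above h.  The empirical immersion
percentage is the fraction of hourly tide-gauge records satisfying that, and
a cubic polynomial fitted to (height, immersion%) pairs over the mussel zone
turns the hourly series into a smooth immersion model evaluated at quadrat
heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TideSeries", "ImmersionModel", "empirical_immersion",
           "fit_immersion_polynomial", "assign_immersion",
           "read_tides", "DEFAULT_HEIGHT_GRID"]

# 0.1 m steps across the observed mussel zone (3.0-5.5 m above LAT)
DEFAULT_HEIGHT_GRID = np.round(np.arange(3.0, 5.5 + 1e-9, 0.1), 3)


@dataclass
class TideSeries:
    """Hourly water heights (m above LAT) at strictly increasing timestamps."""

    timestamps: pd.DatetimeIndex
    heights: np.ndarray

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.timestamps) != self.heights.size:
            raise ValueError("timestamps and heights must be parallel")
        if self.heights.size == 0:
            raise ValueError("empty tide series")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("tide heights must be finite")
        if self.heights.size >= 2:
            deltas = np.diff(self.timestamps.asi8)
            if np.any(deltas <= 0):
                raise ValueError("timestamps must be strictly increasing")
            med = np.median(deltas) / 3.6e12  # ns -> hours
            if not 0.99 <= med <= 1.01:
                raise ValueError(
                    f"median spacing {med:.3f} h is not hourly within 1%")

    def to_csv(self, path) -> None:
        pd.DataFrame({"timestamp": self.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                      "height_m_lat": self.heights}).to_csv(path, index=False)


def read_tides(path) -> TideSeries:
    """Read tides.csv (ISO timestamp, height_m_lat)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"timestamp", "height_m_lat"} <= set(df.columns):
        raise ValueError("tide table needs columns timestamp, height_m_lat")
    return TideSeries(pd.to_datetime(df["timestamp"]),
                      df["height_m_lat"].to_numpy(dtype=float))


def empirical_immersion(series: TideSeries, height: float) -> float:
    """Percentage of records with water height >= ``height`` (tie immersed).

    Computed as the grand fraction over all hourly records, which equals the
    mean of daily immersion percentages for complete days.
    """
    return 100.0 * float(np.mean(series.heights >= height))


@dataclass
class ImmersionModel:
    """Cubic polynomial immersion(h) fitted over ``fit_range`` heights."""

    coefficients: np.ndarray  # highest degree first, np.polyval convention
    fit_range: tuple[float, float]
    rmse: float

    def __call__(self, height) -> np.ndarray | float:
        h = np.asarray(height, dtype=float)
        val = np.clip(np.polyval(self.coefficients, h), 0.0, 100.0)
        return float(val) if np.isscalar(height) else val

    def in_range(self, height) -> np.ndarray | bool:
        h = np.asarray(height, dtype=float)
        ok = (h >= self.fit_range[0]) & (h <= self.fit_range[1])
        return bool(ok) if np.isscalar(height) else ok

    def to_dict(self) -> dict:
        return {"coefficients": [float(c) for c in self.coefficients],
                "fit_range": [float(self.fit_range[0]), float(self.fit_range[1])],
                "rmse": float(self.rmse)}


def fit_immersion_polynomial(series: TideSeries,
                             height_grid=None) -> ImmersionModel:
    """Least-squares cubic of empirical immersion % against height (m).

    The default grid steps 0.1 m across the 3.0-5.5 m mussel zone; any grid
    of at least 8 heights spanning the zone of interest works.
    """
    grid = np.asarray(DEFAULT_HEIGHT_GRID if height_grid is None else height_grid,
                      dtype=float)
    if np.unique(grid).size < 4:
        raise ValueError("need >= 4 distinct heights to fit a cubic")
    if grid.size < 8:
        raise ValueError("need a grid of >= 8 heights")
    pct = np.array([empirical_immersion(series, h) for h in grid])
    coeffs = np.polyfit(grid, pct, deg=3)
    rmse = float(np.sqrt(np.mean((np.polyval(coeffs, grid) - pct) ** 2)))
    return ImmersionModel(coefficients=coeffs,
                          fit_range=(float(grid.min()), float(grid.max())),
                          rmse=rmse)


def assign_immersion(model: ImmersionModel, quadrats: pd.DataFrame,
                     height_col: str = "height_lat_m") -> pd.DataFrame:
    """Annotate a quadrat table with ``immersion_pct`` (clamped to [0, 100])
    and ``immersion_out_of_range`` flags.  Row count and order preserved."""
    out = quadrats.copy()
    h = out[height_col].to_numpy(dtype=float)
    out["immersion_pct"] = model(h)
    out["immersion_out_of_range"] = ~model.in_range(h)
    return out
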