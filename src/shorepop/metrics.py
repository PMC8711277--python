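"""Standardized per-quadrat population parameters for mussel aggregations.

Density, biomass and recruit density are expressed per square meter of
mussel-covered area: raw quadrat quantities are divided by ``CC * QA`` where
``CC`` is the fraction of the quadrat covered by the patch and ``QA`` the
quadrat area (default 0.0625 m^2, a 25 x 25 cm frame).  The crowding index —
the ratio of the cumulative individual basal area, SL^2/4.32 per individual,
to the observed covered area — quantifies how much monolayer neighbours
overlap: 1 means the shells exactly tile the patch, above 1 they overlap.

Individual records travel as a pandas DataFrame with columns
``quadrat_id, sl_mm, tww_g, fww_g, fdw_g, sex, stage`` (mass/sex/stage may
be missing); quadrat metadata as a DataFrame with
``quadrat_id, shore, date, height_lat_m, covered_fraction, quadrat_area_m2``
plus optional ``eastness, northness``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "QuadratSample",
    "AllometryFit",
    "DEFAULT_QUADRAT_AREA",
    "DEFAULT_RECRUIT_THRESHOLD_MM",
    "fit_allometry",
    "predict_mass",
    "total_biomass",
    "density",
    "basal_area",
    "crowding_index",
    "classify_recruits",
    "recruit_density",
    "size_stats",
    "summarize_quadrats",
    "read_individuals",
    "read_quadrats",
]

DEFAULT_QUADRAT_AREA = 0.0625       # m^2 (25 x 25 cm quadrat)
DEFAULT_RECRUIT_THRESHOLD_MM = 1.07  # length at one month under the site curve

INDIVIDUAL_COLUMNS = ["quadrat_id", "sl_mm", "tww_g", "fww_g", "fdw_g",
                      "sex", "stage"]
QUADRAT_COLUMNS = ["quadrat_id", "shore", "date", "height_lat_m",
                   "covered_fraction", "quadrat_area_m2", "eastness",
                   "northness"]


@dataclass(frozen=True)
class QuadratSample:
    """Metadata of one sampled quadrat."""

    quadrat_id: str
    shore: str
    date: str
    height_lat: float
    covered_fraction: float
    quadrat_area: float = DEFAULT_QUADRAT_AREA
    eastness: float | None = None
    northness: float | None = None

    def __post_init__(self):
        if not 0.0 < self.covered_fraction <= 1.0:
            raise ValueError(
                f"covered_fraction must be in (0, 1], got {self.covered_fraction}")
        if not self.quadrat_area > 0:
            raise ValueError("quadrat_area must be > 0")
        if not 0.0 <= self.height_lat <= 8.0:
            raise ValueError(
                f"height_lat {self.height_lat} outside the site range 0-8 m")

    @property
    def covered_area_m2(self) -> float:
        return self.covered_fraction * self.quadrat_area

    @property
    def covered_area_mm2(self) -> float:
        return self.covered_area_m2 * 1e6


@dataclass(frozen=True)
class AllometryFit:
    """Power-law length–mass fit, mass = a * SL^b (mass g, SL mm)."""

    a: float
    b: float
    n: int
    rmse: float

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("a must be > 0")
        if not 2.0 <= self.b <= 4.0:
            warnings.warn(
                f"allometric exponent b={self.b:.3f} outside the usual 2-4 "
                "range for bivalves", stacklevel=2)


def fit_allometry(sl_mm, mass_g, *, min_n: int = 10) -> AllometryFit:
    """Nonlinear least squares for mass = a * SL^b in natural space.

    Initialised from the log–log OLS slope/intercept; residuals are
    minimised on the untransformed masses, so large individuals carry the
    weight they do in biomass.
    """
    sl = np.asarray(sl_mm, dtype=float)
    mass = np.asarray(mass_g, dtype=float)
    ok = np.isfinite(sl) & np.isfinite(mass) & (sl > 0) & (mass > 0)
    sl, mass = sl[ok], mass[ok]
    if sl.size < min_n:
        raise ValueError(f"need >= {min_n} records with length and mass, "
                         f"got {sl.size}")
    if np.ptp(sl) == 0:
        raise ValueError("all lengths identical: exponent b unidentifiable")
    slope, intercept = np.polyfit(np.log(sl), np.log(mass), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = curve_fit(lambda L, a, b: a * np.power(L, b), sl, mass,
                            p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"allometry fit did not converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((mass - a * sl ** b) ** 2)))
    return AllometryFit(a=a, b=b, n=int(sl.size), rmse=rmse)


def predict_mass(fit: AllometryFit, sl_mm):
    """Mass (g) predicted from shell length via the power law."""
    sl = np.asarray(sl_mm, dtype=float)
    out = fit.a * np.power(sl, fit.b)
    return float(out) if np.isscalar(sl_mm) else out


def _masses_with_fallback(individuals: pd.DataFrame,
                          fit: AllometryFit | None) -> tuple[np.ndarray, int]:
    """TWW per individual (g), predicting from SL where unmeasured."""
    sl = individuals["sl_mm"].to_numpy(dtype=float)
    if "tww_g" in individuals:
        tww = individuals["tww_g"].to_numpy(dtype=float)
    else:
        tww = np.full(sl.shape, np.nan)
    missing = ~np.isfinite(tww)
    n_imputed = int(missing.sum())
    if n_imputed:
        if fit is None:
            raise ValueError("individuals lack TWW and no allometry fit given")
        tww = tww.copy()
        tww[missing] = predict_mass(fit, sl[missing])
    return tww, n_imputed


def total_biomass(quadrat: QuadratSample, individuals: pd.DataFrame,
                  fit: AllometryFit | None = None) -> float:
    """Total biomass (kg per m^2 of covered area): sum TWW / (CC * QA)."""
    if len(individuals) == 0:
        return 0.0
    tww, _ = _masses_with_fallback(individuals, fit)
    return float(tww.sum() / 1000.0 / quadrat.covered_area_m2)


def classify_recruits(individuals: pd.DataFrame,
                      threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (recruits, adults): recruits are strictly below the
    threshold length (1.07 mm = length at one month in the source system)."""
    if not threshold_mm >= 0:
        raise ValueError("threshold must be >= 0")
    is_recruit = individuals["sl_mm"] < threshold_mm
    return individuals[is_recruit], individuals[~is_recruit]


def density(quadrat: QuadratSample, individuals: pd.DataFrame,
            include_recruits: bool = True,
            threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM) -> float:
    """Individuals per m^2 of covered area."""
    if include_recruits:
        n = len(individuals)
    else:
        _, adults = classify_recruits(individuals, threshold_mm)
        n = len(adults)
    return n / quadrat.covered_area_m2


def recruit_density(quadrat: QuadratSample, individuals: pd.DataFrame,
                    threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM) -> float:
    """Recruits per m^2 of covered area, attributed to the sampling month."""
    recruits, _ = classify_recruits(individuals, threshold_mm)
    return len(recruits) / quadrat.covered_area_m2


def basal_area(sl_mm):
    """Individual basal footprint (mm^2): (SL/1.8) * (SL/2.4) = SL^2 / 4.32.

    The denominators are the empirical shell length:width and length:depth
    aspect ratios of the mussels, so the product approximates the projected
    vertical shadow of one shell.
    """
    sl = np.asarray(sl_mm, dtype=float)
    if np.any(sl < 0):
        raise ValueError("shell length must be >= 0")
    out = (sl / 1.8) * (sl / 2.4)
    return float(out) if np.isscalar(sl_mm) else out


def crowding_index(individuals: pd.DataFrame, observed_covered_area_mm2: float,
                   threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM,
                   *, inverse: bool = False) -> float:
    """Crowding = sum of adult basal areas / observed covered area.

    Values above 1 mean overlapping, tightly packed shells; exactly 1 means
    the basal areas tile the patch.  Recruits are excluded — they contribute
    no measurable footprint.  ``inverse=True`` returns observed / sum(basal),
    the reciprocal reading.
    """
    if not observed_covered_area_mm2 > 0:
        raise ValueError("observed covered area must be > 0")
    _, adults = classify_recruits(individuals, threshold_mm)
    total = float(basal_area(adults["sl_mm"].to_numpy(dtype=float)).sum())
    if inverse:
        if total == 0:
            raise ValueError("no adults: inverse crowding undefined")
        return observed_covered_area_mm2 / total
    return total / observed_covered_area_mm2


def size_stats(individuals: pd.DataFrame,
               threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM,
               ) -> tuple[float, float]:
    """(median, max) adult shell length in mm; recruits excluded.

    Even-sized samples use the midpoint of the two central order statistics.
    """
    _, adults = classify_recruits(individuals, threshold_mm)
    if len(adults) == 0:
        raise ValueError("no adults: size statistics undefined")
    sl = adults["sl_mm"].to_numpy(dtype=float)
    return float(np.median(sl)), float(sl.max())


def summarize_quadrats(quadrats: pd.DataFrame, individuals: pd.DataFrame,
                       fit: AllometryFit | None = None,
                       threshold_mm: float = DEFAULT_RECRUIT_THRESHOLD_MM,
                       ) -> pd.DataFrame:
    """One summary row per quadrat: density, biomass, crowding, sizes,
    recruit density and counts.

    Quadrats with no individuals get zero densities and NaN size statistics.
    ``density_ind_m2`` counts every individual; the recruit-free variant is
    reported alongside since the two readings differ only by recruit density.
    """
    rows = []
    grouped = dict(tuple(individuals.groupby("quadrat_id")))
    empty = individuals.iloc[0:0]
    for _, q in quadrats.iterrows():
        quad = QuadratSample(
            quadrat_id=str(q["quadrat_id"]), shore=str(q.get("shore", "")),
            date=str(q.get("date", "")),
            height_lat=float(q["height_lat_m"]),
            covered_fraction=float(q["covered_fraction"]),
            quadrat_area=float(q.get("quadrat_area_m2", DEFAULT_QUADRAT_AREA)),
        )
        ind = grouped.get(quad.quadrat_id, empty)
        recruits, adults = classify_recruits(ind, threshold_mm)
        n_imputed = 0
        if len(ind):
            tww, n_imputed = _masses_with_fallback(ind, fit)
            biomass = float(tww.sum() / 1000.0 / quad.covered_area_m2)
        else:
            biomass = 0.0
        if len(adults):
            med, mx = size_stats(ind, threshold_mm)
            crowd = crowding_index(ind, quad.covered_area_mm2, threshold_mm)
        else:
            med = mx = crowd = float("nan")
        rows.append({
            "quadrat_id": quad.quadrat_id,
            "shore": quad.shore,
            "date": quad.date,
            "height_lat_m": quad.height_lat,
            "covered_fraction": quad.covered_fraction,
            "density_ind_m2": density(quad, ind, include_recruits=True,
                                      threshold_mm=threshold_mm),
            "adult_density_ind_m2": density(quad, ind, include_recruits=False,
                                            threshold_mm=threshold_mm),
            "biomass_kg_m2": biomass,
            "crowding": crowd,
            "median_length_mm": med,
            "max_length_mm": mx,
            "recruit_density_ind_m2_month": recruit_density(
                quad, ind, threshold_mm),
            "n_total": len(ind),
            "n_recruits": len(recruits),
            "n_mass_imputed": n_imputed,
        })
    return pd.DataFrame(rows)


def read_individuals(path) -> pd.DataFrame:
    """Read individuals.csv (quadrat_id, sl_mm, tww_g, fww_g, fdw_g, sex, stage)."""
    df = pd.read_csv(path, dtype={"quadrat_id": str},
                     float_precision="round_trip")
    missing = {"quadrat_id", "sl_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"individuals table lacks columns: {sorted(missing)}")
    for col in ("tww_g", "fww_g", "fdw_g"):
        if col not in df:
            df[col] = np.nan
    for col in ("sex", "stage"):
        if col not in df:
            df[col] = "unknown"
        df[col] = df[col].fillna("unknown")
    if (df["sl_mm"] <= 0).any():
        raise ValueError("shell lengths must be > 0")
    return df


def read_quadrats(path) -> pd.DataFrame:
    """Read quadrats.csv (quadrat metadata)."""
    df = pd.read_csv(path, dtype={"quadrat_id": str},
                     float_precision="round_trip")
    missing = {"quadrat_id", "height_lat_m", "covered_fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"quadrat table lacks columns: {sorted(missing)}")
    if "quadrat_area_m2" not in df:
        df["quadrat_area_m2"] = DEFAULT_QUADRAT_AREA
    return df
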