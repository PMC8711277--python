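"""Condition index, spawning-phenology tests and reproductive output.

The potential reproductive output per square meter of covered mussel bed is
built from the population size distribution under five assumptions: a 1:1
sex ratio (only females spawn eggs, so half the mature flesh counts), the
observed size distribution, reproductive maturity above 12 mm shell length,
a fecundity of 28% of flesh dry mass, and the egg mass equivalence
10^6 eggs = 52.5 mg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import AllometryFit, QuadratSample, predict_mass

__all__ = ["ReproConstants", "ReproductiveOutput", "condition_index",
           "g_test", "sex_ratio_test", "eggs_from_mass",
           "reproductive_output"]


@dataclass(frozen=True)
class ReproConstants:
    """Constants of the reproductive-output calculation.

    maturity_length: mm, maturity is strictly above this length.
    fecundity_fraction: fraction of flesh dry mass released as eggs.
    egg_mass_equiv_mg: mg of egg mass per 10^6 eggs.
    female_fraction: fraction of mature individuals that are female.
    """

    maturity_length: float = 12.0
    fecundity_fraction: float = 0.28
    egg_mass_equiv_mg: float = 52.5
    female_fraction: float = 0.5

    def __post_init__(self):
        if not (self.maturity_length > 0 and self.egg_mass_equiv_mg > 0):
            raise ValueError("lengths and mass equivalences must be > 0")
        if not 0 < self.fecundity_fraction <= 1:
            raise ValueError("fecundity_fraction must be in (0, 1]")
        if not 0 < self.female_fraction <= 1:
            raise ValueError("female_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ReproductiveOutput:
    """Per-area reproductive output of one quadrat or shore."""

    mass_output_g_m2: float
    egg_output_m2: float
    n_mature: int
    mature_density_ind_m2: float


def condition_index(fdw_g, sl):
    """Condition index CI = FDW / SL^3 (g per cubic length unit, SL in mm
    by default).  A mass-per-size proxy of physiological state."""
    fdw = np.asarray(fdw_g, dtype=float)
    s = np.asarray(sl, dtype=float)
    if np.any(s <= 0):
        raise ValueError("shell length must be > 0")
    if np.any(fdw < 0):
        raise ValueError("flesh dry weight must be >= 0")
    out = fdw / s ** 3
    return float(out) if np.isscalar(fdw_g) else out


def g_test(table) -> tuple[float, int, float]:
    """G-test of independence on a 2x2 count table.

    Returns (G, df, p) with G = 2 * sum O*ln(O/E); zero cells contribute 0.
    Raises on a zero marginal (expected counts undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("g_test expects a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero marginal")
    res = stats.chi2_contingency(obs, correction=False,
                                 lambda_="log-likelihood")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def sex_ratio_test(n_female: int, n_male: int) -> tuple[float, float]:
    """Chi-squared test of a 1:1 sex ratio.

    chi2 = (n_f - n_m)^2 / (n_f + n_m), df = 1.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be non-negative")
    total = n_female + n_male
    if total == 0:
        raise ValueError("no sexed individuals")
    chi2 = (n_female - n_male) ** 2 / total
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def eggs_from_mass(mass_output_g_m2: float,
                   egg_mass_equiv_mg: float = 52.5) -> float:
    """Convert an egg mass density (g m^-2) to eggs m^-2.

    10^6 eggs weigh ``egg_mass_equiv_mg`` milligrams (default 52.5), so
    eggs = mass_g * 1000 / equiv_mg * 10^6.
    """
    if mass_output_g_m2 < 0:
        raise ValueError("mass must be >= 0")
    return mass_output_g_m2 * 1000.0 / egg_mass_equiv_mg * 1e6


def reproductive_output(individuals: pd.DataFrame, quadrat: QuadratSample,
                        fdw_allometry: AllometryFit | None = None,
                        constants: ReproConstants = ReproConstants(),
                        ) -> ReproductiveOutput:
    """Potential reproductive output per m^2 of covered area.

    mass_output = female_fraction * fecundity_fraction
                  * sum of mature FDW (g) / (CC * QA);
    mature means shell length strictly above ``constants.maturity_length``.
    Individuals without a measured FDW are predicted from shell length via
    ``fdw_allometry`` (a power-law dry-mass fit).
    """
    sl = individuals["sl_mm"].to_numpy(dtype=float)
    mature = sl > constants.maturity_length
    n_mature = int(mature.sum())
    area = quadrat.covered_area_m2
    if n_mature == 0:
        return ReproductiveOutput(0.0, 0.0, 0, 0.0)
    if "fdw_g" in individuals:
        fdw = individuals["fdw_g"].to_numpy(dtype=float)
    else:
        fdw = np.full(sl.shape, np.nan)
    missing = mature & ~np.isfinite(fdw)
    if missing.any():
        if fdw_allometry is None:
            raise ValueError(
                "mature individuals lack FDW and no dry-mass allometry given")
        fdw = fdw.copy()
        fdw[missing] = predict_mass(fdw_allometry, sl[missing])
    mass = (constants.female_fraction * constants.fecundity_fraction
            * float(fdw[mature].sum()) / area)
    return ReproductiveOutput(
        mass_output_g_m2=mass,
        egg_output_m2=eggs_from_mass(mass, constants.egg_mass_equiv_mg),
        n_mature=n_mature,
        mature_density_ind_m2=n_mature / area,
    )
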