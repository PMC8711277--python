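"""Age structure from shell lengths and catch-curve mortality estimation.

Ages are obtained by inverting the fitted growth curve, binned into integer
age classes (class t covers ages in [t-1, t) years, so class 1 is the first
year of life), and the instantaneous mortality rate Z (1/yr) is the negative
slope of ln(N_t) on t under the negative exponential survivorship model
N_t = N_1 * exp(-Z * t).  Age class 1 is excluded by default: its abundance
reflects the vagaries of recent recruitment more than mortality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .growth import GrowthParams, age_from_length

__all__ = ["AgeStructure", "MortalityEstimate", "assign_age_classes",
           "fit_mortality"]

logger = logging.getLogger(__name__)


@dataclass
class AgeStructure:
    """Counts per integer age class (1, 2, ..., max); zero classes retained."""

    age_classes: np.ndarray
    counts: np.ndarray
    n_dropped: int = 0  # individuals with SL >= Linf, excluded before ageing

    def __post_init__(self):
        self.age_classes = np.asarray(self.age_classes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.age_classes.size != self.counts.size:
            raise ValueError("age_classes and counts must be parallel")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        expect = np.arange(1, self.age_classes.size + 1)
        if self.age_classes.size and not np.array_equal(self.age_classes, expect):
            raise ValueError("age classes must run contiguously from 1")


@dataclass
class MortalityEstimate:
    """Catch-curve fit: Z (1/yr), fitted N at class 1 and diagnostics."""

    Z: float
    N1_hat: float
    r_squared: float
    n_classes_used: int
    excluded_class_1: bool


def assign_age_classes(sl_mm, params: GrowthParams) -> AgeStructure:
    """Age individuals from length via the growth curve and bin into classes.

    Individuals at or above Linf cannot be aged; they are dropped and counted
    in ``n_dropped`` (with a logged warning).
    """
    sl = np.asarray(sl_mm, dtype=float)
    if sl.size == 0:
        raise ValueError("no individuals supplied")
    ageable = sl < params.Linf
    n_dropped = int((~ageable).sum())
    if n_dropped:
        logger.warning("%d individuals with SL >= Linf=%.2f dropped from ageing",
                       n_dropped, params.Linf)
    sl = sl[ageable]
    if sl.size == 0:
        raise ValueError("no individuals below Linf: cannot build age structure")
    ages = np.array([age_from_length(params, L) - params.t0 for L in sl])
    classes = np.floor(ages).astype(int) + 1
    max_class = int(classes.max())
    counts = np.bincount(classes, minlength=max_class + 1)[1:]
    return AgeStructure(np.arange(1, max_class + 1), counts, n_dropped)


def fit_mortality(structure: AgeStructure, exclude_class_1: bool = True,
                  *, nonlinear: bool = False) -> MortalityEstimate:
    """Estimate Z from the age distribution, N_t = N_1 * exp(-Z t).

    Default is the catch-curve regression: OLS of ln(N_t) on t over classes
    with positive counts (zero classes cannot enter the log and are skipped
    with a logged note).  ``nonlinear=True`` instead least-squares the counts
    directly — a sensitivity check, not the headline estimator.
    """
    t = structure.age_classes.astype(float)
    n = structure.counts.astype(float)
    if exclude_class_1:
        keep = t >= 2
        t, n = t[keep], n[keep]
    n_zero = int((n == 0).sum())
    if n_zero:
        logger.info("%d zero-count age classes omitted from the regression",
                    n_zero)
    pos = n > 0
    t, n = t[pos], n[pos]
    if t.size < 3:
        raise ValueError(
            f"need >= 3 positive age classes after exclusion, got {t.size}")
    if np.ptp(n) == 0:  # flat structure: slope 0, no explainable variance
        return MortalityEstimate(Z=0.0, N1_hat=float(n[0]), r_squared=0.0,
                                 n_classes_used=int(t.size),
                                 excluded_class_1=exclude_class_1)
    if nonlinear:
        popt, _ = curve_fit(lambda tt, n1, z: n1 * np.exp(-z * tt), t, n,
                            p0=(float(n.max()) * np.e, 0.5), maxfev=20000)
        n1_hat, z = float(popt[0] * np.exp(-popt[1])), float(popt[1])
        resid = n - popt[0] * np.exp(-popt[1] * t)
        ss_tot = float(np.sum((n - n.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        return MortalityEstimate(Z=z, N1_hat=n1_hat, r_squared=r2,
                                 n_classes_used=int(t.size),
                                 excluded_class_1=exclude_class_1)
    res = stats.linregress(t, np.log(n))
    z = -float(res.slope)
    n1_hat = float(np.exp(res.intercept + res.slope * 1.0))
    return MortalityEstimate(Z=z, N1_hat=n1_hat,
                             r_squared=float(res.rvalue ** 2),
                             n_classes_used=int(t.size),
                             excluded_class_1=exclude_class_1)
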