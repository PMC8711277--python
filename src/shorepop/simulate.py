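"""Individual-based generator of rocky-shore mussel datasets with known truth.

The generator emulates the sampling design of a one-year monthly survey of
two shores of contrasting orientation: per shore, three quadrats per month
along the intertidal height gradient.  Each quadrat holds an independent
cohort history: monthly recruitment pulses (a bimodal spring/autumn
schedule) over a burn-in of the maximum longevity, exponential survival to
the sampling date with a height-dependent mortality rate
Z = exp(intercept + slope * height), lengths from the seasonal von
Bertalanffy curve anchored at each individual's birth time with lognormal
between-individual variability in Linf, power-law length-mass allometry
with multiplicative noise, and a covered area set so the crowding index
equals a configured target exactly.

Every quadrat draws from its own random substream derived from
(seed, shore, date, quadrat), so adding a quadrat never perturbs the
draws of existing ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import GrowthParams, decimal_year
from .metrics import DEFAULT_QUADRAT_AREA, basal_area
from .tides import TideSeries

__all__ = ["ShoreConfig", "TideConfig", "SimulationConfig",
           "SimulatedDataset", "simulate_population", "simulate_tides",
           "simulate_lfq_lengths", "write_dataset", "read_dataset",
           "default_config"]


def _bimodal_schedule() -> list[float]:
    """Monthly recruitment intensities: pulses centred April and September,
    normalised to mean 1 (the spring/autumn spawning seasons)."""
    months = np.arange(1, 13, dtype=float)
    raw = (np.exp(-0.5 * ((months - 4.0) / 1.0) ** 2)
           + np.exp(-0.5 * ((months - 9.0) / 1.2) ** 2))
    return [float(v) for v in raw / raw.mean()]


@dataclass
class ShoreConfig:
    """Ground-truth parameters of one shore."""

    growth: GrowthParams
    growth_cv: float = 0.05            # lognormal CV of individual Linf
    mortality_intercept: float = -1.95  # ln Z at height 0 (m above LAT)
    mortality_height_slope: float = 0.35  # d ln Z / d height (1/m)
    recruits_per_month: float = 15.0   # mean monthly settlers per quadrat
    recruitment_schedule: list[float] = field(default_factory=_bimodal_schedule)
    allometry_a: float = 1.2e-4        # g mm^-b
    allometry_b: float = 2.95
    allometry_noise_cv: float = 0.05
    fww_fraction: float = 0.35         # FWW / TWW
    fdw_fraction: float = 0.10         # FDW / TWW
    crowding_target: float = 1.5
    quadrat_heights: list[float] = field(default_factory=lambda: [3.7, 4.3, 4.9])
    covered_fraction_fallback: float = 0.3  # used when a quadrat has no adults
    spawning_phase: float = 0.35       # fraction of year of peak spawning
    spawning_steepness: float = 3.0

    def __post_init__(self):
        if len(self.recruitment_schedule) != 12:
            raise ValueError("recruitment_schedule must have 12 monthly values")
        if any(v < 0 for v in self.recruitment_schedule):
            raise ValueError("recruitment intensities must be >= 0")
        if not self.crowding_target > 0:
            raise ValueError("crowding_target must be > 0")
        if not self.fdw_fraction <= self.fww_fraction <= 1.0:
            raise ValueError("need fdw_fraction <= fww_fraction <= 1")


@dataclass
class TideConfig:
    """Sum-of-sinusoids tide: mixed semidiurnal by default (M2 + S2)."""

    mean_level: float = 4.0
    amplitudes: list[float] = field(default_factory=lambda: [2.0, 0.6])
    periods_h: list[float] = field(default_factory=lambda: [12.4206, 12.0])
    phases: list[float] = field(default_factory=lambda: [0.0, 1.0])
    surge_sd: float = 0.0
    start: str = "2015-01-01"

    def __post_init__(self):
        if any(p <= 0 for p in self.periods_h):
            raise ValueError("tidal periods must be > 0")
        if len(self.amplitudes) != len(self.periods_h):
            raise ValueError("amplitudes and periods must be parallel")


def _default_dates() -> list[str]:
    return [f"2019-{m:02d}-15" for m in range(3, 13)] + \
           ["2020-01-15", "2020-02-15"]


@dataclass
class SimulationConfig:
    """Full study configuration: two shores, monthly sampling, tides."""

    seed: int = 0
    shores: dict = field(default_factory=dict)
    sample_dates: list[str] = field(default_factory=_default_dates)
    n_quadrats_per_date: int = 3
    max_age: float = 11.0              # observed longevity (years)
    quadrat_area_m2: float = DEFAULT_QUADRAT_AREA
    recruit_threshold_mm: float = 1.07
    tide: TideConfig = field(default_factory=TideConfig)
    tide_years: float = 5.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for name, shore in d["shores"].items():
            d["shores"][name]["growth"] = self.shores[name].growth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        shores = {}
        for name, sd in d.get("shores", {}).items():
            sd = dict(sd)
            sd["growth"] = GrowthParams(**sd["growth"])
            shores[name] = ShoreConfig(**sd)
        d["shores"] = shores
        if "tide" in d and not isinstance(d["tide"], TideConfig):
            d["tide"] = TideConfig(**d["tide"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def default_config(seed: int = 0) -> SimulationConfig:
    """Two shores with the contrasting growth/mortality regimes of the
    study system (slower growth and lower mortality on the West shore)."""
    west = ShoreConfig(
        growth=GrowthParams(Linf=65.25, K=0.12, t0=0.52, C=0.42, ts=0.56),
        mortality_intercept=math.log(0.642) - 0.35 * 4.3,
        quadrat_heights=[3.7, 4.3, 4.9],
        recruits_per_month=18.0,
        spawning_phase=0.32,
    )
    east = ShoreConfig(
        growth=GrowthParams(Linf=62.54, K=0.19, t0=0.67, C=0.51, ts=0.50),
        mortality_intercept=math.log(0.919) - 0.35 * 4.55,
        quadrat_heights=[4.1, 4.55, 5.0],
        recruits_per_month=12.0,
        spawning_phase=0.40,
    )
    return SimulationConfig(seed=seed, shores={"West": west, "East": east})


@dataclass
class SimulatedDataset:
    """Generator output in the field-data schema plus the hidden truth."""

    quadrats: pd.DataFrame
    individuals: pd.DataFrame
    tides: TideSeries
    truth: dict


# ---------------------------------------------------------------------------
# Core draws
# ---------------------------------------------------------------------------

def _quadrat_rng(seed: int, shore_idx: int, date_idx: int, quad_idx: int
                 ) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=[int(seed) & 0x7FFFFFFF,
                                         shore_idx, date_idx, quad_idx])
    return np.random.default_rng(ss)


def _draw_individuals(shore: ShoreConfig, sample_t: float, max_age: float,
                      rng: np.random.Generator) -> pd.DataFrame:
    """One quadrat's standing population at decimal-year time ``sample_t``."""
    months_back = int(math.ceil(max_age * 12.0))
    births, sizes = [], []
    for m in range(months_back):
        t_lo = sample_t - (m + 1) / 12.0
        month_of_year = int(math.floor(((t_lo % 1.0) * 12.0))) % 12
        lam = shore.recruits_per_month * shore.recruitment_schedule[month_of_year]
        n = rng.poisson(lam)
        if n:
            births.append(t_lo + rng.random(n) / 12.0)
            sizes.append(n)
    if not births:
        return pd.DataFrame(columns=["sl_mm", "tww_g", "fww_g", "fdw_g",
                                     "sex", "stage", "birth_t"])
    birth_t = np.concatenate(births)
    age = sample_t - birth_t
    # height-dependent mortality applied by the caller via thinning prob
    return pd.DataFrame({"birth_t": birth_t, "age": age})


def _lengths_and_masses(shore: ShoreConfig, df: pd.DataFrame, sample_t: float,
                        rng: np.random.Generator) -> pd.DataFrame:
    g = shore.growth
    n = len(df)
    sigma = math.sqrt(math.log(1.0 + shore.growth_cv ** 2))
    linf_i = g.Linf * rng.lognormal(-0.5 * sigma ** 2, sigma, n)
    tb = df["birth_t"].to_numpy()
    s = g.C * g.K / (2.0 * math.pi)
    expo = (-(g.K * (sample_t - tb))
            + s * np.sin(2.0 * np.pi * (sample_t - g.ts))
            - s * np.sin(2.0 * np.pi * (tb - g.ts)))
    sl = np.maximum(linf_i * (1.0 - np.exp(expo)), 1e-3)
    msig = math.sqrt(math.log(1.0 + shore.allometry_noise_cv ** 2))
    tww = (shore.allometry_a * sl ** shore.allometry_b
           * rng.lognormal(-0.5 * msig ** 2, msig, n))
    fww = shore.fww_fraction * tww
    fdw = shore.fdw_fraction * tww
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    season = math.cos(2.0 * math.pi * ((sample_t % 1.0) - shore.spawning_phase))
    p_spawn = 1.0 / (1.0 + math.exp(-shore.spawning_steepness * season))
    stage = np.where(rng.random(n) < p_spawn, "spawning", "non-spawning")
    out = df.copy()
    out["sl_mm"] = sl
    out["tww_g"] = tww
    out["fww_g"] = fww
    out["fdw_g"] = fdw
    out["sex"] = sex
    out["stage"] = stage
    return out


def simulate_population(config: SimulationConfig,
                        seed: int | None = None) -> SimulatedDataset:
    """Generate the full two-shore dataset; deterministic given the seed."""
    if not config.shores:
        raise ValueError("config defines no shores")
    root_seed = config.seed if seed is None else seed
    quad_rows, ind_frames = [], []
    truth_quadrats = {}
    for s_idx, (shore_name, shore) in enumerate(sorted(config.shores.items())):
        for d_idx, date_str in enumerate(config.sample_dates):
            sample_t = decimal_year(date_str)
            for q_idx in range(config.n_quadrats_per_date):
                rng = _quadrat_rng(root_seed, s_idx, d_idx, q_idx)
                height = shore.quadrat_heights[q_idx % len(shore.quadrat_heights)]
                z = math.exp(shore.mortality_intercept
                             + shore.mortality_height_slope * height)
                pop = _draw_individuals(shore, sample_t, config.max_age, rng)
                if len(pop):
                    surv = rng.random(len(pop)) < np.exp(-z * pop["age"].to_numpy())
                    pop = pop[surv].reset_index(drop=True)
                qid = f"{shore_name}-{date_str}-q{q_idx + 1}"
                if len(pop):
                    pop = _lengths_and_masses(shore, pop, sample_t, rng)
                    adults = pop["sl_mm"] >= config.recruit_threshold_mm
                    sum_basal = float(basal_area(
                        pop.loc[adults, "sl_mm"].to_numpy()).sum())
                else:
                    sum_basal = 0.0
                qa_mm2 = config.quadrat_area_m2 * 1e6
                if sum_basal > 0:
                    cc = sum_basal / (shore.crowding_target * qa_mm2)
                    cc = min(max(cc, 1e-4), 1.0)
                else:
                    cc = shore.covered_fraction_fallback
                quad_rows.append({
                    "quadrat_id": qid, "shore": shore_name, "date": date_str,
                    "height_lat_m": height, "covered_fraction": cc,
                    "quadrat_area_m2": config.quadrat_area_m2,
                    "eastness": 0.0, "northness": 0.0,
                })
                n_recruits = int((pop["sl_mm"] < config.recruit_threshold_mm).sum()) \
                    if len(pop) else 0
                truth_quadrats[qid] = {"Z": z, "height_lat_m": height,
                                       "n_individuals": int(len(pop)),
                                       "n_recruits": n_recruits,
                                       "covered_fraction": cc}
                if len(pop):
                    ind = pop[["sl_mm", "tww_g", "fww_g", "fdw_g",
                               "sex", "stage"]].copy()
                    ind.insert(0, "quadrat_id", qid)
                    ind_frames.append(ind)
    quadrats = pd.DataFrame(quad_rows)
    if ind_frames:
        individuals = pd.concat(ind_frames, ignore_index=True)
    else:
        individuals = pd.DataFrame(columns=["quadrat_id", "sl_mm", "tww_g",
                                            "fww_g", "fdw_g", "sex", "stage"])
    if not len(individuals):
        import warnings
        warnings.warn("configuration produced an empty population")
    tides = simulate_tides(config.tide, config.tide_years, root_seed)
    truth = {"config": config.to_dict(), "seed": int(root_seed),
             "quadrats": truth_quadrats}
    return SimulatedDataset(quadrats=quadrats, individuals=individuals,
                            tides=tides, truth=truth)


def simulate_tides(tide: TideConfig, years: float = 5.0,
                   seed: int | None = None) -> TideSeries:
    """Hourly sum-of-sinusoids water heights, optional Gaussian surge."""
    n = int(round(years * 365.25 * 24))
    hours = np.arange(n, dtype=float)
    h = np.full(n, tide.mean_level)
    phases = tide.phases or [0.0] * len(tide.amplitudes)
    for amp, per, ph in zip(tide.amplitudes, tide.periods_h, phases):
        h += amp * np.sin(2.0 * np.pi * hours / per + ph)
    if tide.surge_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=[(seed or 0) & 0x7FFFFFFF, 999]))
        h += rng.normal(0.0, tide.surge_sd, n)
    ts = pd.date_range(tide.start, periods=n, freq="h")
    return TideSeries(timestamps=ts, heights=h)


def simulate_lfq_lengths(params: GrowthParams, sample_dates, n_per_date: int,
                         Z: float = 0.25, seed: int | None = None,
                         linf_cv: float = 0.02, birth_sd: float = 0.04,
                         max_age: float = 25.0):
    """Shell lengths with annual cohort structure, for growth-recovery tests.

    For each sampling date, individuals are assigned to annual cohorts with
    exponential(Z) age weights, birth phases ~ Normal(t0, birth_sd) within
    the cohort year, and lengths from the seasonal curve with lognormal
    individual Linf.  Returns parallel arrays (lengths_mm, dates_decimal).

    The default age structure is a long-lived, slowly dying stock
    (Z = 0.25/yr, longevity 25 yr): with K near 0.1/yr the observed lengths
    then span the full curve up to the asymptote, which is what makes Linf
    identifiable from length modes at all.
    """
    rng = np.random.default_rng(seed)
    dates = np.array([decimal_year(d) for d in np.asarray(sample_dates,
                                                          dtype=object)])
    all_len, all_date = [], []
    sigma = math.sqrt(math.log(1.0 + linf_cv ** 2))
    for t in dates:
        k_max = int(math.floor(max_age))
        ages_k = np.arange(k_max + 1)
        w = np.exp(-Z * ages_k)
        w /= w.sum()
        cohort = rng.choice(ages_k, size=n_per_date, p=w)
        birth_year = np.floor(t - params.t0) - cohort
        tb = birth_year + params.t0 + rng.normal(0.0, birth_sd, n_per_date)
        tb = np.minimum(tb, t)  # cohort 0 cannot be born after sampling
        linf_i = params.Linf * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                             n_per_date)
        s = params.C * params.K / (2.0 * math.pi)
        expo = (-(params.K * (t - tb))
                + s * np.sin(2.0 * np.pi * (t - params.ts))
                - s * np.sin(2.0 * np.pi * (tb - params.ts)))
        sl = np.maximum(linf_i * (1.0 - np.exp(expo)), 0.1)
        all_len.append(sl)
        all_date.append(np.full(n_per_date, t))
    return np.concatenate(all_len), np.concatenate(all_date)


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, directory) -> dict:
    """Write individuals.csv, quadrats.csv, tides.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": directory / "individuals.csv",
        "quadrats": directory / "quadrats.csv",
        "tides": directory / "tides.csv",
        "truth": directory / "truth.json",
    }
    # full float precision: the crowding round trip must survive the disk
    dataset.individuals.to_csv(paths["individuals"], index=False)
    dataset.quadrats.to_csv(paths["quadrats"], index=False)
    dataset.tides.to_csv(paths["tides"])
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_dataset(directory) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    from .metrics import read_individuals, read_quadrats
    from .tides import read_tides
    directory = Path(directory)
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return SimulatedDataset(
        quadrats=read_quadrats(directory / "quadrats.csv"),
        individuals=read_individuals(directory / "individuals.csv"),
        tides=read_tides(directory / "tides.csv"),
        truth=truth,
    )
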