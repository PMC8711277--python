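# Methods

This note documents the models implemented in `shorepop`, the defaults and
the numerical choices, in enough detail to reproduce every computation from
the source.

## Seasonal von Bertalanffy growth

Length at time *t* (decimal years):

    L(t) = L∞ (1 − exp(−K (t − t₀) + S(t) − S(t₀))),   S(t) = (CK/2π) sin(2π (t − tₛ)).

* `Linf` (mm) and `K` (yr⁻¹) are the usual von Bertalanffy parameters.
* `C ∈ [0, 1]` scales the seasonal modulation of the growth *rate*; C = 0.5
  means growth is 50% faster at the seasonal optimum. C ≤ 1 keeps L(t)
  monotone non-decreasing, which the length→age inversion requires; the
  constructor rejects C > 1.
* `ts ∈ [0, 1)` phases the oscillation; `t0 ∈ [0, 1)` anchors zero length
  and can be read as the within-year recruitment time.

The inverse (`age_from_length`) is a Brent root find on the monotone forward
model, bracketed analytically using the worst-case seasonal lag CK/π in the
exponent; round trips hold to below 10⁻⁶ mm.

`recruit_threshold(params, age=1/12)` returns the length at one month of
age. By default the seasonal term is dropped (plain VBGF): the seasonal
phase an individual settles in is not identifiable from a single pooled
threshold, so the default is the phase-free value, with `seasonal=True`
available. The conventional threshold in the study system is 1.07 mm; it is
a configurable constant throughout, not a derived quantity.

## Length-frequency restructuring (frozen algorithm)

ELEFAN's restructuring is not uniquely defined in the literature; the exact
variant used here is frozen as follows, per date column:

1. centred moving average (MA) over `ma` bins (default 9), truncated at the
   edges (shorter window, never zero-padded) — a flat column therefore maps
   to itself and scores zero everywhere;
2. raw score = count/MA − 1 where MA > 0, else 0 (bounded below by −1);
3. positive raw scores capped at 20;
4. isolated-peak de-emphasis: positive scores multiplied by (1 + n)/3 where
   n ∈ {0, 1, 2} is the number of immediate neighbours with non-zero counts;
5. negative scores rescaled so each column's negative mass equals its
   positive mass (peaks and troughs carry equal total weight);
6. the column divided by its maximum positive score (strongest peak = +1)
   and negatives floored at −1.

The hand-computed reference column (0, 0, 10, 0, 0) with ma = 3 yields
(0, −0.5, +1, −0.5, 0) and is asserted in the tests.

## Curve scoring (ESP/ASP)

Candidate curves are evaluated through annual cohort trajectories anchored
at t₀ + n for every integer n that lets a cohort appear within the sampling
window at an age inside the observed length span. ASP is the sum over dates
of all positive-run maxima. ESP credits each positive run at most once —
with the best bin score the curve actually crosses inside the run, so
threading a peak's crest earns its maximum while clipping a flank earns
less — and debits half the score of each distinct negative bin crossed.

The half-weight on troughs is a deliberate compromise, found during
estimator development on synthetic data: full-weight debits systematically
drag the fitted asymptote down into the terminal length mode (the
superposition of old cohorts, which always sits below L∞), while ignoring
troughs entirely lets fast-growing curves that sweep the whole histogram
collect every peak. The score is ≤ 1, reaches 1 only for a curve threading
every crest while avoiding every trough, and is ≤ 0 for a curve that misses
the observed range.

## Genetic-algorithm fitting

Five parameters (L∞, K, t₀, C, tₛ) are optimised inside a box search space
(defaults L∞ 40–140 mm, K 0.01–1 yr⁻¹, the rest [0, 1)). Hyperparameters:
population 50, 100 generations, tournament size 3, arithmetic crossover at
rate 0.8, per-gene Gaussian mutation (probability 0.25, sd 5% of the range),
elitism, early stop after 20 stagnant generations. Because the ESP/ASP
surface is rugged and piecewise constant, the fit runs four independent GA
restarts and keeps the best, each seeded partly from the top cells of a
coarse response-surface (RSA) pre-search over (L∞, K) with C = 0 — the
classical two-stage protocol — and the winner is polished by deterministic
coordinate descent with shrinking steps. Everything derives from one
`numpy.random.SeedSequence`, so fits are reproducible bit-for-bit given the
seed.

Bootstrap uncertainty: `n_boot` refits (default 100) on histograms
resampled multinomially *within* each sampling date, preserving the temporal
design; refits reuse the main fit's RSA candidates as initial material.
Percentiles (2.5/50/97.5) per parameter are reported.

## Mortality

Age classes are `class t = ages in [t−1, t)` so that class 1 is the first
year of life — the class excluded by default, because its abundance tracks
recruitment pulses rather than survival. Z is the negative OLS slope of
ln N_t on t over classes with positive counts (zero classes cannot enter the
log and are skipped with a log note); `nonlinear=True` offers a direct
exponential least-squares fit as a sensitivity check. A flat age structure
returns Z = 0 with r² = 0 rather than an error. Z is scale-invariant, so
counts and standardized densities give identical estimates.

## Population metrics

* Biomass: ΣTWW(kg)/(CC·QA); TWW missing → predicted from the site
  allometry TWW = a·SLᵇ (nonlinear least squares in natural mass space,
  initialised from the log–log OLS; exponents outside 2–4 warn).
  The number of imputed masses is reported per quadrat.
* Density: n/(CC·QA); computed both with and without recruits (whether
  totals should include recruits is ambiguous in field practice — both are
  one column apart in the summary).
* Crowding: Σ basal area / observed covered area with basal area
  SL²/4.32 mm² per individual and the observed area CC·QA expressed in mm².
  The orientation is chosen so overlap gives values above 1 (a patch whose
  cumulative footprint is 50% larger than its observed area has crowding
  1.5); the reciprocal is available behind `inverse=True`. Recruits are
  excluded.
* Recruits: strictly below the threshold (default 1.07 mm). Median lengths
  of even-sized samples use the midpoint convention.

## Tidal immersion

"Immersed" means water height ≥ sample height (ties immersed). The
empirical immersion percentage is the grand fraction over all hourly
records, which equals the mean of daily percentages for complete days. The
cubic model is least squares on (height, empirical %) pairs over a default
grid of 0.1 m steps across 3.0–5.5 m above LAT (the mussel zone);
evaluations are clamped to [0, 100] and out-of-range queries are flagged.

## Reproductive output

mass output (g m⁻² of covered area) = female_fraction × fecundity_fraction
× Σ FDW of mature individuals / (CC·QA), with maturity strictly above 12 mm,
fecundity 0.28 of flesh dry mass, and female_fraction 0.5 — the 1:1
sex-ratio assumption enters as the female share of the spawning biomass,
and is a config constant so the alternative reading (no halving) is one
change. Egg numbers use 10⁶ eggs = 52.5 mg exactly. Missing FDW is
predicted from a site FDW–length power law fitted with the same machinery
as the TWW allometry. The condition index is CI = FDW/SL³ with SL in mm
(g mm⁻³); only relative comparisons of CI are meaningful, so the unit
choice is a labelled convention.

Spawning phenology contrasts between shores use the G-test of independence
on 2×2 (spawning × shore) tables (G = 2ΣO ln(O/E), df 1, zero cells
contribute 0; degenerate marginals are rejected); the sex ratio uses the
χ² test of 1:1.

## Synthetic population generator

The generator emulates a one-year, two-shore monthly quadrat survey with
known ground truth:

* **Recruitment**: monthly Poisson pulses over a burn-in equal to the
  maximum age (default 11 yr, the observed longevity of the system);
  the default schedule is bimodal with Gaussian pulses centred April and
  September (the spring/autumn spawning seasons), normalised to mean 1,
  scaled by `recruits_per_month` (defaults 18 West, 12 East).
* **Mortality**: survival to the sampling date with probability e^(−Z·age),
  Z = exp(intercept + 0.35·height): mortality increases with intertidal
  height; intercepts are calibrated so mid-shore Z matches the observed
  shore means (0.642 West, 0.919 East).
* **Growth**: lengths from the soVBGF anchored at each individual's birth
  time, with lognormal individual variability acting on L∞ only (CV 5%),
  so the mean curve remains invertible for ageing. Default shore parameter
  sets are the published West/East fits.
* **Masses**: TWW = a·SLᵇ with multiplicative lognormal noise (CV 5%,
  a = 1.2×10⁻⁴ g mm⁻ᵇ, b = 2.95); FWW and FDW are fixed fractions of TWW
  (0.35 and 0.10), preserving FDW ≤ FWW ≤ TWW.
* **Aggregation**: the observed covered fraction is set to
  Σ basal / (crowding_target · QA), so the crowding index of every occupied
  quadrat equals the target (default 1.5) exactly — a closed-loop check of
  the crowding machinery.
* **Sex and spawning**: sex Bernoulli(½); spawning stage from a seasonal
  logistic with a shore-specific phase, so phenology contrasts with known
  truth are constructible.
* **Tides**: hourly sum of M2 (amplitude 2.0 m, period 12.4206 h) and S2
  (0.6 m, 12 h) constituents around a 4 m mean — a mixed semidiurnal regime —
  with optional Gaussian surge noise.

Each quadrat draws from a substream keyed by (seed, shore, date, quadrat),
so enlarging the design never perturbs existing quadrats. Datasets are
written as plain CSV plus a `truth.json` echoing the full configuration and
the realized per-quadrat rates; all recovery tests consume the written
files, not in-memory shortcuts.

**What the generator does not emulate**: spatially explicit settlement or
movement, wave dislodgement, multi-layer (3-D) aggregation, measurement
error in lengths, gear selectivity, and between-quadrat covariance of
recruitment. Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to every field artefact.

### The growth-recovery substrate

`simulate_lfq_lengths` is a separate, lighter substrate used for growth
parameter recovery: annual cohorts with exponential(Z) age weights, tight
within-year birth spread (sd 0.04 yr) and 2% individual L∞ variability.
Its default age structure is a long-lived, slowly dying stock (Z = 0.25 yr⁻¹,
longevity 25 yr): with K near 0.12 yr⁻¹ this makes K·age_max ≈ 3, so the
observed lengths span the curve up to the asymptote. This matters: under the
mussels' own demography (longevity ~11 yr) lengths stop near 73% of L∞ and
the asymptotic length is structurally unidentifiable from one year of
length modes — a known limitation of length-frequency methods for
slow-growing, short-lived stocks, which the validation design must avoid to
test the estimator rather than the data.

## Pipeline

`run_pipeline` stages: read/validate → immersion annotation → per-shore
ELEFAN fit (shores are fitted separately; their length distributions
differ) → recruit threshold (configured constant, or derived from a pooled
site fit when unset) → per-quadrat metrics → per-shore catch-curve →
per-shore reproductive output. Stage seeds are SHA-256 splits of the root
seed, every output embeds the config hash and seed, and re-running with the
same inputs produces byte-identical files.

## Problem sizes in tests

The suite validates recovery at deliberately moderate sizes chosen as
realistic study dimensions: growth recovery on 12 monthly samples × 500
individuals over 3 seeds; mortality on 200 replicates of 2000 ages at
Z ∈ {0.43, 0.9, 1.43}; allometry on 100 replicates of n = 720 with 5%
noise; immersion on a 5-year hourly tide. The full suite runs in about a
minute on a single core.
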