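# shorepop

Within-site analysis of intertidal rocky-shore mussel populations: a tested,
reusable pipeline that turns quadrat surveys of individual shell lengths and
masses, plus an hourly tide series, into the population parameters ecologists
compare along intertidal height gradients — individual growth, mortality,
density, biomass, crowding, recruitment, tidal immersion and potential
reproductive output. A seeded individual-based generator produces synthetic
datasets with known ground truth, so every estimator in the package is
validated by parameter recovery.

## Who it is for

Population ecologists working with length-structured samples of sessile
intertidal invertebrates (mussels in particular), and anyone who needs an
ELEFAN-style growth analysis, a catch-curve mortality estimate, or the
monolayer crowding index in Python.

## The models

**Growth.** Shell length at time *t* (decimal years) follows the seasonally
oscillating von Bertalanffy growth function (soVBGF)

    L(t) = L∞ · (1 − exp(−K·(t − t₀) + S(t) − S(t₀))),
    S(t) = (C·K / 2π) · sin(2π·(t − tₛ)),

with asymptotic length L∞ (mm), growth constant K (yr⁻¹), zero-length anchor
t₀ (interpretable as recruitment time within the year), seasonal amplitude
C ∈ [0, 1] and season phase tₛ. Parameters are estimated from binned
length-frequency data by ELEFAN: histograms are *restructured* against a
centred moving average (peaks score positive, troughs negative), candidate
curves are scored by the explained fraction of peak scores their cohort
trajectories traverse (ESP/ASP), and the score is maximised with a seeded
genetic algorithm preceded by a response-surface pre-search over (L∞, K).
Fits are compared across populations with the growth performance index
φ′ = log₁₀(K) + 2·log₁₀(L∞).

**Mortality.** Ages are obtained by inverting the growth curve and binned
into one-year classes; the instantaneous mortality rate Z (yr⁻¹) is the
catch-curve slope of ln(N_t) on t under N_t = N₁·e^(−Z·t), with age class 1
excluded (its abundance reflects recruitment pulses, not mortality).

**Standardized structure.** Density, biomass (ΣTWW / (CC·QA) with
TWW = a·SLᵇ fitted by nonlinear least squares), and recruit density
(SL < 1.07 mm, the length at one month) are expressed per m² of
mussel-covered area. The crowding index is Σ(SL²/4.32) — the cumulative
basal footprint — divided by the observed covered area: 1 means the shells
tile the patch, 1.5 means 50% overlap.

**Immersion and reproduction.** A cubic polynomial fitted to empirical
immersion fractions of an hourly tide series maps intertidal height (m above
LAT) to immersion time (%). Potential reproductive output per m² combines a
1:1 sex ratio, maturity above 12 mm, fecundity of 28% of flesh dry mass, and
the egg equivalence 10⁶ eggs = 52.5 mg.

## Worked example

Simulate a year of monthly length-frequency samples from a known seasonal
growth curve and recover its parameters:

```python
from shorepop import GrowthParams, build_lfq, elefan_ga
from shorepop.simulate import simulate_lfq_lengths

true = GrowthParams(Linf=65, K=0.12, t0=0.5, C=0.4, ts=0.5)
dates = [2019 + (m + 0.5) / 12 for m in range(12)]
lengths, ldates = simulate_lfq_lengths(true, dates, 500, seed=1)
fit = elefan_ga(build_lfq(lengths, ldates, bin_width=2.0),
                ma=9, n_boot=20, seed=1)
print(fit.params)
print(round(fit.score, 3), round(fit.phi_prime, 3))
print(fit.bootstrap_percentiles()["Linf"])
```

prints

```
GrowthParams(Linf=61.92155022765233, K=0.1299764331331461, t0=0.5414934849123907, C=0.39244394546346884, ts=0.5088509658152031)
0.902 2.698
{'p2.5': 59.430195700323075, 'p50': 63.459008460968796, 'p97.5': 72.81741680851724}
```

The fitted curve (L∞ ≈ 61.9 mm vs 65 true, K ≈ 0.130 vs 0.12) recovers the
truth within ~5–8%, the fit score 0.90 says the curve threads 90% of the
available peak weight, and the bootstrap interval for L∞ brackets the true
value. The same engine runs from the shell:

```bash
shorepop simulate --out data/ --seed 42        # synthetic two-shore survey
shorepop summarize --individuals data/individuals.csv --quadrats data/quadrats.csv
shorepop fit-growth --lfq lfq.csv --ma 9 --boot 100 --seed 42
shorepop reproduce-paper                        # desk-checkable published values
```

`shorepop reproduce-paper` prints

```
         check  computed  rounded  printed  pass
phi_prime_west  2.708342     2.71     2.71  True
phi_prime_east  2.871069     2.87     2.87  True
 eggs_west_1e9  2.150857     2.15     2.15  True
 eggs_east_1e9  2.028571     2.03     2.03  True
```

i.e. φ′ for the two shores' published growth parameters and the conversion
of the published seasonal reproductive-output masses (112.92 and
106.5 g m⁻²) into egg totals (2.15 × 10⁹ and 2.03 × 10⁹ eggs m⁻²).

## Layout

| module | contents |
| --- | --- |
| `shorepop.growth` | soVBGF forward/inverse model, LFQ restructuring, ESP/ASP scoring, RSA pre-search, GA fitting with bootstrap, φ′ |
| `shorepop.metrics` | allometry, density, biomass, basal area, crowding index, recruit classification, per-quadrat summaries |
| `shorepop.demography` | age-structure construction and catch-curve mortality |
| `shorepop.reproduction` | condition index, G-test, sex-ratio test, reproductive output |
| `shorepop.tides` | empirical immersion and the cubic immersion model |
| `shorepop.simulate` | individual-based population generator and tide synthesiser |
| `shorepop.pipeline` | end-to-end orchestration and the worked-example checks |
| `shorepop.cli` | `shorepop` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
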