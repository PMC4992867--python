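# Methods

## Signal model and correction

A well's raw optical density is modelled as
`od_raw(t) = OD(t) + blank + ε_od` and its raw fluorescence as
`fluor_raw(t) = g·F(t) + α·OD(t) + dark + ε_f`, where `OD` is biomass
absorbance, `F` the accumulated reporter amount, `g` the detector gain,
`α` autofluorescence per biomass and `dark` the instrument offset. Blank
(medium-only) wells estimate `blank`; wells of a non-fluorescent reference
strain grown in parallel estimate `α·OD + dark` at matched times.
Correction is therefore **time-matched** subtraction of the mean across
reference wells — the mean (not median) because plates carry few reference
wells. An OD-matched background correction would be preferable if the
reference grew very differently from the samples; with genotype-matched
references the time-matched form is standard and is what is implemented.

Expression is `F/OD` per time point. Division is masked where corrected OD
falls below `od_epsilon` (default **0.01 absorbance units**): below
detectable growth the ratio is dominated by noise amplification (at
OD = 0.01 an OD noise of 0.003 alone is a 30 % error). Negative corrected
fluorescence is clamped to 0 before division by default (negative
expression is physically meaningless); the raw signed values remain
available with `clamp_negative_f=False`.

## Promoter-activity estimators

**Discrete difference.** `d(F/OD)_n = (F/OD)_n − (F/OD)_{n-1}` on the
measurement grid. Raw signed values are always retained; the clipped
profile (negatives set to zero) exists for display, mirroring common
practice. Note the difference mixes synthesis and dilution:
`d(F/OD)/dt = q − μ·(F/OD)`, so for a constitutive promoter it is constant
only at constant biomass.

**Spline synthesis rate.** `q(t) = F′(t)/OD(t)` with both corrected
signals smoothed by least-squares cubic B-splines on a shared knot vector.
Interior knots are placed at data quantiles — implemented as midpoints
between the data points flanking each quantile cut, so every inter-knot
interval contains an observation by construction — and boundary knots are
clamped (repeated degree+1 times) at the data extremes. Admissibility is
verified against the **Schoenberg–Whitney conditions** (a strictly
increasing assignment of data points to B-spline basis supports, the rank
condition of the design matrix); inadmissible vectors are rejected rather
than repaired silently. This knot rule trades the smoothness of
cross-validated knot optimisation for speed and simplicity while still
suppressing plate-reader noise (the fit residual on noisy data matches the
injected noise sd within ±30 % in the tests).

Defaults: `n_interior = max(4, N/12)` for `N` fitted points — dense enough
to track growth-phase transitions on a 10-min grid without chasing noise;
evaluation excludes a **30-min margin** at both ends because cubic-spline
derivatives are boundary-dominated; the OD spline is floored at
`od_epsilon` before division. The reporter is treated as stable — no
maturation delay or degradation term — so `q` is the rate at which mature
fluorescence accumulates per biomass; a fast-maturing, stable fluorophore
makes this a good approximation, and the same assumption underlies the
F/OD read-out itself.

## Induction response and normalization

The response of a well to an H₂O₂ pulse is
`ΔF/OD = F/OD(t_treat + w) − F/OD(t_treat)` with window `w = 40 min`
(the pulse response is essentially complete after 40 min) and
`t_treat = 170 min` by default; the dose (50 µg/ml) is recorded as
metadata only. Endpoints are taken at the **nearest grid point** — the
10-min cadence makes 40 min exactly four steps — rather than interpolated.
Negative responses are floored at 0 (with a recorded flag) before
normalization so fractions lie in [0, 100]. Within each genetic
background, a position's fraction is `100·rᵢ/Σrⱼ`; a zero group total
yields undefined fractions with a group-level flag instead of an error.
Replicate dispersion is reported as per-position min/max/sd (ddof = 1)
across experiments.

## Synthetic plate generator

The generator provides ground truth for every stage; its defaults encode
the study conditions of the experiments it emulates.

**Growth.** Logistic growth `dOD/dt = μ_max·OD·(1 − OD/K)` starting after
a lag (default 60 min), from an inoculum of `K/200` (1:200 dilution),
integrated with a fixed 0.25-min Euler step so the measurement cadence
does not alter the trajectory. Defaults `μ_max = 0.02 min⁻¹` (~35 min
doubling) and `K = 0.5` absorbance are typical of glucose minimal medium
with casamino acids in 150-µl plate cultures. An optional **intermediate
lag** pauses growth for a set duration when the culture first reaches a
trigger OD, emulating the pause seen after switching from rich starter
medium to minimal medium.

**Promoter programs.** Per-biomass activity `a(t)` is `base_rate` times an
archetype gain: *fis* — a pulse at the onset of exponential growth
(default 150 min window) over a low floor; *hns* — constitutive with a
mild rise (default +30 %) as growth slows; *dps* — low during fast growth,
rising to full strength as `μ(t)/μ_max` falls (stationary-phase
induction), transiently boosted during an intermediate lag, and boosted by
`pulse_gain` (default 5× base) for exactly `pulse_duration = 40 min` after
an H₂O₂ treatment — the hard stop stands in for regulator shutdown, for
which no kinetic mechanism is modelled. A *piecewise* archetype takes an
explicit step profile and exists for estimator validation.

**Position and genotype effects.** The copy-number multiplier is
`2^(c·(1−x)·μ(t)/μ_max)` with `x` the relative origin→terminus coordinate
and `c = 1` by default: origin-proximal modules gain up to ~2× during fast
growth and the effect vanishes in stationary phase, when replication has
ceased. Static `genotype_multiplier`s encode HU-dependent position
effects; in the packaged scenarios the *hupA/B* fis module at MLup carries
2.5 (midpoint of the observed 2–3×) versus 1.0 at ML, and the dps-module
multipliers encode the observed qualitative pattern (e.g. MR stronger, TR
weaker); their magnitudes beyond the fis pair are free parameters.
Between-replicate fluctuation is a mean-one lognormal factor drawn once
per well, with CV 0.4 in the *hupA/B* dps scenarios — where strong
replicate-to-replicate variation is the documented phenomenon — and 0.1 in
the other mutant scenarios; wild type has CV 0. `upstream_coupling`
(0.5 in the mutant ara scenario) multiplies activity while the upstream
operon is induced.

**Measurement model.** `od_raw = OD + offset + N(0, od_sd)`,
`fluor_raw = g·F + α·OD + dark + N(0, f_sd)`, clipped at zero. Defaults:
offset 0.04, `od_sd` 0.003 absorbance, `f_sd` 5 and dark 20 fluorescence
units, `α = 150` units per absorbance — plausible magnitudes for a
filter-based plate reader at moderate gain. Reporter amounts reach 10³–10⁴
units, so late-signal relative noise is well below 1 %.

**What the generator does not emulate:** reporter maturation/degradation
(consistent with the estimator), cell-to-cell heterogeneity, evaporation
and edge effects, nutrient-explicit diauxie, and any mechanistic
supercoiling dynamics — position effects enter as static multipliers, not
as a biophysical model. Tests passing on these plates therefore validate
the *pipeline arithmetic and estimator accuracy* under the assumed signal
model, not the biological model itself.

## Packaged scenarios and problem sizes

`build_study_scenarios()` returns ten plates: six-position dps induction
plates (wild type and *hupA/B*; 340 min at 10-min cadence, treatment at
170 min), six-position hns plates, the fis ML/MLup pair, the ara
upstream-coupling pair and the dps media comparison (all 23 h at 10-min
cadence, 139 points per well). The casamino medium variant grows slightly
faster (`μ_max` 0.023 vs 0.020 min⁻¹) to a higher yield (K 0.55 vs 0.45)
than plain minimal medium, and its dps program is 2.5× stronger (midpoint
of the observed 2–3×). Estimator-validation fixtures use single-well
zero-noise plates on a 1-min grid (1381 points).

## Numerical choices and degenerate inputs

- Quantile-cut knot placement guarantees populated inter-knot intervals;
  duplicate cuts (more knots than distinct gaps) are dropped, the minimal
  adjustment that restores admissibility.
- All-masked expression series yield an empty activity profile with a
  warning; fewer than 10 unmasked points refuse a spline fit.
- Induction endpoints falling on masked points raise an error naming the
  time point rather than silently shifting.
- Zero group totals in fraction normalization return flagged NaNs.
- The stationary end-point statistic is the mean F/OD over the final
  60 min of unmasked data — long enough to average noise, short enough to
  stay within the plateau.
- Ties in nearest-grid-point lookup cannot arise on the 10-min grid with
  the default 170/40-min windows.

## Known limitations

- The synthesis rate inherits spline boundary bias despite the margin;
  rates within ~30 min of the unmasked span's ends are not reported.
- Time-matched background correction assumes reference and sample grow
  alike; a systematic growth difference leaks autofluorescence into F.
- The F/OD mask threshold trades early-time coverage against noise; at
  `od_epsilon = 0.01` the first ~2 h of a standard culture are masked.
- Fraction normalization makes per-position responses compositional:
  a single position's change moves all fractions of its group.
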