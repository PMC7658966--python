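# Methods

## Problem and quality criteria

A power injector should deliver a contrast-medium (CM) bolus whose
concentration at the patient end of the tube line is a boxcar: zero
during the saline baseline, a constant plateau while the programmed
volume flows at the programmed rate, and zero again after the saline
chaser. Real injectors deviate — roller-pump (RP) mechanisms pulsate,
pressure limits slow the flow ramp, and the CM slug intermixes with the
saline propellant inside the line, blurring the flanks in proportion to
the line's filling volume.

Each photometric time–contrast (TC) recording is summarised by two
criteria:

* **cBCF** — Pearson correlation R_P between the measured deflection
  and the least-squares boxcar fitted to it. 1 means an ideal bolus.
* **dBIT** — effective minus expected injection time, in seconds. The
  effective time is the fitted plateau length t_off − t_on; the
  expected time is volume/flow from the protocol. Both the signed value
  and |dBIT| are stored; rankings and group tests use |dBIT| (smaller
  is better), matching the criterion's "lower is better" reading.

## Preprocessing

The sensor reports transmitted light; dye dips the intensity. The
pre-injection baseline (the first `injection_delay_s` seconds, default
10 s, ≥ 10 samples enforced) gives a mean/SD estimate. Deflection is
the Beer–Lambert absorbance −log(I/I_baseline) by default; a `linear`
mode ((I₀−I)/I₀) is retained as the small-absorbance approximation (the
two agree to first order below ≈ 0.05 absorbance). Baseline noise is
propagated to deflection units by the delta method (sd/mean in both
modes), so the validity rule is dimensionally coherent: a recording is
admitted only if its mean deflection over the final 2 s lies within 2
baseline SDs of zero ("returned to baseline"). A second, advisory flag
marks baselines noisier than 5% of the peak deflection — a threshold
chosen permissively, not a bench-derived constant. Deflections are not
clipped at zero: clipping would bias the baseline-window mean positive
and break the zero-mean baseline property the validity rule relies on.
No detrending or filtering is applied beyond baseline subtraction.

## Boxcar fit

The fit minimises the residual sum of squares over *every* pair of
changepoints (i_on, i_off) on the sample grid, with the two levels given
in closed form as the conditional means inside/outside the plateau and
the plateau constrained to lie at or above the baseline (boluses are
positive deflections). Prefix sums make each candidate O(1), the whole
scan O(n²); at 12.2 Hz recordings are short enough that the global
optimum costs well under a second, so no heuristic search is used and
an independent exhaustive oracle can verify optimality case by case.
SSE ties are broken toward the shorter plateau, then the earlier onset.
Degenerate inputs (constant curves) return a flagged one-sample fit
rather than raising; cBCF is undefined (NaN) there and the recording is
excluded from group statistics. The fit spans the full recording
(baseline through washout); no sub-sample interpolation of the
changepoints is attempted, so dBIT has a quantisation floor of about
one sample interval (82 ms).

## Group statistics

* **Kruskal–Wallis** omnibus test across injectors (mid-ranks, tie
  correction, chi-squared reference with k−1 df), per protocol group
  (all / vVol / cVol / mVol — the 10 ml @ 5 ml/s protocols are members
  of both vVol and cVol) and metric. The chi-squared reference is a
  tail approximation; at group sizes around 4 it tracks an exact
  permutation enumeration to within 0.02 only for moderately large H.
* **Pairwise comparisons** in the Dunnett-modified Tukey–Kramer family
  for unequal sizes and variances: per pair, the unpooled standard
  error with Welch–Satterthwaite degrees of freedom and the studentized
  range quantile q_{α'}(k, ν)/√2 at the Bonferroni-tightened level
  α' = α/#pairs. For k = 2 the exact identity q(2, ν) = √2·t_{α/2}(ν)
  is used. Significance is tagged at 0.05/0.01/0.001.
* **ANCOVA** of each metric on pump type and CM type (categorical) and
  line volume and injection power (numeric covariates), with all
  pairwise interactions, Type II sums of squares (the convention of the
  R `car::Anova` stack this analysis mirrors). The caller restricts to
  the constant-flow subset (5 ml/s, volumes 2–15 ml). The full
  interaction model needs the two experimental line-swap configurations
  to be identifiable: with only the five regular injectors the seven
  injector-level design columns are aliased, and the fit refuses with
  an explicit list of aliased terms.
* **Compliance odds ratio**: a recording is compliant when cBCF ≥ and
  |dBIT| ≤ their thresholds (defaults: study-wide medians, always
  reported alongside the result). The CM-type × compliance 2×2 table
  gives a Fisher exact p; empty cells trigger the Haldane–Anscombe
  +0.5 correction, flagged.
* **Rank summaries**: median and [min, max] per injector, ordered
  best-first (cBCF descending, |dBIT| ascending).

## Synthetic bench

No recordings are deposited with the study this package reimplements,
so a generative model stands in for the sensor. It is a simulator of
the bench's *structure*, not a calibrated model of any vendor's device.

**Flow profile.** The pump idles for the injection delay (10 s of
saline baseline), ramps linearly to the set flow over
`ramp_viscosity_coeff · viscosity · flow / max_pressure` seconds
(pressure-limited acceleration; Gadoterate 3.4 mPa·s, Gadoteridol
2.0 mPa·s at 20 °C), and pumps until it has delivered the CM volume
plus the flush (line volume + 25 ml, the bench's washout rule). RP
pumps modulate the flow by 1 + a·sin(2πft) (default a = 0.3,
f = 1.5 Hz — order-of-magnitude choices; no quantitative flow-variance
data exist for these pumps). Inlet concentration is 1 exactly while
the commanded CM volume passes, with fractional edge steps, so the
delivered CM volume is exact by construction. A ramp longer than half
the injection is rejected as an underpowered configuration.

**Transport.** The line is a tanks-in-series cascade: N equal
well-mixed compartments summing to the line volume, advanced by
explicit conservative volume-balance updates sub-stepped so no tank
turns over more than half its volume per step (the update telescopes,
so CM volume is conserved exactly up to quadrature of the output).
N = clamp(round(n_tanks_base · viscosity_ratio / (dispersion_scale ·
line_volume)), 1, 400): mixing grows with line volume and shrinks with
viscosity (the Stokes–Einstein direction — a viscous bolus resists
dissolution into the propellant). With the defaults (n_tanks_base =
120), a 6 ml PS line gets ≈ 70 tanks (sharp flanks) and a 100 ml RP
line 2–4 (heavy blur). Because the idealized cascade has far longer
tails than a real line, the simulator keeps pushing saline at the set
flow beyond the commanded flush until the outlet clears 10⁻³, so every
recording ends on baseline as bench recordings did.

**Readout.** Intensity = 1000·exp(−c) plus Gaussian noise (SD 2
intensity units, ≈ 0.2% of baseline), sampled at 12.2 Hz from t = 0
until the concentration has stayed below 10⁻³ for 2 s. Per-recording
noise seeds derive from a stable hash of (master seed, injector,
protocol, day), so studies are bit-reproducible and extending a design
never perturbs existing recordings; the day index adds a 1% baseline
intensity drift.

**What it does and does not emulate.** Passing tests show the analysis
machinery recovers known truths and the qualitative orderings — PS
above RP on both criteria, degradation with line volume, the slight
Gadoterate advantage — under this generative model. They do not show
vendor-level fidelity: real lines disperse far less per millilitre
than a 2–4-tank cascade, so simulated |dBIT| for 60–100 ml lines
(tens of seconds) exaggerates the bench's second-scale errors; real
roller-pump waveforms are not sinusoidal; elastic line deformation,
cannula back-pressure and staining chemistry are not modelled at all.
Line volumes and injection powers in the bundled design are
illustrative placeholders, not vendor data.

## Numerical and design choices

* Least squares for the boxcar levels (the loss is otherwise
  unspecified); positivity of the plateau assumed.
* Euler sub-stepping bounded by half-tank turnover; the single-tank
  wash-in then matches 1 − exp(−Qt/V) to < 1%, and configurations that
  would need > 10⁴ steps/s are rejected rather than silently coarsened.
* SSE tie tolerance 10⁻⁹ relative; p-values reported to 4 decimals in
  the JSON summaries.
* Problem sizes in the test-suite calibrations (200 oracle curves up to
  500 samples, 50 conservation configurations, 2000-replicate null for
  the pairwise test) were chosen to bound each check's Monte-Carlo
  error well below its asserted tolerance while keeping the default
  suite quick to run.

## Known limitations

Absolute cBCF/dBIT magnitudes from the simulator are not comparable to
bench values (see above); only directions and orderings are meaningful.
The ANCOVA treats line volume and injection power as continuous — with
five to seven injector configurations the covariate support is sparse,
which is faithful to the original design but limits interpretation of
the interaction terms. The boxcar is the only bolus model implemented;
gamma-variate or trapezoid alternatives are deliberately out of scope.
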