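# Methods

`embryomech` re-implements, as a tested pipeline over synthetic data, an
analysis that predicts the developmental potential of one-cell (2PN)
embryos from their viscoelastic response to micropipette aspiration.  This
note documents the models, the choices behind every tunable default, what
the synthetic data does and does not emulate, and the package's known
limitations.

## The mechanical model

During a measurement the embryo is sealed to a micropipette under a small
holding suction (−0.03 psi), then a suction step to −0.345 psi is applied
and the aspiration depth `x(t)` of the embryo tongue into the pipette is
recorded at 75 Hz.  The net force of the step is taken as the pressure
change across the opening times the opening area,

    F0 = |p_step − p_hold| · π (d/2)²,

with `d` = 40 μm (mouse) or 70 μm (human) inner diameter; 1 psi =
6894.757 Pa.  Using the net change rather than the absolute step pressure
is a convention (the two differ by < 10 % here) and is recorded in the
protocol object.

The embryo's response shows an instantaneous elongation, an exponential
settling and a late constant-rate tail.  The bulk model with exactly these
features is a **modified Zener body**: an equilibrium spring `k0` (N·m⁻¹)
in parallel with a Maxwell arm (spring `k1`, dashpot `η1`), all in series
with an extra dashpot `η0` (N·s·m⁻¹).  Its creep response to a force step
is

    x(t) = F0/k0 − [F0·k1 / (k0(k0+k1))] · e^(−t/τ) + F0·t/η0,
    τ    = η1 (k0+k1) / (k0 k1),

with the jump `x(0⁺) = F0/(k0+k1)`, the asymptote `F0/k0` and the tail
slope `F0/η0`.  The comparison models (Maxwell, Kelvin–Voigt, Zener, and a
two-arm Wiechert five-parameter variant built from the same per-arm
constants) are nested simplifications or enrichments of this form.  Label
convention: `k0` is always the parallel equilibrium spring and `k1` the
Maxwell-arm spring; conditioning analysis of the fit (below) supports this
assignment for the printed parameter values.

A numerical oracle (`creep_ode_oracle`) integrates the network's governing
force-balance ODEs with a stiff solver (Radau, rtol 1e−12) and never
touches the closed forms; closed form and oracle agree to < 1e−8 relative
over `t ∈ [0, 5]` s for random positive parameters.

## Fitting

`fit_trace` minimizes the unweighted squared residual of the closed form
against the measured depths with `scipy.optimize.least_squares`, operating
on log-parameters, which enforces positivity and makes the step tolerance
relative (`xtol` 1e−12, bounds e^±20.7).  Initialisation is read off the
data — `η0` from the late-time slope, `k0` from the late-time intercept,
`k1` from the initial jump, `η1` from the transient's 63 % time — with
log-spaced multistarts as a fallback.  `compare_models` fits
simplest-first and warm-starts each richer model from the nested solution
embedded in its parameter space (Kelvin–Voigt is the `k1→∞` limit of
Zener, Zener the `η0→∞` limit of the modified Zener, and a slow second
arm emulates the series dashpot), so the reported residuals respect model
nesting to solver tolerance.

**Identifiability.**  At the printed human viable center (k1 = 0.30,
η1 = 0.59, k0 = 0.12 N·m⁻¹) the creep time constant is τ ≈ 6.9 s.  Over a
5-s record at 75 Hz with 0.1 μm measurement noise, the Cramér–Rao bound
gives relative standard deviations of roughly 15 % for `k0`, 6 % for
`k1`, 3.5 % for `η1`, and `(F0/η0)`-dependent uncertainty for `η0` (≈ 37 %
at the default η0 = 5 N·s·m⁻¹): the exponential never settles inside the
window, so the asymptote (k0) and tail (η0) are partly confounded.  No
unbiased estimator can do better on such records; recovering `k0` and
`η0` to a few per cent requires longer records (≈ 3τ, about 20 s), which
the fitter handles without change.  The swapped label convention
(parallel spring = 0.30) is several times worse conditioned, which is why
the stated convention is kept.

## Synthetic data

The generator provides every fixture the pipeline consumes.  Its defaults
are the study's conditions; everything is configurable.

- **Cohorts** (`CohortSpec`): 31 viable + 58 non-viable embryos (the human
  cohort size).  Viable mechanics are log-normal around the printed viable
  centers — human (k1 = 0.30, η1 = 0.59, k0 = 0.12), mouse (k1 = 0.17,
  η1 = 1.3, k0 = 0.06) — with 15 % multiplicative spread (no dispersion is
  printed; 15 % renders the visibly tight viable cluster).  Non-viable
  mechanics come from a 50/50 "too stiff" (centers ×1.8) / "too soft"
  (×0.55) mixture with 40 % spread, with the stiff/soft component drawn
  once per embryo, so there is no typical non-viable phenotype.  `η0` has
  no printed center; 5.0 (human) and 3.0 (mouse) N·s·m⁻¹ make the
  constant-rate tail the same order as the creep amplitude over 5 s.  `η0`
  is drawn from one shared distribution for both classes and is therefore
  uninformative by construction.  Cell-cycle intervals (c1, c2, c3) center
  on (0.20, 11.32, 2.91) h for viable embryos (10 % CV) and spread over a
  wide uniform band (0.25–2.5× center) for non-viable ones.  Blastocyst
  labels equal the mechanical class flipped with probability 0.1
  (`label_noise`), making classification hard but learnable.
- **Traces**: closed-form modified-Zener creep plus i.i.d. Gaussian depth
  noise (default sd 0.1 μm), 75 Hz, 5 s.
- **Videos**: 8-bit grayscale scenes, pipette horizontal from the left,
  0.5 μm/px; anti-aliased embryo disk and aspirated tongue whose leading
  edge carries the creep motion.  A small holding tongue (default 4 μm) is
  drawn before the step so that the frame-0 template contains the same
  edge profile as later frames.
- **Confocal stacks**: a flat cortical ring (annulus 0.87R–1.03R, slightly
  wider than the 10 %-of-radius scoring band so band-edge interpolation
  stays inside the flat region), Gaussian granule puncta on the annulus, a
  cytoplasm level above background (which real cells show, and which cell
  detection needs), and per-slice `exp(−k/λ)` attenuation to exercise
  contrast normalisation.

Everything is driven by `numpy.random.default_rng(seed)`; identical seeds
give bit-identical outputs.  The generator does **not** emulate optics
(point-spread, shading), debris or neighbouring cells, non-circular or
drifting embryos, pressure-controller dynamics, or cryopreservation
effects — so green tests demonstrate correctness of the algorithms on
idealised data, not robustness to every artefact of real recordings.

## Tracking

`detect_pipette` isolates the wall gray level by two-stage Otsu
thresholding (the second pass separates walls from the embryo among the
dark pixels), takes rows whose longest dark run spans ≥ 25 % of the width
as the two wall bands, and refines the opening corner with Canny edges
(σ = 2 px).  Failures name the stage (wall vs corner detection) instead of
returning a guess.  `track_edge` matches a frame-0 template of the
leading edge (half-width 8 px, lumen rows only) by normalized
cross-correlation along the pipette axis within ±50 px of the previous
position — wide enough to cover the instantaneous elongation at the
pressure step (≈ 40 px for the human center at 0.5 μm/px) — and refines
the peak parabolically.  Frames whose peak correlation falls below 0.6
are flagged and linearly interpolated (error beyond 3 consecutive).
Depth is positive into the pipette, zeroed at the step-onset frame; only
post-onset frames enter the fitted trace, since the onset-frame depth
belongs to the pre-step baseline rather than the creep curve.  On
rendered scenes the tracker is accurate to ~0.003 px RMS; the spec-level
guarantee is 0.5 px.

## Classification

Features are `k1`, `log η1` (natural log; its spread is multiplicative),
`k0`, `η0`, optionally joined with `c1–c3`.  The classifier is an
RBF-kernel SVM with `K(x, z) = exp(−‖x−z‖²/2σ²)` (scikit-learn,
`gamma = 1/2σ²`).  Because the features mix N·m⁻¹ and N·s·m⁻¹ scales,
each cross-validation fold z-scores with statistics of its training rows
only; standardization and tuning never see test-fold rows.

- **Tuning**: grid search over `c ∈ 2^[−5, 15]`, `σ ∈ 2^[−10, 5]`
  (step 2²) maximising mean 10-fold CV accuracy (raw accuracy; the
  stratified folds keep class ratios), ties broken toward smaller `c`
  then larger `σ` — the smoother model.
- **Evaluation**: 100 Monte-Carlo repetitions of stratified 10-fold CV;
  per repetition the pooled out-of-fold decision scores form one ROC and
  one PR curve (pooling keeps thresholds coherent across folds); the mean
  and s.d. of the trapezoidal AUCs are reported.  The ROC sweep groups
  tied scores, which makes its area exactly the Mann–Whitney statistic.
- **Operating points**: Youden's J by default; fixed-specificity and
  fixed-precision criteria are exposed because the study's printed
  sensitivity/specificity/precision triplet does not identify which was
  used.  Infeasible constraints are reported as such.
- **Forward selection**: greedy, hyperparameters re-tuned for every
  candidate at every step on a coarser 3×3 grid (tuning repeats ~10 times
  per run), candidate AUC averaged over 5 stratified fold reshuffles
  shared by all candidates of a step.  At cohort scale (n ≈ 89) a single
  10-fold AUC estimate is noisy enough to scramble near-tied candidates;
  the small average makes the path stable without changing the estimator.

Because the three informative mechanical features share the per-embryo
stiff/soft mixture component, they are strongly redundant: once two are
selected, the third adds almost no cross-validated AUC, and the ordering
of the last informative feature against `η0` is close to a coin flip on a
sizable fraction of default-size cohorts.  This is a property of the
cohort geometry, not of the selection estimator, and it bounds how often
`η0` can rank last (observed ≈ 72 % of seeded default cohorts).

**Null calibration.**  The permutation null draws an independent label
permutation for every MC repetition (hyperparameters tuned once on a
separate permutation).  A single fixed permutation is *not* a valid null
at this scale: its accidental association with the feature geometry is
real at the sample level and a tuned RBF-SVM recovers it (mean pooled AUC
up to ≈ 0.58 at n = 200).

## Granule scoring

Stacks are normalised per slice by the 1st–99th percentile window
(rescaled to [0, 1]); a multiplicative depth attenuation cancels exactly.
The projection is per-pixel maximum by default (granules are sparse
bright puncta; mean available).  Cell detection is Otsu binarisation,
hole-filling (the bright ring encloses the dimmer cytoplasm), Canny
edges, then a circle Hough over 15–60 % of the image size; the best
circle must exceed a normalized vote of 0.6 — comfortably above what
speckle noise accumulates (≈ 0.4) — otherwise detection fails loudly.
The circumferential profile samples, at ⌈2π·0.95R⌉ angles, the mean of
bilinear interpolations at 7 radii spanning the band of width 0.10R
centred at 0.95R (the centred-band reading of the band convention;
configurable).  The score is the mean (total retained-granule signal) and
s.d. (punctateness) of the angular profile.  Group comparisons use the
Wilcoxon rank-sum test, optionally stratified by a covariate quartile
(e.g. the stiffest quarter of each group by fitted `k1`).

## Statistics

All tests are two-sided and record their conventions in the report:
Wilcoxon rank-sum exact by enumeration for tie-free pooled n ≤ 20, else
normal approximation with tie and continuity corrections; two-sample KS
exact for `n_x·n_y ≤ 400`, else the effective-n asymptotic (note: the
exact two-sample null is discrete and the asymptotic can sit ~0.1 away at
n = 10 vs 10); Pearson χ² with Yates correction on 2×2 tables and a
low-expected-count flag; pooled-variance two-proportion z (z² equals the
uncorrected 2×2 χ²); Lilliefors normality with a seeded Monte-Carlo null
(the statistic's null distribution depends on fitting mean and s.d. to
the data, so tables or simulation are required; simulation keeps the
convention explicit); Welch t by default with a pooled option.

## Problem sizes

Simulation sizes used by the test-suite and the acceptance script — 100
parameter draws for the oracle, 100 replicate traces for recovery and
model ordering, 100 seeded cohorts for selection, 100 MC repetitions for
CV, 2–3 rendered videos, 50–100 confocal render pairs — are chosen so
each study estimates its quantity with small Monte-Carlo error while the
whole suite completes in minutes on one core.

## Limitations

- The bulk lumped-parameter model has no continuum interpretation
  (no Young's modulus estimation) and one global force balance; spatial
  heterogeneity (soft cell + stiff zona) is out of scope.
- Short records (< 3τ) leave `k0`/`η0` weakly identified (see above).
- The tracker assumes a single embryo, near-horizontal pipette and a
  leading edge visible in frame 0; no re-detection after gross failure.
- Cell detection expects one dominant, roughly circular cell.
- Classification metrics on synthetic cohorts depend on the assumed
  mixture geometry; they validate the machinery, not clinical
  performance.
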