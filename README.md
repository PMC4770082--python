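# embryomech

Mechanics-based viability analysis for one-cell embryos.

Within hours after fertilization — long before the embryonic genome
switches on — a zygote's viscoelastic properties already separate embryos
that will form blastocysts from those that will arrest.  The measurement
is micropipette aspiration: the embryo is held at a pipette under a small
suction, a suction step is applied, and the depth `x(t)` to which the
embryo is drawn into the pipette is recorded on video.  `embryomech`
implements the full analysis around that measurement for researchers in
embryology, IVF methods development and cell mechanics:

- **Viscoelastic modelling** (`embryomech.viscoelastic`): closed-form
  creep responses of the modified Zener model — an equilibrium spring
  `k0` in parallel with a Maxwell arm `(k1, η1)`, in series with a
  dashpot `η0`:

      x(t) = F0/k0 − [F0 k1 / (k0(k0+k1))] e^(−t/τ) + F0 t/η0,
      τ = η1 (k0+k1)/(k0 k1),  F0 = |Δp| π (d/2)²

  plus the Maxwell, Kelvin–Voigt, Zener and five-parameter comparison
  models, nonlinear least-squares fitting of recorded traces, an
  independent ODE oracle, and residual-based model comparison.
- **Video tracking** (`embryomech.tracking`): pipette detection
  (thresholding + Canny), normalized cross-correlation template tracking
  of the aspirated edge with subpixel refinement, and conversion of pixel
  tracks to depth traces.
- **Viability classification** (`embryomech.classify`): RBF-kernel SVM on
  `(k1, log η1, k0, η0)` and cell-cycle intervals `(c1, c2, c3)`, 10-fold
  cross-validated hyperparameter tuning, 100× Monte-Carlo cross-validated
  ROC/PR curves, greedy forward feature selection, operating points.
- **Cortical-granule scoring** (`embryomech.granules`): per-slice contrast
  normalization, projection, Otsu → Canny → circle-Hough cell detection,
  and the circumferential intensity profile at 95 % of the cell radius.
- **Statistics** (`embryomech.stats`): Wilcoxon rank-sum (exact or
  corrected-asymptotic), two-sample KS, χ², two-proportion z, Lilliefors
  (Monte-Carlo null) and Welch t, with conventions recorded per report.
- **Synthetic data** (`embryomech.synthetic`): seeded generators for
  cohorts, traces, aspiration videos and confocal z-stacks that emulate
  the study's measurements and drive the entire test suite.

## Worked example

Fit a synthetic aspiration trace recorded at the human viable-cluster
center (k0 = 0.12, k1 = 0.30, η1 = 0.59 N·m⁻¹/N·s·m⁻¹, η0 = 5.0) with
0.1 μm depth noise, then classify a default cohort:

```python
from embryomech import (HUMAN_PROTOCOL, CohortSpec, ViscoParams,
                        cohort_to_frame, fit_trace, render_trace,
                        sample_cohort)
from embryomech.classify import (feature_matrix, mc_cross_validate,
                                 tune_hyperparams)

center = ViscoParams(k0=0.12, k1=0.30, eta1=0.59, eta0=5.0)
trace = render_trace(center, HUMAN_PROTOCOL, noise_sd_m=1e-7, seed=0)
fit = fit_trace(trace, HUMAN_PROTOCOL)
print(fit.params, fit.rms_residual_m)

cohort = cohort_to_frame(sample_cohort(CohortSpec(seed=0)))
X, y = feature_matrix(cohort, ("k1", "log_eta1", "k0"))
c, sigma = tune_hyperparams(X, y, seed=0)
mc = mc_cross_validate(X, y, c, sigma, n_mc=100, seed=0)
print(mc.mean_auc_roc, mc.mean_auc_pr)
```

This prints (seed 0):

```
ViscoParams(k0=0.144, k1=0.276, eta1=0.555, eta0=3.415, ...)  1.00e-07
0.797  0.755
```

The fitted residual sits exactly at the injected noise floor (0.1 μm).
The springs come back within ~10–20 % on a single noisy 5-s trace — the
creep time constant (τ ≈ 6.9 s) exceeds the record, so the asymptote
parameters are the weakly identified ones; see `docs/methods.md` for the
identifiability analysis.  The cross-validated AUCs (~0.80/0.76 on this
31 + 58 cohort with 10 % label noise) quantify how well mechanics alone
predicts the blastocyst label on the synthetic cohort.

The same operations are scriptable from the shell:

```sh
embryomech simulate cohort --seed 0 --out cohort.csv
embryomech classify evaluate cohort.csv --features k1,log_eta1,k0 --seed 0
embryomech simulate video --seed 1 --out video.tiff
embryomech track video.tiff --out trace.csv
embryomech fit trace.csv
embryomech stats ztest --counts 189,282,25,35
```

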