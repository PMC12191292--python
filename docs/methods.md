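# Methods

## Problem and model

Dorsal-root-ganglion proton density (DRG-PD) is an MRI-derived biomarker:
the equilibrium magnetisation M0 of DRG tissue, estimated from a multi-echo
spin-echo (CPMG) acquisition and expressed relative to cerebrospinal fluid
(CSF), which serves as an internal ~100% water reference. The package
implements the full quantification chain and the cohort-level statistics
that relate DRG-PD (together with DRG T2 and volume) to small-fibre-
neuropathy (SFN) status in Fabry disease.

### Signal model

A CPMG train with echo train length 10 and echo spacing 15 ms ideally decays
as `S_k = M0 exp(-TE_k / T2)`. In practice the transmit (B1) field is
inhomogeneous, so the effective refocusing flip angle α falls below the
nominal 180°. Imperfect refocusing stores part of the magnetisation
longitudinally between pulses; it returns in later echoes as stimulated
echoes. Two consequences matter here:

* the decay flattens — a naive mono-exponential fit overestimates T2;
* the back-extrapolated intercept no longer equals M0 — typically an
  underestimate of ~10–25% at α ≈ 120–140°.

The extended phase graph (EPG) formalism (`drgpd.epg`) computes the echo
amplitudes exactly for arbitrary α by propagating transverse/longitudinal
configuration states through relaxation, crusher dephasing and the
refocusing rotation. Conventions: ideal 90° excitation about x, refocusing
about y (CPMG condition), ideal crushers (one configuration-order shift per
half echo spacing), magnitude signals, full relaxation between repetitions
(TR = 4.8 s ≫ T2). The state space is untruncated, so the recursion is
exact; correctness is pinned by an independent brute-force isochromat
simulator (exact rotation matrices over a uniform fan of dephasing angles)
to relative 1e-4 across α ∈ [100°, 180°], T2 ∈ [40, 300] ms,
T1 ∈ [500, 4000] ms. Because the isochromat signal is a trigonometric
polynomial of bounded degree in the dephasing angle, the uniform-fan
average is effectively exact, making it a genuine oracle rather than an
approximation.

### Correction algorithm

Per voxel (`drgpd.relaxometry`):

1. **Preliminary fit.** Weighted log-linear mono-exponential fit (weights ∝
   squared amplitude, the variance-stabilising choice for log data). A
   closed-form deterministic fit was preferred over nonlinear least squares:
   the correction loop absorbs the model mismatch, and determinism aids
   reproducibility. All 10 echoes are used — the flip-angle step needs
   echoes 1–2, so the common "drop echo 1" convention is not applicable.
2. **Flip-angle estimate.** α is the root of `S2/S1(α; T2, T1_assumed) =
   measured ratio`, found by bisection on [60°, 180°] (tolerance 0.01°).
   The ratio-vs-α curve is monotone on this bracket (verified at call
   time); ratios at/below the pure-exponential value map to 180°, ratios
   beyond the 60° bound are clamped and flagged rather than extrapolated,
   because the curve is not guaranteed monotone below ~60°.
3. **Correction factors.** A unit-M0 EPG train at the current (α, T2) is
   itself mono-exponentially fitted; the fitted M0 and fitted-to-true T2
   ratio are the biases κ_M0, κ_T2 of step 1. Dividing the measured
   preliminary estimates by them undoes the bias.
4. Steps 2–3 iterate until the maximum relative change of (M0, T2, α) drops
   below 1e-4 (max 25 iterations; non-converged voxels are flagged, not
   dropped). Both M0 and T2 are refined — T2 refinement is needed for a
   consistent α estimate — but the uncorrected T2 map is also retained so
   either convention can be reported.

The single-TR protocol cannot estimate T1, so a fixed assumed T1 (default
1000 ms, configurable) enters the EPG simulations. Sensitivity is small:
with a true T1 of 1000 ms and the assumption off by −20%/+50%, corrected M0
moves by < 1% across the tested (α, T2) grid (see
`test_t1_mismatch_robustness`). For CSF-like tissue (T2 ≈ 2000 ms, T1 ≈
4000 ms) T2 itself becomes unidentifiable over a 150 ms readout at low α,
but its M0 — the only CSF quantity the pipeline consumes — stays within 1%.

Noise handling: amplitudes at or below a configurable noise floor
(recommended 2× the background Rician σ) are excluded from the log fit,
since log-transformed noise-floor samples bias T2 upward.

### ROI metrics

`drgpd.roi` computes, per subject: DRG-T2 (median corrected T2 over DRG
voxels), DRG-Vol (voxel count × voxel volume, default 1.5·1.5·1.8 =
4.05 mm³), and DRG-PD — median corrected M0 over DRG voxels divided by the
per-slice 98th percentile of CSF M0 (slice axis = last axis, the
paracoronal acquisition direction). The percentile uses linear
interpolation between order statistics; the convention is pinned by a test
fixture (CSF values 1..100 → divisor 98.02) because "98th percentile" is
convention-dependent. Slices need ≥ 20 CSF voxels to yield a normaliser
(guarding a high percentile against tiny samples); other slices propagate
NaN. Subject-level aggregation over the four ganglia is the pooled-voxel
median (per-ganglion values are retained so alternative aggregations remain
reproducible). The slice-wise ratio makes DRG-PD invariant to any global or
per-slice multiplicative intensity scaling — the pipeline's core
identifiability property, asserted end-to-end on phantoms.

CSF can be supplied as a label (which always wins) or found automatically:
voxels with T2 > 400 ms and M0 above the volume's 90th percentile, minus
connected components smaller than 10 voxels.

### Statistics layer

`drgpd.stats` implements the analysis plan: Mann–Whitney U (exact
enumeration when n_x·n_y ≤ 400 and tie-free, otherwise tie/continuity-
corrected normal approximation), Cliff's δ by direct pair counting with a
95% CI from the consistent-variance estimator and the asymmetric
endpoint-shrinking transformation (a percentile bootstrap is available —
the asymmetric published intervals suggest a non-symmetric method, and the
exact construction used originally is not stated), the rank identity
AUC = (δ+1)/2 (exact under shared midrank tie handling, checked to machine
precision), ROC curves with midrank AUC, Spearman ρ, ICC(2,1) (two-way
random effects, absolute agreement, single measures, F-based CI; verified
against an independent variance-component oracle and against pingouin),
OLS and maximum-likelihood logistic regression via statsmodels with Wald z,
AIC = deviance + 2k, McFadden pseudo-R² and a likelihood-ratio test, and a
Lilliefors-type KS normality test whose p-value is Monte-Carlo (10,000
seeded replicates, cached per sample size) because moment-estimated normal
parameters invalidate the standard KS null.

`sfn_analysis` reproduces the full result structure: 9 strata × 3 metrics
group comparisons, the Spearman matrix, three linear models, the
nine-covariate logistic model (covariates on native scales — the published
DRG-PD coefficient of ≈ 11.5 implies unscaled a.u. input; a standardisation
flag exists but defaults off), and per-phenotype ROC. VUS subjects fall in
the "other" arm of the classical-vs-other contrast. No multiplicity
adjustment by default (exploratory stance); a Holm option exists.
Degenerate strata (constant SFN) yield None sentinels, not errors.

## Synthetic data

The phantom generator emulates the acquisition the pipeline inverts: a
64×64×12 grid (1.5×1.5×1.8 mm voxels) with an elliptical tissue body
(M0 0.5, T2 60 ms), a CSF tube spanning all slices (M0 1.0, T2 2000 ms,
T1 4000 ms), four DRG ellipsoids (T2 95 ms; M0 set per scenario — 0.765 and
0.701 a.u. are the SFN-positive/negative classical-phenotype medians), and
signal-free air outside the body. The effective flip-angle field is a
radial profile plus a heavily smoothed seeded perturbation mapped into
(115°, 180°); at defaults the voxel-to-voxel change stays below 2°.
Partial volume is simulated by 3× supersampled occupancy fractions mixing
compartment signals; labels default to the "pure" policy (only voxels fully
inside a compartment), mirroring the deliberate exclusion of boundary
voxels in careful manual segmentation — a "majority" policy exists to
demonstrate the partial-volume bias. Noise is Rician (magnitude of a
complex Gaussian), the physically correct magnitude-image model, whose
positive floor in air (mean σ√(π/2)) is what the noise-floor handling
expects. Compartment T1s default to 1000 ms for tissue — equal to the
correction's assumed T1 — and 4000 ms for CSF, deliberately different from
the assumed value so end-to-end tests exercise T1-mismatch robustness
rather than a rigged identity.

The cohort generator samples n = 80 subjects with the study-condition
marginals (38 m / 42 f; 18 classical / 54 late-onset-benign / 8 VUS;
sex-dependent α-Gal A activity and lyso-Gb3 as log-normals from the
published medians/IQRs; 19 of 80 missing biopsies). SFN is assigned by a
logistic link on the classical-phenotype indicator calibrated to the
published prevalences (25/80 overall, 7/18 classical). Imaging metrics are
then drawn per (phenotype-group × SFN) stratum: DRG-PD from a logit-normal
bounded to (0, 1.2) parameterised directly by median and IQR — so published
stratum summaries translate verbatim into generator settings — T2 normal,
volume log-normal by sex. A `null_effect` switch collapses the SFN+/−
distributions for calibration checks. Within-stratum dispersion beyond the
printed IQRs is unknown and is exposed as a free parameter, not asserted.

What passing tests on these generators do **not** show: real DRGs are not
ellipsoids, real B1 fields and coil profiles are not radial polynomials,
motion/registration/segmentation error are absent, and the cohort's
covariate dependence structure is simplified (e.g. metrics depend on SFN
and phenotype only through the stratum means). The tests establish that the
estimator chain is correct when its model holds, and quantify its
robustness to noise, intensity scaling and T1 mismatch — not clinical
validity.

## Numerical choices and degenerate inputs

* T2 estimates are clamped to [1, 3000] ms; fits with fewer than 3 positive
  echoes or non-decaying slope return NaN sentinels and propagate as
  unfitted voxels.
* Voxels whose correction train degenerates mid-iteration (e.g. noise-only
  voxels driven to the bracket edge at long T2) are dropped to NaN rather
  than poisoning the batch.
* Bisection uses a fixed iteration count derived from the 0.01° tolerance;
  batch and scalar paths share one vectorised core, and `fit_volume` is
  test-verified to equal per-voxel `fit_voxel` exactly.
* The EPG/isochromat cross-check grid, the 200-seed effect-size
  calibration, the 1000-seed type-I calibration and the 100-replicate noise
  bias comparison are the problem sizes used throughout; they were chosen
  to pin each property with comfortable Monte-Carlo margin at desk scale.
* Percentile convention, aggregation convention and slice axis are recorded
  in every run's resolved config; CSV/JSON outputs of identical
  (config, seed) reruns are byte-identical (provenance is timestamp-free).

## Known limitations

* The exact functional form of the originally published heuristic M0
  correction is not public; this package's documented choice — the
  mono-exponential fit of a unit EPG train — is validated against its own
  forward model, not against the original implementation.
* Slice-profile effects, diffusion, magnetisation transfer and
  complex-valued reconstruction are out of scope; the effective flip angle
  absorbs what it can of the former.
* CSF T2 is reported but not quantitative at this echo-train length; only
  its "detectably long" character and its M0 are load-bearing.
* Whether the original per-slice normaliser used all slices or only
  DRG-intersecting ones is unstated; divisors are computed for all slices,
  consumed only where DRG voxels lie.
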