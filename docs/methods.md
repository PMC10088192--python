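# Methods

## Scope and design

`qmristats` reimplements, as a tested library, a quantitative-MRI
analysis chain for a four-cohort rat study (state control/tumor ×
condition fed/fasted): voxel-wise T1 mapping from a variable-TR
saturation-recovery series, voxel-wise single-tensor diffusion fitting
to MD and FA maps, R²-based voxel inclusion, per-pixel ROI extraction
in four hunger-related regions, and factorial GEE inference. A
synthetic phantom supplies ground truth so that every stage is
verifiable by parameter recovery; no animal data are required or
included.

## Phantom

The phantom is deliberately geometric, not anatomical: four
axis-aligned rectangular regions (cortex 21 px, hippocampus 21 px,
hypothalamus 20 px, thalamus 22 px) on one designated central slice of
a 128×128×5 grid at 0.25×0.25 mm² in-plane and 1.5 mm slice thickness.
Region shape is irrelevant downstream — only the pixel count enters
the statistics — so rectangles keep placement trivial and disjointness
checkable. Regions sit in the left hemisphere, matching the convention
of drawing ROIs contralateral to the (right-side) tumor in
tumor-bearing animals and on the left in controls.

Value generation is hierarchical: group mean → per-animal region mean
(between-animal SD) → per-voxel value (coefficient of variation).
Defaults:

| quantity | baseline | between-animal SD | voxel CV |
|---|---|---|---|
| T1 (ms) | 1400–1550 by region | 50 | 3% |
| MD (mm²/s) | 0.72–0.80 ×10⁻³ | 0.022×10⁻³ | 5% |
| FA | 0.15–0.20 | 0.015 | 8% |

Baselines are plausible 7 T rodent gray-matter values and are package
presets; the study this design emulates reports its own per-region
means only in supplementary material, so absolute levels here are
deliberately *not* claims about any real measurement. What the preset
does encode, as directions and magnitudes of group effects, is the
emulated finding pattern:

* fed tumor cortex and thalamus T1 lowered by 150 and 140 ms (~10%);
* control fasted MD lowered by 6% in cortex, hippocampus and thalamus;
  tumor MD insensitive to condition;
* tumor FA lowered by 0.05 in cortex, hippocampus and thalamus under
  both conditions.

Effect sizes were fixed once at magnitudes typical of the respective
literatures (fasting/activity MD responses of a few percent; clearly
supra-threshold MEMRI and tumor-infiltration effects).

Diffusion ground truth is an axially symmetric (prolate) tensor per
voxel: given target MD and FA, λ₁ = MD(1+2f), λ₂ = λ₃ = MD(1−f) with
f = FA/√(3−2FA²), rotated so λ₁ lies along a configurable per-region
direction. The inversion is exact (round-trip MD/FA to ~1e-15); a
nonnegative triple exists for every MD > 0, 0 ≤ FA < 1, and other
pairs are rejected. One root seed deterministically spawns per-animal
substreams, so studies are reproducible and animals independent.

## Signal simulation

Both acquisitions are forward-simulated from truth: S(TR) =
S0(1−e^(−TR/T1)) at the seven default TRs (150, 200, 400, 800, 1600,
3500, 6000 ms), and S(b,g) = S0·e^(−b·gᵀDg) for b = 0 plus six
directions × b ∈ {200, 1000} s/mm² (13 frames). The default direction
set is the six-vertex icosahedral scheme; any validated set (≥6 unit
vectors, pairwise non-collinear, jointly non-coplanar) can be
substituted, and the property tests randomize it. Gradient timing
(Δ = 20 ms, δ = 4 ms) is carried as metadata only — b is never
recomputed from it. Both shells share one direction set.

Magnitude noise is Rician: each clean value s becomes
√((s+n₁)²+n₂²) with n₁, n₂ ~ N(0, σ²). Noise level is parameterized
as SNR = S0/σ at full signal; the working default is SNR 50, a
realistic preclinical magnitude-image regime in which Rician bias at
full signal is ≈ σ²/(2S0) ≈ 0.01% and the noise is near-Gaussian.
The simulator does not model EPI distortion, motion, eddy currents or
multi-compartment diffusion; passing tests therefore demonstrate
correctness of estimation and inference under the stated noise model,
not robustness to acquisition artifacts.

## T1 fitting

Per voxel, (S0, T1) minimize the squared residuals of the
saturation-recovery model in the native signal domain. The solver is
vectorized over voxels: a profiled grid seed (S0 is linear given T1,
so the 1-D profile RSS is evaluated on a 96-point log grid between
10⁻³·min TR and ~20 s) followed by damped Gauss–Newton with analytic
2×2 normal equations, backtracking line search, and an active set that
retires converged voxels (relative step < 1e-12 or a stalled search,
i.e. a local minimum at working precision). Estimates pinned at the T1
bounds, non-positive S0, constant signals (zero total sum of squares,
including all-zero background) are flagged failed rather than raised.

R² = 1 − SS_res/SS_tot is computed about the signal mean in the signal
domain. The fit could alternatively be scored after log or other
transforms; the native-domain choice is documented rather than claimed
universal. The default inclusion threshold is R² > 0.75 (strict).

## Tensor fitting

With y = ln S, the model is linear: y = ln S0 − b·gᵀDg, giving the
standard 7-column design [1, −b gx², −b gy², −b gz², −2b gx gy,
−2b gx gz, −2b gy gz]. Plain OLS (no variance weighting, no nonlinear
refinement) solves all voxels in one pseudoinverse application; R² is
computed in the log domain where the fit lives. Voxels with any
non-positive signal are invalid by precondition. Negative eigenvalues
(noise) are clamped to zero before MD/FA so FA ∈ [0, 1]; a final 1-ulp
clip guards rank-1 degenerate voxels. MD equals trace(D)/3
independently of the eigendecomposition, which the tests exploit as a
two-path consistency check. One tensor fit feeds both maps, so MD and
FA share a single validity mask.

Note the null distribution of the log-domain R² with 7 parameters on
13 points is centered near 0.5, so the R² > 0.75 gate alone removes
only ~85% of pure-noise background voxels in the DTI fit (against
>99% for the 2-parameter T1 fit); in practice background removal for
DTI additionally relies on the ROI labels, which is also how the
pipeline uses it.

## ROI extraction and summaries

Observations are individual pixels, not ROI means: each valid voxel of
each region contributes one row (value, parameter, animal, state,
condition, region, voxel index). Dropped-voxel counts are logged;
regions left empty after masking are omitted with a warning. ROI pixel
counts outside [20, 22] warn but run, so user-supplied label volumes
of other sizes remain usable. Physical ROI volume is
count × (in-plane resolution)² × slice thickness — 21 px ≈ 1.97 mm³.
Summaries report mean ± sample SD (n−1 denominator; n = 1 groups are
flagged and report SD 0).

## GEE inference

The mean structure is the full factorial state × condition × region
with treatment coding (references control, fed, cortex; 16
coefficients), Gaussian family, identity link. Clusters are animals:
pixels within an animal share unmodelled animal-level variation and
are not independent. Estimation iterates a weighted least-squares β
update under the current working covariance with moment re-estimation
of the dispersion φ and the exchangeable correlation α from Pearson
residuals (α clamped to its positive-definite range), to relative
tolerance 1e-8, max 100 iterations; non-convergence is flagged, not
raised. The implementation reproduces statsmodels' GEE to machine
precision on shared inputs (cross-checked in the tests), but is
self-contained.

Covariance policy:

* **Pairwise contrasts** (differences of two cell means at fixed
  levels of the other factors) use the cluster-robust sandwich
  covariance, the conventional choice for GEE contrast SEs, and are
  reported unadjusted by default (optional Šídák adjustment is
  available through the multiplicity helper).
* **Omnibus effect tests** (multi-df Wald chi-square per term, e.g.
  the 3-df state×condition×region interaction) default to the
  model-based (working) covariance. With ~24 animal clusters and 16
  mean parameters, the unadjusted sandwich is markedly anticonservative
  in multi-df tests (empirically ~14% rejection at nominal 5% in this
  design) — a known few-cluster pathology whose dedicated remedies
  (Mancl–DeRouen-type corrections) are out of scope here. The
  model-based covariance is exactly valid when the exchangeable
  working correlation is correctly specified, which holds by
  construction for the phantom's animal-intercept generative model and
  yields near-nominal calibration (~4%). `wald_cov="robust"` restores
  the sandwich for sensitivity analysis; the result object records the
  choice.

The significance convention is p < 0.05 throughout. Physiology
endpoints (body weight, glucose) use two-sided unpaired t-tests —
Welch by default, since equal group variances are not guaranteed;
classic Student's t via `equal_var=True` — with the step-down
Holm–Šídák adjustment: sort ascending, adjusted p(i) = max over j ≤ i
of 1 − (1 − p(j))^(m−j+1), capped at 1, returned in input order. The
adjustment is order-invariant; idempotence on already-adjusted inputs
is not claimed. Zero-variance degeneracies are resolved explicitly
(equal constants → p = 1; different constants → p = 0 with infinite
statistic).

## Pipeline, IO, determinism

Volumes are NIfTI-1 with RAS diagonal affines, 0-based (x, y, slice)
indices, slice axis third. Frame metadata travels in text sidecars:
a one-column TR table, and FSL-style bval/bvec tables for DWI. The
configuration round-trips through YAML with unknown keys rejected.
The pipeline driver chains simulate → fit → extract → infer, records
every artifact with a SHA-256 hash in a manifest, logs the acquisition
constants in effect and per-map valid/masked voxel counts, and is
byte-deterministic for a fixed seed. A stage failure aborts with the
stage name, leaving partial outputs and the manifest on disk.

## Problem sizes used in validation

Replicated Monte-Carlo studies run on a reduced 32×32 single-slice
grid with the same four 20–22-pixel regions, full protocol, SNR 50 and
default cohort sizes (6/6/6/7); region pixel counts, cohorts and noise
— not the empty background — drive the statistics, so the reduction
leaves measured rates representative while making replication cheap.
Calibration tables for the GEE (type-I error, effect recovery) are
drawn directly from the hierarchical model (animal intercept SD 50 ms,
pixel residual SD 100 ms, 21 px/region, 6 animals/group) without the
imaging stages, since they measure the inference procedure itself.
Standard validation sizes: 1000 voxels for recovery-bias medians, 5000
voxels for background masking, 1000 replicates for type-I error, 200
for effect recovery, 50 replicated studies for detection rates.

## Known limitations

* Anatomical realism, partial-volume effects, tumor mass and
  registration are out of scope; the phantom validates estimation and
  inference, not segmentation or spatial processing.
* The T1 model is saturation recovery only (no inversion-recovery,
  Look-Locker or B1 correction); the diffusion model is a single
  tensor (no IVIM/kurtosis), fit unweighted in the log domain.
* Small-sample GEE corrections are not implemented; the model-based
  Wald default above is the package's mitigation, and it relies on the
  working correlation being adequate. With grossly misspecified
  correlation structure the robust option should be preferred and its
  few-cluster inflation kept in mind.
* Detection-rate figures quantify power under the phantom's Gaussian
  between-animal / within-region variation; real tissue heterogeneity,
  ROI placement error and scanner drift are not represented.
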