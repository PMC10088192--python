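# qmristats

Quantitative-MRI parametric mapping with clustered group statistics,
built around a digital rat-brain phantom.

The package implements the analysis pipeline of a preclinical
hunger-imaging experiment: rats (healthy controls and glioblastoma
bearers, each fed ad libitum or fasted overnight) are scanned with a
variable-TR saturation-recovery sequence for T1 mapping — the readout
of manganese-enhanced MRI, where activity-dependent Mn²⁺ uptake
shortens T1 — and a two-shell, six-direction DWI sequence for
diffusion-tensor MD/FA maps. Group effects are then tested on the
individual ROI pixels with a generalized linear model estimated by
generalized estimating equations (GEE), clustering pixels by animal.

Because no animal data ship with the method, every stage is driven and
validated by a synthetic phantom whose ground truth is known exactly:
parameter recovery, masking behavior, statistical calibration and
detection of the emulated group effects are all measurable.

## Models

**Saturation recovery.** Each voxel's signal across repetition times
TR follows

    S(TR) = S0 · (1 − exp(−TR / T1)),

fit by nonlinear least squares at seven TRs (150–6000 ms). Voxels with
R² = 1 − SS_res/SS_tot ≤ 0.75 are masked out.

**Diffusion tensor.** The monoexponential single-tensor model

    S(b, g) = S0 · exp(−b · gᵀ D g)

is log-linearized and solved by ordinary least squares over 13
measurements (b = 0 plus six directions at b = 200 and 1000 s/mm²).
From the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of D:

    MD = (λ₁ + λ₂ + λ₃) / 3,
    FA = sqrt(3/2) · sqrt(Σ(λᵢ − MD)²) / sqrt(Σλᵢ²).

**Inference.** Pixel values y from the four 20–22-pixel ROIs (cortex,
hippocampus, hypothalamus, thalamus; ~2 mm³ each) enter a Gaussian
marginal model with the full factorial state × condition × region mean
structure, estimated by GEE with an exchangeable working correlation
over animals. Pairwise cell contrasts use cluster-robust (sandwich)
standard errors; physiology endpoints use unpaired Welch t-tests with
step-down Holm–Šídák correction.

## Worked example

```python
import qmristats as q
from qmristats.power import run_reduced_study

obs = run_reduced_study(seed=8)          # simulate + fit one full study
res = q.fit_gee(obs, parameter="T1")     # factorial GEE, pixels within animals
c = q.pairwise_contrast(res, "state", "control", "tumor",
                        condition="fed", region="cortex")
print(f"{c.estimate:+.1f} ms, p = {c.p:.4g}")
```

prints (seed 8):

```
-151.0 ms, p = 4.498e-05
```

i.e. in the fed condition the tumor-bearing cortex shows a T1 about
150 ms below control — the phantom's preset effect (−150 ms, here with
little sampling noise) — and the clustered test calls it significant.
The `examples/` directory walks through each capability: phantom
generation, T1 mapping, DTI mapping, ROI summaries, GEE inference and
the end-to-end pipeline driver. A thin CLI mirrors the stages
(`qmristats simulate | fit-t1 | fit-dti | extract-rois | gee | ttest |
run-all`).

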