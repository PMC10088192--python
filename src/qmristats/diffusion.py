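"""Voxel-wise single-tensor diffusion fitting and MD/FA map derivation.

The monoexponential tensor model S = S0·exp(−b gᵀDg) is linear in
(ln S0, D) after taking logs, so each voxel is fit by ordinary least
squares of ln S against the standard 7-column diffusion design. Mean
diffusivity is the eigenvalue average (equivalently trace/3) and
fractional anisotropy the normalized eigenvalue dispersion

    FA = sqrt(3/2) · ||λ − MD|| / ||λ||,  λ = (λ1, λ2, λ3).

R² is computed in the log-signal domain, where the fit is performed;
voxels with any non-positive signal are flagged invalid rather than
fit. Negative eigenvalues (noise) are clamped to zero before MD/FA so
FA stays in [0, 1]; clamped voxels carry a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DEFAULT_R2_THRESHOLD, ParametricMap
from .protocol import ProtocolError, validate_directions
from .volume import ImageVolume


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric diffusion tensor (mm²/s) with derived eigenvalues."""

    dxx: float
    dyy: float
    dzz: float
    dxy: float
    dxz: float
    dyz: float

    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ]
        )

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (λ1 ≥ λ2 ≥ λ3)."""
        return np.linalg.eigvalsh(self.matrix())[::-1]

    @property
    def md(self) -> float:
        return (self.dxx + self.dyy + self.dzz) / 3.0

    @property
    def fa(self) -> float:
        lam = np.clip(self.eigenvalues(), 0.0, None)
        return fractional_anisotropy(lam)


def mean_diffusivity(eigenvalues) -> float:
    """MD = (λ1 + λ2 + λ3) / 3."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues")
    return lam.mean(axis=-1) if lam.ndim > 1 else float(lam.mean())


def fractional_anisotropy(eigenvalues) -> float:
    """FA = sqrt(3/2)·sqrt(Σ(λi − MD)²) / sqrt(Σλi²); 0 for an
    all-zero (degenerate) input."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected 3 eigenvalues")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative (clamp first)")
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - md) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return float(fa) if fa.ndim == 0 else fa


def build_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Design matrix of the log-linearized tensor model.

    Row for measurement (b, g):
    [1, −b gx², −b gy², −b gz², −2b gx gy, −2b gx gz, −2b gy gz],
    acting on [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]. Validates the
    direction set (≥ 6, non-collinear, non-coplanar) and rejects
    rank-deficient designs.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if bvals.size < 7:
        raise ProtocolError(f"need at least 7 measurements, got {bvals.size}")
    nz = bvals > 0
    dirs = np.unique(np.round(bvecs[nz], 12), axis=0)
    validate_directions(dirs)
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    design = np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx**2,
            -bvals * gy**2,
            -bvals * gz**2,
            -2.0 * bvals * gx * gy,
            -2.0 * bvals * gx * gz,
            -2.0 * bvals * gy * gz,
        ]
    )
    if np.linalg.matrix_rank(design) < 7:
        raise ProtocolError("rank-deficient diffusion design (directions do not span the tensor space)")
    return design


def _tensors_from_coefs(coefs: np.ndarray) -> np.ndarray:
    """(n, 6) unique elements -> (n, 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = coefs.T
    t = np.empty(coefs.shape[:1] + (3, 3))
    t[:, 0, 0], t[:, 1, 1], t[:, 2, 2] = dxx, dyy, dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    return t


def fit_tensor_signals(
    signals: np.ndarray, design: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS tensor fit of an (n_voxels, n_meas) signal array.

    Returns (s0, tensors (n,3,3), r_squared, fit_ok). Voxels with any
    non-positive signal are skipped (fit_ok False, r² = −inf).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n, m = signals.shape
    if m != design.shape[0]:
        raise ValueError(f"{m} signals per voxel but design has {design.shape[0]} rows")

    s0 = np.full(n, np.nan)
    tensors = np.full((n, 3, 3), np.nan)
    r2 = np.full(n, -np.inf)
    fit_ok = np.zeros(n, dtype=bool)

    positive = np.all(signals > 0, axis=1)
    if positive.any():
        y = np.log(signals[positive])
        pinv = np.linalg.pinv(design)
        beta = y @ pinv.T  # (n_pos, 7)
        fitted = beta @ design.T
        res = y - fitted
        ss_res = np.einsum("vm,vm->v", res, res)
        yc = y - y.mean(axis=1, keepdims=True)
        ss_tot = np.einsum("vm,vm->v", yc, yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_pos = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, -np.inf)
        s0[positive] = np.exp(beta[:, 0])
        tensors[positive] = _tensors_from_coefs(beta[:, 1:])
        r2[positive] = r2_pos
        fit_ok[positive] = np.isfinite(r2_pos)
    return s0, tensors, r2, fit_ok


def fit_tensor_voxel(signals: np.ndarray, design: np.ndarray) -> tuple[float, DiffusionTensor | None, float]:
    """Fit one voxel; returns (S0_hat, DiffusionTensor or None, r²).

    A voxel with any non-positive signal is invalid: (nan, None, −inf).
    """
    s0, tensors, r2, fit_ok = fit_tensor_signals(np.asarray(signals, float)[None, :], design)
    if not fit_ok[0]:
        return float("nan"), None, float(r2[0])
    t = tensors[0]
    dt = DiffusionTensor(t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2])
    return float(s0[0]), dt, float(r2[0])


def fit_dti_maps(
    series: ImageVolume,
    protocol=None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> tuple[ParametricMap, ParametricMap]:
    """Voxel-by-voxel MD and FA maps from a 4-D DWI series.

    The two maps share a single per-voxel validity mask (one tensor
    fit feeds both). b-values/directions come from the protocol if
    given, else from the series' sidecar metadata.
    """
    if series.data.ndim != 4:
        raise ValueError("DWI series must be 4-D")
    if protocol is not None:
        bvals, bvecs = protocol.dwi_scheme()
    elif "bvals" in series.frame_meta and "bvecs" in series.frame_meta:
        bvals = np.asarray(series.frame_meta["bvals"], dtype=float)
        bvecs = np.asarray(series.frame_meta["bvecs"], dtype=float)
    else:
        raise ValueError("no b-value/direction metadata available")
    if series.n_frames != len(bvals):
        raise ValueError(f"series has {series.n_frames} frames but {len(bvals)} b-values")

    design = build_design(bvals, bvecs)
    shape = series.spatial_shape
    flat = series.data.reshape(-1, series.n_frames)
    _, tensors, r2, fit_ok = fit_tensor_signals(flat, design)

    md = np.full(flat.shape[0], np.nan)
    fa = np.full(flat.shape[0], np.nan)
    if fit_ok.any():
        lam = np.linalg.eigvalsh(tensors[fit_ok])  # ascending
        lam_clamped = np.clip(lam, 0.0, None)
        md[fit_ok] = lam_clamped.mean(axis=1)
        # guard against 1-ulp overshoot on degenerate (rank-1) voxels
        fa[fit_ok] = np.minimum(fractional_anisotropy(lam_clamped), 1.0)

    kwargs = dict(voxel_size_mm=series.voxel_size_mm, r2_threshold=r2_threshold)
    md_map = ParametricMap(md.reshape(shape), r2.reshape(shape), name="MD", fit_ok=fit_ok.reshape(shape), **kwargs)
    fa_map = ParametricMap(fa.reshape(shape), r2.reshape(shape), name="FA", fit_ok=fit_ok.reshape(shape), **kwargs)
    return md_map, fa_map
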