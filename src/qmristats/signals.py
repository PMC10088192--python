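"""Forward signal models for the two acquisitions.

Saturation recovery: S(TR) = S0 · (1 − exp(−TR/T1)), the longitudinal
magnetization regrowth sampled at each repetition time.

Diffusion (single tensor, monoexponential): S(b, g) = S0 · exp(−b gᵀDg),
the Stejskal–Tanner attenuation along gradient direction g at
diffusion weighting b.

Magnitude images carry Rician noise: |s + n1 + i·n2| with independent
zero-mean Gaussians of SD sigma on the two channels.
"""

from __future__ import annotations

import numpy as np

from .phantom import AnimalTruth
from .protocol import AcquisitionProtocol
from .volume import ImageVolume


def saturation_recovery_signal(s0: float, t1_ms: float, tr_ms) -> np.ndarray:
    """Noise-free saturation-recovery signal at each TR (ms)."""
    if s0 < 0:
        raise ValueError(f"S0 must be nonnegative, got {s0}")
    if t1_ms <= 0:
        raise ValueError(f"T1 must be positive, got {t1_ms}")
    tr = np.asarray(tr_ms, dtype=float)
    return s0 * (1.0 - np.exp(-tr / t1_ms))


def stejskal_tanner_signal(s0: float, tensor: np.ndarray, b: float, g: np.ndarray | None = None) -> float:
    """Noise-free DWI signal for one (b, direction) measurement.

    ``g`` may be omitted (or anything) at b = 0.
    """
    if b < 0:
        raise ValueError(f"b-value must be nonnegative, got {b}")
    if b == 0:
        return float(s0)
    g = np.asarray(g, dtype=float)
    if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
        raise ValueError("gradient direction must be a unit vector")
    d = np.asarray(tensor, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("diffusion tensor must be symmetric")
    return float(s0 * np.exp(-b * g @ d @ g))


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each value s by sqrt((s + n1)² + n2²), n1, n2 ~ N(0, σ²).

    sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    return np.hypot(s + n1, n2)


def sigma_for_snr(s0: float, snr: float) -> float:
    """Noise SD giving the requested SNR = S0/sigma at full signal."""
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return s0 / snr


def _t1_series_clean(truth: AnimalTruth, tr_ms: np.ndarray) -> np.ndarray:
    t1 = truth.t1_ms[..., None]
    return truth.s0[..., None] * (1.0 - np.exp(-tr_ms / t1))


def _dwi_series_clean(truth: AnimalTruth, bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    # quadratic form b_k * g_k^T D g_k per voxel and frame
    quad = np.einsum("...ij,ki,kj->...k", truth.tensor, bvecs, bvecs)
    return truth.s0[..., None] * np.exp(-bvals * quad)


def simulate_animal(
    truth: AnimalTruth,
    protocol: AcquisitionProtocol,
    sigma: float,
    seed: int | np.random.SeedSequence,
) -> tuple[ImageVolume, ImageVolume]:
    """Simulate both series for one animal; deterministic per seed.

    Returns (saturation-recovery series, DWI series) with per-frame
    metadata (TR list, or bvals/bvecs) attached.
    """
    if truth.t1_ms.shape != protocol.geometry.shape:
        raise ValueError(
            f"truth geometry {truth.t1_ms.shape} does not match protocol "
            f"geometry {protocol.geometry.shape}"
        )
    rng = np.random.default_rng(seed)
    tr_ms = np.asarray(protocol.tr_list_ms, dtype=float)
    bvals, bvecs = protocol.dwi_scheme()

    t1_clean = _t1_series_clean(truth, tr_ms)
    dwi_clean = _dwi_series_clean(truth, bvals, bvecs)

    t1_noisy = add_rician_noise(t1_clean, sigma, rng)
    dwi_noisy = add_rician_noise(dwi_clean, sigma, rng)

    vox = protocol.geometry.voxel_size_mm
    t1_series = ImageVolume(t1_noisy, vox, {"tr_ms": tr_ms})
    dwi_series = ImageVolume(dwi_noisy, vox, {"bvals": bvals, "bvecs": bvecs})
    return t1_series, dwi_series
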