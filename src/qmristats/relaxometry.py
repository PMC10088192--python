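"""Voxel-wise T1 mapping from a variable-TR saturation-recovery series.

Each voxel's signal vector is fit by nonlinear least squares to

    S(TR) = S0 · (1 − exp(−TR / T1))

in the native signal domain, with R² = 1 − SS_res/SS_tot (SS_tot about
the signal mean) as the per-voxel goodness of fit; only voxels with
R² above the configured threshold (default 0.75) survive masking.

The fitter runs vectorized over all voxels at once: a coarse profiled
grid search over T1 (S0 is linear given T1, so it is profiled out in
closed form) seeds a damped Gauss–Newton refinement on (S0, T1). This
makes whole-volume maps cheap without per-voxel scipy calls.
"""

from __future__ import annotations

import numpy as np

from .maps import DEFAULT_R2_THRESHOLD, ParametricMap
from .protocol import AcquisitionProtocol
from .volume import ImageVolume

T1_MIN_FACTOR = 1e-3  # lower bound as a fraction of min(TR)
T1_MAX_FACTOR = 20.0 / 6.0  # upper bound ≈ 20 s for a 6 s max TR
MAX_ITER = 200
XTOL = 1e-12


def _t1_bounds(tr: np.ndarray) -> tuple[float, float]:
    return (T1_MIN_FACTOR * tr.min(), T1_MAX_FACTOR * tr.max())


def _profiled_grid_seed(signals: np.ndarray, tr: np.ndarray, n_grid: int = 96) -> np.ndarray:
    """Best T1 per voxel on a log grid, with S0 profiled out.

    For fixed T1 the model is linear in S0: the optimal S0 is
    (s·f)/(f·f) with f = 1 − exp(−TR/T1), and the residual sum of
    squares is ||s||² − (s·f)²/(f·f); maximizing (s·f)²/(f·f) over the
    grid therefore minimizes the RSS.
    """
    lo, hi = _t1_bounds(tr)
    grid = np.geomspace(lo, hi, n_grid)
    f = 1.0 - np.exp(-tr[None, :] / grid[:, None])  # (grid, nTR)
    ff = np.einsum("gt,gt->g", f, f)
    sf = signals @ f.T  # (vox, grid)
    score = sf**2 / ff
    return grid[np.argmax(score, axis=1)]


def _gauss_newton(signals: np.ndarray, tr: np.ndarray, t1_0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Gauss–Newton on (S0, T1), vectorized over voxels.

    Maintains an active set: voxels whose relative parameter change
    drops below XTOL (or whose line search can no longer descend — a
    local minimum to working precision) leave the iteration. Returns
    (s0, t1, converged).
    """
    t1 = t1_0.astype(float).copy()
    lo, hi = _t1_bounds(tr)

    f0 = 1.0 - np.exp(-tr[None, :] / t1[:, None])
    ff = np.einsum("vt,vt->v", f0, f0)
    s0 = np.einsum("vt,vt->v", signals, f0) / np.maximum(ff, 1e-300)

    def rss(sig: np.ndarray, s0v: np.ndarray, t1v: np.ndarray) -> np.ndarray:
        model = s0v[:, None] * (1.0 - np.exp(-tr[None, :] / t1v[:, None]))
        return np.einsum("vt,vt->v", model - sig, model - sig)

    converged = np.zeros(t1.shape, dtype=bool)
    active = np.arange(t1.size)
    current = rss(signals, s0, t1)
    for _ in range(MAX_ITER):
        sig = signals[active]
        s0a, t1a, cura = s0[active], t1[active], current[active]
        e = np.exp(-tr[None, :] / t1a[:, None])
        f = 1.0 - e
        dfdt1 = -(tr[None, :] / t1a[:, None] ** 2) * e
        r = s0a[:, None] * f - sig
        j2 = s0a[:, None] * dfdt1
        a11 = np.einsum("vt,vt->v", f, f)
        a12 = np.einsum("vt,vt->v", f, j2)
        a22 = np.einsum("vt,vt->v", j2, j2)
        b1 = -np.einsum("vt,vt->v", f, r)
        b2 = -np.einsum("vt,vt->v", j2, r)
        det = a11 * a22 - a12**2
        ok = det > 1e-300
        ds0 = np.where(ok, (b1 * a22 - b2 * a12) / np.where(ok, det, 1.0), 0.0)
        dt1 = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), 0.0)

        step = np.ones_like(t1a)
        new_s0, new_t1 = s0a.copy(), t1a.copy()
        improved = np.zeros(t1a.shape, dtype=bool)
        for _bt in range(20):
            todo = ~improved
            if not todo.any():
                break
            cand_s0 = s0a[todo] + step[todo] * ds0[todo]
            cand_t1 = np.clip(t1a[todo] + step[todo] * dt1[todo], lo, hi)
            cand = rss(sig[todo], cand_s0, cand_t1)
            better = cand <= cura[todo] + 1e-15 * np.abs(cura[todo])
            idx = np.flatnonzero(todo)[better]
            new_s0[idx], new_t1[idx] = cand_s0[better], cand_t1[better]
            cura[idx] = cand[better]
            improved[idx] = True
            step[np.flatnonzero(todo)[~better]] /= 4.0

        rel = np.maximum(
            np.abs(new_t1 - t1a) / np.maximum(np.abs(t1a), 1e-300),
            np.abs(new_s0 - s0a) / np.maximum(np.abs(s0a), 1e-300),
        )
        s0[active], t1[active], current[active] = new_s0, new_t1, cura
        # stalled line search = local minimum to working precision
        done = (rel < XTOL) | ~improved
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return s0, t1, converged


def fit_t1_signals(signals: np.ndarray, tr_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the saturation-recovery model to an (n_voxels, n_TR) signal
    array. Returns (s0, t1, r_squared, fit_ok).

    Voxels whose fit fails (all-zero signal, degenerate/constant
    signal, or an estimate pinned at a T1 bound) get NaN parameters or
    fit_ok = False and r_squared = −inf where R² is undefined.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    tr = np.asarray(tr_ms, dtype=float)
    if signals.shape[1] != tr.size:
        raise ValueError(f"signal length {signals.shape[1]} != number of TRs {tr.size}")
    if tr.size < 3:
        raise ValueError("need at least 3 TR values")

    n = signals.shape[0]
    s0 = np.full(n, np.nan)
    t1 = np.full(n, np.nan)
    r2 = np.full(n, -np.inf)
    fit_ok = np.zeros(n, dtype=bool)

    ss_tot = np.einsum("vt,vt->v", signals - signals.mean(axis=1, keepdims=True),
                       signals - signals.mean(axis=1, keepdims=True))
    fittable = ss_tot > 0  # constant (incl. all-zero) signals cannot be fit
    if fittable.any():
        sub = signals[fittable]
        t1_seed = _profiled_grid_seed(sub, tr)
        s0_f, t1_f, conv = _gauss_newton(sub, tr, t1_seed)
        model = s0_f[:, None] * (1.0 - np.exp(-tr[None, :] / t1_f[:, None]))
        ss_res = np.einsum("vt,vt->v", model - sub, model - sub)
        r2_f = 1.0 - ss_res / ss_tot[fittable]
        lo, hi = _t1_bounds(tr)
        at_bound = (t1_f <= lo * (1 + 1e-9)) | (t1_f >= hi * (1 - 1e-9))
        ok = conv & ~at_bound & (s0_f > 0) & np.isfinite(t1_f)
        s0[fittable] = np.where(ok, s0_f, np.nan)
        t1[fittable] = np.where(ok, t1_f, np.nan)
        r2[fittable] = np.where(np.isfinite(r2_f), r2_f, -np.inf)
        tmp = np.zeros(int(fittable.sum()), dtype=bool)
        tmp[:] = ok
        fit_ok[fittable] = tmp
    return s0, t1, r2, fit_ok


def fit_t1_voxel(signal: np.ndarray, tr_ms: np.ndarray) -> tuple[float, float, float]:
    """Fit one voxel; returns (S0_hat, T1_hat, r_squared).

    Failed fits return NaN parameters and r_squared = −inf rather than
    raising.
    """
    s0, t1, r2, _ = fit_t1_signals(np.asarray(signal, float)[None, :], tr_ms)
    return float(s0[0]), float(t1[0]), float(r2[0])


def fit_t1_map(
    series: ImageVolume,
    protocol: AcquisitionProtocol | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> ParametricMap:
    """Voxel-by-voxel T1 map from a 4-D saturation-recovery series.

    TRs come from the protocol if given, else from the series'
    sidecar metadata. No smoothing, registration or other
    pre-processing is applied before fitting.
    """
    if series.data.ndim != 4:
        raise ValueError("saturation-recovery series must be 4-D")
    if protocol is not None:
        tr = np.asarray(protocol.tr_list_ms, dtype=float)
    elif "tr_ms" in series.frame_meta:
        tr = np.asarray(series.frame_meta["tr_ms"], dtype=float)
    else:
        raise ValueError("no TR metadata available")
    if series.n_frames != tr.size:
        raise ValueError(f"series has {series.n_frames} frames but {tr.size} TRs")

    shape = series.spatial_shape
    flat = series.data.reshape(-1, series.n_frames)
    _, t1, r2, fit_ok = fit_t1_signals(flat, tr)
    return ParametricMap(
        values=t1.reshape(shape),
        r_squared=r2.reshape(shape),
        name="T1",
        voxel_size_mm=series.voxel_size_mm,
        r2_threshold=r2_threshold,
        fit_ok=fit_ok.reshape(shape),
    )
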