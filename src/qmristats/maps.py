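"""Per-voxel parametric maps with goodness-of-fit masking."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_R2_THRESHOLD = 0.75


@dataclass
class ParametricMap:
    """One fitted quantity per voxel plus its fit quality.

    A voxel is valid iff the fit itself was admissible (converged,
    finite, not pinned at a bound — recorded in ``fit_ok``) and its R²
    exceeds ``r2_threshold`` (strict inequality). Invalid voxels keep
    their fitted value (or NaN) in ``values`` but are excluded from
    all analysis.
    """

    values: np.ndarray
    r_squared: np.ndarray
    name: str
    voxel_size_mm: tuple[float, float, float]
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    fit_ok: np.ndarray | None = None
    valid_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.fit_ok is None:
            self.fit_ok = np.isfinite(self.values)
        if not (self.values.shape == self.r_squared.shape == self.fit_ok.shape):
            raise ValueError("values, r_squared and fit_ok shapes must agree")
        self.valid_mask = self.fit_ok & np.isfinite(self.values) & (self.r_squared > self.r2_threshold)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def remasked(self, r2_threshold: float) -> "ParametricMap":
        """Same fit, different R² threshold. Raising the threshold can
        only remove voxels (monotone masking)."""
        return ParametricMap(
            self.values, self.r_squared, self.name, self.voxel_size_mm, r2_threshold, self.fit_ok
        )
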