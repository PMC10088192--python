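"""Acquisition protocol and image geometry.

The default protocol mirrors a 7 T rodent hunger-imaging session: a
variable-TR saturation-recovery series for T1 mapping (seven TRs from
150 to 6000 ms) and a single-shot DWI series with one b=0 frame plus
six non-coplanar, non-collinear gradient directions acquired at
b = 200 and b = 1000 s/mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_TR_LIST_MS = (150.0, 200.0, 400.0, 800.0, 1600.0, 3500.0, 6000.0)
DEFAULT_B_VALUES = (0.0, 200.0, 1000.0)

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def icosahedral_directions() -> np.ndarray:
    """Six unit vectors through non-antipodal icosahedron vertices.

    A classic minimal DTI scheme: no two directions are collinear and
    the set spans all of 3-space.
    """
    raw = np.array(
        [
            [1.0, _PHI, 0.0],
            [-1.0, _PHI, 0.0],
            [0.0, 1.0, _PHI],
            [0.0, -1.0, _PHI],
            [_PHI, 0.0, 1.0],
            [_PHI, 0.0, -1.0],
        ]
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


class ProtocolError(ValueError):
    """Raised when an acquisition protocol violates its preconditions."""


@dataclass(frozen=True)
class Geometry:
    """Image-grid geometry: matrix size, slices and voxel dimensions."""

    matrix: tuple[int, int] = (128, 128)
    n_slices: int = 5
    in_plane_resolution_mm: float = 0.25
    slice_thickness_mm: float = 1.5

    def __post_init__(self) -> None:
        if min(self.matrix) < 1 or self.n_slices < 1:
            raise ValueError("matrix size and slice count must be positive")
        if self.in_plane_resolution_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.matrix[0], self.matrix[1], self.n_slices)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        r = self.in_plane_resolution_mm
        return (r, r, self.slice_thickness_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_resolution_mm**2 * self.slice_thickness_mm


def validate_directions(directions: np.ndarray) -> None:
    """Check a gradient-direction set: unit norm, >= 6 vectors, no two
    collinear (|g_i . g_j| < 1 - 1e-9) and not all coplanar (rank 3).

    Raises ProtocolError naming the violated condition.
    """
    g = np.asarray(directions, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ProtocolError("directions must be an (n, 3) array")
    if g.shape[0] < 6:
        raise ProtocolError(f"need at least 6 directions, got {g.shape[0]}")
    norms = np.linalg.norm(g, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ProtocolError("directions must be unit vectors")
    dots = np.abs(g @ g.T)
    np.fill_diagonal(dots, 0.0)
    if np.any(dots >= 1.0 - 1e-9):
        i, j = np.unravel_index(np.argmax(dots), dots.shape)
        raise ProtocolError(f"directions {i} and {j} are collinear")
    if np.linalg.matrix_rank(g, tol=1e-9) < 3:
        raise ProtocolError("directions are coplanar (rank < 3)")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One study's acquisition parameters.

    ``delta_ms`` (gradient duration) and ``Delta_ms`` (gradient
    separation) are carried as metadata only; b-values are taken as
    given in s/mm² and never recomputed from them.
    """

    tr_list_ms: tuple[float, ...] = DEFAULT_TR_LIST_MS
    te_ms: float = 12.6
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    directions: np.ndarray = field(default_factory=icosahedral_directions)
    Delta_ms: float = 20.0
    delta_ms: float = 4.0
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        trs = np.asarray(self.tr_list_ms, dtype=float)
        if trs.size < 3:
            raise ProtocolError("need at least 3 TR values")
        if np.any(trs <= 0) or np.any(np.diff(trs) <= 0):
            raise ProtocolError("TR list must be strictly increasing and positive")
        bvals = np.asarray(self.b_values, dtype=float)
        if np.any(bvals < 0):
            raise ProtocolError("b-values must be nonnegative")
        validate_directions(self.directions)
        object.__setattr__(self, "directions", np.asarray(self.directions, float))

    @property
    def nonzero_b_values(self) -> tuple[float, ...]:
        return tuple(b for b in self.b_values if b > 0)

    def dwi_scheme(self) -> tuple[np.ndarray, np.ndarray]:
        """Expanded per-frame (bvals, bvecs) for the DWI series.

        One b=0 frame (zero vector by convention), then every nonzero
        b paired with every direction.
        """
        bvals = [0.0]
        bvecs = [np.zeros(3)]
        for b in self.nonzero_b_values:
            for g in self.directions:
                bvals.append(float(b))
                bvecs.append(np.asarray(g, float))
        return np.array(bvals), np.array(bvecs)

    @property
    def n_t1_frames(self) -> int:
        return len(self.tr_list_ms)

    @property
    def n_dwi_frames(self) -> int:
        n_b0 = sum(1 for b in self.b_values if b == 0)
        return n_b0 + len(self.nonzero_b_values) * len(self.directions)
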