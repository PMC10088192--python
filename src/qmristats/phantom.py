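"""Digital rat-brain phantom: region-labelled ground-truth studies.

The generator builds four-cohort studies (state control/tumor ×
condition fed/fasted) with per-animal, per-region true T1 and diffusion
tensor fields, so every downstream stage — signal simulation, voxel-wise
fitting, ROI extraction, clustered inference — can be verified by
parameter recovery instead of animal data.

Regions are four axis-aligned rectangular blocks of 20–22 in-plane
pixels (cortex, hippocampus, hypothalamus, thalamus) on one designated
central slice, placed in the left hemisphere: the study convention puts
ROIs contralateral to the tumor in tumor-bearing animals and in the
left hemisphere of controls, and the phantom's tumor side defaults to
the right hemisphere.

Absolute baseline values are package presets (plausible 7 T rodent
gray matter); only the *directions* of the group effects are bound to
the findings being emulated:

* fed tumor-bearing animals have lower T1 than fed controls in cortex
  and thalamus (higher activity-dependent Mn²⁺ uptake);
* fasting lowers MD in healthy controls (cortex, hippocampus,
  thalamus) but not in tumor-bearing animals;
* FA is lower in tumor-bearing animals than controls in cortex,
  hippocampus and thalamus under both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import Geometry

STATES = ("control", "tumor")
CONDITIONS = ("fed", "fasted")
REGIONS = ("cortex", "hippocampus", "hypothalamus", "thalamus")
REGION_LABELS = {"cortex": 1, "hippocampus": 2, "hypothalamus": 3, "thalamus": 4}
PARAMETERS = ("T1", "MD", "FA")


class PhantomError(ValueError):
    pass


def axially_symmetric_eigenvalues(md: float, fa: float) -> tuple[float, float, float]:
    """Eigenvalues (λ1, λ2, λ3) of a prolate tensor with given MD and FA.

    For λ1 = MD(1 + 2f), λ2 = λ3 = MD(1 - f) the fractional anisotropy
    is 3f / sqrt(3 + 6f²); inverting gives f = FA / sqrt(3 - 2 FA²).
    A nonnegative triple exists for any MD > 0 and FA in [0, 1).
    """
    if md <= 0:
        raise PhantomError(f"MD must be positive, got {md}")
    if not 0 <= fa < 1:
        raise PhantomError(f"no nonnegative eigenvalue triple for FA={fa}")
    f = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    lam1 = md * (1.0 + 2.0 * f)
    lam23 = md * (1.0 - f)
    return (lam1, lam23, lam23)


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose first column is ``direction``."""
    e1 = np.asarray(direction, float)
    e1 = e1 / np.linalg.norm(e1)
    helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def tensor_from_md_fa(md: float, fa: float, direction: np.ndarray) -> np.ndarray:
    """Axially symmetric 3×3 diffusion tensor with exact MD and FA,
    principal eigenvector along ``direction``."""
    lam = axially_symmetric_eigenvalues(md, fa)
    r = _rotation_to(direction)
    return r @ np.diag(lam) @ r.T


@dataclass(frozen=True)
class RegionSpec:
    """One rectangular ROI block on the designated slice."""

    label: int
    x0: int
    y0: int
    nx: int
    ny: int
    principal_direction: tuple[float, float, float]

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to draw one synthetic four-cohort study."""

    geometry: Geometry = field(default_factory=Geometry)
    regions: dict[str, RegionSpec] = field(default_factory=dict)
    central_slice: int = 2
    tumor_side: str = "right"  # ROIs go on the opposite (left) hemisphere
    animals_per_group: dict[tuple[str, str], int] = field(default_factory=dict)
    # means[param][region][(state, condition)] -> value
    means: dict[str, dict[str, dict[tuple[str, str], float]]] = field(default_factory=dict)
    between_animal_sd: dict[str, float] = field(default_factory=dict)
    voxel_cv: dict[str, float] = field(default_factory=dict)
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.central_slice < self.geometry.n_slices:
            raise PhantomError("central slice outside the volume")
        seen: set[tuple[int, int]] = set()
        for name, reg in self.regions.items():
            if reg.x0 < 0 or reg.y0 < 0:
                raise PhantomError(f"region {name} has negative origin")
            if reg.x0 + reg.nx > self.geometry.matrix[0] or reg.y0 + reg.ny > self.geometry.matrix[1]:
                raise PhantomError(f"region {name} exceeds the image matrix")
            pix = {(x, y) for x in range(reg.x0, reg.x0 + reg.nx) for y in range(reg.y0, reg.y0 + reg.ny)}
            if seen & pix:
                raise PhantomError(f"region {name} overlaps another region")
            seen |= pix
        for param, per_region in self.means.items():
            for region, cells in per_region.items():
                for cell, v in cells.items():
                    if param in ("T1", "MD") and v <= 0:
                        raise PhantomError(f"{param} mean must be positive ({region}, {cell})")
                    if param == "FA" and not 0 <= v < 1:
                        raise PhantomError(f"FA mean must be in [0, 1) ({region}, {cell})")

    def label_volume(self) -> np.ndarray:
        """Integer label array (0 = background) over the full geometry."""
        vol = np.zeros(self.geometry.shape, dtype=np.int16)
        for reg in self.regions.values():
            vol[reg.x0 : reg.x0 + reg.nx, reg.y0 : reg.y0 + reg.ny, self.central_slice] = reg.label
        return vol

    def group_sizes(self) -> dict[tuple[str, str], int]:
        return dict(self.animals_per_group)


def _default_means() -> dict[str, dict[str, dict[tuple[str, str], float]]]:
    t1_base = {"cortex": 1500.0, "hippocampus": 1550.0, "hypothalamus": 1450.0, "thalamus": 1400.0}
    md_base = {"cortex": 0.75e-3, "hippocampus": 0.80e-3, "hypothalamus": 0.78e-3, "thalamus": 0.72e-3}
    fa_base = {"cortex": 0.15, "hippocampus": 0.17, "hypothalamus": 0.16, "thalamus": 0.20}

    means: dict[str, dict[str, dict[tuple[str, str], float]]] = {"T1": {}, "MD": {}, "FA": {}}
    for region in REGIONS:
        t1 = {cell: t1_base[region] for cell in _cells()}
        # Mn-enhanced study: fed tumor-bearing animals show lower T1
        # (greater Mn uptake) in cortex and thalamus only.
        if region in ("cortex", "thalamus"):
            t1[("tumor", "fed")] = t1_base[region] - 150.0
        means["T1"][region] = t1

        md = {cell: md_base[region] for cell in _cells()}
        # Fasting decreases MD ~6% in controls (activity-related cell
        # swelling) in cortex, hippocampus and thalamus; tumor-bearing
        # animals lose this response.
        if region in ("cortex", "hippocampus", "thalamus"):
            md[("control", "fasted")] = md_base[region] * 0.94
        means["MD"][region] = md

        fa = {cell: fa_base[region] for cell in _cells()}
        # Tumor infiltration lowers FA in cortex, hippocampus and
        # thalamus under both feeding conditions.
        if region in ("cortex", "hippocampus", "thalamus"):
            for cond in CONDITIONS:
                fa[("tumor", cond)] = fa_base[region] - 0.05
        means["FA"][region] = fa
    return means


def _cells() -> list[tuple[str, str]]:
    return [(s, c) for s in STATES for c in CONDITIONS]


def default_study_spec(
    geometry: Geometry | None = None,
    animals_per_group: dict[tuple[str, str], int] | None = None,
) -> PhantomSpec:
    """The preset four-cohort study specification.

    Geometry defaults to the acquisition grid (128×128, 5 slices,
    0.25 mm in-plane, 1.5 mm slices); cohort sizes default to
    6/6/6/7 (control-fed / control-fasted / tumor-fed / tumor-fasted).
    Pass a smaller :class:`Geometry` to run reduced-size studies; the
    four ROI blocks are placed relative to the matrix size.
    """
    geometry = geometry or Geometry()
    nx, ny = geometry.matrix
    if nx < 16 or ny < 16:
        raise PhantomError("matrix too small to place four 20-22 px regions")
    # Left hemisphere = x < nx // 2; blocks tiled with 1-px gaps.
    x = 1
    regions = {
        "cortex": RegionSpec(1, x, 1, 3, 7, (1.0, 0.0, 0.0)),
        "hippocampus": RegionSpec(2, x + 4, 1, 3, 7, (0.0, 1.0, 0.0)),
        "hypothalamus": RegionSpec(3, x, 9, 4, 5, (0.0, 0.0, 1.0)),
        "thalamus": RegionSpec(4, x + 5, 9, 2, 11, (1.0, 1.0, 0.0)),
    }
    assert all(20 <= r.n_pixels <= 22 for r in regions.values())
    central = geometry.n_slices // 2
    return PhantomSpec(
        geometry=geometry,
        regions=regions,
        central_slice=central,
        animals_per_group=animals_per_group
        or {("control", "fed"): 6, ("control", "fasted"): 6, ("tumor", "fed"): 6, ("tumor", "fasted"): 7},
        means=_default_means(),
        between_animal_sd={"T1": 50.0, "MD": 0.022e-3, "FA": 0.015},
        voxel_cv={"T1": 0.03, "MD": 0.05, "FA": 0.08},
    )


@dataclass
class AnimalTruth:
    """Ground truth for one simulated animal."""

    animal_id: str
    state: str
    condition: str
    t1_ms: np.ndarray  # (x, y, z)
    tensor: np.ndarray  # (x, y, z, 3, 3), mm²/s
    s0: np.ndarray  # (x, y, z)
    region_means: pd.DataFrame  # per-region drawn animal means (long format)


def make_study(spec: PhantomSpec, seed: int) -> list[AnimalTruth]:
    """Draw a full synthetic study: per-animal region means around the
    group means (between-animal SD), then per-voxel values around the
    animal mean (voxel-level CV). Deterministic for a fixed seed; each
    animal consumes an independent substream of the root seed.
    """
    root = np.random.SeedSequence(seed)
    n_animals = sum(spec.animals_per_group.values())
    child_seeds = root.spawn(n_animals)
    animals: list[AnimalTruth] = []
    k = 0
    for (state, condition), n in sorted(spec.animals_per_group.items()):
        for i in range(n):
            aid = f"{state[:4]}-{condition[:4]}-{i + 1:02d}"
            animals.append(_make_animal(spec, aid, state, condition, child_seeds[k]))
            k += 1
    return animals


def _make_animal(
    spec: PhantomSpec, animal_id: str, state: str, condition: str, seed: np.random.SeedSequence
) -> AnimalTruth:
    rng = np.random.default_rng(seed)
    shape = spec.geometry.shape
    t1 = np.full(shape, 1200.0)
    s0 = np.zeros(shape)
    tensor = np.zeros(shape + (3, 3))
    # background: isotropic tensor, zero signal amplitude
    tensor[..., 0, 0] = tensor[..., 1, 1] = tensor[..., 2, 2] = 1.0e-3

    rows = []
    for region, reg in spec.regions.items():
        cell = (state, condition)
        animal_mean = {
            p: spec.means[p][region][cell] + spec.between_animal_sd.get(p, 0.0) * rng.standard_normal()
            for p in PARAMETERS
        }
        animal_mean["T1"] = max(animal_mean["T1"], 1.0)
        animal_mean["MD"] = max(animal_mean["MD"], 1e-6)
        animal_mean["FA"] = float(np.clip(animal_mean["FA"], 0.0, 0.95))
        rows.append({"animal_id": animal_id, "state": state, "condition": condition, "region": region, **animal_mean})

        sl = (slice(reg.x0, reg.x0 + reg.nx), slice(reg.y0, reg.y0 + reg.ny), spec.central_slice)
        npix = reg.n_pixels
        vox_t1 = animal_mean["T1"] * (1.0 + spec.voxel_cv.get("T1", 0.0) * rng.standard_normal(npix))
        vox_md = animal_mean["MD"] * (1.0 + spec.voxel_cv.get("MD", 0.0) * rng.standard_normal(npix))
        vox_fa = animal_mean["FA"] * (1.0 + spec.voxel_cv.get("FA", 0.0) * rng.standard_normal(npix))
        vox_t1 = np.clip(vox_t1, 1.0, None)
        vox_md = np.clip(vox_md, 1e-6, None)
        vox_fa = np.clip(vox_fa, 0.0, 0.95)

        t1[sl] = vox_t1.reshape(reg.nx, reg.ny)
        s0[sl] = spec.s0
        direction = np.asarray(reg.principal_direction, float)
        tensors = np.array([tensor_from_md_fa(m, f, direction) for m, f in zip(vox_md, vox_fa)])
        tensor[sl] = tensors.reshape(reg.nx, reg.ny, 3, 3)

    return AnimalTruth(
        animal_id=animal_id,
        state=state,
        condition=condition,
        t1_ms=t1,
        tensor=tensor,
        s0=s0,
        region_means=pd.DataFrame(rows),
    )


def study_design_table(animals: list[AnimalTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"animal_id": a.animal_id, "state": a.state, "condition": a.condition} for a in animals]
    )


def write_truth_maps(truth: AnimalTruth, spec: PhantomSpec, directory) -> list:
    """Write one NIfTI per ground-truth parameter (T1, MD, FA, S0) for
    one animal. MD and FA are derived from the true tensor field."""
    from pathlib import Path

    from .volume import ImageVolume, write_volume

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lam = np.linalg.eigvalsh(truth.tensor)
    md = lam.mean(axis=-1)
    mean = md[..., None]
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    fa = np.where(den > 0, np.sqrt(1.5) * num / np.maximum(den, 1e-300), 0.0)
    vox = spec.geometry.voxel_size_mm
    written = []
    for name, arr in (("t1", truth.t1_ms), ("md", md), ("fa", fa), ("s0", truth.s0)):
        written += write_volume(ImageVolume(arr, vox), directory / f"{truth.animal_id}_truth_{name}.nii")
    return written


def _means_to_flat(means: dict) -> dict:
    return {
        p: {r: {f"{s},{c}": v for (s, c), v in cells.items()} for r, cells in per.items()}
        for p, per in means.items()
    }


def _means_from_flat(flat: dict) -> dict:
    return {
        p: {r: {tuple(k.split(",")): v for k, v in cells.items()} for r, cells in per.items()}
        for p, per in flat.items()
    }


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a phantom specification (YAML/JSON-safe)."""
    return {
        "geometry": {
            "matrix": list(spec.geometry.matrix),
            "n_slices": spec.geometry.n_slices,
            "in_plane_resolution_mm": spec.geometry.in_plane_resolution_mm,
            "slice_thickness_mm": spec.geometry.slice_thickness_mm,
        },
        "regions": {
            name: {
                "label": r.label,
                "x0": r.x0,
                "y0": r.y0,
                "nx": r.nx,
                "ny": r.ny,
                "principal_direction": list(r.principal_direction),
            }
            for name, r in spec.regions.items()
        },
        "central_slice": spec.central_slice,
        "tumor_side": spec.tumor_side,
        "animals_per_group": {f"{s},{c}": n for (s, c), n in spec.animals_per_group.items()},
        "means": _means_to_flat(spec.means),
        "between_animal_sd": dict(spec.between_animal_sd),
        "voxel_cv": dict(spec.voxel_cv),
        "s0": spec.s0,
    }


def spec_from_dict(data: dict) -> PhantomSpec:
    """Inverse of :func:`spec_to_dict`; unknown keys are rejected."""
    known = {
        "geometry",
        "regions",
        "central_slice",
        "tumor_side",
        "animals_per_group",
        "means",
        "between_animal_sd",
        "voxel_cv",
        "s0",
    }
    unknown = set(data) - known
    if unknown:
        raise PhantomError(f"unknown phantom-spec keys: {sorted(unknown)}")
    g = data["geometry"]
    geometry = Geometry(
        matrix=tuple(g["matrix"]),
        n_slices=g["n_slices"],
        in_plane_resolution_mm=g["in_plane_resolution_mm"],
        slice_thickness_mm=g["slice_thickness_mm"],
    )
    regions = {
        name: RegionSpec(
            label=r["label"],
            x0=r["x0"],
            y0=r["y0"],
            nx=r["nx"],
            ny=r["ny"],
            principal_direction=tuple(r["principal_direction"]),
        )
        for name, r in data["regions"].items()
    }
    return PhantomSpec(
        geometry=geometry,
        regions=regions,
        central_slice=data["central_slice"],
        tumor_side=data["tumor_side"],
        animals_per_group={tuple(k.split(",")): int(n) for k, n in data["animals_per_group"].items()},
        means=_means_from_flat(data["means"]),
        between_animal_sd=dict(data["between_animal_sd"]),
        voxel_cv=dict(data["voxel_cv"]),
        s0=data["s0"],
    )


def simulate_observation_table(
    spec: PhantomSpec,
    parameter: str,
    seed: int,
    residual_sd: float,
    pixels_per_region: int = 21,
    intercept_sd: float | None = None,
) -> pd.DataFrame:
    """Pixel-level observation table drawn directly from the phantom's
    hierarchy, bypassing the imaging stages.

    Each animal gets one random intercept (SD ``intercept_sd``,
    default the spec's between-animal SD for ``parameter``) shared by
    all its regions, and each pixel adds independent Gaussian residual
    noise — so within-animal correlation comes solely from the shared
    animal effect. Used for statistical calibration where the quantity
    of interest is the inference procedure itself, not the fitting
    pipeline.
    """
    rng = np.random.default_rng(seed)
    if intercept_sd is None:
        intercept_sd = spec.between_animal_sd.get(parameter, 0.0)
    rows = []
    for (state, condition), n in sorted(spec.animals_per_group.items()):
        for i in range(n):
            aid = f"{state[:4]}-{condition[:4]}-{i + 1:02d}"
            intercept = intercept_sd * rng.standard_normal()
            for region in spec.regions:
                mu = spec.means[parameter][region][(state, condition)]
                values = mu + intercept + residual_sd * rng.standard_normal(pixels_per_region)
                for j, v in enumerate(values):
                    rows.append(
                        {
                            "value": v,
                            "parameter": parameter,
                            "animal_id": aid,
                            "state": state,
                            "condition": condition,
                            "region": region,
                            "voxel_index": j,
                        }
                    )
    return pd.DataFrame(rows)


def null_spec(spec: PhantomSpec, parameter: str) -> PhantomSpec:
    """Copy of ``spec`` with all state/condition effects on
    ``parameter`` removed: every cell of a region takes that region's
    (control, fed) mean. Region differences remain; used for
    type-I-error studies of group-effect tests."""
    means = {p: {r: dict(cells) for r, cells in per.items()} for p, per in spec.means.items()}
    for region, cells in means[parameter].items():
        base = cells[("control", "fed")]
        means[parameter][region] = {cell: base for cell in _cells()}
    return replace(spec, means=means)
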