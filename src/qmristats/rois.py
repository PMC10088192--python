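"""ROI definition, per-pixel value extraction and group summaries.

Four hunger-related regions (cortex, hippocampus, hypothalamus,
thalamus) are carried as an integer label volume on one designated
central slice. Observations are individual pixels, not ROI means:
every valid-mask pixel of every ROI contributes one row per parameter
to the long-format table that feeds inference.

ROI placement follows the contralateral convention: regions sit on the
hemisphere opposite the tumor in tumor-bearing animals and on the left
hemisphere in controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import ParametricMap
from .phantom import REGION_LABELS, PhantomSpec

DEFAULT_PIXEL_WINDOW = (20, 22)

OBSERVATION_COLUMNS = ["value", "parameter", "animal_id", "state", "condition", "region", "voxel_index"]


class ROIError(ValueError):
    pass


@dataclass
class ROISet:
    """Integer label volume (0 = background) plus label dictionary."""

    labels: np.ndarray
    label_names: dict[int, str] = field(default_factory=lambda: {v: k for k, v in REGION_LABELS.items()})
    slice_index: int = 0
    side: str = "left"
    pixel_window: tuple[int, int] = DEFAULT_PIXEL_WINDOW

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_names)
        if unknown:
            raise ROIError(f"labels {sorted(unknown)} missing from the label dictionary")
        for lab, name in self.label_names.items():
            n = int((self.labels == lab).sum())
            if n == 0:
                raise ROIError(f"region {name} (label {lab}) is empty")
            lo, hi = self.pixel_window
            if not lo <= n <= hi:
                warnings.warn(
                    f"region {name} has {n} pixels, outside the usual [{lo}, {hi}] window",
                    stacklevel=2,
                )

    @classmethod
    def from_phantom(cls, spec: PhantomSpec) -> "ROISet":
        names = {reg.label: name for name, reg in spec.regions.items()}
        side = "left" if spec.tumor_side == "right" else "right"
        return cls(spec.label_volume(), names, slice_index=spec.central_slice, side=side)

    def region_voxels(self, name: str) -> np.ndarray:
        label = {v: k for k, v in self.label_names.items()}[name]
        return np.flatnonzero(self.labels.ravel() == label)


def roi_volume(pixel_count: int, in_plane_resolution_mm: float, slice_thickness_mm: float) -> float:
    """Physical ROI volume in mm³ for single-slice ROIs."""
    if pixel_count <= 0:
        raise ValueError("pixel count must be positive")
    return pixel_count * in_plane_resolution_mm**2 * slice_thickness_mm


def expected_roi_side(state: str, tumor_side: str = "right") -> str:
    """Hemisphere an ROI should occupy: contralateral to the tumor for
    tumor-bearing animals, left for controls."""
    if state == "control":
        return "left"
    return "left" if tumor_side == "right" else "right"


def extract_observations(
    maps: dict[str, ParametricMap] | list[ParametricMap],
    rois: ROISet,
    animal_id: str,
    state: str,
    condition: str,
    tumor_side: str = "right",
) -> tuple[pd.DataFrame, dict]:
    """One row per valid voxel per parameter for one animal.

    Returns (table, log) where ``log`` counts extracted and dropped
    (invalid-mask) voxels per region and parameter. Regions left empty
    after masking are omitted with a warning.
    """
    if isinstance(maps, list):
        maps = {m.name: m for m in maps}
    exp = expected_roi_side(state, tumor_side)
    if rois.side != exp:
        warnings.warn(
            f"ROIs for {state} animal {animal_id} are on the {rois.side} hemisphere "
            f"but the contralateral convention expects {exp}",
            stacklevel=2,
        )
    rows = []
    log: dict = {"animal_id": animal_id, "regions": {}}
    for name in rois.label_names.values():
        idx = rois.region_voxels(name)
        reg_log = {}
        for pname, pmap in maps.items():
            if pmap.values.shape != rois.labels.shape:
                raise ROIError(
                    f"map {pname} shape {pmap.values.shape} does not match "
                    f"label volume shape {rois.labels.shape}"
                )
            valid = pmap.valid_mask.ravel()[idx]
            kept = idx[valid]
            reg_log[pname] = {"kept": int(valid.sum()), "dropped": int((~valid).sum())}
            if kept.size == 0:
                warnings.warn(
                    f"region {name} of animal {animal_id} has no valid {pname} voxels; omitted",
                    stacklevel=2,
                )
                continue
            vals = pmap.values.ravel()[kept]
            rows.extend(
                {
                    "value": float(v),
                    "parameter": pname,
                    "animal_id": animal_id,
                    "state": state,
                    "condition": condition,
                    "region": name,
                    "voxel_index": int(i),
                }
                for v, i in zip(vals, kept)
            )
        log["regions"][name] = reg_log
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS), log


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per parameter × region × state × condition mean ± SD.

    SD uses the n−1 denominator; single-observation groups report
    SD = 0 with ``n_is_1`` flagged.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty observation table")
    g = table.groupby(["parameter", "region", "state", "condition"], sort=True)["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["n_is_1"] = out["n"] == 1
    out.loc[out["n_is_1"], "sd"] = 0.0
    return out
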