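"""Study configuration: YAML round-trip with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Everything a full synthetic-study pipeline run needs.

    ``matrix`` / ``n_slices`` override the phantom geometry (the
    acquisition default is 128×128 × 5 slices); ``snr`` is S0/σ of the
    Rician noise at full signal; ``animals_per_group`` maps
    "state,condition" keys to cohort sizes.
    """

    output_dir: str = "study_output"
    seed: int = 0
    matrix: tuple[int, int] = (128, 128)
    n_slices: int = 5
    in_plane_resolution_mm: float = 0.25
    slice_thickness_mm: float = 1.5
    snr: float = 50.0
    r2_threshold: float = 0.75
    working_correlation: str = "exchangeable"
    animals_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "control,fed": 6,
            "control,fasted": 6,
            "tumor,fed": 6,
            "tumor,fasted": 7,
        }
    )
    write_nifti: bool = True

    def group_sizes(self) -> dict[tuple[str, str], int]:
        out = {}
        for key, n in self.animals_per_group.items():
            state, condition = (part.strip() for part in key.split(","))
            out[(state, condition)] = int(n)
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["matrix"] = list(self.matrix)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        if "matrix" in data:
            data["matrix"] = tuple(data["matrix"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        return cls.from_dict(data)
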