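"""Run configuration: one serializable object drives every experiment."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Scan and simulation parameters for the experiment grid.

    Defaults reproduce the modelled scanner's body protocol: 120 kVp, large
    bowtie filter, 23 mm axial beam, 36 projections per rotation, ODM with a
    180-degree anterior arc and 40% current reduction, and the scanner's
    10-500 mA AEC limits.
    """

    kvp: float = 120.0
    anode_angle_deg: float = 7.0
    filter_label: str = "large"
    sid_mm: float = 541.0
    z_width_mm: float = 23.0
    n_angles: int = 36
    # modulation
    odm_arc_deg: float = 180.0
    odm_reduction: float = 0.4
    compensate_posterior: bool = False
    matched_factor: float = 1.25  # 1/0.8 CTDIvol-matching rescale
    base_ma: float = 200.0
    min_ma: float = 10.0
    max_ma: float = 500.0
    region_boundaries_cm: tuple[float, float] = (20.0, 40.0)
    # bowtie decomposition
    n_subfields: int = 10
    bowtie_noise_sd: float = 0.01
    # phantoms
    ctdi_voxel_mm: float = 2.0
    ctdi_length_mm: float = 150.0
    torso_voxel_mm: float = 10.0
    torso_height_cm: float = 178.6
    torso_mass_kg: float = 73.2
    # photon budgets (per projection)
    ctdi_photons: int = 100_000
    torso_photons: int = 20_000
    # bookkeeping
    seed: int = 1
    output_dir: str = "results"

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "region_boundaries_cm" in data:
            data = dict(data, region_boundaries_cm=tuple(data["region_boundaries_cm"]))
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
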