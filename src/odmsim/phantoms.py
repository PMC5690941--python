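"""Voxel phantoms: the 32 cm CTDI cylinder and a simplified labelled torso.

Coordinate convention (right-handed, all mm): x = patient left, y = anterior,
z = caudo-cranial, isocenter on the phantom axis.  Voxel grids are half-open
and 0-based; ``origin`` is the position of the grid corner (voxel [0,0,0]'s
low corner).

The torso is a deliberately simple stand-in for an anthropomorphic phantom: a
uniform elliptical soft-tissue cylinder, 70 cm long, with lungs, a posterior
spine, rib and pelvic bone shells, and thirteen labelled organ compartments
placed as literature-typical primitives.  It preserves the feature that
drives organ-dose-modulation results — most radiosensitive organs sit
anteriorly while the active bone marrow sits posteriorly — without claiming
anatomical fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attenuation import MATERIALS

TORSO_LENGTH_MM = 700.0
#: pelvis/abdomen and abdomen/chest boundaries along z (mm from torso base)
DEFAULT_REGION_BOUNDARIES_MM = (200.0, 400.0)
#: torso share of whole-body mass used to target the phantom mass
DEFAULT_TRUNK_FRACTION = 0.52

ORGAN_IDS = {
    "lungs": 1,
    "breasts": 2,
    "oesophagus": 3,
    "thyroid": 4,
    "stomach": 5,
    "liver": 6,
    "colon": 7,
    "urinary_bladder": 8,
    "ovaries": 9,
    "testicles": 10,
    "active_bone_marrow": 11,
    "skin": 12,
    "remainder": 13,
}
ORGAN_NAMES = {v: k for k, v in ORGAN_IDS.items()}


@dataclass
class VoxelPhantom:
    """Material + organ label grid with per-material densities."""

    voxel_mm: np.ndarray  # (3,) voxel size per axis
    material_grid: np.ndarray  # int8 (nx, ny, nz), index into material_names
    organ_grid: np.ndarray  # int16, 0 = unlabelled
    material_names: list[str]
    densities: np.ndarray  # g/cm^3 per material
    origin_mm: np.ndarray  # (3,) grid corner relative to isocenter
    organ_names: dict[int, str] = field(default_factory=dict)
    air_index: int = 0
    #: organ id -> material index whose energy-transfer coefficient (and
    #: density) is used when tallying that organ's dose, regardless of the
    #: voxel material.  Used for active bone marrow: a soft tissue residing
    #: in the bone compartment, whose dose is the bone-voxel photon fluence
    #: times the *tissue* mass-energy-transfer coefficient (scoring mineral
    #: bone kerma would overestimate it severalfold at CT energies).
    tally_material: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.material_grid.shape != self.organ_grid.shape:
            raise ValueError("material and organ grids must be congruent")
        if np.any(self.densities <= 0):
            raise ValueError("densities must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.material_grid.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_mm)) / 1000.0

    def voxel_mass_g(self) -> np.ndarray:
        """Mass per material index for one voxel (g)."""
        return self.densities * self.voxel_volume_cm3

    def organ_mask(self, organ: int | str) -> np.ndarray:
        if isinstance(organ, str):
            by_name = {v: k for k, v in self.organ_names.items()}
            oid = by_name[organ]
        else:
            oid = organ
        return self.organ_grid == oid

    def organ_mass_g(self, organ: int | str) -> float:
        mask = self.organ_mask(organ)
        return float(self.voxel_mass_g()[self.material_grid[mask]].sum())

    def total_mass_g(self) -> float:
        m = self.voxel_mass_g()[self.material_grid]
        return float(m[self.material_grid != self.air_index].sum())

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        cx = self.origin_mm[0] + (np.arange(nx) + 0.5) * self.voxel_mm[0]
        cy = self.origin_mm[1] + (np.arange(ny) + 0.5) * self.voxel_mm[1]
        cz = self.origin_mm[2] + (np.arange(nz) + 0.5) * self.voxel_mm[2]
        return cx, cy, cz

    def save(self, path: str | Path) -> None:
        """Binary array container (.npz) plus a JSON sidecar with labels."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            material_grid=self.material_grid,
            organ_grid=self.organ_grid,
        )
        sidecar = {
            "voxel_mm": self.voxel_mm.tolist(),
            "origin_mm": self.origin_mm.tolist(),
            "material_names": self.material_names,
            "densities": self.densities.tolist(),
            "organ_names": {str(k): v for k, v in self.organ_names.items()},
            "air_index": self.air_index,
            "tally_material": {str(k): v for k, v in self.tally_material.items()},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelPhantom":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            voxel_mm=np.array(meta["voxel_mm"]),
            material_grid=arrays["material_grid"],
            organ_grid=arrays["organ_grid"],
            material_names=meta["material_names"],
            densities=np.array(meta["densities"]),
            origin_mm=np.array(meta["origin_mm"]),
            organ_names={int(k): v for k, v in meta["organ_names"].items()},
            air_index=meta["air_index"],
            tally_material={int(k): v for k, v in meta.get("tally_material", {}).items()},
        )


@dataclass(frozen=True)
class CTDIPhantomSpec:
    """The standard 32 cm body CTDI phantom with chamber holes.

    Eight 1.5 cm holes at 45-degree spacing on each of two rings (radii 15 cm
    and 7 cm, starting at the anterior position) plus one central hole.
    """

    diameter_mm: float = 320.0
    hole_diameter_mm: float = 15.0
    ring_radii_mm: tuple[float, ...] = (150.0, 70.0)
    holes_per_ring: int = 8
    center_hole: bool = True


#: compass labels for the outer ring, anterior first, clockwise seen from feet
COMPASS = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]


def ctdi_hole_positions(spec: CTDIPhantomSpec) -> dict[str, tuple[float, float]]:
    """Hole label -> (x, y) center.  N = anterior (+y), E = patient left (+x)."""
    holes: dict[str, tuple[float, float]] = {}
    for ring_i, radius in enumerate(spec.ring_radii_mm):
        prefix = "" if ring_i == 0 else "inner_"
        for k in range(spec.holes_per_ring):
            theta = np.radians(k * 360.0 / spec.holes_per_ring)
            holes[prefix + COMPASS[k]] = (radius * np.sin(theta), radius * np.cos(theta))
    if spec.center_hole:
        holes["center"] = (0.0, 0.0)
    return holes


def build_ctdi_phantom(
    spec: CTDIPhantomSpec = CTDIPhantomSpec(),
    voxel_mm: float = 2.0,
    length_mm: float = 150.0,
) -> VoxelPhantom:
    """Voxelize the PMMA CTDI cylinder; hole voxels are air tally regions."""
    if voxel_mm > 5.0:
        raise ValueError("CTDI phantom needs voxels <= 5 mm")
    holes = ctdi_hole_positions(spec)
    centers = np.array(list(holes.values()))
    if len(centers) > 1:
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < spec.hole_diameter_mm:
            raise ValueError("hole positions overlap")
    half_xy = spec.diameter_mm / 2 + 10.0
    nx = ny = int(np.ceil(2 * half_xy / voxel_mm))
    nz = int(np.ceil(length_mm / voxel_mm))
    origin = np.array([-nx * voxel_mm / 2, -ny * voxel_mm / 2, -nz * voxel_mm / 2])
    vox = np.array([voxel_mm] * 3, float)
    cx = origin[0] + (np.arange(nx) + 0.5) * voxel_mm
    cy = origin[1] + (np.arange(ny) + 0.5) * voxel_mm
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    material_names = ["air", "pmma"]
    densities = np.array([MATERIALS["air"].density, MATERIALS["pmma"].density])
    slab = np.zeros((nx, ny), dtype=np.int8)
    slab[X**2 + Y**2 <= (spec.diameter_mm / 2) ** 2] = 1
    organ_slab = np.zeros((nx, ny), dtype=np.int16)
    organ_names = {}
    r_hole = spec.hole_diameter_mm / 2
    for i, (label, (hx, hy)) in enumerate(holes.items(), start=1):
        mask = (X - hx) ** 2 + (Y - hy) ** 2 <= r_hole**2
        slab[mask] = 0  # air-filled chamber hole
        organ_slab[mask] = i
        organ_names[i] = label
    material_grid = np.repeat(slab[:, :, None], nz, axis=2)
    organ_grid = np.repeat(organ_slab[:, :, None], nz, axis=2)
    return VoxelPhantom(
        voxel_mm=vox,
        material_grid=material_grid,
        organ_grid=organ_grid,
        material_names=material_names,
        densities=densities,
        origin_mm=origin,
        organ_names=organ_names,
    )


def region_of(z_cm: float, boundaries_cm: tuple[float, float] = (20.0, 40.0)) -> str:
    """Map a torso z position (cm from the base) to pelvis/abdomen/chest."""
    if not 0.0 <= z_cm <= TORSO_LENGTH_MM / 10.0:
        raise ValueError(f"z={z_cm} cm outside the torso [0, 70] cm")
    lo, hi = boundaries_cm
    if z_cm < lo:
        return "pelvis"
    if z_cm < hi:
        return "abdomen"
    return "chest"


@dataclass(frozen=True)
class OrganModel:
    """Geometric description of one organ compartment (mm, isocenter frame)."""

    organ_id: int
    name: str
    tissue_weighting_key: str
    kind: str  # ellipsoid | cylinder_z | cylinder_x | shell_patch
    params: dict


def _default_organ_models() -> list[OrganModel]:
    E, CZ, CX, SH = "ellipsoid", "cylinder_z", "cylinder_x", "shell_patch"
    o = ORGAN_IDS
    return [
        OrganModel(o["lungs"], "lungs", "lung", E, dict(
            centers=[(-70, 0, 550), (70, 0, 550)], semi=(55, 65, 130))),
        OrganModel(o["breasts"], "breasts", "breast", SH, dict(
            s_range=(0.90, 1.01), y_min=25, x_abs=(30, 130), z_range=(480, 620))),
        OrganModel(o["oesophagus"], "oesophagus", "oesophagus", CZ, dict(
            centers=[(0, -35)], radius=10, z_range=(400, 690))),
        OrganModel(o["thyroid"], "thyroid", "thyroid", E, dict(
            centers=[(0, 45, 685)], semi=(25, 15, 15))),
        OrganModel(o["stomach"], "stomach", "stomach", E, dict(
            centers=[(50, 30, 360)], semi=(50, 40, 60))),
        OrganModel(o["liver"], "liver", "liver", E, dict(
            centers=[(-55, 15, 370)], semi=(75, 55, 75))),
        OrganModel(o["colon"], "colon", "colon", CZ, dict(
            centers=[(-80, 10), (80, 10)], radius=22, z_range=(100, 320),
            transverse=dict(y=40, z=310, radius=22, x_abs=80))),
        OrganModel(o["urinary_bladder"], "urinary_bladder", "bladder", E, dict(
            centers=[(0, 45, 80)], semi=(40, 35, 30))),
        OrganModel(o["ovaries"], "ovaries", "gonads", E, dict(
            centers=[(-40, 0, 150), (40, 0, 150)], semi=(15, 15, 15))),
        OrganModel(o["testicles"], "testicles", "gonads", E, dict(
            centers=[(-15, 25, 15), (15, 25, 15)], semi=(15, 15, 15))),
    ]


ORGAN_MODELS = _default_organ_models()

# bone structures (material only; all bone voxels feed the marrow compartment)
_SPINE = dict(center=(0, -65), radius=20)
_RIBS = dict(s_range=(0.80, 0.88), z_range=(400, 700), band_mm=20)
_PELVIS_BONE = dict(s_range=(0.78, 0.90), y_max=-20, z_range=(30, 180))
_SKIN_S_MIN = 0.96


def _build_torso_grids(a_mm: float, b_mm: float, voxel_mm: float):
    margin = 20.0
    nx = int(np.ceil(2 * (a_mm + margin) / voxel_mm))
    ny = int(np.ceil(2 * (b_mm + margin) / voxel_mm))
    nz = int(np.ceil(TORSO_LENGTH_MM / voxel_mm))
    if nx % 2:
        nx += 1  # keep the grid left-right symmetric about x = 0
    origin = np.array([-nx * voxel_mm / 2, -ny * voxel_mm / 2, 0.0])
    cx = origin[0] + (np.arange(nx) + 0.5) * voxel_mm
    cy = origin[1] + (np.arange(ny) + 0.5) * voxel_mm
    cz = origin[2] + (np.arange(nz) + 0.5) * voxel_mm
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    # squared scaled ellipse radius: s = 1 on the body surface
    S2 = (X / a_mm) ** 2 + (Y / b_mm) ** 2
    body = S2 <= 1.0
    material = np.zeros((nx, ny, nz), dtype=np.int8)
    material[body] = 1  # soft tissue
    # bone
    bone = np.zeros_like(body)
    bone |= body & (((X - _SPINE["center"][0]) ** 2 + (Y - _SPINE["center"][1]) ** 2)
                    <= _SPINE["radius"] ** 2)
    s = np.sqrt(S2)
    rib_band = ((Z - _RIBS["z_range"][0]) // _RIBS["band_mm"]).astype(int) % 2 == 0
    bone |= (body & (s >= _RIBS["s_range"][0]) & (s < _RIBS["s_range"][1])
             & (Z >= _RIBS["z_range"][0]) & (Z < _RIBS["z_range"][1]) & rib_band)
    bone |= (body & (s >= _PELVIS_BONE["s_range"][0]) & (s < _PELVIS_BONE["s_range"][1])
             & (Y <= _PELVIS_BONE["y_max"])
             & (Z >= _PELVIS_BONE["z_range"][0]) & (Z < _PELVIS_BONE["z_range"][1]))
    material[bone] = 3
    organ = np.zeros((nx, ny, nz), dtype=np.int16)
    taken = np.zeros_like(body)

    def claim(mask, oid):
        mask = mask & body & ~taken
        organ[mask] = oid
        taken[mask] = True
        return mask

    for model in ORGAN_MODELS:
        p = model.params
        mask = np.zeros_like(body)
        if model.kind == "ellipsoid":
            sa, sb, sc = p["semi"]
            for cx0, cy0, cz0 in p["centers"]:
                mask |= ((X - cx0) / sa) ** 2 + ((Y - cy0) / sb) ** 2 + (
                    (Z - cz0) / sc
                ) ** 2 <= 1.0
        elif model.kind == "cylinder_z":
            z0, z1 = p["z_range"]
            for cx0, cy0 in p["centers"]:
                mask |= ((X - cx0) ** 2 + (Y - cy0) ** 2 <= p["radius"] ** 2) & (
                    Z >= z0
                ) & (Z < z1)
            if "transverse" in p:
                t = p["transverse"]
                mask |= ((Y - t["y"]) ** 2 + (Z - t["z"]) ** 2 <= t["radius"] ** 2) & (
                    np.abs(X) <= t["x_abs"]
                )
        elif model.kind == "shell_patch":
            s0, s1 = p["s_range"]
            z0, z1 = p["z_range"]
            xa, xb = p["x_abs"]
            mask |= ((s >= s0) & (s <= s1) & (Y >= p["y_min"])
                     & (np.abs(X) >= xa) & (np.abs(X) <= xb)
                     & (Z >= z0) & (Z < z1))
        if model.name == "lungs":
            mask &= ~bone
            lung_mask = claim(mask, model.organ_id)
            material[lung_mask] = 2
        elif model.name == "breasts":
            claim(mask & ~bone, model.organ_id)
        else:
            claim(mask & ~bone, model.organ_id)
    # active bone marrow = the bone compartment
    claim(bone, ORGAN_IDS["active_bone_marrow"])
    # skin: outermost soft-tissue shell not already claimed
    claim((s >= _SKIN_S_MIN) & (material == 1), ORGAN_IDS["skin"])
    # remainder: every unlabelled soft-tissue voxel
    claim(material == 1, ORGAN_IDS["remainder"])
    return material, organ, origin, (cx, cy, cz)


def build_torso_phantom(
    height_cm: float = 178.6,
    mass_kg: float = 73.2,
    voxel_mm: float = 10.0,
    trunk_fraction: float = DEFAULT_TRUNK_FRACTION,
) -> VoxelPhantom:
    """Build the simplified 70 cm torso phantom.

    The elliptical cross-section (aspect ratio fixed at 1.81) is scaled once
    so the voxelized torso mass hits ``trunk_fraction * mass_kg`` — the
    reference height/mass describe the whole body while the phantom is
    trunk-only.  Height enters only through that mass target; the torso
    length is fixed at 70 cm.
    """
    if voxel_mm > 10.0:
        raise ValueError("torso phantom needs voxels <= 10 mm")
    target_g = mass_kg * trunk_fraction * 1000.0
    material_names = ["air", "soft_tissue", "lung", "bone"]
    densities = np.array([MATERIALS[m].density for m in material_names])
    a, b = 172.0, 95.0
    phantom = None
    for _ in range(2):  # one corrective rescale pass
        material, organ, origin, _centers = _build_torso_grids(a, b, voxel_mm)
        phantom = VoxelPhantom(
            voxel_mm=np.array([voxel_mm] * 3, float),
            material_grid=material,
            organ_grid=organ,
            material_names=material_names,
            densities=densities,
            origin_mm=origin,
            organ_names=dict(ORGAN_NAMES),
            tally_material={
                ORGAN_IDS["active_bone_marrow"]: material_names.index("soft_tissue")
            },
        )
        scale = np.sqrt(target_g / phantom.total_mass_g())
        if abs(scale - 1.0) < 0.01:
            break
        if not 0.5 < scale < 2.0:
            raise ValueError(
                f"mass {mass_kg} kg / height {height_cm} cm give a non-physical "
                f"cross-section (scale {scale:.2f})"
            )
        a, b = a * scale, b * scale
    return phantom


def anterior_fraction(phantom: VoxelPhantom, organ: int | str) -> float:
    """Diagnostic: fraction of an organ's voxels with y > 0 (anterior half)."""
    mask = phantom.organ_mask(organ)
    if not mask.any():
        return float("nan")
    _, cy, _ = phantom.voxel_centers()
    frac = (mask.sum(axis=(0, 2)) * (cy > 0)).sum() / mask.sum()
    return float(frac)


def organ_centroid(phantom: VoxelPhantom, organ: int | str) -> np.ndarray:
    mask = phantom.organ_mask(organ)
    cx, cy, cz = phantom.voxel_centers()
    idx = np.nonzero(mask)
    return np.array([cx[idx[0]].mean(), cy[idx[1]].mean(), cz[idx[2]].mean()])
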