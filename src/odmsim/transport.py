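"""Monte-Carlo fan-beam transport over voxel phantoms.

Projections are simulated independently with counter-mixed per-projection
seeds, so scans are reproducible regardless of execution order, and dose is
exactly linear in the tube-current multiplier.  A scan is therefore simulated
once per (z position, angle) and any number of modulation weightings (ODM
on/off, TCM on/off) are formed from the same underlying projections, which
also makes paired dose ratios tightly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import attenuation
from ._kernels import run_projection_kernel
from .beam import Spectrum, SubFieldSet
from .modulation import ModulationProfile
from .phantoms import VoxelPhantom

ENERGY_CUTOFF_KEV = 5.0


@dataclass(frozen=True)
class BeamGeometry:
    """Fan-beam geometry: focus-to-isocenter distance and axial beam width."""

    sid_mm: float = 541.0
    z_width_mm: float = 23.0
    n_angles: int = 36

    def __post_init__(self):
        if self.sid_mm <= 0 or self.z_width_mm <= 0 or self.n_angles < 1:
            raise ValueError("sid, z_width and n_angles must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * 360.0 / self.n_angles


@dataclass
class DoseMap:
    """Per-voxel / per-region absorbed dose (keV/g, relative units) with SEs."""

    region_labels: list[str]
    region_dose: np.ndarray
    region_se: np.ndarray
    region_mass_g: np.ndarray
    histories: int
    seed: int
    emitted_kev: float
    deposited_kev: float
    primary_exit: int = 0
    dose_voxel: np.ndarray | None = None
    region_dose_by_z: np.ndarray | None = None  # (nz_positions, n_regions)
    z_positions_mm: np.ndarray | None = None

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.region_labels,
                "dose": self.region_dose,
                "se": self.region_se,
                "histories": self.histories,
            }
        )

    def dose(self, label: str) -> float:
        return float(self.region_dose[self.region_labels.index(label)])

    def se(self, label: str) -> float:
        return float(self.region_se[self.region_labels.index(label)])


def mix_seed(seed: int, *stream: int) -> int:
    """Counter-based substream seed (splitmix64 finalizer), < 2**31."""
    mask = (1 << 64) - 1
    x = int(seed) & mask
    for s in stream:
        x = (x + 0x9E3779B97F4A7C15 * (int(s) + 1)) & mask
        x ^= x >> 30
        x = (x * 0xBF58476D1CE4E5B9) & mask
        x ^= x >> 27
        x = (x * 0x94D049BB133111EB) & mask
        x ^= x >> 31
    return int(x % (2**31 - 1)) + 1


class _TransportContext:
    """Pre-tabulated kernel inputs shared across projections."""

    def __init__(self, phantom: VoxelPhantom, spectrum: Spectrum, subfields: SubFieldSet):
        if spectrum.total_fluence <= 0:
            raise ValueError("spectrum has zero fluence")
        self.phantom = phantom
        tables = attenuation.build_transport_tables(
            phantom.material_names, phantom.densities
        )
        self.mu = tables["mu"]
        self.mu_tr = tables["mu_tr"]
        self.p_pe = tables["p_pe"]
        self.mu_max = tables["mu_max"]
        # spectrum CDF over bins with support
        keep = spectrum.fluence > 0
        f = spectrum.fluence[keep]
        self.spec_e = np.ascontiguousarray(spectrum.energy_kev[keep])
        self.spec_cdf = np.cumsum(f) / f.sum()
        # sub-field sampling probability ~ weight x width (photons per field),
        # uniform within each field: reproduces the staircase fluence profile
        hw = subfields.half_widths
        w = subfields.weights
        p = w * np.maximum(hw, 1e-9)
        self.sub_cdf = np.cumsum(p) / p.sum()
        self.sub_hw = np.ascontiguousarray(hw)
        mass = phantom.voxel_mass_g()
        self.inv_voxel_mass = 1.0 / mass
        # region labels: index 0 reserved for "no region"
        ids = sorted(phantom.organ_names)
        self.region_ids = ids
        self.region_labels = [phantom.organ_names[i] for i in ids]
        self.region_grid = np.zeros_like(phantom.organ_grid, dtype=np.int16)
        for new, oid in enumerate(ids, start=1):
            self.region_grid[phantom.organ_grid == oid] = new
        # per-region tally-material override (-1 = score the voxel material)
        self.region_score_mat = np.full(len(ids) + 1, -1, dtype=np.int64)
        for new, oid in enumerate(ids, start=1):
            if oid in phantom.tally_material:
                self.region_score_mat[new] = phantom.tally_material[oid]
        weights_mass = np.bincount(
            self.region_grid.ravel().astype(np.int64),
            weights=mass[phantom.material_grid.ravel()],
            minlength=len(ids) + 1,
        )
        voxel_counts = np.bincount(
            self.region_grid.ravel().astype(np.int64), minlength=len(ids) + 1
        )
        self.region_mass = weights_mass[1:]
        # overridden regions: mass must use the tally material's density so
        # energy-sum / mass yields fluence x (mu_tr/rho) of that material
        for new in range(1, len(ids) + 1):
            ms = self.region_score_mat[new]
            if ms >= 0:
                self.region_mass[new - 1] = voxel_counts[new] * mass[ms]

    def run(self, angle_deg, z_center, geometry, n_photons, seed, scatter, collect_voxel):
        th = np.radians(angle_deg)
        src = np.array(
            [geometry.sid_mm * np.sin(th), geometry.sid_mm * np.cos(th), z_center]
        )
        lat_axis = np.array([np.cos(th), -np.sin(th), 0.0])
        n_reg = len(self.region_ids)
        region_sum = np.zeros(n_reg + 1)
        region_sumsq = np.zeros(n_reg + 1)
        dose_voxel = (
            np.zeros(self.phantom.shape)
            if collect_voxel
            else np.zeros((1, 1, 1))
        )
        emitted, deposited, n_exit = run_projection_kernel(
            self.phantom.material_grid,
            self.region_grid,
            self.region_score_mat,
            self.phantom.origin_mm.astype(np.float64),
            self.phantom.voxel_mm.astype(np.float64),
            self.mu,
            self.mu_tr,
            self.p_pe,
            self.mu_max,
            attenuation.E_MIN,
            attenuation.E_STEP,
            ENERGY_CUTOFF_KEV,
            self.inv_voxel_mass,
            src,
            lat_axis,
            float(z_center),
            geometry.z_width_mm / 2.0,
            self.sub_cdf,
            self.sub_hw,
            self.spec_cdf,
            self.spec_e,
            n_photons,
            seed,
            scatter,
            collect_voxel,
            dose_voxel,
            region_sum,
            region_sumsq,
        )
        var = np.maximum(region_sumsq[1:] - region_sum[1:] ** 2 / n_photons, 0.0)
        return {
            "region_sum": region_sum[1:],
            "region_var": var,
            "dose_voxel": dose_voxel if collect_voxel else None,
            "emitted": emitted,
            "deposited": deposited,
            "primary_exit": n_exit,
        }


def simulate_projection(
    phantom: VoxelPhantom,
    spectrum: Spectrum,
    subfields: SubFieldSet,
    geometry: BeamGeometry,
    angle_deg: float,
    n_photons: int,
    seed: int,
    z_center_mm: float = 0.0,
    scatter: bool = True,
    collect_voxel: bool = True,
) -> DoseMap:
    """Simulate one fan-beam projection and tally dose per voxel and region."""
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    ctx = _TransportContext(phantom, spectrum, subfields)
    res = ctx.run(angle_deg, z_center_mm, geometry, n_photons, int(seed), scatter, collect_voxel)
    with np.errstate(divide="ignore", invalid="ignore"):
        dose = np.where(ctx.region_mass > 0, res["region_sum"] / ctx.region_mass, 0.0)
        se = np.where(ctx.region_mass > 0, np.sqrt(res["region_var"]) / ctx.region_mass, 0.0)
    return DoseMap(
        region_labels=list(ctx.region_labels),
        region_dose=dose,
        region_se=se,
        region_mass_g=ctx.region_mass,
        histories=n_photons,
        seed=int(seed),
        emitted_kev=res["emitted"],
        deposited_kev=res["deposited"],
        primary_exit=res["primary_exit"],
        dose_voxel=res["dose_voxel"],
    )


def scan_z_positions(z_start_mm: float, z_end_mm: float, z_width_mm: float) -> np.ndarray:
    """Contiguous axial beam centers stepped by the beam width (step-and-shoot).

    The last position may overrange past ``z_end`` so the full range is
    covered, as a real scanner does.
    """
    n = int(np.ceil((z_end_mm - z_start_mm) / z_width_mm))
    return z_start_mm + z_width_mm * (np.arange(n) + 0.5)


def simulate_scan(
    phantom: VoxelPhantom,
    spectrum: Spectrum,
    subfields: SubFieldSet,
    geometry: BeamGeometry,
    modulations: ModulationProfile | list[ModulationProfile],
    z_start_mm: float,
    z_end_mm: float,
    n_photons_per_projection: int,
    seed: int,
    scatter: bool = True,
    collect_voxel: bool = False,
) -> DoseMap | list[DoseMap]:
    """Axial step-and-shoot scan: weighted sum of projections over (z, angle).

    ``modulations`` may be a list of profiles, in which case every profile is
    applied to the *same* simulated projections (dose is exactly linear in
    the mA multiplier) and one DoseMap per profile is returned.  Standard
    errors combine in quadrature across projections.
    """
    single = isinstance(modulations, ModulationProfile)
    profiles = [modulations] if single else list(modulations)
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")
    z_positions = scan_z_positions(z_start_mm, z_end_mm, geometry.z_width_mm)
    for prof in profiles:
        if prof.z_mm.min() > z_start_mm + geometry.z_width_mm or prof.z_mm.max() < (
            z_end_mm - geometry.z_width_mm
        ):
            raise ValueError("modulation profile does not cover the scan range")
    ctx = _TransportContext(phantom, spectrum, subfields)
    n_reg = len(ctx.region_ids)
    n_prof = len(profiles)
    sums = np.zeros((n_prof, n_reg))
    variances = np.zeros((n_prof, n_reg))
    sums_by_z = np.zeros((n_prof, len(z_positions), n_reg))
    voxel = [np.zeros(phantom.shape) for _ in range(n_prof)] if collect_voxel else None
    emitted = np.zeros(n_prof)
    deposited = np.zeros(n_prof)
    for iz, zc in enumerate(z_positions):
        for ia, angle in enumerate(geometry.angles_deg):
            sub = mix_seed(seed, iz, ia)
            res = ctx.run(angle, zc, geometry, n_photons_per_projection, sub, scatter, collect_voxel)
            for p, prof in enumerate(profiles):
                w = prof.multiplier_at(zc, angle)
                sums[p] += w * res["region_sum"]
                variances[p] += w * w * res["region_var"]
                sums_by_z[p, iz] += w * res["region_sum"]
                emitted[p] += w * res["emitted"]
                deposited[p] += w * res["deposited"]
                if collect_voxel:
                    voxel[p] += w * res["dose_voxel"]
    histories = int(n_photons_per_projection) * len(z_positions) * geometry.n_angles
    out = []
    mass = ctx.region_mass
    with np.errstate(divide="ignore", invalid="ignore"):
        for p in range(n_prof):
            dose = np.where(mass > 0, sums[p] / mass, 0.0)
            se = np.where(mass > 0, np.sqrt(variances[p]) / mass, 0.0)
            by_z = np.where(mass > 0, sums_by_z[p] / mass, 0.0)
            out.append(
                DoseMap(
                    region_labels=list(ctx.region_labels),
                    region_dose=dose,
                    region_se=se,
                    region_mass_g=mass,
                    histories=histories,
                    seed=int(seed),
                    emitted_kev=float(emitted[p]),
                    deposited_kev=float(deposited[p]),
                    dose_voxel=voxel[p] if collect_voxel else None,
                    region_dose_by_z=by_z,
                    z_positions_mm=z_positions,
                )
            )
    return out[0] if single else out
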