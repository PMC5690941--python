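"""Tube-current modulation: AEC noise-index model, quadrant TCM and ODM.

The scanner's automatic exposure control (AEC) holds a target image noise set
by a vendor "Noise Index" (NI): higher NI means lower tube current, and dose
scales as NI^-2 until the configured mA floor or ceiling engages.  Quadrant
TCM assigns one mA level to the anterior/posterior quadrants and another to
the lateral quadrants of each rotation, with levels that vary by anatomical
region (chest/abdomen/pelvis).  Organ dose modulation (ODM) additionally
reduces the current by a fixed fraction over an anterior arc (180 degrees for
body protocols), without posterior compensation.

Angle convention: theta = 0 places the tube anterior, increasing clockwise as
seen from the patient's feet.  Discretized profiles use sector-average
multipliers, so a sector straddling the arc boundary gets the exact average
and the ideal rotation mean (1 - reduction * arc/360) is preserved on any
uniform angular grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .phantoms import region_of

REGIONS = ("chest", "abdomen", "pelvis")
QUADRANT_CLASSES = ("AP", "lateral")

#: Default normalized median mA per (region, quadrant class), used when no
#: patient log file is supplied.  Shaped like typical chest-abdomen-pelvis
#: AEC behaviour: low current through the air-filled chest (lowest for the AP
#: quadrants), high lateral current through the bony pelvis.  The source
#: study plots medians/IQRs without printing numbers, so these are plausible
#: configurable defaults, not measured values.
DEFAULT_TCM_MEDIANS = {
    ("chest", "AP"): 0.72,
    ("chest", "lateral"): 0.88,
    ("abdomen", "AP"): 0.95,
    ("abdomen", "lateral"): 1.05,
    ("pelvis", "AP"): 1.10,
    ("pelvis", "lateral"): 1.40,
}


def aec_dose_for_noise_index(
    ni: float,
    ref_ni: float,
    ref_dose: float,
    min_ma: float = 10.0,
    max_ma: float = 500.0,
    base_ma_at_ref: float = 200.0,
) -> float:
    """Predicted CTDIvol at Noise Index ``ni`` given a reference point.

    Dose scales as ``(ref_ni/ni)**2``; the implied tube current is clamped to
    ``[min_ma, max_ma]`` and dose rescales proportionally to the clamped mA,
    so high NI settings bottom out at the mA floor.
    """
    if ni <= 0 or ref_ni <= 0 or ref_dose <= 0:
        raise ValueError("noise index and dose must be positive")
    if not 0 < min_ma <= base_ma_at_ref <= max_ma:
        raise ValueError("need 0 < min_ma <= base_ma_at_ref <= max_ma")
    ma = base_ma_at_ref * (ref_ni / ni) ** 2
    ma_clamped = float(np.clip(ma, min_ma, max_ma))
    return ref_dose * ma_clamped / base_ma_at_ref


def noise_index_to_match_dose(ref_ni: float, ref_dose: float, target_dose: float) -> float:
    """Noise Index that yields ``target_dose`` under the NI^-2 model (no clamp)."""
    if ref_ni <= 0 or ref_dose <= 0:
        raise ValueError("reference values must be positive")
    if target_dose <= 0:
        raise ValueError("target dose must be positive")
    return ref_ni * float(np.sqrt(ref_dose / target_dose))


def _wrap_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-180, 180]."""
    return -np.mod(180.0 - np.asarray(theta, float), 360.0) + 180.0


def odm_multiplier(
    theta_deg: float,
    arc_deg: float = 180.0,
    reduction: float = 0.4,
    sector_deg: float | None = None,
) -> float:
    """ODM mA multiplier at tube angle ``theta``.

    ``1 - reduction`` inside the anterior arc (|theta| < arc/2), 1 outside.
    With ``sector_deg`` set, the returned value is the average over the
    sector centered on ``theta`` (exact, analytic at the arc boundary).
    """
    if not 0 < arc_deg <= 360:
        raise ValueError("arc must be in (0, 360]")
    if not 0 <= reduction < 1:
        raise ValueError("reduction must be in [0, 1)")
    if sector_deg is None:
        inside = abs(float(_wrap_deg(theta_deg))) < arc_deg / 2.0
        return 1.0 - reduction if inside else 1.0
    w = _wrap_deg(theta_deg)
    half_in = arc_deg / 2.0
    lo, hi = w - sector_deg / 2.0, w + sector_deg / 2.0
    # overlap of [lo, hi] with the anterior arc (-half_in, half_in), on a circle
    overlap = max(0.0, min(hi, half_in) - max(lo, -half_in))
    if hi > 360.0 - half_in:  # wrap-around into the arc from the far side
        overlap += max(0.0, hi - (360.0 - half_in))
    if lo < -(360.0 - half_in):
        overlap += max(0.0, -(360.0 - half_in) - lo)
    frac = overlap / sector_deg
    return 1.0 - reduction * frac


def quadrant_class_of(theta_deg: float) -> str:
    """'AP' for the anterior/posterior quadrants, 'lateral' otherwise."""
    w = abs(float(_wrap_deg(theta_deg)))
    return "AP" if (w < 45.0 or w >= 135.0) else "lateral"


@dataclass(frozen=True)
class MedianModulationTable:
    """Median (and IQR) normalized mA per (region, quadrant class)."""

    values: dict  # (region, class) -> dict(median=..., iqr_low=..., iqr_high=...)

    def __post_init__(self):
        for key in self.values:
            if self.values[key]["median"] <= 0:
                raise ValueError(f"median for {key} must be positive")

    def median(self, region: str, quadrant_class: str) -> float:
        try:
            return self.values[(region, quadrant_class)]["median"]
        except KeyError:
            raise KeyError(f"no table entry for ({region}, {quadrant_class})")

    @classmethod
    def identity(cls) -> "MedianModulationTable":
        return cls({(r, q): dict(median=1.0, iqr_low=1.0, iqr_high=1.0)
                    for r in REGIONS for q in QUADRANT_CLASSES})

    @classmethod
    def default(cls) -> "MedianModulationTable":
        return cls({k: dict(median=v, iqr_low=v, iqr_high=v)
                    for k, v in DEFAULT_TCM_MEDIANS.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(region=r, quadrant_class=q, **self.values[(r, q)])
            for r, q in self.values
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MedianModulationTable":
        values = {
            (row.region, row.quadrant_class): dict(
                median=row.median_, iqr_low=row.iqr_low, iqr_high=row.iqr_high
            )
            for row in df.rename(columns={"median": "median_"}).itertuples()
        }
        return cls(values)


def tcm_multiplier(
    z_mm: float,
    theta_deg: float,
    table: MedianModulationTable,
    boundaries_cm: tuple[float, float] = (20.0, 40.0),
) -> float:
    """Quadrant-TCM multiplier: the region's AP or lateral median mA."""
    region = region_of(z_mm / 10.0, boundaries_cm)
    return table.median(region, quadrant_class_of(theta_deg))


@dataclass(frozen=True)
class ModulationProfile:
    """mA multiplier per (z position, gantry angle)."""

    z_mm: np.ndarray
    angles_deg: np.ndarray
    multipliers: np.ndarray  # (nz, nangles), >= 0
    base_ma: float = 200.0
    min_ma: float = 10.0
    max_ma: float = 500.0

    def __post_init__(self):
        m = np.asarray(self.multipliers, float)
        if m.shape != (len(self.z_mm), len(self.angles_deg)):
            raise ValueError("multiplier grid shape mismatch")
        if np.any(m < 0):
            raise ValueError("multipliers must be non-negative")
        d = np.diff(np.asarray(self.angles_deg, float))
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("angles must cover [0, 360) uniformly")
        object.__setattr__(self, "multipliers", m)

    def clamped(self) -> np.ndarray:
        """Multipliers after the mA floor/ceiling (mA = base_ma * multiplier)."""
        ma = np.clip(self.multipliers * self.base_ma, self.min_ma, self.max_ma)
        return ma / self.base_ma

    def multiplier_at(self, z_mm: float, theta_deg: float) -> float:
        iz = int(np.argmin(np.abs(self.z_mm - z_mm)))
        ia = int(np.argmin(np.abs(_wrap_deg(self.angles_deg - theta_deg))))
        return float(self.clamped()[iz, ia])

    def rotation_mean(self) -> np.ndarray:
        return self.clamped().mean(axis=1)


def build_profile(
    z_positions_mm: np.ndarray,
    angles_deg: np.ndarray,
    odm: bool = False,
    tcm_table: MedianModulationTable | None = None,
    arc_deg: float = 180.0,
    reduction: float = 0.4,
    rescale: float = 1.0,
    compensate_posterior: bool = False,
    boundaries_cm: tuple[float, float] = (20.0, 40.0),
    base_ma: float = 200.0,
    min_ma: float = 10.0,
    max_ma: float = 500.0,
) -> ModulationProfile:
    """Compose TCM x ODM x rescale into one multiplier grid.

    ``compensate_posterior`` raises the posterior arc to conserve the rotation
    mean (the behaviour of rival posterior-compensating implementations);
    disabled by default, matching ODM.
    """
    z = np.asarray(z_positions_mm, float)
    ang = np.asarray(angles_deg, float)
    sector = 360.0 / len(ang)
    m = np.ones((len(z), len(ang)))
    for j, theta in enumerate(ang):
        m_odm = odm_multiplier(theta, arc_deg, reduction, sector_deg=sector) if odm else 1.0
        if odm and compensate_posterior and reduction > 0 and arc_deg < 360:
            anterior_frac_total = arc_deg / 360.0
            boost = 1.0 + reduction * anterior_frac_total / (1.0 - anterior_frac_total)
            sector_anterior_frac = (1.0 - m_odm) / reduction
            m_odm = (1.0 - reduction) * sector_anterior_frac + boost * (
                1.0 - sector_anterior_frac
            )
        for i, zi in enumerate(z):
            # an overranging final beam position keeps the adjacent region's mA
            zc = float(np.clip(zi, 0.0, 700.0))
            m_tcm = tcm_multiplier(zc, theta, tcm_table, boundaries_cm) if tcm_table else 1.0
            m[i, j] = m_odm * m_tcm * rescale
    return ModulationProfile(z, ang, m, base_ma=base_ma, min_ma=min_ma, max_ma=max_ma)


def match_ctdivol_rescale(profile: ModulationProfile, factor: float) -> ModulationProfile:
    """Scale all multipliers by ``factor`` (e.g. 1/0.8 to restore CTDIvol)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    m = profile.multipliers * factor
    if np.any(m * profile.base_ma > profile.max_ma):
        warnings.warn("rescaled mA exceeds max_ma; values will clamp", stacklevel=2)
    return replace(profile, multipliers=m)


def normalize_patient_currents(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each patient's mA values by that patient's mean mA.

    ``records`` needs columns patient_id, z_mm, quadrant_class, ma; a
    ``region`` column is added (or validated) from z via :func:`region_of`.
    Returns a copy with a ``norm_ma`` column; each patient's mean norm_ma is
    exactly 1.
    """
    required = {"patient_id", "z_mm", "quadrant_class", "ma"}
    if not required <= set(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if (records["ma"] <= 0).any():
        raise ValueError("all mA values must be positive")
    out = records.copy()
    out["region"] = [region_of(z / 10.0) for z in out["z_mm"]]
    out["norm_ma"] = out["ma"] / out.groupby("patient_id")["ma"].transform("mean")
    return out


def median_modulation_table(normalized: pd.DataFrame) -> MedianModulationTable:
    """Median and IQR of normalized mA per (region, quadrant class)."""
    if "norm_ma" not in normalized.columns:
        raise ValueError("run normalize_patient_currents first (need norm_ma)")
    values = {}
    for r in REGIONS:
        for q in QUADRANT_CLASSES:
            sel = normalized[(normalized["region"] == r)
                             & (normalized["quadrant_class"] == q)]["norm_ma"]
            if sel.empty:
                raise ValueError(f"no records for ({r}, {q})")
            values[(r, q)] = dict(
                median=float(sel.median()),
                iqr_low=float(sel.quantile(0.25)),
                iqr_high=float(sel.quantile(0.75)),
            )
    return MedianModulationTable(values)
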