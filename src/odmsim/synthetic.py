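"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes from measurement — bowtie dose profiles,
per-slice per-quadrant patient mA logs, and AEC-phantom image stacks — can be
generated here with a documented, recoverable ground truth.  All generators
are bit-reproducible from (seed, parameters).

The generators emulate the *shape* of the real measurements (flat-top bowtie
profiles with lateral falloff, log-normal patient current variation around
region medians, per-segment noise scaling in a stepped AEC phantom), not any
particular scanner's raw data formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import INNERMOST_WEIGHT, BowtieProfile
from .modulation import DEFAULT_TCM_MEDIANS, QUADRANT_CLASSES

#: analytic arc-frame bowtie shapes: flat top half-width and falloff length
#: (mm).  The large filter shapes the beam more aggressively, falling faster.
BOWTIE_SHAPES = {
    "small": dict(flat_mm=60.0, falloff_mm=120.0),
    "large": dict(flat_mm=40.0, falloff_mm=70.0),
}

#: insert HU means for the stepped AEC phantom generator
INSERT_HU = {
    "pmma": 120.0,
    "polyethylene": -90.0,
    "polyoxymethylene": 340.0,
    "water": 0.0,
    "air": -1000.0,
}

#: per-segment noise amplification from increasing phantom thickness
SEGMENT_ATTENUATION_FACTORS = (1.0, 1.25, 1.55, 1.9, 2.3)


def bowtie_truth(filter_kind: str, lateral_mm: np.ndarray) -> np.ndarray:
    """Noise-free arc-frame relative dose: flat top, exponential falloff."""
    shape = BOWTIE_SHAPES[filter_kind]
    x = np.abs(np.asarray(lateral_mm, float))
    return np.where(
        x <= shape["flat_mm"],
        1.0,
        np.exp(-(x - shape["flat_mm"]) / shape["falloff_mm"]),
    )


def gen_bowtie_measurements(
    filter_kind: str,
    n_points: int = 201,
    noise_sd: float = 0.01,
    seed: int = 0,
    span_mm: float = 250.0,
    sid_mm: float = 541.0,
) -> BowtieProfile:
    """Emulated line-frame sensor traverse across the bore.

    The analytic truth is defined in the arc frame (per-ray); the emitted
    line-frame samples include the inverse-square falloff a translated sensor
    sees, plus multiplicative Gaussian measurement noise, so the measured
    profile round-trips through ``inverse_square_correct``.
    """
    if n_points < 21:
        raise ValueError("need at least 21 sample points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x = np.linspace(-span_mm, span_mm, n_points)
    arc = bowtie_truth(filter_kind, x)
    line = arc * sid_mm**2 / (sid_mm**2 + x**2)
    noisy = line * (1.0 + noise_sd * rng.standard_normal(n_points))
    return BowtieProfile(x, np.clip(noisy, 1e-6, None), frame="line")


def gen_patient_ma_logs(
    n_patients: int = 20,
    slices_per_patient: int = 40,
    region_medians: dict | None = None,
    dispersion: float = 0.25,
    patient_dispersion: float = 0.30,
    seed: int = 0,
    base_ma: float = 200.0,
    min_ma: float = 10.0,
    max_ma: float = 500.0,
    z_range_mm: tuple[float, float] = (0.0, 700.0),
    boundaries_cm: tuple[float, float] = (20.0, 40.0),
) -> pd.DataFrame:
    """Synthetic chest-abdomen-pelvis AEC logs: one AP and one lateral mA per slice.

    Per-slice currents are log-normal around the region median times a
    log-normal patient-size factor, clamped to the scanner's [min, max] mA.
    Columns: patient_id, z_mm, quadrant_class, ma, region.
    """
    if dispersion < 0 or patient_dispersion < 0:
        raise ValueError("dispersions must be non-negative")
    medians = dict(DEFAULT_TCM_MEDIANS if region_medians is None else region_medians)
    if any(v <= 0 for v in medians.values()):
        raise ValueError("region medians must be positive")
    from .phantoms import region_of

    rng = np.random.default_rng(seed)
    z = np.linspace(z_range_mm[0], z_range_mm[1] - 1e-9, slices_per_patient)
    rows = []
    for pid in range(1, n_patients + 1):
        scale = float(np.exp(patient_dispersion * rng.standard_normal()))
        for zi in z:
            region = region_of(zi / 10.0, boundaries_cm)
            for qc in QUADRANT_CLASSES:
                med = medians[(region, qc)]
                ma = base_ma * med * scale * float(
                    np.exp(dispersion * rng.standard_normal())
                )
                rows.append(
                    dict(
                        patient_id=pid,
                        z_mm=float(zi),
                        quadrant_class=qc,
                        ma=float(np.clip(ma, min_ma, max_ma)),
                        region=region,
                    )
                )
    return pd.DataFrame(rows)


@dataclass
class SteppedPhantomImages:
    """HU image stack for a stepped AEC phantom, with ground truth."""

    images: np.ndarray  # (n_segments, n, n)
    pixel_mm: float
    insert_centers: dict[str, tuple[float, float]]
    insert_diameter_mm: float
    sd_truth: np.ndarray  # per-segment background noise SD (HU)
    dose: float
    seed: int

    def sidecar(self) -> str:
        return json.dumps(
            {
                "pixel_mm": self.pixel_mm,
                "insert_centers": {k: list(v) for k, v in self.insert_centers.items()},
                "insert_diameter_mm": self.insert_diameter_mm,
                "sd_truth_hu": self.sd_truth.tolist(),
                "dose": self.dose,
                "seed": self.seed,
                "note": "synthetic stepped-phantom stack; segment thicknesses "
                "are abstractions, not a published phantom geometry",
            },
            indent=1,
        )


def gen_stepped_phantom_images(
    n_segments: int = 5,
    materials: tuple[str, ...] = ("pmma", "polyethylene", "polyoxymethylene", "water", "air"),
    dose: float = 1.0,
    seed: int = 0,
    image_size: int = 160,
    pixel_mm: float = 2.0,
    base_sd_hu: float = 10.0,
    body_hu: float = 120.0,
    body_radius_mm: float = 140.0,
    insert_radius_mm: float = 50.0,
    insert_diameter_mm: float = 30.0,
) -> SteppedPhantomImages:
    """Generate one axial image per phantom segment.

    Background: a circular PMMA-like body on air.  Inserts: one disc per
    material on a ring.  Noise: white Gaussian with per-segment SD
    ``base_sd * attenuation_factor / sqrt(dose)`` — thicker segments attenuate
    more and are noisier; the 0.5 power law links noise to dose.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    unknown = set(materials) - set(INSERT_HU)
    if unknown:
        raise ValueError(f"unknown insert materials: {sorted(unknown)}")
    if n_segments > len(SEGMENT_ATTENUATION_FACTORS):
        raise ValueError("too many segments for the configured attenuation factors")
    rng = np.random.default_rng(seed)
    n = image_size
    x = (np.arange(n) - n / 2 + 0.5) * pixel_mm
    X, Y = np.meshgrid(x, x, indexing="ij")
    base = np.where(X**2 + Y**2 <= body_radius_mm**2, body_hu, INSERT_HU["air"])
    centers = {}
    for i, mat in enumerate(materials):
        ang = 2 * np.pi * i / len(materials)
        cx, cy = insert_radius_mm * np.sin(ang), insert_radius_mm * np.cos(ang)
        centers[mat] = (float(cx), float(cy))
        mask = (X - cx) ** 2 + (Y - cy) ** 2 <= (insert_diameter_mm / 2) ** 2
        base = np.where(mask, INSERT_HU[mat], base)
    sd_truth = np.array(
        [base_sd_hu * SEGMENT_ATTENUATION_FACTORS[i] / np.sqrt(dose) for i in range(n_segments)]
    )
    images = np.stack(
        [base + sd_truth[i] * rng.standard_normal((n, n)) for i in range(n_segments)]
    )
    return SteppedPhantomImages(
        images=images,
        pixel_mm=pixel_mm,
        insert_centers=centers,
        insert_diameter_mm=insert_diameter_mm,
        sd_truth=sd_truth,
        dose=dose,
        seed=seed,
    )


def default_innermost_weight(filter_kind: str) -> float:
    """Innermost sub-field weight for the built-in filters (8%/6%)."""
    return INNERMOST_WEIGHT[filter_kind]
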