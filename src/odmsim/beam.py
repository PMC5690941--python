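"""X-ray beam model: spectrum generation, filtration and bowtie decomposition.

The tube spectrum is a Kramers-type bremsstrahlung continuum with anode
self-filtration plus fixed-intensity tungsten K fluorescence lines; only the
spectral *shape* matters downstream (relative doses), so no absolute output
calibration is attempted.

The bowtie filter is characterized by a measured lateral relative-dose
profile.  Because the transport model treats each projection as a point
source weighting nested uniform fields, a measured line profile is first
corrected for inverse-square falloff (so values are per-ray rather than
per-point-on-a-line) and then quantized into nested uniform sub-fields, each
contributing a fixed fraction of the central dose.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .attenuation import MATERIALS, mass_atten

TUNGSTEN_K_EDGE_KEV = 69.5
# Kalpha2, Kalpha1, Kbeta1, Kbeta2 energies and relative intensities
_K_LINES = np.array([[57.98, 0.58], [59.32, 1.0], [67.24, 0.33], [69.07, 0.08]])
_K_LINE_FLUENCE_FRACTION = 0.06  # of the filtered continuum fluence
_REFERENCE_ANODE_DEG = 7.0
_SELF_FILTRATION_MM_AL = 1.0  # aluminum-equivalent at the reference anode angle

#: per-filter innermost sub-field weight (share of the central dose)
INNERMOST_WEIGHT = {"small": 0.08, "large": 0.06}


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin."""

    energy_kev: np.ndarray  # bin centers, monotone ascending
    fluence: np.ndarray  # relative photons per bin, >= 0

    def __post_init__(self):
        e = np.asarray(self.energy_kev, float)
        f = np.asarray(self.fluence, float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy bins must be >= 2 and strictly increasing")
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        object.__setattr__(self, "energy_kev", e)
        object.__setattr__(self, "fluence", f)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        return float((self.energy_kev * self.fluence).sum() / self.fluence.sum())


@dataclass(frozen=True)
class FilterStack:
    """Ordered filter layers, e.g. the scanner's small/large bowtie flat stacks."""

    layers: tuple[tuple[str, float], ...]  # (material, thickness mm)
    label: str = "custom"
    qef_mm_al: float | None = None  # quality-equivalent aluminum thickness

    def __post_init__(self):
        for mat, t in self.layers:
            if mat not in MATERIALS:
                raise ValueError(f"unknown filter material: {mat!r}")
            if t < 0:
                raise ValueError("layer thickness must be non-negative")


# Flat-filter stacks of the modelled scanner, tube-side outward.
FILTER_STACKS = {
    "small": FilterStack(
        (("aluminum", 5.500), ("graphite", 1.998), ("aluminum", 0.250)),
        label="small",
        qef_mm_al=5.9,
    ),
    "large": FilterStack(
        (
            ("aluminum", 5.500),
            ("graphite", 1.998),
            ("aluminum", 0.250),
            ("copper", 0.075),
        ),
        label="large",
        qef_mm_al=8.6,
    ),
}


def generate_spectrum(
    kvp: float, anode_angle_deg: float = 7.0, bin_width_kev: float = 1.0
) -> Spectrum:
    """Generate the unfiltered (beyond the anode) tube spectrum.

    Kramers continuum ``N(E) ~ (kvp - E)/E`` attenuated by an
    aluminum-equivalent anode self-filtration that scales inversely with the
    anode-angle tangent (shallower anodes harden the beam), plus tungsten K
    lines when the tube potential exceeds the K edge (69.5 keV).
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kvp must be in [40, 150], got {kvp}")
    if bin_width_kev <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(5.0, 150.0 + bin_width_kev, bin_width_kev)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.where(centers < kvp, np.clip(kvp - centers, 0, None) / centers, 0.0)
    t_self_cm = (
        0.1
        * _SELF_FILTRATION_MM_AL
        * np.tan(np.radians(_REFERENCE_ANODE_DEG))
        / np.tan(np.radians(anode_angle_deg))
    )
    mu_al = mass_atten("aluminum", centers) * MATERIALS["aluminum"].density
    fluence = fluence * np.exp(-mu_al * t_self_cm)
    if kvp > TUNGSTEN_K_EDGE_KEV:
        line_total = _K_LINE_FLUENCE_FRACTION * fluence.sum()
        weights = _K_LINES[:, 1] / _K_LINES[:, 1].sum()
        for (e_line, _), w in zip(_K_LINES, weights):
            idx = int(np.clip(np.searchsorted(edges, e_line) - 1, 0, len(centers) - 1))
            fluence[idx] += line_total * w
    fluence[centers > kvp] = 0.0
    return Spectrum(centers, fluence / fluence.max())


def apply_filtration(spectrum: Spectrum, stack: FilterStack) -> Spectrum:
    """Attenuate each bin by ``exp(-sum mu_m(E) * t_m)`` over the stack layers."""
    atten = np.zeros_like(spectrum.energy_kev)
    for mat_name, t_mm in stack.layers:
        mat = MATERIALS[mat_name]
        atten += mass_atten(mat, spectrum.energy_kev) * mat.density * (t_mm / 10.0)
    return Spectrum(spectrum.energy_kev, spectrum.fluence * np.exp(-atten))


def compare_to_qef(source: Spectrum, stack: FilterStack) -> dict:
    """Compare the stack-filtered spectrum with its aluminum quality equivalent.

    Both the composite stack and a pure-aluminum stack of ``qef_mm_al`` are
    applied to the same source spectrum; returns the per-bin relative
    difference and the overall (total-fluence) relative difference.  This is a
    diagnostic report: "overall agreement" has no unique definition, so
    nothing is asserted here.
    """
    if stack.qef_mm_al is None:
        raise ValueError("stack has no quality-equivalent filtration defined")
    if source.total_fluence <= 0:
        raise ValueError("source spectrum has zero fluence")
    actual = apply_filtration(source, stack)
    qef = apply_filtration(
        source, FilterStack((("aluminum", stack.qef_mm_al),), label="qef")
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_bin = np.where(
            qef.fluence > 0, np.abs(actual.fluence - qef.fluence) / qef.fluence, 0.0
        )
    return {
        "energy_kev": source.energy_kev,
        "per_bin_rel_diff": per_bin,
        "overall_rel_diff": abs(actual.total_fluence - qef.total_fluence)
        / qef.total_fluence,
    }


@dataclass(frozen=True)
class BowtieProfile:
    """Lateral relative-dose profile at the isocenter plane.

    ``frame='line'`` means measured along a straight line (sensor translated
    across the bore); ``frame='arc'`` means inverse-square corrected so every
    value is per-ray at constant distance from the focus.
    """

    lateral_mm: np.ndarray
    relative_dose: np.ndarray
    frame: str = "line"

    def __post_init__(self):
        x = np.asarray(self.lateral_mm, float)
        d = np.asarray(self.relative_dose, float)
        if np.any(np.diff(x) <= 0):
            raise ValueError("lateral positions must be strictly increasing")
        if self.frame not in ("line", "arc"):
            raise ValueError("frame must be 'line' or 'arc'")
        object.__setattr__(self, "lateral_mm", x)
        object.__setattr__(self, "relative_dose", d)

    def normalized(self) -> "BowtieProfile":
        return replace(self, relative_dose=self.relative_dose / self.relative_dose.max())


@dataclass(frozen=True)
class SubFieldSet:
    """Nested uniform fields approximating a bowtie profile.

    ``fields`` is ordered widest first; each entry is (half-width mm at the
    isocenter, weight as a fraction of the central dose).  The reconstructed
    profile at x is the sum of the weights of the fields covering x.
    """

    fields: tuple[tuple[float, float], ...]
    filter_label: str = "custom"

    def __post_init__(self):
        hw = [f[0] for f in self.fields]
        w = [f[1] for f in self.fields]
        if any(b > a + 1e-9 for a, b in zip(hw, hw[1:])):
            raise ValueError("sub-field half-widths must be nested (non-increasing)")
        if any(not 0 < wi <= 1 for wi in w):
            raise ValueError("weights must be in (0, 1]")

    @property
    def half_widths(self) -> np.ndarray:
        return np.array([f[0] for f in self.fields])

    @property
    def weights(self) -> np.ndarray:
        return np.array([f[1] for f in self.fields])


def inverse_square_correct(profile: BowtieProfile, sid_mm: float) -> BowtieProfile:
    """Convert a line-frame profile to the arc frame.

    A point at lateral offset x sits ``sqrt(sid^2 + x^2)`` from the focus, so
    its per-ray dose is the measured value times ``(sid^2 + x^2)/sid^2``.
    The result is renormalized to max 1.
    """
    if profile.frame != "line":
        raise ValueError("profile is already inverse-square corrected")
    if sid_mm <= 0:
        raise ValueError("sid must be positive")
    mult = 1.0 + (profile.lateral_mm / sid_mm) ** 2
    corrected = profile.relative_dose * mult
    return BowtieProfile(profile.lateral_mm, corrected / corrected.max(), frame="arc")


def _symmetrized_half(profile: BowtieProfile, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
    """Average the +-x branches onto a dense half-axis grid."""
    xmax = min(-profile.lateral_mm[0], profile.lateral_mm[-1])
    x = np.linspace(0.0, xmax, n)
    right = np.interp(x, profile.lateral_mm, profile.relative_dose)
    left = np.interp(-x, profile.lateral_mm, profile.relative_dose)
    return x, 0.5 * (left + right)


def decompose_bowtie(
    profile: BowtieProfile,
    n_fields: int = 10,
    innermost_weight: float = 0.10,
    unimodal_tol: float = 0.05,
    label: str = "custom",
) -> SubFieldSet:
    """Quantize an arc-frame profile into nested uniform sub-fields.

    The outer ``n_fields - 1`` fields each carry ``1/n_fields`` of the central
    dose; the innermost carries ``innermost_weight`` (smaller for wider
    filters, to better render the peak).  Field k spans the lateral region
    where the profile exceeds a level placed at the midpoint of its cumulative
    weight band, which minimizes the sup error of the staircase
    reconstruction.
    """
    if profile.frame != "arc":
        raise ValueError("decompose expects an arc-frame (corrected) profile")
    prof = profile.normalized()
    x, p = _symmetrized_half(prof, n=4001)
    running_min = np.minimum.accumulate(p)
    worst = float(np.max(p - running_min))
    if worst > unimodal_tol:
        xbad = float(x[int(np.argmax(p - running_min))])
        raise ValueError(
            f"profile is not unimodal about 0: rises by {worst:.3f} at "
            f"|x|={xbad:.1f} mm (tolerance {unimodal_tol})"
        )
    p = running_min  # noise-robust monotone envelope
    weights = [1.0 / n_fields] * (n_fields - 1) + [innermost_weight]
    cumulative = 0.0
    fields = []
    for w in weights:
        level = cumulative + 0.5 * w
        above = np.nonzero(p >= level)[0]
        if above.size == 0:
            raise ValueError(f"quantization level {level:.3f} above profile maximum")
        i = above[-1]
        if i == len(x) - 1:
            hw = float(x[-1])
        else:  # linear interpolation to the crossing
            x0, x1, p0, p1 = x[i], x[i + 1], p[i], p[i + 1]
            hw = float(x0 + (p0 - level) / (p0 - p1) * (x1 - x0)) if p0 > p1 else float(x0)
        fields.append((hw, w))
        cumulative += w
    return SubFieldSet(tuple(fields), filter_label=label)


def reconstruct_profile(subfields: SubFieldSet, grid_mm: np.ndarray) -> BowtieProfile:
    """Staircase profile: at each x, the sum of the weights of covering fields."""
    x = np.asarray(grid_mm, float)
    dose = np.zeros_like(x)
    for hw, w in subfields.fields:
        dose += np.where(np.abs(x) <= hw, w, 0.0)
    return BowtieProfile(x, dose, frame="arc")


def read_bowtie_csv(path) -> BowtieProfile:
    """Read a two-column ``lateral_mm,relative_dose`` CSV (header required)."""
    df = pd.read_csv(path)
    if not {"lateral_mm", "relative_dose"} <= set(df.columns):
        raise ValueError("bowtie CSV needs columns lateral_mm, relative_dose")
    df = df.sort_values("lateral_mm")
    return BowtieProfile(df["lateral_mm"].to_numpy(), df["relative_dose"].to_numpy())


def write_bowtie_csv(profile: BowtieProfile, path) -> None:
    pd.DataFrame(
        {"lateral_mm": profile.lateral_mm, "relative_dose": profile.relative_dose}
    ).to_csv(path, index=False)
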