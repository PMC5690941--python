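# Methods

This note documents the models implemented in `odmsim`, the defaults chosen
where the design was open, and what the simulations can and cannot say about
real scanners.

## Beam model

**Spectrum.** The tube output is a Kramers continuum, fluence
N(E) ∝ (kVp − E)/E, attenuated by an aluminum-equivalent anode
self-filtration of 1 mm (at the 7° reference anode angle, scaled by the
inverse tangent of the configured angle). Tungsten K-fluorescence lines at
57.98 / 59.32 / 67.24 / 69.07 keV, with standard relative intensities and a
total fluence fixed at 6% of the filtered continuum, are added whenever the
tube potential exceeds the 69.5 keV K edge. No absolute output calibration
is attempted: every reported quantity is a ratio, so only the spectral shape
matters. Spectra live on a 1 keV grid from 5–150 keV.

**Attenuation data.** Mass attenuation coefficients are computed, not
tabulated from an external source: incoherent scattering uses the exact
Klein–Nishina cross section times electron density; photoelectric absorption
uses the classic power-law parametrization τ/ρ ∝ Σᵢ wᵢZᵢ⁴·⁶/Aᵢ · E⁻³·²,
with one constant calibrated to water at 30 keV (0.134 cm²/g). Agreement
with reference data for H–Cu over 15–150 keV is within ~15%, dominated by
the fixed energy exponent; coherent scattering (no energy deposition,
small-angle) is omitted. Because every headline output is a dose *ratio*
between runs that differ only in mA weighting, residual cross-section error
largely cancels.

**Bowtie decomposition.** A measured (here: synthetically generated)
line-frame lateral dose profile is multiplied by (SID² + x²)/SID² so each
sample is per-ray rather than per-point-on-a-line, renormalized to max 1,
symmetrized by averaging ±x, and replaced by its outward running minimum (a
noise-robust monotone envelope). It is then quantized into n = 10 nested
uniform fields: the outer nine carry 10% of the central dose each, the
innermost 8% (small filter) or 6% (large filter). Field k spans the lateral
region where the profile exceeds the midpoint of its cumulative weight band
— the level that minimizes the sup error of a staircase quantization — so
the reconstruction error is bounded by one quantization step (≤ 0.10,
verified on a dense grid). Profiles whose monotone envelope is violated by
more than 0.05 are rejected as non-unimodal.

## Phantoms

Coordinates: x = patient left, y = anterior, z = caudo-cranial (mm,
isocenter on the axis).

**CTDI cylinder.** 32 cm diameter PMMA (1.19 g/cm³), 150 mm long, with
seventeen 15 mm air-filled holes: 8 at radius 150 mm and 8 at 70 mm in 45°
steps starting anterior, plus a central hole. Default voxels 2 mm; at that
resolution hole volumes match the analytic value within 5%.

**Torso.** A 70 cm elliptical soft-tissue cylinder (aspect ratio 1.81)
whose cross-section is scaled once so the voxelized mass equals
`trunk_fraction` (default 0.52) × the 73.2 kg reference body mass — the
phantom is trunk-only, so the whole-body mass cannot be applied directly.
Materials: soft tissue 1.04, inflated lung 0.26, bone 1.55, air
0.0012 g/cm³. The skeleton is a posterior spine cylinder, alternating rib
shell bands in the chest, and posterior-lateral pelvic shells. Thirteen
organ compartments are placed as literature-typical primitives: lungs,
breasts (an anterior shell patch outside the rib line, all voxels anterior),
oesophagus, thyroid (top slices), stomach (left, anterior), liver (right),
colon (two vertical limbs plus a transverse arch), bladder, ovaries,
testicles (bottom boundary), active bone marrow (the bone compartment), a
skin shell, and the remaining soft tissue. Region boundaries default to
pelvis/abdomen at 20 cm and abdomen/chest at 40 cm: the anatomical
definitions (base of the lungs, top of the iliac crest) have no unique
coordinates in a simplified torso, so these are configurable.

The phantom preserves the single feature that drives organ-dose-modulation
results — radiosensitive organs anterior, marrow posterior — but it is not
anthropomorphic: no arms, no head/neck, uniform cross-section, idealized
organ shapes. Absolute organ doses are therefore not meaningful; paired
ratios between modulation settings are.

## Photon transport

Analog Monte Carlo with Woodcock (delta) tracking against the per-energy
majorant cross section; physics is photoelectric absorption plus incoherent
scattering sampled from the Klein–Nishina distribution by rejection, with
local deposition of the recoil energy (kerma approximation — no electron
transport) and a 5 keV cutoff. Photons start at the focal spot (SID
541 mm), aimed at a point drawn from the nested sub-fields (field chosen
with probability ∝ weight × width, lateral position uniform within the
field, z uniform over the 23 mm beam width) and are first advanced to the
grid bounding box analytically.

**Tallies.** Doses are scored with a collision-density kerma estimator: at
every Woodcock vertex — real or null — the photon scores
E·μ_tr(material, E)/μ_max(E) into its voxel and tally region, where μ_tr is
the photoelectric coefficient plus the Compton coefficient weighted by the
mean recoil fraction. This has the same expectation as analog deposition
but far lower variance, which matters in the air-filled CTDI chamber holes.
Analog deposition is still accumulated as a scalar, and every run asserts
deposited ≤ emitted energy. Standard errors come from per-history score
variances and combine in quadrature across projections.

**Marrow dosimetry.** The active-marrow tally uses a per-region material
override: marrow is a soft tissue residing in the skeleton, so its dose is
the bone-voxel photon fluence times the *soft-tissue* mass-energy-transfer
coefficient. Scoring mineral-bone kerma instead would overestimate marrow
dose severalfold at CT energies and distort the effective-dose weighting.

**Reproducibility and linearity.** Each (z-position, angle) projection gets
a counter-mixed substream seed (splitmix64), so scans are bitwise
reproducible and order-independent. Dose is exactly linear in the mA
multiplier, so one set of projections serves every modulation weighting
(ODM on/off × TCM on/off); paired ratios are then tightly correlated and
need far fewer histories than independent runs would.

## Modulation models

- **Noise Index (AEC):** dose ∝ NI⁻², inferred from the scanner's displayed
  CTDIvol quartering when NI doubles; the implied mA is clamped to
  [min, max] = [10, 500] mA and dose follows the clamped mA. The vendor
  algorithm is proprietary; this is the simplest model consistent with its
  published behaviour.
- **ODM:** multiplier 1 − r (default r = 0.4) inside the anterior arc
  (default 180°), 1 outside; a discretized sector straddling the boundary
  receives the exact sector average, so the ideal rotation mean
  1 − r·arc/360 (= 0.8) is preserved on any uniform angular grid.
  Posterior compensation (the rival implementation's behaviour) exists as a
  flag, default off.
- **Quadrant TCM:** one multiplier for the anterior/posterior quadrants
  (|θ| < 45° or > 135°) and one for the lateral quadrants, per region.
  Defaults (chest AP 0.72 / lat 0.88, abdomen 0.95 / 1.05, pelvis
  1.10 / 1.40) are shaped like typical chest–abdomen–pelvis AEC behaviour —
  low current through the air-filled chest, high lateral current through
  the bony pelvis — and are configurable, since only median/IQR plots and
  no numbers are published for the reference data. They can be replaced by
  a table estimated from patient mA logs (median and IQR of per-patient
  mean-normalized currents per region × quadrant class).

## Image-noise models

For a central region reconstructed by filtered backprojection from
projections with independent Poisson noise, image variance is proportional
to the mean reciprocal per-projection dose, so the noise ratio against a
uniform rotation is √(mean 1/mᵢ). For the unmatched ODM rotation
(0.6 anterior / 1.0 posterior on a 36-sector grid) this gives +15.3%,
compared with +11.8% from the global power law dose⁻⁰·⁵ — the
projection-variance model is never below the power law at equal mean dose
(Jensen's inequality, property-tested). Both are reported side by side; the
synthetic image generator itself uses the power law (per-segment SD ∝
attenuation factor / √dose), since it emulates ROI statistics, not a
reconstruction chain.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical shape* of the real inputs: bowtie
profiles as flat-top + exponential falloff (large filter falling faster)
with multiplicative Gaussian measurement noise; patient currents as
log-normal per-slice draws around region medians times a log-normal
patient-size factor, clamped to [10, 500] mA; AEC-phantom images as white
Gaussian HU noise on ideal inserts. Passing tests therefore demonstrate
that the *pipeline* recovers known ground truth and reproduces the expected
dose-redistribution physics — not that any particular scanner's raw data
would yield identical numbers. Real bowtie profiles, AEC logs and CT noise
textures are all richer (correlated noise, table attenuation, patient
anatomy).

## Numerical choices

- Energy grid 1 keV (5–150 keV); kernel lookups use floor indexing.
- Klein–Nishina angle sampling by rejection against the exact differential
  cross section (envelope 2, acceptance ≈ 50% at CT energies).
- Woodcock step epsilon 10⁻⁶ mm; grid boundaries half-open.
- Default photon budgets: 10⁵ per projection for the CTDI phantom
  (36 projections, 2 mm voxels) and 2 × 10⁴ per position-angle for the torso
  (31 positions × 36 angles, 10 mm voxels). These give sub-percent standard
  errors on the paired ratios and keep a full experiment grid to a few
  minutes on one CPU; both are config-exposed.
- The axial scan steps by the 23 mm beam width from the torso base; the
  final position overranges past 70 cm, as a real step-and-shoot scan does.

## Known limitations

- No coherent scattering, electron transport, heel effect or detector
  model; no helical trajectories (helical modes are represented by the same
  rotation-mean arithmetic).
- The torso is not anthropomorphic (see above); tolerance bands on the
  torso-grid results are correspondingly wide.
- The AEC model cannot reproduce scanner-internal interactions between ODM
  and the mA clamps (observed on real scanners as CTDIvol ratios of
  0.75–0.83 instead of the ideal 0.80).
- The spectrum/attenuation stack is self-consistent rather than traceable
  to a standards library; comparisons against the aluminum
  quality-equivalent filtration are reported as diagnostics, not asserted.
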