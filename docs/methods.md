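# Methods

## Scope and model

`hucorr` models one physical mechanism: the depression of bulk water's
effective X-ray attenuation with depth and body size, attributed to the
forward-peaked Rayleigh (coherent) component of scattering re-entering the
imaging beam, and the consequences of that depression for CT numbers.  It
deliberately does **not** model image reconstruction (no sinograms, no
filtered back-projection), vendor beam-hardening corrections, bowtie
filtration, heel effect, or polychromatic spectra beyond a single effective
energy per tube voltage.  Simulated images are the forward model of what an
ideal scanner obeying the correction physics would report, voxel by voxel.

The chain is:

1. **Rayleigh power law.** Water's coherent cross section is fit as
   `σ_R(V) = A V^b` over 50–100 keV by ordinary least squares in log–log
   space (deterministic, reproduces straight-line fits of the usual
   log-log plots). Defaults `A = 27.696`, `b = −1.856`.
2. **Intensity model.** `I(x,V) = B V^(εx+β) e^(−τ_b x)` with defaults
   `β = 2`, `τ_b = 0.5302 /cm`, and hardening exponent `ε` composed of a
   body-size part (0.034) and a depth part (0.023), generic default 0.057.
3. **Transport balance.** Substituting `I` into the one-dimensional photon
   transport equation with the Rayleigh kernel `A V^b` gives
   `μ_eff = τ_b − ε ln V + f(x,V)` with the gain term
   `f = A V^(b+1)/(εx + β + b + 1)`.  The denominator constant is always
   computed as `β + b + 1` (1.144 at the defaults) so refitted constants
   stay algebraically consistent; `transport_residual` exposes the identity
   as a diagnostic and is zero to machine precision by construction.
4. **Correction factor.** `f_c(x,V) = f(x₀) − f(x₀+x)` with
   `x₀(V) = 1/σ_R(V)` the Rayleigh mean free path taken from the packaged
   water table in linear-attenuation units (≈ 95 cm at 64 keV).
5. **Corrected HU.** Numerator correction at the query depth, denominator
   correction at the body radius:
   `HU(x,V) = 1000 (μ − μ_w + f_c(x,V)) / (μ_w − f_c(r,V))`.

## Calibration referencing

The plain corrected-HU form assumes a scanner calibrated on a zero-sized
phantom.  Clinical systems are calibrated on a finite body, so the package
replaces `f_c` by the difference against the calibration geometry,
`Δf_c(x,V) = f_c(x,V) − f_c(x_cal,V)` with `x_cal` the calibration radius.
This makes the calibration point an exact fixed point — water measured at
the calibration size reads 0 HU at every mapped voltage, matching the
observed near-constant water values on a large phantom — and reduces to the
unreferenced form when `cal_diameter = 0` is configured.  Defaults model the
studied system: 30 cm calibration diameter, 110 kVp, effective energies
58/64/72 keV at 80/110/130 kVp (linear interpolation between map keys, no
extrapolation), and a scanner-specific `ε = 0.045` that overrides the
generic 0.057 in all scanner-facing operations.

`V` everywhere in the formulas is the effective mono-energy in keV; tube
voltages in kVp appear only at the `ScannerCalibration` boundary.

## Choice of depth in the size prediction

The corrected-HU formula uses two geometric arguments: the insert depth `x`
(numerator) and the body radius `r` (denominator).  For size-change
predictions `predict_delta_hu_size` defaults to a centre-of-body insert
(`x = r`), but accepts explicit per-size depths because the measured insert
hole sits well off centre: 3.5 cm deep in the head phantom and 11.0 cm deep
in the abdomen.  The distinction matters qualitatively.  `f_c` is concave
increasing in depth, so over intervals of equal length the shallower
interval produces the larger `f_c` change; with the centre convention the
depth contrast (5 → 11 cm) would outweigh the size contrast (9 → 15 cm) for
near-water materials, while at the true hole geometry (3.5 → 11 cm) the
size contrast dominates for every material and voltage — which is the
experimentally observed ordering.  Pattern-level tests and the worked
examples therefore evaluate size changes at the hole geometry.  Depth-change
predictions within one body are material-independent in this model: the
material term cancels in the difference and only the numerator correction
moves.

## Cross-section fixtures and units

Two packaged tables (CSV, `#`-commented headers carrying a `units_label`):

- `water_rayleigh_50_100keV_synthetic.csv` — 11 energies, Rayleigh column
  only, reconstructed from the published power-law fit because the
  underlying per-energy points exist only as a figure.  Its units are "fit
  units": the refit exponent is unit-independent; the amplitude is
  meaningful only in these units.  The model treats `A` as a constant of the
  gain term, not as a physical cross section in 1/cm.
- `water_xsection_10_150keV_synthetic.csv` — 18 energies, all four
  components in mass-attenuation units (cm²/g, water density 1.0 g/cm³),
  XCOM-like magnitudes smoothed onto the grid (≈ 1–2% of standard
  tabulations; adequate for modelling, not dosimetry).  Totals equal the
  component sums; a loader invariant rejects tables whose totals deviate
  from the sum by more than 5%.

Interpolation of any component is piecewise-linear in (log E, log σ),
exact on grid points, bounded by neighbours in between, and never
extrapolates (hard error outside the grid span).

## Materials

`MaterialTable` defaults assign each CIRS-style insert a nominal HU at the
calibration energy (water 0, breast −46, adipose −69, liver 49, muscle 44,
bone200/800/1250 at their nameplate values) and back-computes
`μ(V) = μ_w(V)(1 + HU/1000)`.  Treating the water-relative contrast as
energy-independent is a fixture simplification: real bone contrast rises
steeply at low energy, so the voltage dependence of predictions here comes
entirely from the correction model, not from material spectroscopy.  A CSV
with per-energy `μ` values can replace the defaults; a water row is
validated against the cross-section table to 1%.

## Phantom geometry

Head: 18 cm disk, holes 1–9 (hole 1 central, holes 2–9 on a 5.5 cm ring at
45° steps, hole 6 on the −x axis).  Abdomen: the head disk plus a 33 × 27 cm
elliptical outline, holes 10–17 on an 11.5 cm ring, so hole 14 sits exactly
6 cm outboard of hole 6.  Published descriptions fix only the outlines, the
hole counts and that 6 cm separation; the ring radii and angular layout are
a documented fixture.  Hole diameter defaults to 3 cm — nine 6 cm holes
cannot fit in an 18 cm disk (their combined area equals the disk's), and
real electron-density inserts are about 3 cm across.

Depth of a point is its Euclidean distance to the outer outline.  For the
ellipse this is computed by a vectorized bisection on the nearest-point
parametrisation (unique root for interior points off the major axis; axis
points are nudged by 10⁻⁹·b, and the method agrees with a dense
boundary-sampling oracle to 10⁻⁶ cm).  The body radius entering the
denominator correction is the mean of the semi-axes: 9 cm for the head,
15 cm for the abdomen (the "averaged 30 cm" body).  Hole-centre depths at
the defaults: 3.5 cm (hole 6, head), 11.0 cm (hole 6, abdomen), 5.0 cm
(hole 14).

## Image simulation

`rasterize_phantom` voxelizes one axial plane at the requested spacing
(default 0.1 cm; an error if the spacing exceeds the smallest hole radius),
replicates it over the slices (default 8 slices of 1.5 mm), and assigns each
in-body voxel the corrected HU of its material at the voxel's own depth
(plain HU when the size effect is disabled); air outside is −1000 HU.
Noise is additive zero-mean Gaussian in HU, homoscedastic, independent per
voxel and slice (default SD 5 HU, typical of a 280 mAs abdomen protocol) —
no quantum-noise spectrum, no reconstruction-kernel correlation.  Images are
deterministic for a fixed seed; changing one hole's insert changes no voxel
outside that hole.  The geometry (inside mask and depth map) is memoized per
outline and spacing, which makes sweeping materials/voltages over the same
phantom cheap.  DICOM output stores one file per slice with rescale
intercept −1024 and deterministic UIDs derived from the acquisition
metadata, so HU round-trips within the 0.5 integer quantization and
re-running a configuration is byte-identical.

## ROI protocol

ROIs are circles concentric with a hole at 0.7 × the hole radius (the
shrink avoids edge partial-volume voxels; the exact fraction used in the
original reading-room analysis is unknown, so 0.7 is a documented default).
Membership is a voxel-centre-in-circle test (matching common ROI tools and
an exhaustive-loop oracle).  Statistics pool the eight slices nearest the
axial midpoint, biased toward the inferior side on ties; repeated
acquisitions are averaged unweighted, mirroring the three-repeat scan
protocol.  The reported SE combines per-replicate voxel-noise SEs.

## Numerical and testing notes

- The closure test simulates the full 2-size × 3-kVp × 7-material grid at
  0.1 cm spacing with three replicate seeds {1,2,3} (the problem size is
  chosen so the whole suite runs in well under a minute) and compares
  measured contrasts against an analytic oracle at 3 standard errors.  The
  oracle is the ROI-*averaged* per-voxel corrected HU, which is the true
  expectation of the measurement: it differs from the hole-centre value by
  a geometric averaging term (up to ≈ 1.4 HU for hole 6 in the abdomen,
  whose centre sits just past the ellipse's evolute cusp where the depth
  level-sets curve strongly), and that offset is asserted separately with a
  3 HU bound rather than folded into the statistical comparison.
- Beam-parameter recovery from (depth, energy, intensity) profiles is a
  linear least-squares problem in `(ln B, β, ε, τ_b)`.  Within the narrow
  effective-energy window 58–72 keV the regressors `x ln V` and `x` are
  nearly collinear, so `ε` carries a few-percent sampling SD at 1%
  intensity noise; the estimator is unbiased (mean bias < 1% over 100
  replicates) and single-digit-percent accurate per fit, and designs with a
  single depth or a single energy are rejected as unidentifiable.
- HU values are floating point throughout; rounding to integers happens
  only at the DICOM boundary.  Simulated HU is clipped to [−1024, 4000].

## Known limitations

Passing tests show the pipeline is self-consistent and that the model
reproduces the qualitative experimental patterns (size ≫ depth, strongest
at low kVp and high density).  They do not show agreement with any specific
scanner's absolute numbers: measured depth effects depend on the vendor's
proprietary beam-hardening correction, material contrast is energy-dependent
in reality, and the simulator omits reconstruction physics entirely.  The
shipped `scanner_measured_deltas.csv` contains published scanner
measurements for comparison plots only and is not a target of the model.
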