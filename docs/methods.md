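# Methods

`opmcal` implements the characterisation and calibration computations of
an oblique plane microscope (OPM) built around a remote-focusing train,
driven by a synthetic bead-scene simulator that stands in for the
instrument. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic validation does and does
not establish.

## Optical model and design arithmetic (`opmcal.optics`)

Aberration-free remote focusing requires the overall magnification
between the primary-objective space and the remote-objective space to
equal the ratio of the immersion refractive indices, `M = n1/n2`
(Maxwell's perfect-imaging condition for refocusing through index
mismatch). With objectives specified by nominal magnification against a
tube-lens standard `f_design` (180 mm for Olympus), the remote tube-lens
focal length that satisfies the condition is

```
f_tl2* = M1 · (f_design / M2) · n2 / n1 .
```

For a 100X silicone-oil primary (n1 = 1.406) and a 40X air remote
objective this gives 320.06 mm; the exact value is reported and rounding
is left to the caller, since the nearest practical assembly (two
achromats, 321 mm effective) is a build decision.

Supporting scalings: lateral extents demagnify as `1/M`, axial extents
as `1/M²` (longitudinal magnification), so 0.92 mm of image-plane field
curvature at 100X is a 92 nm sample-space focal shift. Because the two
objective spaces are conjugated through their tube lenses, a primary
displacement `d` is equivalent to a remote displacement
`d · (f_tl2/f_tl1)²` = 3.18 d for the 180/321 mm pair. All lengths are
carried in micrometres internally; constructors take the conventional
units (mm for focal lengths).

Objective focal lengths are derived as `f_design / M_nominal`; vendors
do not publish them directly and the 180 mm standard is implied by the
tube lenses used. Ray tracing, pupil modelling and aberration theory are
out of scope.

## Synthetic scenes (`opmcal.scene`)

The simulator emulates the three bead preparations the analyses need:
coverslip-immobilised bead layers (thin z-slab fields), the same fields
stepped to a series of depths, and agarose-suspended fields scanned
obliquely. Its statistical structure is, by construction, exactly the
structure each estimator assumes — linear radial growth of PSF widths,
radial displacement proportional to radius and depth, illumination
linear in scan step — so recovery tests are well-posed.

**PSF field.** Beads render as separable anisotropic 3D Gaussians. A
diffraction or vectorial PSF model would be unidentifiable by the
pipeline, whose estimators are themselves Gaussian fits. FWHMs grow
linearly with field radius and |depth|:

| parameter | default | meaning |
|---|---|---|
| `fwhm_lat0` | 255 nm | lateral FWHM at centre/focus |
| `fwhm_ax0` | 688 nm | axial FWHM at centre/focus |
| `radial_growth` | 8×10⁻⁴ /µm | fractional growth per µm of field radius |
| `depth_growth_lat` | 2×10⁻³ /µm | lateral growth per µm of depth |
| `depth_growth_ax` | 3×10⁻³ /µm | axial growth per µm of depth |

Defaults emulate a well-aligned remote-focusing train: ~255/688 nm at
centre focus with roughly 10% centre-to-edge growth across a 200 µm
field. Real instruments' radial growth differs between lateral and
axial; the model uses a single coefficient, which is sufficient for the
pipeline's linear-trend recovery checks.

**Distortion.** Axial misconjugation is modelled as a radial scaling of
lateral bead positions about the image centre, `1 + k·z` at depth `z`,
with `k = 1.5×10⁻⁴ /µm per mm` of remote-objective displacement from its
optimum (placed at +0.4 mm from the nominal design position). The
coefficient is chosen so the error stays below ~0.5% for ±10 µm depths
over the ±3 mm misalignment equivalent to routine ±1 mm focusing travel
— the regime a well-built instrument operates in. Positive error means
apparent magnification increase.

**Scan series.** An oblique scan at mirror-voltage ratio ρ and objective
position `z` applies a per-step global illumination factor
`1 + G·(ρ − ρ_opt(z))·(s − (n−1)/2)` to a fixed agarose-like bead
projection, plus fresh camera noise per step. The injected optimum is
linear, `ρ_opt(z) = 1.015 + 0.0025·z` (spanning the 1.013–1.041 sweep
window over 0–9 mm of travel), and the gain default `G = 0.1` per unit
ratio mismatch per step produces intensity trends of up to ~±14% across
a 100-step scan at the largest mismatches — clearly visible, as on a
real instrument. Frames share identical expected content: the series
isolates the illumination model, which is what the calibration assumes;
bead turnover between steps (a random walk in frame totals) is real but
is not part of the linear model and is deliberately not injected.
Geometrically faithful oblique volumes (tilted-plane sampling of the 3D
Gaussians) are rendered separately by `render_oblique_stack` for the
deskew analyses.

**Noise.** Poisson shot noise, Gaussian read noise (σ = 1.6 counts) and
a 100-count camera offset, clipped at zero. The default flux of 7000
expected photons per bead gives a peak SNR ≈ 20 at the default voxel
size (108.3 nm pixels, 150 nm steps, 54 planes). No published bead
densities or SNRs exist for this kind of acquisition; these are declared
stand-ins, not reproductions. Fixed-pattern noise, shadowing and
light-sheet propagation are not modelled.

All renders are bit-reproducible from `SceneTruth.seed` (or an explicit
`seed=` override).

## PSF metrology (`opmcal.psf`)

The cascade: best-focus frame → wavelet detection → provisional 2D fit
→ axial 1D fit → lateral refit at each bead's own best plane. When the
provisional fit fails (a bead defocused at the globally sharpest frame),
the axial profile is taken at the raw candidate position instead, so the
bead can still be recovered from its own best plane; a bead is flagged
only if no plane yields an acceptable lateral fit.

- **Focus metric**: variance of the 4-neighbour discrete Laplacian
  (LAPV), the standard form of the second-derivative sharpness family.
  Ties break toward the stack centre.
- **Detection**: à-trous (undecimated) B3-spline wavelet transform,
  implemented with dilated `[1,4,6,4,1]/16` convolutions. Detection on
  plane W2 (the scale of a diffraction-limited spot), threshold 3 robust
  SDs (MAD × 1.4826) of the plane, connected components of ≥ 9 pixels,
  candidates at intensity-weighted centroids, merged within a 5 px
  minimum separation. The minimum component area was sized on blank
  noise frames for a < 1% per-frame false-positive rate; for noise-free
  images, where the MAD collapses to zero, the threshold falls back to
  1% of the plane maximum. All parameters are configurable; none are
  published for this class of pipeline.
- **Lateral fit**: axis-aligned elliptical Gaussian + constant
  background on an 11×11 ROI (half-width 5 px ≥ 3σ at the enforced bead
  separations), unweighted least squares, bounds σ ∈ [0.3, 10] px. A fit
  is rejected when the ROI is border-clipped, a parameter pins at a
  bound, the centre leaves the ROI, or R² < 0.8. FWHM = 2√(2 ln 2) σ.
  The reported "lateral" FWHM is the mean of the x and y fits; whether a
  rotated major axis should be reported instead is a convention choice,
  and x/y are also kept per record.
- **Axial fit**: the z-profile is sampled at the fitted sub-pixel (x, y)
  by bilinear interpolation (for a separable Gaussian this rescales the
  profile without distorting its shape) and fitted with a 1D Gaussian +
  offset. Profiles peaking within 2 planes of either stack end are
  rejected as unbracketed.

On noise-free renders the estimators are model-matched and essentially
exact (bias ≪ 0.1%); at the default SNR, ~500-bead scene means recover
the injected widths to well within 2%.

## Distortion mapping (`opmcal.distortion`)

Beads at depth Z are matched to the Z = 0 reference in polar
coordinates: candidates within a 2° angular tolerance (the matching
angle tolerance is not a published quantity; 2° is configurable),
nearest radius wins, one-to-one enforced greedily by ascending |Δr|,
unmatched beads dropped. The per-depth radial displacement is fitted vs.
radius **through the origin** — under the radial-scaling model a bead at
the centre cannot displace — giving the fractional magnification error;
error % vs. depth is likewise fitted through the origin (Z = 0 is the
self-reference), giving an error rate in %/µm. The zero crossing of an
OLS line through error rate vs. remote displacement yields the optimal
remote-objective position, with a delta-method standard error; crossings
outside the sampled range are returned with a warning. Non-radial
distortion models (skew, anisotropic scaling) are out of scope.

## Scan calibration (`opmcal.scancal`)

Summed frame intensity (all pixels — no ROI masking), optionally
offset-corrected, normalised by its mean; OLS slope vs. step index;
OLS line of slope vs. ratio whose root is the optimal ratio; OLS line of
optimum vs. objective position as the calibration. The slope–ratio
relationship is treated as linear throughout (it is observed to be on
the instrument this emulates; no higher-order model is offered). The
camera offset must be subtracted when frames carry a dark level —
otherwise the normalised slope shrinks by the signal/(signal+offset)
ratio — so the analyses pass the known simulator offset; on a real
instrument this is the measured dark level. Step index, not physical X,
is the regressor; the conversion is presentation-only.

## Deskew (`opmcal.deskew`)

The oblique acquisition samples cartesian space on the shear grid
`x = s·Δs + i·p·cosθ, y = j·p_y, z = i·p·sinθ`. The deskewed grid uses
X voxel = scan step and Z voxel = `p·sinθ`, so the oblique axis lands
exactly on output planes and interpolation acts only along the scan
axis. The output container requires scan step = camera Y pixel (square
XY voxels), which is the standard acquisition choice (117 nm at 28°).

Interpolation default is **cubic spline** (`scipy.ndimage` prefiltered
order 3). At near-Nyquist sampling (~1 sample per lateral σ along the
scan axis) linear interpolation behaves on average like convolution
with a triangle kernel, adding ~Δ²/6 of variance — several percent of
fitted FWHM — whereas the interpolating cubic spline is width-preserving
to well under 1%. `linear` and `nearest` remain available (`nearest` for
count-preserving QC); the geometric round trip (centroids to < 0.5
voxel) holds already under `linear`. Intensity is interpolated, not
integrated, and is conserved to ≪ 1% away from borders because the
output voxel volume equals the input sampling volume (Jacobian
`Δs·p_y·p·sinθ`).

## Problem sizes and what the tests show

The validation scenes are sized for single-CPU runs while keeping every
estimator in its operating regime: the PSF scene uses ~500 beads over an
88 µm field (54 planes × 150 nm); the distortion sweep uses 70 beads
over 34 µm, five depths (0, ±10, ±20 µm) and eleven displacements (±5 mm
in 1 mm steps); the calibration sweep uses the full 15 ratios × 10
positions × 100 steps; the deskew cross-check uses 40 beads at the
native 117 nm oblique sampling. Passing these tests shows that the
estimators are unbiased and precise **for data satisfying the injected
models** — Gaussian PSFs, strictly linear distortion and illumination
trends, ideal camera noise. They do not certify behaviour under real
instrument effects (non-Gaussian aberrated PSFs, shadowing, drift,
fixed-pattern noise), and the simulator defaults are plausible operating
points, not measurements.
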