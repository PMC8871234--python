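# Methods

## Coordinate system and geometry

`x` is the lateral scan direction and coincides with the artery's
longitudinal axis; `y` is elevation (out of the imaging plane); `z` is
depth below the transducer face. The artery axis runs along `x` at
`y = 0`, `z = 17.5` mm. Radial wall motion therefore lives in the
imaging plane at `y ~ 0` and longitudinal motion is a pure `x`
translation.

The default artery is a 5 mm lumen with a 0.7 mm intima–media complex
(IMC) and a 0.3 mm adventitia, i.e. layer radii 2.5 / 3.2 / 3.5 mm. The
single IMC thickness is split into intima and media sub-layers 1:6 (a
typical histological ratio); the split only affects which scattering
variance a scatterer receives, not the kinematics. Radial layer
intervals are half-open with the boundary point assigned to the outer
layer. The default tissue block spans 10 mm laterally, 4 mm in
elevation and 11–29 mm in depth, covering the full midline evaluation
range; desk-scale runs trim the lateral extent to the scanned width
plus a beam margin.

## Scatterer phantom

The scatterer count is `density x block_volume / cell_volume` with a
default density of 10 per resolution cell — the classical threshold for
fully developed speckle. The resolution cell is a configuration-derived
closed form: axial = half the two-way pulse length (`n_cycles x
lambda / 2` = 0.308 mm at 5 MHz), lateral = `F#_rx x lambda` (0.524 mm),
elevation = `elevation_focus x lambda / element_height` (1.232 mm).
Positions are uniform in the block; amplitudes are `Normal(0, variance
of the layer)`. The lumen is anechoic by default (variance 0; every
motion operation leaves lumen scatterers static), and "blood" scatterers
can be enabled simply by giving the lumen a non-zero variance.

The per-layer variances default to intima 1.0, media 0.1, adventitia
0.8, surrounding 0.35 — chosen to reproduce the characteristic
double-line wall appearance (bright lumen–intima interface, hypoechoic
media, bright adventitia) — and can instead be scaled from a reference
B-scan with `variance_from_bscan`, which maps mean 0–255 ROI brightness
per layer proportionally onto variances with the brightest layer at a
reference value.

A guard rejects phantoms above 5 million scatterers.

## Motion model

For a scatterer with *reference* radial coordinate `y0` and reference
lateral position `x0`, frame `f` applies

* radially: `y(f) = y0 + d_radial(f)/2 * slope_radial(y0)` along the
  outward radial unit vector in the (y, z) plane — half the
  diameter-change waveform per wall, with `slope_radial(y) =
  exp(-b1 (y - r_l))` beyond the lumen radius, `b1 = 0.17 mm^-1`;
* longitudinally: `x(f) = x0 + d_longitudinal(f) * slope_longitudinal(y0)`
  with a plateau of 1 across the IMC and `exp(-b2 (y - r_ma))` beyond
  the media–adventitia radius, `b2 = 1.08 mm^-1`.

Slopes are evaluated at the reference coordinate and positions are
computed as reference plus total displacement. This makes the animation
frame-order independent, numerically stable, and exactly consistent
with the closed-form ground truth used as the error reference; at these
amplitudes the difference from incrementally re-evaluating the slope at
the moved coordinate is second order. Proximal/distal symmetry is
exact. The lumen diameter follows `D(f) = D0 + d_radial(f)`; a
`lag_one_frame` flag exposes the alternative one-frame-delayed indexing
convention (default off, the delay being read as notational). A
waveform large enough to push a wall scatterer across the axis raises
an error.

Ground truth for a midline grid point is Lagrangian: the estimators
track the scatterers initially at the point, so the reference
coordinate is recovered by inverting the frame-0 radial motion map
(fixed-point iteration, a few steps suffice) before evaluating the
analytic displacement series.

## Motion waveforms

Measured traces are band-pass filtered 0.5–8 Hz with a 4th-order
Butterworth applied forward–backward (zero phase; order and family are
implementation choices, only "band-pass IIR" being prescribed), mean
subtracted, and one manually selected cycle is FFT-resampled to the 45
imaging frames; the time axis is never normalized. Peak-to-peak
normalization is a pure linear scaling about the mean.

The surrogate generator stands in for unavailable in vivo recordings.
The radial channel has a strict minimum at frame 0 and maximum at frame
8 (t = 8/52 ~ 0.154 s), so the M-mode extremes fall at t1 = 0 and
t2 ~ 0.15 s. Its systolic upstroke is a monotone PCHIP through
fractions (0, 0.35, 0.85, 1.0) of the rise interval (frames 5–8),
followed by an exponential diastolic decay (tau = 0.18 s) with an
optional dicrotic bump. With 45 frames at 52 fps the three systolic
inter-frame steps are 0.35/0.50/0.15 of the peak-to-peak level; per
wall that places 0, 1 and 2 frame pairs beyond the half-wavelength
(154 um) cross-correlation ambiguity bound at 0.5, 0.75 and 1.0 mm
peak-to-peak — reproducing the reported ambiguity behaviour of
echo tracking at the higher amplitudes. The longitudinal channel rises
more gently (peak ~0.25 s) and is bidirectional by default (antegrade
systolic lobe, retrograde excursion), per the consensus waveform types.
All morphology parameters are exposed.

## Virtual scanner

A full spatial-impulse-response simulation is deliberately replaced by
a separable depth-dependent PSF model (hours per frame versus seconds;
`RenderBackend` is a documented protocol so a genuine
impulse-response engine can be substituted). Each scatterer contributes
amplitude x axial pulse x lateral weight x elevation weight:

* axial pulse: two-way Hanning-windowed 2-cycle cosine at 5 MHz,
  evaluated continuously at the exact delay `2 z / c` and sampled at
  40 MHz — no nearest-sample rounding, so sub-sample motion stays
  observable;
* lateral weight: Gaussian with -6 dB width `F#_rx x lambda` (dynamic
  receive focusing holds the receive F-number constant) broadened in
  quadrature by the transmit defocus term
  `F#_tx x lambda x (z/z_tx - 1)` away from the 15.5 mm transmit focus;
* elevation weight: Gaussian from the 16 mm elevation lens,
  one-way -6 dB width `(z_el/h) lambda sqrt(1 + 4 (z/z_el - 1)^2)`;
  the same lens acts on transmit and receive, so the applied two-way
  sigma is the one-way sigma divided by sqrt(2).

No attenuation or TGC is modeled. Rendering is linear in amplitudes
and bitwise deterministic. B-mode is the Hilbert envelope
log-compressed to [-73, 0] dB; M-mode stacks one line's columns over
frames; multi-cycle sequences tile the single cycle (quasi-periodic
assumption) and additive white Gaussian noise at a stated per-frame SNR
is available, seeded.

Because the renderer is not an impulse-response engine, RF-sample-level
agreement with any particular scanner simulation is out of scope by
construction; displacement-level results are the comparison surface.

## Estimators

**1DCC.** Windows of two pulse lengths (64 samples) with 75 % overlap;
search bounded by the half-wavelength ambiguity limit; normalized
cross-correlation with parabolic sub-sample refinement; conversion
`c/(2 fs)` = 19.25 um per sample. A window is invalid when its peak
sits at the search boundary, the implied shift reaches 95 % of
lambda/2, the window is (near) silent, the peak correlation is below
0.25, or the carrier-free envelope correlation disagrees with the RF
peak by more than a quarter wavelength — the signature of the RF peak
having aliased onto a neighbouring carrier cycle (the plain magnitude
rule cannot see shifts that fold back under lambda/2).

**Optical flow.** RF frames are normalized to unit peak, envelope
detected, expressed in dB, floored at -90 dB and mapped to 0–255. A
Gaussian pre-filter of sigma = size_filter/2 (size filter 4) is
applied. The initial field is Horn–Schunck (lambda1 = 120, standard
weighted-average iteration) computed coarse-to-fine on a 2-level
pyramid — two levels resolve the ~6-pixel systolic steps without the
over-smoothing across the anechoic lumen that deeper pyramids showed —
followed by Liu–Shen refinement (lambda2 = 3000) on the warped residual
pair, repeated in three warp-and-refine passes. The Liu–Shen equations
minimize `integral (I_t + div(I u))^2 + lambda2 |grad u|^2`; the
discretization uses central differences for first derivatives, a
compact face-centred flux stencil for the `div(I^2 grad)` terms and a
4-neighbour Laplacian, solved by damped Jacobi iteration (cap 120,
mean-update tolerance 1e-4; hitting the cap returns the best iterate
with a warning).

Flow is sampled onto the same (line x window) grid the 1DCC uses, by
echo-energy-weighted averaging (linear energy recovered from the log
display image — the weighting a correlation window applies implicitly).
The footprint is channel-specific: the radial channel matches the
64-sample correlation window so the two estimators report the same
functional; the longitudinal channel uses about one pulse length only,
because the `b2` decay collapses longitudinal motion within a
millimetre of the wall and a wall-wide footprint would mix collapsed
tissue motion into the wall estimate. A small across-line footprint
averages estimator noise and is exact for this phantom, whose motion
field does not vary along the artery axis. Pixel-to-micrometre
conversion respects the axial/lateral anisotropy (19.25 vs 62.5 um).

**Accumulation.** Inter-frame fields are integrated relative to frame 0
by semi-Lagrangian advection: each grid point's trajectory position
(reference + accumulated displacement) samples the next inter-frame
field bilinearly. Invalid entries (dead lumen windows hold zeros) are
replaced by their nearest valid neighbour before interpolation so they
cannot drag adjacent trajectories toward zero; validity itself is
propagated — a trajectory that leaves the grid or crosses an invalid
window is masked from that frame on.

**Wall-trace measurements.** Displacements that exceed half a
wavelength (inter-extreme-frame shifts, M-mode wall separation) are
measured in two stages: inter-frame tracking with window re-centring
builds a carrier-cycle-unambiguous but drift-prone trajectory prior,
then a drift-free direct frame0-to-f correlation is resolved to the RF
peak nearest that prior. The M-mode wall-separation reading anchors one
window per wall at the nominal lumen–intima interface, offset 0.2 mm
toward the lumen so the innermost (fastest) wall layer dominates, and
reports the per-frame median over several scan lines. Any finite
correlation window weights some sub-interface tissue whose motion has
already decayed, so this reading sits a few percent below the nominal
boundary amplitude; the forward model puts its ceiling at ~95–97 % of
the nominal value.

## Evaluation

NRMSE = RMS(estimate - theory over the cycle) / std(theory), per axial
position on the midline (19 positions, 11–29 mm). Band medians over the
proximal (14–15 mm) and distal (20–21 mm) wall bands exclude
masked-invalid samples rather than imputing them, mirroring
"not available" gaps where echo tracking is ambiguous. Point-wise
estimator comparisons (1DCC vs optical flow; optical flow vs
longitudinal theory) are evaluated at one selected mid-wall midline
point per wall (14.5 and 20.5 mm) — windows straddling the lumen–intima
interface average across a motion discontinuity, which measures the
window footprint rather than estimator quality. Medians pool over axial
positions of per-position NRMSE (not over time windows).

## Problem sizes

Desk-scale runs scan 40 lines (2.5 mm) around the midline with the
block trimmed laterally accordingly. The 0.5 mm validation run keeps
the full speckle density of 10 scatterers per resolution cell
(~13 600 scatterers, ~35 s on one CPU); the 1 mm echo-shift and M-mode
runs use a quarter density (~3 400 scatterers, seconds), which is
sufficient for windowed correlation on the bright wall echoes. The
full-width 160-line, full-block configuration (~36 000 scatterers) runs
in a few minutes.

## What the synthetic data does and does not show

The phantom reproduces the geometry, layered scattering contrast,
speckle statistics, motion decay fields and frame timing of a pulsating
CCA scan, so passing tests demonstrate that the estimators recover the
modeled kinematics from realistic speckle. It does not model
attenuation, reverberation or other in vivo artifacts, proximal/distal
asymmetry, viscoelastic or anisotropic tissue behaviour, circumferential
strain, blood flow, or probe motion — conclusions about estimator
accuracy on real recordings are correspondingly limited, and the
surrogate waveform is a morphological stand-in, not a measured trace.

## Known limitations

* The PSF renderer approximates diffraction with separable Gaussian
  beams; side lobes, element directivity and aperture growth limits are
  not modeled.
* The 1DCC ambiguity detector relies on envelope correlation and can
  mislabel windows at very low SNR.
* Optical-flow accuracy degrades at the lateral image edges (fewer
  lines of support), consistent with the known behaviour of global
  variational estimators.
* The M-mode wall-separation reading under-reports the boundary
  amplitude by a few percent by construction (finite window footprint
  over a decaying motion field).
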