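# Methods

`fanpat` models a tomographic photoacoustic scanner built around a 384-element
transducer arc (11.5 cm long, on a dome of 12 cm radius of curvature) that a
motor rotates through 360° in 200 steps of 1.8°, and a fan-shaped diffuse
illuminator (90° × 0.24° divergence) rigidly attached to the arc, shining
through an optical window in the dome. This note records the model, the
numerical choices, and what the bundled synthetic studies do and do not show.

## Coordinate frame and geometry

The origin is the dome's center of curvature; z is the rotation axis, pointing
away from the dome opening; the pose-0 imaging plane is the x–z plane. Element
positions lie on a circle of radius 12 cm centered at the origin, uniformly
spaced along the arc and symmetric about a configurable polar angle (default
45°). Normals point at the dome center; the lateral axis is the arc tangent
toward increasing element index; the elevational axis is normal × lateral. A
tomographic pose is a single rotation about z applied to array and illuminator
together; the sample stays fixed.

The element's elevational extent is not a published quantity; the element area
defaults to pitch × 0.5 cm. Only relative solid-angle weights enter the
reconstruction, so this choice scales weights uniformly and cancels in the
normalization.

The fan's virtual origin is placed on the circle having the window chord as
diameter (so the 90° wide divergence exactly subtends the window arc), aimed at
the window midpoint, with the 0.24° narrow divergence out of plane. Interfaces
take degrees; internals use radians.

## Fluence model

Within a homogeneous scattering medium the fluence of a point source is the
diffusion Green's function Ψ(r) = exp(−μ_eff r)/(4πDr), with
μ_s′ = μ_s(1−g), D = 1/(3(μ_a0+μ_s′)), μ_eff = √(μ_a0/D). Bundled coefficient
sets: breast tissue at 700 nm (μ_s = 10 cm⁻¹, μ_a0 = 0.2 cm⁻¹) and the 50/50
milk/water calibration bath (μ_s = 15 cm⁻¹, μ_a0 = 0.0075 cm⁻¹). The quoted
μ_s values are treated as already-reduced coefficients (g defaults to 0);
g is configurable for users who want to supply μ_s and g separately. An
advisory flag notes when μ_a0/μ_s′ > 0.1 and the diffusion limit is doubtful
(true for the breast set, which is nevertheless the field's standard usage).

The fan fluence is the integral of this kernel over the illuminated dome band,
parameterized by the two divergence angles. The quadrature is a midpoint rule:
patch centers are fan rays intersected with the dome sphere, and each patch
carries its angular measure Δθ·Δφ — the diffuser spreads energy uniformly per
angle, which is also what makes the modeled window profile center-peaked, as
measured profiles are. The patch-count factorization (n_θ × n_φ = n_patches)
follows the fan's aspect ratio, so the default 200 patches form a single row
along the window. Distances are floored at half a voxel spacing to avoid the
1/r singularity at the surface. Because the illuminator rotates with the
array, the map is recomputed per pose. Fluence is relative throughout (an
optional global scale exists); the reconstruction divides by it, so absolute
units cancel.

## Forward model

Each absorbing point emits amplitude ∝ fluence × absorption, scaled by the
element's angular sensitivity and 1/distance spreading, arriving after the
time of flight at 40 MHz sampling; sub-sample delays are split linearly onto
adjacent samples before convolution with the temporal pulse. The default
pulse is a derivative-of-Gaussian wavelet peaked at 5 MHz — a delta pulse
would alias at 40 MHz — but studies that localize argmaxes on 1 mm grids use
a 1 MHz pulse instead: the full-bandwidth point response is a few tenths of a
millimeter wide and would fall between voxel centers. Wires are discretized
as point chains at quarter-voxel spacing. Acoustic attenuation, reflection,
and heterogeneity are not modeled. Arrivals later than the record are simply
absent (a finite record is the physical behavior); a strict mode raises
instead.

Structured noise imitates the DAQ's cross-channel bands: a configurable
number of low-rank (channel-profile ⊗ temporal-burst) components scaled
relative to the clean plane's RMS, plus white noise, plus per-pulse energy
jitter (default ±12.5%, matching the observed 10–15% shot-to-shot
variability) that scales the trace and is recorded in the plane's energy
metadata. The hardware's actual noise spectrum is not quantified anywhere, so
these are calibration knobs, not claims; the defaults make the bands dominate
the leading singular values, which is the regime the denoiser targets.

## Preprocessing

Order is fixed: (1) fifth-order Butterworth low-pass at 14.5 MHz along time
(zero-phase by default, so arrival times survive; a causal single-pass mode
exists), (2) truncated-SVD subtraction of the leading k = 10 components of
the channels × time matrix, per plane (the bands are stochastic, so each
plane is decomposed independently), (3) scaling by reference/pulse energy,
with the scan-mean energy as the default reference. Low frequencies are
deliberately retained before the SVD step; the ramp filter removes them
later. Note that subtracting a rank-k component necessarily removes the
signal's projection onto those row/column spaces — about √(1/channels +
1/samples) of the signal norm — which is the irreducible price of the method;
the retained signal *energy* changes by far less.

## Reconstruction

The inversion evaluates, per voxel, the ramp-filtered record
b(t) = p(t) − t·∂p/∂t (central differences, one-sided at the ends, t from the
laser firing) at t = |r − r_D|/v_s (linear interpolation; v_s = 1500 m/s),
weighted by the solid angle the element subtends from the voxel
(A·cosΘ/d², clipped at grazing) and, optionally, by the separable Gaussian
directivity exp(−θ_L²/2σ_L²)·exp(−θ_E²/2σ_E²) with σ_L = 18.5°, σ_E = 6.2°
— the measured angular sensitivity of the lensed elements. The flat-frequency
-response assumption (point-like elements with purely angular sensitivity)
means there is no deconvolution stage.

The solid-angle prefactor is realized as a weighted mean: per voxel, the
weighted sum of b values divided by the sum of applied weights. Absolute
pressure units are arbitrary. Combining poses uses the same principle
extended over the whole detection surface swept by the rotation: each pose
contributes its weighted sum and its weight sum, and the volume is the global
ratio. This matters once the fluence compensation enters, because each pose's
pressure is divided by that pose's fluence before accumulation (the
illuminator moves with the array, so the absorption estimate cannot be
factored into one final fluence correction). A pose that views a voxel
edge-on, from far away, or outside its directivity cone produces a
noise-level pressure estimate there; dividing that by the pose's tiny fluence
and adding it at full strength floods deep voxels with amplified artifacts. A
plain per-pose sum (`accumulation="sum"`) is retained for comparison and for
single-pose work, where the two coincide up to scale. Voxels whose fluence
falls below ε = 1% of the pose's maximum are masked out of that pose's
contribution and tallied. Negative values are retained; display thresholds
are an evaluation concern.

A literal per-voxel/per-element loop transcription
(`backproject_plane_reference`) is kept in the package; the numba kernel is
required to match it to 1e-9 relative on small instances, and each voxel is
written by exactly one thread, so results do not depend on the parallel
schedule.

## Metrics

SNR is mean amplitude over the peak region (the contiguous run above half the
profile maximum containing the argmax) divided by the standard deviation of
amplitude over the whole evaluated image, in dB as 20·log₁₀; the peak
region's width is the FWHM. RMSE and windowed SSIM (scikit-image, standard
constants) compare normalized images. The relative image error is
‖A − M‖₂/‖M‖₂ against the voxelized phantom model; both volumes are scaled
to unit maximum first (configurable: unit-max, unit-norm, none), since
reconstructions carry arbitrary units and the model is binary. The
depth-resolved version partitions the grid into 50 equal-width spherical
shells of distance from the detector surface (depth = 12 cm − |r|) and
evaluates the same ratio per shell; empty shells are reported as missing, and
the per-shell squared numerators/denominators recombine exactly to the global
error.

## Bundled studies and their scale

The acceptance studies shrink the published acquisition to workstation scale
and state their sizes as package defaults:

- **Localization** (`localization_study`): 10 random point absorbers near the
  rotation axis, noise-free, 32 poses, 64³ voxels at 1 mm, no directivity
  (the check isolates delay geometry). Near the axis the rotated pose planes
  bunch together, so 32 poses azimuthally sample the targets the way 200
  poses sample the full dome. Each source's reconstruction peak (the argmax
  of |volume| in a ±4-voxel window around truth) must land on the voxel
  containing the source or an immediate neighbor along each axis.
- **Depth-error comparison** (`depth_error_study`): three 0.25 mm wires at
  0.8/1.8/2.8 cm depth running tangentially in the imaging plane, milk-bath
  optics, directivity and fan fluence in the forward model, seeded band
  noise at a scan-wide floor, the full preprocessing chain, then all four
  (±directivity, ±compensation) reconstructions scored by depth shell. This
  study keeps the scanner's native 200 × 1.8° pose sampling — angular
  sampling sets the in-plane artifact floor that the comparison is measured
  against, so it is the one dimension not reduced — and evaluates on a
  one-voxel slab through the imaging plane, because the elevational
  point response (several millimetres, set by the σ_E = 6.2° cone) cannot be
  scored against a thin binary wire model. Wires are grid-aligned and
  band-limited-thin, so they reconstruct as line responses rather than
  edge-enhanced shells (a cylinder thicker than the acoustic pulse
  reconstructs only at its boundary, and a wire along the viewing direction
  only at its ends — both well-known band-limitation effects that would
  measure the point-spread function, not the illumination physics).
- **Deep rod** (`deep_rod_study`): a 0.5 mm-diameter rod at 2 cm depth in the
  same acquisition/slab design, reconstructed through the full pipeline with
  noise; SNR and FWHM from a depth-direction profile crossing the rod.

What these reductions preserve: the geometry, the fluence physics, the noise
structure, and every algorithmic stage. What they do not show: absolute SNR
or resolution of the hardware (bandwidth and pose count are reduced),
behavior under acoustic heterogeneity or attenuation (not modeled), or the
validity of the diffusion approximation itself in low-scattering media.

## Degenerate inputs and tie-breaks

Voxels coincident with an element or a patch center are guarded (singularity
error, or the half-voxel distance floor); back-facing voxels get zero
solid-angle weight; voxels beyond every element's record, or masked in every
pose, reconstruct to 0 and are counted. The peak region for SNR/FWHM is the
run containing the global argmax; disjoint secondary runs are ignored.
Rotation angles are taken modulo 360°. All randomness flows through a single
seed per scan; per-pose generators are spawned from it, so scans are
reproducible plane-by-plane.
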