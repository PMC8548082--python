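# Methods

`cryotwin` is a desk-scale digital twin of a cryo-electron tomography
(cryo-ET) experiment: it builds a virtual specimen with known ground
truth, simulates a physically motivated tilt series of transmission
electron microscope (TEM) images, reconstructs the specimen from those
images, and scores the reconstruction against the truth.  Because the
truth is known exactly, the effect of acquisition choices (tilt range,
tilt increment, sample geometry, dose) on reconstruction quality can be
measured directly.  This note records the models, the numerical choices,
and — importantly — which features of a real experiment the desk-scale
defaults do and do not capture.

## Coordinate and Fourier conventions

Right-handed coordinates in Angstrom; the beam travels along −z at zero
tilt; the tilt rotation is about +y; the specimen geometry is centred at
the origin; particle positions are centroids.  Forward Fourier transforms
use the `exp(−2πiqx)` kernel (the numpy/scipy default) with spatial
frequency `q` in cycles/Å.  Angles are degrees at configuration
boundaries and radians internally.  Volumes are indexed `[z, y, x]`, and
voxel `k` of an axis of length `n` sits at `(k − n/2) · voxel_size`.

## Virtual specimen

**Geometry.**  A planar slab (lamella-like) or a cylinder along the tilt
axis.  The cylinder radius and centre offset may vary along its length
through cubic-spline knots, so "natural" non-ideal shapes are
expressible; constant knots reproduce an exact cylinder to floating-point
precision.

**Particles.**  Atomic models come from PDB/mmCIF files (parsed with
gemmi; every ATOM/HETATM record is kept with its occupancy) or from the
built-in phantom generator: `n` atoms uniformly distributed in a ball
with a protein-like C/N/O/S mix.  A uniform random cloud has no
accidental point symmetry, which makes orientation handling testable.
When a mean atom density is requested (default 0.05 atoms/Å³,
heavy-atom protein density), occupancies are scaled so a phantom carries
the integrated potential of a full-density particle even when represented
by fewer discrete atoms — the coarse-graining that keeps the sweeps fast.
Placement is rejection sampling (bound: 10⁴ attempts per particle, then a
loud error) with bounding-sphere overlap tests; the bounding radius is
the maximum atom distance from the centroid.  A single requested particle
defaults to the geometry centre.  Random orientations are uniform over
SO(3) via the quaternion (Shoemake) method.

**Milling.**  Arbitrary regions can be cut from a built sample by a
signed point predicate; particles are then baked to world-frame atom
sets, and instances left empty are dropped.

**Amorphous ice.**  Two models:

* *random_water*: rigid H₂O molecules (O–H 0.9572 Å, 104.52°) at uniform
  random positions and orientations, `round(ρV)` molecules at default
  ρ = 0.031 molecules/Å³ (≈0.93 g/cm³).  No minimum-distance constraint
  is applied; relaxing contacts would need molecular dynamics and is out
  of scope.
* *grf*: a continuum Gaussian random field for the ice potential, with a
  Gaussian correlation function `exp(−r²/2ℓ²)` (spectrum
  `∝ exp(−k²ℓ²/2)`), mean equal to the vitreous-ice mean inner potential
  (4.87 V by default), and user-set variance and correlation length ℓ.
  The Gaussian spectrum family is a documented stand-in for a measured
  amorphous-ice structure factor and is pluggable at one function
  boundary.

Samples persist to a self-describing HDF5 schema (version attribute,
explicit group layout) with bit-exact atom coordinates.

## Image formation

**Atomic potential.**  A screened-Coulomb (Wentzel) atom with the
Thomas–Fermi radius `R = 0.885·a₀·Z^(−1/3)` is reduced to one Gaussian
per element matched in integrated potential (`4π·e_k·Z·R²`,
`e_k = 14.3996 V·Å`) and projected mean-square radius (`⟨b²⟩ = 4R²`).
Kernels are additionally widened by half a pixel so sub-pixel atoms stay
resolvable on the grid.  The single-Gaussian table is a stated accuracy
limitation relative to modern multi-parameter scattering-factor fits; the
coefficient table is pluggable.  At the ≥1 Å sampling used here the
difference is confined to frequencies near and beyond the aperture.

**Multislice.**  The specimen is rotated to the tilt angle and divided
into slices of `t_s = 5 Å`; each slice's projected potential (V·Å) is the
sum of its atoms' projected Gaussians.  A unit plane wave alternates
phase-object transmission `exp(iσV)` (σ is the relativistic interaction
constant, 6.53·10⁻⁴ rad/(V·Å) at 300 keV) with Fresnel propagation
`exp(−iπλt_s q²)`.  An anti-alias aperture at 2/3 of Nyquist is applied
at every propagation step; electrons scattered beyond it leave the beam,
which is the mechanism by which thick ice attenuates the image.  With
zero potential the propagation is unitary to better than 10⁻⁶.

**Continuum ice in the simulator.**  Projecting the 3D GRF over one slice
yields a 2D random screen with variance `σ_V²·√(2π)·ℓ·t_s` and lateral
spectrum `exp(−k²ℓ²/2)`.  Each slice receives an independent in-band
screen realization (synthesized spectrally, confined to the rotated
sample interior) plus the mean-inner-potential phase; the spectral power
beyond the aperture — for sub-pixel ℓ the large majority, matching the
fact that real water scatters mainly into the 2.7 Å ring, far beyond a
4 Å-pixel band — is applied as an analytic absorption term
`exp(−σ²P_out/2)` per slice.  Consequence: the continuum ice is
statistically stationary but not tilt-consistent (each projection sees a
fresh realization); the atomistic water model is tilt-consistent but
costly at scale.

**Radiation damage.**  The specimen potential is damped by
`exp(−q²B/4)` with `B = 8π²·D_E·S_E`, linear in accumulated dose `D_E`
through the sensitivity `S_E` (default 0.022 Å²/e⁻).  In the pipeline the
filter is applied analytically — the Gaussian kernels widen by
`D_E·S_E` — which is exactly the Fourier filter for this atom model and
costs nothing; the standalone Fourier implementation exists and a test
pins the two routes together.  Damage is applied to the structured
(particle) potential and not to the stationary continuum ice: beam-driven
rearrangement keeps amorphous ice statistically amorphous, so its
spectrum is treated as dose-independent.  Dose bookkeeping: for the k-th
acquired image (1-based), `D_E = k · flux · exposure` (damage accrues
during the exposure itself); the dose-symmetric ordering therefore gives
the low tilts the least-damaged specimen.

**Optics.**  The contrast transfer function uses
`χ(q) = πλΔf q² − (π/2)C_sλ³q⁴` with underfocus positive, plus an
optional phase-plate shift.  Temporal coherence: defocus spread
`δF = C_c·√((ΔE/E*)² + (ΔV/V)² + (2ΔI/I)²)` with the relativistically
corrected energy scale `E*`, applied as a Gaussian rms envelope
`exp(−½(πλδF q²)²)`.  Spatial coherence: a Gaussian source of rms angular
spread θ_c damps by the squared aberration-phase gradient,
`exp(−2π²θ_c²(Δf q − C_sλ²q³)²)`.  The image is
`|F⁻¹[F[ψ]·E(q)e^(−iχ)]|²` applied to the exit wave (linear transfer on
the full wave).  Defaults describe a 300 keV instrument: Δf = 2.5 µm,
C_s = C_c = 2.7 mm, ΔE = 0.8 eV, ΔV/V = 0.8 ppm, ΔI/I = 0.33 ppm,
θ_c = 0.1 mrad.

**Detector.**  Expected counts are `intensity · dose · d_px²`, filtered
in Fourier space by a parametric
`DQE(q) = DQE₀(1 − a(q/q_N)²)` (clipped at 0; DQE₀ = 0.8, a = 0.5 by
default — the functional form is a modelling choice, no standard curve is
implied), then Poisson-sampled.  The defocus gradient across a tilted
specimen within one image is not modelled (a single nominal defocus per
image); the per-particle defocus is honoured at correction time instead.

## Reconstruction and scoring

**Phase flipping.**  `F[out] = F[in]·sign(sinχ·E)` corrects the contrast
inversions only; applying it twice is the identity.  Per-particle
correction evaluates the CTF at the particle-centre defocus (nominal
defocus minus the particle's beam-axis offset at that tilt).

**Weighted back projection.**  Each projection is ramp-filtered along x
with a weight equal to its local angular gap (directions taken modulo
180°, nearest-gap rule at range edges, exact duplicates sharing their
direction's weight); for uniform full-range sampling this reduces to the
classical ramp.  Filtered projections are back-projected with linear
interpolation.

**Per-particle reconstruction.**  For each particle (poses known exactly
from the ground truth; there is no alignment search) a box-sized patch is
interpolated around the projected particle centre in every image,
converted to fractional contrast against its own mean (the per-particle
normalization convention of subtomogram processing), normalized by
removing its mean along the tilt axis (the container body — slab or
cylinder — is uniform along y, and its projected background otherwise
dominates the `q_y = 0` plane of every particle), phase-flipped, and
back-projected into a cube.  The reference volume gets the identical
y-mean normalization before comparison.  Because the patch mean is
Poisson-noisy on heavily attenuated projections, normalization amplifies
the noise of dark high-tilt frames — a real property of per-particle
processing that contributes to the high-tilt penalty the missing-wedge
study measures.

**Subtomogram averaging.**  Boxes are rotated to the reference frame,
their Fourier transforms multiplied by the correspondingly rotated
missing-wedge mask (sampled directions: `(q_x, q_z)` within the tilt
range of the x-axis; optional cosine soft edge), summed, and divided by
the summed mask with a Wiener-style floor of 10⁻³ of its maximum; regions
never covered are zero-filled and reported.

**FSC.**  Shells are one frequency voxel wide up to the Nyquist sphere.
`FSC_i = Re⟨F_aF_b*⟩_i / √(⟨|F_a|²⟩_i⟨|F_b|²⟩_i)`; zero-power shells are
recorded as undefined and excluded, with their counts, from the
element-count-weighted average `FSC_avg = ΣN_iFSC_i / ΣN_i`.  Resolution
bins split at half Nyquist (a declared convention).  Plane-restricted
averages bin only elements within ±15° of the named reciprocal plane (the
slab convention, declared in outputs).

## The scaled-down study and what it shows

The headline in-silico experiments compare acquisition schemes on planar
and cylindrical samples with the total dose held constant.  A full-scale
study (micron fields, 1 Å pixels, 90 projections, thousands of particles
averaged) is far beyond a desk budget, so the sweep defaults preserve the
*dimensionless* quantities that govern the physics and coarse-grain the
rest:

* **Thickness-to-mean-free-path ratio.**  The planar high-tilt penalty is
  controlled by `D₀/Λ`, the zero-tilt thickness over the beam mean free
  path.  The sweeps use a 240 Å slab (or a 240 Å-diameter cylinder) with
  the continuum-ice variance calibrated in closed form
  (`grf_variance_for_attenuation`) so that the zero-tilt elastic loss
  equals `exp(−D₀/Λ)` at `D₀/Λ = 200/314 ≈ 0.64` — the thick-lamella
  condition, where the high-tilt information starvation is strongest.
  The slab is 8× wider than thick, so the beam path (and hence the
  attenuation) saturates at grazing tilts exactly as for a real lamella.
* **Sampling and dose.**  4 Å pixels and voxels, 64³ particle boxes,
  48 projections, 100 e⁻/Å² total dose split equally among projections,
  6 particles of a 45 Å-radius phantom at protein density.  With these
  numbers a zero-tilt image carries ~7 counts/pixel inside the specimen
  while a planar image beyond ~75° tilt carries well under one — the
  same "high tilts contribute almost nothing" regime as a full-scale
  lamella series, reached at 16× the pixel dose.
* **Paired replicates.**  Conditions that differ only in the acquisition
  scheme share the specimen and ice random streams, like one physical
  sample imaged under several schemes; scheme comparisons are paired, and
  replicate seeds vary the specimen.
* **Orientations.**  Sweep particles share a fixed orientation, which
  makes the missing-wedge anisotropy fully visible in the average (random
  orientations would rotate the wedges apart and partially fill Fourier
  space).

What passing sweeps do *not* show: absolute FSC values comparable to a
full-scale study (the desk-scale averages combine 6 particles, not
thousands, so FSC magnitudes are small and meaningful only relatively);
tilt-consistent ice noise; alignment errors (poses are known exactly);
holder shadowing; inelastic/chromatic blurring beyond the loss model.
The sweep outputs are ordinal/qualitative reproductions of full-scale
behaviour, not absolute predictions.

One full-scale ordering is out of reach at this scale and its test is
left failing rather than weakened: the advantage of a fixed projection
count over a fixed tilt increment.  That advantage requires the
sampling-limited regime (quality rising with projection count at constant
total dose), which needs enough particle averaging to make counting noise
negligible; with a handful of particles the loop is noise-limited, and
concentrating the dose into fewer projections ties or wins.

The "stops improving" tilt of the planar curve is reported as the
smallest maximum tilt whose median quality is within one standard error
(estimated from the pooled across-replicate scatter) of the curve
maximum — a pre-declared plateau rule, robust to a flat or noisy top.

The projection-economy analysis compares the no-wedge cylinder against a
120°-tilt-range planar condition: for each operating point `(N_w, Q_w)`
of the planar quality-vs-N envelope, the minimal projection count at
which the cylinder envelope reaches `Q_w` is interpolated, and the
fraction `N_ref/N_w` reported.  At constant total dose the planar curve
plateaus very early at desk scale (per-image SNR trades against angular
sampling), so matching both conditions by "minimal N at a fixed level"
would be degenerate; matching against the wedge condition's operating
points is the construction that remains meaningful — and is what a
full-scale fraction-of-projections figure measures.

## Numerical choices and degenerate inputs

* Anti-alias aperture at 2/3 Nyquist, applied at every propagation step.
* Splat kernels truncate at 4 widths; pixel-sampling of marginally
  resolved kernels makes the analytic and Fourier damage routes agree to
  ~2%, which bounds the discretization error of the potential.
* FFT sizes are chosen smooth (scipy `next_fast_len`); transmission is
  applied only on the occupied window of each slice.
* Rejection placement retries with perturbed sub-seeds when a tight
  packing strands the last particle (deterministic).
* Scan plans: `fixed_count` places angles uniformly including both
  endpoints; `fixed_increment` steps symmetrically through 0°;
  dose-symmetric ordering breaks |angle| ties positive-first.
* Stage translation and beam drift offset the specimen before each
  exposure (pre-exposure convention, documented on the drift model); the
  recorded image is of the already-displaced specimen.
* Degenerate inputs fail loudly: <2 projections for WBP, empty FSC shell
  selections, mismatched grids, schema-version mismatches, |tilt| ≥ 90°
  in the planar thickness formulas.

## Known limitations

* The single-Gaussian atomic potential overestimates low-angle scattering
  relative to tabulated factors (screened-Coulomb amplitude); relative
  contrasts between elements are Z-weighted correctly.
* Per-slice ice realizations mean ice "structural noise" does not
  reconstruct coherently across tilts; its effect enters as per-image
  noise plus absorption.
* The FEI-style extended MRC header uses this package's own record layout
  (exttyp `CTW1`), carrying tilt angle, defocus, exposure, accumulated
  dose and pixel size; it is not a bit-exact emulation of vendor headers.
* No GPU path; everything is numpy/scipy on one core.
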