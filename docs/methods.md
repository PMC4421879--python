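# Methods

This note records the models behind `gipct`, the defaults and why they
were chosen, what the synthetic studies do and do not demonstrate, and the
numerical choices a maintainer would want written down.

## Instrument model

The interferometer is two gratings under quasi-parallel monochromatic
illumination.  All design quantities are closed-form:

* Wavelength λ = hc/E with hc = 1.23984 keV·nm.  A "3 significant
  figures" rounding mode exists alongside full precision because the
  headline bench numbers (z_T = 3024 mm at 25 keV) are only reproduced
  with λ rounded to 0.0496 nm; full precision gives 3026 mm.  Formula
  outputs otherwise carry full precision, and visible rounding (nearest
  mm, 2 s.f. shifts, 0.1 mm field of view) is applied at the reporting
  layer only.
* Talbot distance z_T = p d²/(2λ), odd p.  Even p is rejected: a phase
  grating has no intensity self-image there.
* Tilted analyser: inclining G2 by angle θ toward the optical axis spreads
  the G1–G2 distance by Δz = ±(extent/2)·sin θ across the field of view.
  Since z_T ∝ 1/λ, the spread is equivalent to a relative wavelength
  spread 2Δz/z_T; at 45° on a 25 mm grating this is 5.8 × 10⁻³, small
  enough to treat the tilted instrument as achromatic.
* Grating phase shift scales as φ ∝ 1/E (δ ∝ λ² at fixed thickness).
  This is a model assumption valid away from the grating material's
  absorption edges; no tabulated δ(E) is bundled.
* Beam-path transmission is Beer–Lambert over caller-supplied
  (μ/ρ, ρ, t) entries.  No attenuation database is embedded — published
  μ/ρ tables differ between versions, and bundling one would pin results
  to it.  With the standard water coefficient at 25 keV
  (0.5075 cm² g⁻¹) a 25 mm water cell transmits 28 %.
* The detector's effective pixel is native/magnification (6.5/0.425 =
  15.29 µm) unless an explicit calibrated override is supplied; the
  reference instrument's calibrated value is 15.5 µm and its field of
  view 2048 × 15.5 µm = 31.7 mm.  Both numbers cannot be derived from one
  another — the override exists precisely because bench calibration and
  nominal optics disagree at the percent level.

## Scan scheduling

The sample rotates continuously while G2 steps N times per projection at
the trigger cadence (exposure + readout + settle; defaults 0.5/0.05/0.03 s).
One stepping series must fit one projection's angular span, so the stage
speed is X_proj/T = (X_total/Y)/(N·cadence) pulses s⁻¹, truncated to an
integer — truncation, not rounding, because a faster stage would outrun
the stepping.  The default protocol (Y = 600, N = 5, X_total = 90000 at
0.002°/pulse) gives 51 pulses s⁻¹ and a rotation-limited 29.4 min scan; a
three-step variant is exactly 3/5 of the stepping period.

Flat-field blocks (default: a full N-step series) are scheduled at t = 0
and after every completed flat interval, including the 180° endpoint;
whether an initial block exists is configurable since either convention is
defensible.  Per-block stage-translation overhead defaults to 0 s and is a
parameter: measured totals exceed the rotation-limited time by an amount
that depends on the flat mechanics of the specific beamline.

## Phantoms

Two scenario families, both deterministic functions of their parameters
(the seed is reserved for future texture options):

* **Fetus-like body** — nested ellipsoids in saline (ρ_w = 1.000 g cm⁻³):
  body 1.030, liver 1.055, brain-like organ 1.040 g cm⁻³.  The fresh
  liver density is not an experimentally established value; it is a
  parameter, chosen so that the fixed state (+0.015 g cm⁻³) sits at the
  1.07 g cm⁻³ a fixed liver exhibits.  The `fetus_fixed` variant shrinks
  the liver isotropically about its centroid by 35 % of its volume
  (linear factor 0.65^⅓) and raises every tissue compartment by the
  configured increment — fixation in this model changes volume and
  density but conserves nothing by design, so liver mass falls.
  Shrinkage is isotropic because only volumes, not strain fields, are
  analysed downstream.
* **Ring vessel (aorta segment)** — an annular cylinder along the
  rotation axis with two wall layers: inner (intima-like) 1.060, outer
  (externa-like) 1.045 g cm⁻³, giving a bimodal wall histogram.  Stretch
  step k of K elongates the cylinder by 1 + 0.08k and raises both layer
  densities linearly so that the step-K increment equals the configured
  total (default 0.005 g cm⁻³); each layer's cross-section then follows
  from mass conservation ρ·V = const, so the wall thins.  The generator
  stores the analytic layer volumes/densities in `meta`, and a test
  verifies that the voxelized grid integrates to them within 0.5 %.

Compartment surfaces are anti-aliased over one voxel in the density grid
(integral quantities converge quadratically); the label map thresholds
coverage at one half.  Default grids are 128³ at 0.1 mm voxels;
the studies below use 64³–96³.

Optical conversion: δ = r_e λ² N_A (Z/M) ρ/2π per voxel with Z/M = 0.55
(soft-tissue average) — at 25 keV a density step of 1 g cm⁻³ is
Δδ ≈ 3.65 × 10⁻⁷.  Attenuation is a single proportionality
μ = 0.0507 mm⁻¹ per g cm⁻³ (water at 25 keV): absorption is not the
signal here, it only sets photon statistics, and a one-constant model
keeps the module database-free.

## Forward model and retrieval

Projection is parallel-beam (the modelled station sits hundreds of metres
from the source): the volume is rotated about the vertical axis (linear
interpolation, matching the classical rotate-and-sum Radon evaluation,
validated against `skimage.transform.radon` on odd-sized grids where both
share a rotation centre) and summed along the beam.  δ is integrated
*relative to the saline*, mirroring a measurement flat-fielded against
the water cell, so the background stepping phase is zero.  The stepping
phase is ψ = (2π z_T/d₂)·∂t/∂x with central differences on the pixel
grid (one-sided at edges); ψ is positive where δ increases toward +x and
the reconstruction uses the same sign.

Stepping frames have expected counts gain × budget × trans × s_k, where
s_k is 1 + V cos(2πk/N + ψ) for the sine profile or the even unit-period
triangle wave for fully coherent illumination.  Poisson sampling acts on
photons, then the gain multiplies — so count variance is gain × mean,
the photon-limited regime of a lens-coupled scintillator camera with
several counts per X-ray photon.  Step positions are assumed ideal
(closed-loop piezo).  Detector blur is off by default.  Two fixed
per-pixel imperfections exist for artefact studies: a multiplicative
gain error (which cancels exactly in the retrieved phase — a useful
negative control) and a flat-drift stepping-phase offset (which survives
retrieval and backprojects into rings).  `flat_budget_factor` (default 8)
samples the reference at a multiple of the frame budget and rescales,
representing the several flat blocks accumulated over a scan; without it
a single noisy flat imprints a fixed ring pattern whose few angular
degrees of freedom make background statistics unstable.

Retrieval is the standard first-harmonic estimator: I₀ = mean,
a₁ = (2/N)Σ I_k e^{−2πik/N}, ψ = arg a₁, V = |a₁|/I₀ — exact for a
noiseless sinusoid at any N ≥ 3, and identical to the linear
least-squares sinusoid fit at equally spaced steps.  Flat correction
divides I₀ and V and subtracts ψ (wrapped to (−π, π], with the nearest
flat block in angle); a per-row 1-D unwrapper is provided for strongly
refracting edges.  Pixels with zero mean intensity are flagged invalid
rather than propagated as NaN.

**Triangle-profile visibility.**  The triangle wave's first Fourier
harmonic is 8/π² ≈ 0.811 of its peak modulation.  With fine stepping the
retrieved visibility matches this to <0.5 %.  At N = 3 or 5, however, the
triangle's higher odd harmonics alias into both the first harmonic and
the mean (at N = 5 the net retrieved visibility is ≈ 1.3 % above
(8/π²)·V_peak), so the 8/π² transfer is checked at N = 64 and the coarse-
stepping values are checked against the exact Fourier alias sums.  This
is the quantitative basis for preferring three-step stepping only when
the measured profile is sine-like.

## Reconstruction

Slice-by-slice filtered backprojection over [0°, 180°).  Because ψ is the
derivative of the projected phase, the ramp |f| is replaced by
sgn(f)/(2πi) (ramp divided by the derivative's 2πif); the scale factor
d₂/(2π z_T) converts ψ to ∂t/∂x so voxels come out as Δδ relative to the
medium — absolute δ never appears.  Numerical choices:

* The Hilbert kernel decays only as 1/x, so sinogram rows are
  zero-padded to the next power of two ≥ 8× the detector width before
  FFT filtering; at 2× padding the circular wrap-around biases the DC
  level by ≈1.5 %.
* A Hann window apodizes the kernel up to Nyquist (default on): an
  unwindowed sign filter amplifies high-frequency noise.  The window is
  irrelevant to interior means of smooth structures.
* Backprojection is linear interpolation on the detector coordinate;
  the rotation centre is (n−1)/2 throughout the package.
* Validation is two-route: the same ψ sinograms are also integrated
  along x (trapezoid) and reconstructed with an independently written
  classical ramp FBP; on a 64² cylinder the two routes agree to <1 % RMS
  of the contrast over the inscribed circle, and the noiseless round
  trip recovers a cylinder's interior Δδ to 0.1 %.

The ring-artefact score of a slice is the standard deviation of the
polar-angle-averaged radial profile over a background annulus: rings are
concentric, so they survive angular averaging while pixel noise does not.

## Densitometry

Δρ = calibration × Δδ × 2π/(r_e λ² N_A (Z/M)); ρ = ρ_w + Δρ.  The
calibration factor is an opaque scalar: on the reference instrument it is
1.45, determined from standard samples and attributed mainly to the
detector; the simulator has no detector bias to calibrate away, so
simulation self-consistency mode uses 1.0.  Constants are fixed in one
place: r_e = 2.8179 × 10⁻¹⁵ m, N_A = 6.022 × 10²³ mol⁻¹.

ROI statistics use the sample (n−1) standard deviation throughout.
Histograms use uniform bins (default 0.002 g cm⁻³) and report modes as
local maxima above 5 % prominence of the tallest bin.  Volume is voxel
count × voxel volume; mass is Σρ dV.  Density resolution is the
background standard deviation in mg cm⁻³.  Segmentation is deliberately
minimal — a density threshold plus largest connected component — since
anything subtler is the analyst's job and masks are accepted as inputs.

## Synthetic studies and their scope

* **Fixation comparison** (64³, 600 angles, noiseless): fresh and fixed
  fetus phantoms through the whole chain; the liver is segmented at the
  body/liver density midpoint, its interior mean density on a 2-voxel
  eroded core.  Recovered: volume ratio 0.635 (injected 0.65 — the
  ≈1.5 % deficit is curvature bias of threshold segmentation on the
  smaller, more blurred fixed liver), density increment 0.0149 g cm⁻³
  (injected 0.015), mass decrease.
* **Stretch series** (96³, 300 angles, noiseless): six stretch states;
  the wall ROI is an annular band that lies inside the inner wall layer
  at its thinnest (final-step) geometry — the same specimen position
  throughout, as a fixed ROI box on a thick wall would be.  96³ rather
  than 64³ because the thinned inner layer must stay several voxels
  thick for its reconstructed plateau to be resolved.  Recovered: ROI
  mean rises monotonically, total increment 0.0047 g cm⁻³ against the
  configured 0.005 cap; step-0 wall histogram is bimodal.
* **Exposure series** (64² × 4 slices, 240 angles, 5 seeds): budgets
  proportional to exposure with 860 photons/pixel/frame at the 100 ms
  reference (the measured flux through the system), visibility 0.3,
  gain 7.  Background density resolution improves strictly with
  exposure and follows 1/√exposure within a few per cent; the ring
  score is non-increasing (endpoint comparison plus rank trend — with
  finite seeds the adjacent-pair differences at long exposures are
  within estimator noise).  At the 500 ms-equivalent budget the
  simulated resolution lands at ≈1.5 mg cm⁻³ — the low-mg cm⁻³ regime
  a real instrument of this class reaches, though the exact value is
  geometry- and instrument-specific and is logged as a diagnostic, not
  asserted.

What these studies show: the chain is quantitatively self-consistent —
injected densities, volumes and their changes are recovered through
simulation, retrieval, reconstruction and conversion, and noise behaves
photon-limitedly.  What they do not show: fidelity to real specimens.
The phantoms have piecewise-constant compartments, no anatomy, no motion,
no beam hardening, no partial coherence, no scintillator blur, and the
fixation/stretch transformations are idealized (isotropic shrinkage,
exact mass conservation).  Agreement here validates the software, not
the biology.

## Known limitations

* Parallel-beam only; no cone/fan geometry.
* No Fresnel propagation or partial-coherence modelling of the
  self-image; visibility is an input, not predicted from coherence.
* Single-shot (Moiré/Fourier) retrieval and interlaced stepping are out
  of scope.
* The derivative is taken on the pixel grid after projection; objects
  touching the grid edge produce one-sided-difference artefacts (a
  warning is emitted).
* Threshold segmentation under-reports volumes of small, strongly curved
  objects by ~1–2 % at 64³; use finer grids when absolute volumes matter.
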