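# Methods

## Image formation model

The package treats reflection-mode iSCAT scalar-optically. The detector
intensity, normalised to the incident intensity, is
`r² + |s|² + 2 r |s| cos Δφ`: the coherent sum of the reference field
reflected at the glass/medium interface (field reflectance `r`, default
0.2) and the field scattered by the object (`s`). The relative phase
`Δφ = (4πn/λ) z + φ_G` combines the round-trip propagation phase of an
object at height `z` above the cover glass with the Gouy phase of the
focused beam. The iSCAT contrast is `C = (I − I_bg)/I_bg`; for a weak
scatterer (`s ≪ r`) it reduces to `2 (s/r) cos Δφ` plus an `(s/r)²`
self-interference offset.

### Parametric axial iPSF

Scanning the focus through a point object or thin interface traces the
axial interferometric PSF, modelled as

    C(z) = A · [1 + (z/z_env)²]^(−p/2) · cos(k_z z + atan(z/z_R) + a_sa (z/z_env)³ + φ₀)

clamped to exactly zero beyond ±`truncation_halfwidth`. Parameters, all
in nm unless noted:

| parameter | default | meaning |
|---|---|---|
| `amplitude` A | 1 | signed peak contrast |
| `axial_wavevector` k_z | 4π·1.33/445 rad/nm | interferometric phase slope |
| `gouy_range` z_R | λ/2 = 222.5 | scale of the arctan Gouy term |
| `envelope_scale` z_env | 400 | envelope half-width-at-half-max ≈ confocal axial FWHM/2 |
| `envelope_power` p | 2 | asymptotic decay power: 2 confocal ("intensity drops quadratically with distance from focus"), 1 wide-field |
| `sa_coefficient` a_sa | 0 | cubic-phase spherical-aberration weight (axial asymmetry) |
| `phase_offset` φ₀ | 0 | residual phase at focus |
| `truncation_halfwidth` | 1500 | support of the fitted/rendered model |
| `lateral_sigma` | 50 | in-focus lateral Gaussian width used in rendering |
| `lateral_growth` | 0.1 | lateral width increase per nm defocus |

The envelope exponent is written `−p/2` so that `p` is the asymptotic
decay power of the *contrast amplitude tracking the detected intensity*:
with `p = 2` the envelope ratio between 10 and 20 envelope scales is
401/101 ≈ 3.97, i.e. the quadratic far-field drop of confocal
detection. The Gouy phase is modelled as `atan(z/z_R)` with `z_R` free;
empirical iPSFs do not pin a functional form, and one parametric form
keeps simulation and inversion consistent. Spherical aberration is
collapsed into a single cubic phase coefficient (default 0); full pupil
models are out of scope, as is vectorial high-NA diffraction.

The lateral confocal amplitude is `h_ill · (h_det ⊗ pinhole disk)`,
each `h` an Airy amplitude `2J₁(v)/v`, `v = 2πNA·r/λ`, the pinhole
diameter given in Airy units (1 AU = 1.22 λ/NA = 374.4 nm at default).
The pinhole convolution is evaluated by quadrature on a radial grid.
Shrinking the pinhole from 1.2 AU to 0.3 AU measurably sharpens the
effective PSF — the working resolution advantage of confocal iSCAT.

Axis convention: `z = 0` at the cover glass, increasing into the
sample; defocus is structure height minus focus position.

## Synthetic scenes and rendering

Phantom generators provide ground truth with the statistical structure
the analyses assume:

* **membranes** — band-limited Gaussian ripples (white noise smoothed
  to a correlation length, rescaled to the requested RMS exactly) over
  an optional parabolic bow; defaults RMS 200 nm / correlation 1 µm,
  matching nuclear-envelope-scale modulations (hundreds of nm over a
  ~900 nm global range).
* **staircases** — 50 nm terraces with an optional bare-glass margin,
  the validation target for height-step recovery.
* **tubule networks** — edges of a Voronoi diagram of random seed
  points: internal vertices generically have degree 3, reproducing the
  three-way junction topology of the ER; radii sampled from 25–50 nm
  (diameters 50–100 nm), default peak contrast 12%.
* **particle ensembles** — Brownian steps of per-axis variance `2DΔt`
  plus drift, reflected at the cover glass; defaults chosen for the
  tracked-vesicle regime (RMSD of order 200 nm over an observation).

Rendering applies thin structures (interfaces, tubules) as a
multiplicative contrast `A · ipsf(z_structure − focus)` on the
reference intensity — matching how the analyses invert them and keeping
cost O(pixels) — while point particles are summed **coherently** into
the reference field, so contrast reversal with axial motion emerges
from the interference itself rather than being imposed. Tubules are
chord-projected and blurred with the in-focus lateral PSF. ER-sheet
fluctuations are emulated by per-pixel sinusoidal height modulation
with static nodes (zero-amplitude pixels). Shot noise is Poissonian at
`photon_budget` expected photons per pixel at background (default 10⁴,
i.e. ~1% contrast noise — enough to see the ~2% contrast of a
microtubule). What the phantoms deliberately omit: speckle from the
out-of-focus cell body beyond the envelope attenuation, refractive
heterogeneity inside volumes, and detector artefacts; passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not performance on arbitrary real recordings.

All generators and the renderer are bit-reproducible under a fixed
seed.

## Background correction and contrast

Backgrounds are estimated per z/time plane by a Gaussian low-pass of
the raw intensity with kernel FWHM a multiple of the PSF FWHM; the
recommended multiple range is 16–32 (values outside warn, not fail) and
the default is 24, the midpoint. Boundaries are mirror-padded to avoid
edge contrast artefacts. Where the field of view contains bare cover
glass, its median reflected intensity may serve as the background
instead (`background_from_region`) — this avoids the bias the blurred
background inherits from structures that fill the field of view, and is
what the staircase validation uses. Temporal background models are out
of scope. Wide-field images can additionally be flat-fielded by a
smooth illumination reference (output renormalised to mean 1).

## Interface reconstruction

Per pixel, the contrast z-profile `C(f) = A·ipsf(z₀ − f)` is inverted
for the interface height `z₀` by one of three estimators:

* **ridge** — strongest |C| extremum, chosen under the peak of the
  Hilbert envelope of the profile (adjacent oscillation lobes are only
  a few percent weaker than the true one, so raw sample argmax is
  unreliable), refined by 3-point parabolic interpolation and shifted
  by the model's extremum offset.
* **matched** (default for stacks) — inner product of the profile with
  model templates centred on a fine grid of candidate heights (grid
  step = z-step/8), peak refined parabolically. Fine sampling matters:
  the correlation oscillates at the iPSF period and coarse sampling
  mis-ranks near-equal lobes. Amplitude sign is not assumed (|corr| is
  scored).
* **fit** — bounded nonlinear least squares over (z₀, A, φ₀),
  initialised from the ridge estimate; accurate but ~ms per pixel.

Validity: per-profile estimates are rejected when the extremum
prominence is below 3 noise sigmas, with sigma estimated spectrally
(top quarter of the profile's spectrum, which the narrowband iPSF
oscillation does not reach); stack reconstruction thresholds the
matched amplitude against the propagated per-pixel noise. Ties between
equal-|C| extrema resolve toward the window centre. A radius-1 median
filter (optional, default on) smooths the final height map. Reconstructed
heights are invariant to global contrast rescaling, as only the phase
structure carries height. Windowed searches allow recovering two
interfaces (e.g. basal and apical envelope) from one profile; deeper
windows may use a different SA coefficient, as aberration grows with
depth. Volumetric index tomography is explicitly not attempted: voxel
contrast inside extended volumes is not directly structural.

Edge sharpness of lateral interface transitions is quantified by the
10–90% width between plateau levels (robust plateau medians, linear
interpolation between samples); a Gaussian-blurred step of width σ
yields 2×1.2816σ ≈ 2.563σ.

## Particle tracking

Localisation uses the radial variance transform: per pixel, the mean
intensity over concentric 1-px annuli (edge-corrected at image borders)
and the variance of those means across radius. The variance is computed
in two passes (a one-pass moment difference cancels catastrophically
when the background offset dwarfs the annular spread). The score is
blind to contrast sign and scales as a² under affine intensity changes
`aI + b`. Peaks above threshold, separated by at least one PSF FWHM,
are refined to sub-pixel by a quadratic fit on the 3×3 neighbourhood
(noiseless bias < 0.1 px; < 0.5 px std at 10⁴ photons and |C| = 0.2).

Linking is greedy frame-to-frame optimal assignment (Hungarian on the
distance matrix, candidates within `max_disp`), with gap bridging up to
`memory_frames` and a minimum trajectory length of 25 localisations —
tracks shorter than that are discarded. At the sparse densities of
interest this reproduces the behaviour of standard single-particle
trackers without depending on one.

Axial conversion inverts `C(t) = c_max cos(π z/d + φ₀)` on a continuous
phase branch; `d` is the full-inversion distance `λ/(4 n_eff)`
(111.25 nm → 110 nm at λ = 445 nm, `n_eff = 1`) or can be derived from
the model's local phase slope (`Calibration.from_model`), which adds
the Gouy contribution near focus. Per-frame phase increments take the
smallest |Δphase| consistent with the measured |C|; the `inward_only`
prior (endocytic pits can only move into the cell) forbids reversals of
the cumulative displacement. The branch start φ₀ is estimated from the
first frame (branch nearest focus) unless supplied, and an explicit
`initial_phase` is anchored to the nearest measured branch. Limitations
are inherent to the cosine: at a contrast extremum, crossing and
reflection are indistinguishable from |C| alone, so the inversion is a
left inverse of the forward model only while the phase stays inside
(0, π); |C| above `c_max` by ≤10% is clipped (noise headroom), more
raises an error. The effective index entering `d` is exposed rather
than fixed: imaging media span n = 1.33–1.365 while the 110 nm
calibration corresponds to n_eff ≈ 1.

Tubule segmentation thresholds the scale-normalised principal Hessian
eigenvalue at the tubule scale (bright or dark ridges, or the stronger
of the two), followed by small-object removal. Learning-based
segmentation is out of scope. Colocalization between detections and a
reference mask is the fraction of detections inside the mask dilated by
a tolerance radius (the tolerance is a parameter, as no canonical value
exists).

## Dynamics maps

* **Persistency** — per pixel, the longest occupancy run in a boolean
  (t, y, x) stack, tolerating interruptions shorter than a lag period
  (default 5 s); tolerated gaps count toward the run, so 40 frames on +
  a sub-lag 10-frame gap + 40 on scores 90 frames. At lag = one frame
  interval this reduces to the plain maximal run; a `total` mode counts
  non-contiguous occupancy instead. The rule is recorded in the output
  metadata. The gap-tolerant reading is a deliberate choice between two
  defensible definitions.
* **Contrast inversions** — per pixel, sign changes of mean-subtracted
  contrast counted with Schmitt-trigger hysteresis (a crossing
  registers only once the signal exceeds ±h on the far side). Default
  h = 0.25× the per-pixel temporal std: rejects shot-noise chatter
  while keeping ≥2σ oscillations. A noiseless f-cycle cosine scores 2f;
  counts are invariant to sign flips and to affine rescaling when h is
  rescaled identically. Fluctuation nodes (zero programmed motion)
  score 0.

## Problem sizes and numerics

The recovery tests use grids of 64²–256² pixels, z-stacks of ~50–70
planes at 30 nm, 100-realization Monte-Carlo loops for localisation
precision, and 100-particle ensembles over 500 steps for diffusion
recovery; these sizes give estimator statistics well inside the
asserted tolerances while keeping the full suite in the tens of
seconds. Random numbers all flow from explicit seeds
(`numpy.random.default_rng`); CLI runs derive every stage from one
top-level seed and log it with the resolved parameters. TIFF output
carries a JSON sidecar (axes, voxel sizes, frame interval, seed), since
plain multi-page TIFF does not preserve 3–4D axis semantics.
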