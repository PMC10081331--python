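# iscatlab

Simulation and quantitative analysis of **confocal interferometric
scattering (iSCAT) microscopy** — label-free imaging of nanoscopic
cellular structures (nuclear envelope, ER tubules and sheets,
microtubules, clathrin-coated pits, single virions) through the
interference of the light they scatter with a reference reflection from
the cover glass.

## Who this is for

Microscopists and image analysts who want to (a) prototype and validate
iSCAT analysis algorithms against synthetic data with known ground
truth, and (b) run the analyses themselves: background correction and
contrast maps, 3D interface reconstruction from z-stacks, radial-
variance-transform particle tracking with contrast-to-height
calibration, tubule segmentation, and pixelwise dynamics maps.

## The model

In reflection-mode iSCAT the detected intensity is

    I_det / |E_inc|² = r² + |s|² + 2 r |s| cos Δφ,

where `r` is the field reflectance of the glass/medium interface, `s`
the scattered field ratio of a nano-object (∝ its polarizability), and

    Δφ = (4π n / λ) z + φ_G

the relative phase, carrying the object height `z` above the cover
glass and the Gouy phase `φ_G` of the focused beam. The iSCAT contrast
is `C = (I_det − I_bg) / I_bg`. Scanning the focus traces an
oscillatory, sign-reversing axial interferometric PSF, modelled here as
a truncated damped oscillation

    C(z) = A · [1 + (z/z_env)²]^(−p/2) · cos(k_z z + atan(z/z_R) + a_sa (z/z_env)³ + φ₀)

with `k_z = 4πn/λ`, a confocal quadratic intensity envelope (`p = 2`;
`p = 1` wide-field), and a cubic phase term standing in for spherical
aberration. Every analysis in the package is an inversion of this
forward model:

* **surface reconstruction** finds, per pixel, the height `z₀` whose
  model profile best matches the measured contrast z-profile;
* **3D particle tracking** inverts `C(t) = c_max cos(π z/d + φ₀)` on a
  continuous phase branch, where `d = λ/(4 n_eff)` is the axial
  distance of one full contrast inversion (≈110 nm at λ = 445 nm);
* the **radial variance transform** localises particles by the radial
  symmetry of their ringed iPSF, insensitive to the sign flips the
  contrast undergoes with axial motion.

A forward renderer plus phantom generators (rippled membranes,
staircases, three-way-junction tubule networks, Brownian particle
ensembles) replace the microscope, so every stage is testable by
parameter recovery.

## Worked example: membrane topography from a virtual z-stack

```python
import numpy as np
import iscatlab as il

cfg = il.OpticalConfig()          # 445 nm, NA 1.45, 0.3 AU pinhole, r = 0.2
ipsf = il.IPSFModel()             # confocal quadratic envelope, Gouy reversal

# 1. phantom: rippled membrane, RMS 150 nm, correlation length 1 um
ph = il.make_membrane_phantom(shape=(128, 128), ripple_rms=150.0,
                              correlation_length=1000.0, base_height=1000.0,
                              seed=42)
truth = ph.interfaces[0].heights

# 2. virtual z-stack, 30 nm steps, 10^4 photons/pixel at background
focus = np.arange(truth.min() - 450.0, truth.max() + 450.0, 30.0)
plan = il.AcquisitionPlan(focus_positions=focus, photon_budget=1e4)
stack = il.render_acquisition(ph, plan, cfg, ipsf, seed=42)

# 3. background correction -> contrast -> height map
cm = il.stack_contrast(stack.data, psf_fwhm_px=cfg.lateral_fwhm_nm / cfg.pixel_size)
hm = il.reconstruct_surface(cm.values, focus, ipsf, method="matched")
err = (hm.heights - truth)[hm.validity]
print(f"height RMSE:  {np.sqrt(np.mean(err**2)):.1f} nm")

# 4. tracking calibration constant
d = il.full_inversion_distance(cfg, effective_index=1.0)
print(f"full contrast inversion: {d:.2f} nm  (~{round(d, -1):.0f} nm)")
```

Output:

```
height RMSE:  5.2 nm
full contrast inversion: 111.25 nm  (~110 nm)
```

The 5 nm height error on 30 nm z-steps shows the sub-step precision of
matching the full oscillatory profile rather than a single extremum;
111.25 nm ≈ 110 nm is the calibration constant converting a full
contrast swing of a tracked particle into axial displacement.

A command-line front end chains the same stages
(`iscatlab simulate | contrast | reconstruct | track | maps`); see
`iscatlab --help`.

## Documentation

`docs/methods.md` describes the forward model, the estimators, the
phantom generators and their parameters, numerical choices, and known
limitations.
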