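"""Forward rendering of phantoms into noisy iSCAT intensity stacks.

Interfaces and tubules are thin structures, so their signal is applied as
a multiplicative contrast on the reference intensity: each contributes
``A * ipsf(z_structure - focus)`` per pixel, with tubules additionally
convolved laterally with the in-focus PSF.  Point particles are instead
summed coherently into the reference field, so contrast reversal with
axial motion emerges from the interference itself — the behaviour the
contrast-to-height tracking inverts.

Shot noise is Poissonian at ``photon_budget`` expected photons per pixel
at background level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import gaussian_filter

from .optics import IPSFModel, OpticalConfig, axial_ipsf
from .phantoms import AcquisitionPlan, Phantom, Tubule
from .stackio import ImageStack


def _tubule_map(tubule: Tubule, shape, pixel_size, lateral_sigma) -> np.ndarray:
    """Peak-normalised lateral footprint of one tubule (chord-projected, blurred)."""
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float) * pixel_size
    dist2 = np.full(shape, np.inf)
    pts = tubule.polyline
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        if L2 == 0:
            d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        else:
            u = np.clip(((xx - x0) * dx + (yy - y0) * dy) / L2, 0.0, 1.0)
            d2 = (xx - (x0 + u * dx)) ** 2 + (yy - (y0 + u * dy)) ** 2
        dist2 = np.minimum(dist2, d2)
    r2 = tubule.radius**2
    chord = np.sqrt(np.clip(r2 - dist2, 0.0, None)) / tubule.radius
    blurred = gaussian_filter(chord, lateral_sigma / pixel_size)
    peak = blurred.max()
    return blurred / peak if peak > 0 else blurred


def render_acquisition(phantom: Phantom, plan: AcquisitionPlan,
                       cfg: OpticalConfig, ipsf: IPSFModel,
                       seed: int | None = 0) -> ImageStack:
    """Render a phantom through the optical model into an intensity stack.

    Returns an :class:`ImageStack` whose axes depend on the plan:
    ``yx`` (single frame), ``zyx`` (z-stack), ``tyx`` (time series) or
    ``tzyx``.  Intensities are normalised to the incident intensity, so
    the noiseless background level is ``r^2``.
    """
    if plan.photon_budget is not None and plan.photon_budget <= 0:
        raise ValueError("photon_budget must be positive")
    r = cfg.reference_reflectivity
    unit_ipsf = dataclasses.replace(ipsf, amplitude=1.0)
    ny, nx = phantom.shape
    n_t, n_z = len(plan.frame_times), len(plan.focus_positions)
    wide = plan.mode == "widefield"
    if wide and unit_ipsf.envelope_power != 1.0:
        unit_ipsf = dataclasses.replace(unit_ipsf, envelope_power=1.0)

    tub_maps = [_tubule_map(t, phantom.shape, phantom.pixel_size, ipsf.lateral_sigma)
                for t in phantom.tubules]

    rng = np.random.default_rng(seed)
    out = np.empty((n_t, n_z, ny, nx), dtype=np.float32)
    for ti, t in enumerate(plan.frame_times):
        for zi, focus in enumerate(plan.focus_positions):
            contrast = np.zeros((ny, nx))
            for iface in phantom.interfaces:
                dz = iface.height_at(t) - focus
                contrast += iface.amplitude * axial_ipsf(dz, unit_ipsf)
            for tub, tmap in zip(phantom.tubules, tub_maps):
                contrast += (tub.amplitude * tmap
                             * axial_ipsf(tub.z - focus, unit_ipsf))
            field = np.full((ny, nx), r, dtype=complex)
            for p in phantom.particles:
                pos = p.positions
                if len(pos) == n_t:
                    idx = ti
                else:
                    dt_traj = phantom.meta.get("dt")
                    idx = (min(int(round(t / dt_traj)), len(pos) - 1)
                           if dt_traj else min(ti, len(pos) - 1))
                x, y, z = pos[idx]
                dz = z - focus
                if abs(dz) > unit_ipsf.truncation_halfwidth:
                    continue
                sigma = ipsf.lateral_sigma + ipsf.lateral_growth * abs(dz)
                half = int(np.ceil(4 * sigma / phantom.pixel_size))
                cx, cy = x / phantom.pixel_size, y / phantom.pixel_size
                x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
                y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
                x0, x1 = max(x0, 0), min(x1, nx)
                y0, y1 = max(y0, 0), min(y1, ny)
                if x0 >= x1 or y0 >= y1:
                    continue
                yy, xx = np.mgrid[y0:y1, x0:x1]
                rho2 = (((xx - cx) ** 2 + (yy - cy) ** 2)
                        * phantom.pixel_size**2)
                lat = np.exp(-0.5 * rho2 / sigma**2)
                phase = unit_ipsf.phase(dz) + p.intrinsic_phase
                field[y0:y1, x0:x1] += (p.amplitude * unit_ipsf.envelope(dz)
                                        * lat * np.exp(1j * phase))
            intensity = np.abs(field) ** 2 + r**2 * contrast
            if plan.photon_budget is not None:
                lam = plan.photon_budget * np.clip(intensity, 0.0, None) / r**2
                intensity = rng.poisson(lam) * r**2 / plan.photon_budget
            out[ti, zi] = intensity.astype(np.float32)

    # squeeze singleton axes into the canonical axis orders
    if n_t == 1 and n_z == 1:
        data, axes = out[0, 0], "yx"
    elif n_t == 1:
        data, axes = out[0], "zyx"
    elif n_z == 1:
        data, axes = out[:, 0], "tyx"
    else:
        data, axes = out, "tzyx"
    dt = float(plan.frame_times[1] - plan.frame_times[0]) if n_t > 1 else 1.0
    dz_step = (float(plan.focus_positions[1] - plan.focus_positions[0])
               if n_z > 1 else cfg.z_step)
    return ImageStack(
        data=data, axes=axes, pixel_size=phantom.pixel_size,
        z_step=abs(dz_step), frame_interval=dt,
        z_positions=plan.focus_positions if n_z > 1 else None,
        meta={"seed": seed, "reference_reflectivity": r,
              "photon_budget": plan.photon_budget, "mode": plan.mode},
    )
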