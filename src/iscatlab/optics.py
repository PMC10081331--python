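"""Interferometric scattering (iSCAT) image formation model.

In reflection-mode iSCAT the detector sees the interference of the
reference field reflected at the cover glass (field reflectance ``r``)
and the field scattered by a nano-object (field ratio ``s``),

    I_det / |E_inc|^2 = r^2 + |s|^2 + 2 r |s| cos(dphi),

where the relative phase ``dphi = (4 pi n / lambda) z + phi_G`` carries
the axial position ``z`` of the object above the cover glass and the
Gouy phase ``phi_G`` of the focused beam.  Scanning the focus therefore
produces an oscillatory, sign-reversing axial point-spread function
(the iPSF), which this module parameterises for both forward simulation
and inversion of contrast into height.

All lengths are in nanometres, angles in radians, intensities
dimensionless (normalised to the incident intensity).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import j1


class InvalidConfiguration(ValueError):
    """An optical parameter is outside its physical domain."""


class DegenerateBackground(ValueError):
    """Background intensity is non-positive; contrast is undefined."""


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument constants of the confocal iSCAT microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in nm (blue diode laser, 445 nm).
    numerical_aperture : float
        Objective NA.
    medium_index : float
        Refractive index of the imaging medium (1.33 water;
        1.365 for iodixanol-matched cytoplasm).
    pinhole : float
        Confocal pinhole diameter in Airy units, 1 AU = 1.22 lambda / NA.
    pixel_size, z_step : float
        Lateral and axial sampling in nm.
    reference_reflectivity : float
        Field reflectance r of the glass/medium interface, in (0, 1].
    """

    wavelength: float = 445.0
    numerical_aperture: float = 1.45
    medium_index: float = 1.33
    pinhole: float = 0.3
    pixel_size: float = 30.0
    z_step: float = 30.0
    reference_reflectivity: float = 0.2

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidConfiguration("wavelength must be positive")
        if self.numerical_aperture <= 0:
            raise InvalidConfiguration("numerical aperture must be positive")
        if self.pinhole <= 0:
            raise InvalidConfiguration("pinhole must be positive")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise InvalidConfiguration("sampling steps must be positive")
        r = self.reference_reflectivity
        if not 0 < r <= 1:
            raise InvalidConfiguration("reference reflectivity must be in (0, 1]")

    @property
    def airy_unit_nm(self) -> float:
        """One Airy unit, 1.22 lambda / NA, in nm."""
        return 1.22 * self.wavelength / self.numerical_aperture

    @property
    def axial_wavevector(self) -> float:
        """Interferometric axial wavevector 4 pi n / lambda in rad/nm."""
        return 4.0 * np.pi * self.medium_index / self.wavelength

    @property
    def lateral_fwhm_nm(self) -> float:
        """Approximate in-focus lateral PSF FWHM, 0.51 lambda / NA."""
        return 0.51 * self.wavelength / self.numerical_aperture


@dataclass(frozen=True)
class IPSFModel:
    """Parametric axial/lateral interferometric PSF.

    The axial profile is a truncated oscillation

        C(z) = A * [1 + (z/z_env)^2]^(-p/2)
                 * cos(k_z z + atan(z/z_R) + a_sa (z/z_env)^3 + phi0)

    clamped to exactly zero outside ``|z| > truncation_halfwidth``.
    ``p = envelope_power`` is the asymptotic decay power of the envelope:
    2 for confocal detection (intensity drops quadratically with distance
    from the focal plane), 1 for wide-field.  The arctan term is the Gouy
    phase, responsible for contrast reversal through focus; the cubic
    phase term is a one-parameter stand-in for spherical aberration,
    which breaks the axial symmetry of the measured iPSF.
    """

    amplitude: float = 1.0
    axial_wavevector: float = 4.0 * np.pi * 1.33 / 445.0
    gouy_range: float = 222.5
    envelope_scale: float = 400.0
    envelope_power: float = 2.0
    sa_coefficient: float = 0.0
    phase_offset: float = 0.0
    truncation_halfwidth: float = 1500.0
    lateral_sigma: float = 50.0
    lateral_growth: float = 0.1

    def __post_init__(self) -> None:
        if self.envelope_scale <= 0:
            raise InvalidConfiguration("envelope_scale must be positive")
        if self.truncation_halfwidth <= 0:
            raise InvalidConfiguration("truncation_halfwidth must be positive")
        if self.lateral_sigma <= 0:
            raise InvalidConfiguration("lateral_sigma must be positive")

    def envelope(self, z_defocus):
        """Axial contrast envelope, 1 at focus, ~|z|^-p far from focus."""
        z = np.asarray(z_defocus, dtype=float)
        return (1.0 + (z / self.envelope_scale) ** 2) ** (-self.envelope_power / 2.0)

    def phase(self, z_defocus):
        """Total interferometric phase at defocus z (rad)."""
        z = np.asarray(z_defocus, dtype=float)
        return (
            self.axial_wavevector * z
            + np.arctan(z / self.gouy_range)
            + self.sa_coefficient * (z / self.envelope_scale) ** 3
            + self.phase_offset
        )


@dataclass(frozen=True)
class PointScatterer:
    """A point-like scatterer: position above the cover glass and field ratio.

    ``amplitude`` is the dimensionless scattered-to-incident field ratio
    |s|, proportional to the polarizability of the object.
    """

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    amplitude: float = 0.01
    intrinsic_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidConfiguration("scatterer amplitude must be >= 0")
        if self.position[2] < 0:
            raise InvalidConfiguration("scatterer z must be >= 0 (above cover glass)")


def interferometric_intensity(r, s_mag, dphi):
    """Detected iSCAT intensity, normalised to the incident intensity.

    Implements ``r^2 + s^2 + 2 r s cos(dphi)``, i.e. |r + s e^{i dphi}|^2.

    Parameters
    ----------
    r : float or array
        Reference field reflectance, > 0.
    s_mag : float or array
        Scattered field magnitude, >= 0.
    dphi : float or array
        Relative phase between scattered and reflected fields (rad).
    """
    r = np.asarray(r, dtype=float)
    s_mag = np.asarray(s_mag, dtype=float)
    if np.any(r <= 0):
        raise InvalidConfiguration("reference reflectance r must be positive")
    if np.any(s_mag < 0):
        raise InvalidConfiguration("scattered field magnitude must be >= 0")
    out = r**2 + s_mag**2 + 2.0 * r * s_mag * np.cos(np.asarray(dphi, dtype=float))
    return out if out.ndim else float(out)


def iscat_contrast(i_det, i_bg):
    """iSCAT contrast C = (I_det - I_bg) / I_bg.

    With I_det from the interference law and I_bg = r^2 this reduces to
    (s^2 + 2 r s cos dphi) / r^2, i.e. ~ 2 (s/r) cos dphi for s << r.
    """
    i_det = np.asarray(i_det, dtype=float)
    i_bg = np.asarray(i_bg, dtype=float)
    if np.any(i_bg <= 0):
        raise DegenerateBackground("background intensity must be positive")
    out = (i_det - i_bg) / i_bg
    return out if out.ndim else float(out)


def axial_ipsf(z_defocus, model: IPSFModel):
    """Axial iPSF contrast at defocus ``z_defocus`` (nm).

    Zero exactly outside the truncation window; inside, an envelope-damped
    cosine of the total interferometric phase.  Exhibits the sign reversals
    (contrast inversions) characteristic of iSCAT defocus series.
    """
    z = np.asarray(z_defocus, dtype=float)
    out = model.amplitude * model.envelope(z) * np.cos(model.phase(z))
    out = np.where(np.abs(z) <= model.truncation_halfwidth, out, 0.0)
    return out if out.ndim else float(out)


def _airy_amplitude(v):
    """Normalised Airy field amplitude 2 J1(v) / v, 1 at v = 0."""
    v = np.asarray(v, dtype=float)
    small = np.abs(v) < 1e-9
    safe = np.where(small, 1.0, v)
    return np.where(small, 1.0, 2.0 * j1(safe) / safe)


def lateral_confocal_amplitude(radius, z_defocus, cfg: OpticalConfig,
                               lateral_growth: float = 0.0,
                               n_grid: int = 257):
    """Scalar confocal detection amplitude vs lateral radius (nm).

    The confocal amplitude PSF is the product of the illumination Airy
    amplitude and the detection Airy amplitude convolved with the pinhole
    disk (diameter ``cfg.pinhole`` Airy units).  The profile is widened
    with defocus by ``lateral_growth`` (nm of extra width per nm of
    defocus) and normalised to 1 at r = 0, z = 0.

    A small pinhole sharpens the profile toward the product of two Airy
    amplitudes; a wide pinhole degrades it toward the illumination-only
    (wide-field) response.
    """
    if cfg.pinhole <= 0:
        raise InvalidConfiguration("pinhole must be positive")
    radius = np.asarray(radius, dtype=float)
    # defocus widening: rescale the radial coordinate
    widen = 1.0 + lateral_growth * abs(float(z_defocus)) / max(cfg.lateral_fwhm_nm, 1e-9)
    r_eff = radius / widen

    pinhole_radius_nm = 0.5 * cfg.pinhole * cfg.airy_unit_nm
    k_lat = 2.0 * np.pi * cfg.numerical_aperture / cfg.wavelength

    # detection amplitude convolved with the pinhole disk, evaluated on a
    # radial grid by 2-D quadrature (the profile is radially symmetric)
    r_max = float(np.max(np.abs(r_eff))) + pinhole_radius_nm
    grid_r = np.linspace(0.0, max(r_max, pinhole_radius_nm) * 1.05 + 1.0, n_grid)
    n_disk = 41
    du = np.linspace(-pinhole_radius_nm, pinhole_radius_nm, n_disk)
    uu, vv = np.meshgrid(du, du, indexing="ij")
    inside = uu**2 + vv**2 <= pinhole_radius_nm**2
    uu, vv = uu[inside], vv[inside]
    # h_det sampled at |r_vec - u| for each disk sample u
    dist = np.sqrt((grid_r[:, None] - uu[None, :]) ** 2 + vv[None, :] ** 2)
    h_det_pinhole = _airy_amplitude(k_lat * dist).sum(axis=1) / uu.size

    det = np.interp(np.abs(r_eff), grid_r, h_det_pinhole)
    det0 = h_det_pinhole[0]
    ill = _airy_amplitude(k_lat * r_eff)
    out = ill * det / det0
    return out if out.ndim else float(out)


def full_inversion_distance(cfg: OpticalConfig, effective_index: float = 1.0) -> float:
    """Axial displacement producing one full contrast inversion, in nm.

    A pi change of the interferometric phase (4 pi n_eff / lambda) z flips
    the sign of the cosine term, so the distance is lambda / (4 n_eff).
    This is the calibration that converts the contrast swing of a tracked
    nanoparticle into an axial displacement.
    """
    if effective_index <= 0:
        raise InvalidConfiguration("effective index must be positive")
    return cfg.wavelength / (4.0 * effective_index)


# ---------------------------------------------------------------------------
# flat key-value serialisation (one parameter per line, nm / rad / unitless)

def save_config(obj, path) -> None:
    """Write an OpticalConfig or IPSFModel as ``key = value`` lines."""
    kind = type(obj).__name__
    lines = [f"# {kind}"]
    for key, val in asdict(obj).items():
        lines.append(f"{key} = {val!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path):
    """Read an OpticalConfig or IPSFModel written by :func:`save_config`."""
    text = Path(path).read_text().splitlines()
    kinds = {"OpticalConfig": OpticalConfig, "IPSFModel": IPSFModel}
    cls = None
    fields: dict[str, float] = {}
    for line in text:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            name = line.lstrip("# ").strip()
            if name in kinds:
                cls = kinds[name]
            continue
        key, _, val = line.partition("=")
        fields[key.strip()] = ast.literal_eval(val.strip())
    if cls is None:
        raise ValueError(f"{path}: missing '# OpticalConfig' or '# IPSFModel' header")
    return cls(**fields)
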