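"""Background estimation and conversion of intensity stacks to contrast maps.

The iSCAT contrast C = (I - I_bg) / I_bg requires the reference (background)
intensity per pixel.  Where no bare-glass region is available, the
background is approximated by a strong Gaussian low-pass of the raw image;
an appropriate kernel lies between 16 and 32 PSF FWHM — wide enough to
blur the structures of interest into the background, narrow enough to
follow slow illumination variations.  Stacks are treated plane by plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import gaussian_filter

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

KERNEL_RANGE_FWHM = (16.0, 32.0)
DEFAULT_KERNEL_MULTIPLE = 24.0  # midpoint of the recommended range


class KernelRangeWarning(UserWarning):
    """The background kernel lies outside the recommended 16-32 FWHM range."""


@dataclass
class ContrastMap:
    """Dimensionless contrast array with the background used to compute it."""

    values: np.ndarray
    background: np.ndarray
    kernel_fwhm_multiple: float | None = None
    meta: dict = dfield(default_factory=dict)


def estimate_background(image, psf_fwhm_px: float,
                        kernel_fwhm_multiple: float = DEFAULT_KERNEL_MULTIPLE):
    """Low-pass Gaussian background of a raw intensity image (or stack).

    The kernel FWHM is ``kernel_fwhm_multiple`` times the lateral PSF FWHM
    (both in pixels).  Values outside the 16-32 range are allowed but emit
    a :class:`KernelRangeWarning`.  3-D/4-D inputs are blurred per 2-D
    plane (the last two axes).  Boundaries are mirror-padded.
    """
    image = np.asarray(image, dtype=float)
    if kernel_fwhm_multiple <= 0:
        raise ValueError("kernel_fwhm_multiple must be positive")
    if np.any(image <= 0):
        raise ValueError("background estimation requires strictly positive intensities")
    lo, hi = KERNEL_RANGE_FWHM
    if not lo <= kernel_fwhm_multiple <= hi:
        warnings.warn(
            f"kernel multiple {kernel_fwhm_multiple} outside the recommended "
            f"[{lo:.0f}, {hi:.0f}] PSF-FWHM range",
            KernelRangeWarning, stacklevel=2)
    sigma_px = kernel_fwhm_multiple * psf_fwhm_px * _FWHM_TO_SIGMA
    sigma = (0,) * (image.ndim - 2) + (sigma_px, sigma_px)
    return gaussian_filter(image, sigma, mode="mirror")


def contrast_map(image, background, *, kernel_fwhm_multiple=None) -> ContrastMap:
    """Elementwise contrast (I - I_bg) / I_bg."""
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=float)
    if image.shape != background.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs "
                         f"background {background.shape}")
    if np.any(background <= 0):
        raise ValueError("background must be strictly positive")
    return ContrastMap(values=(image - background) / background,
                       background=background,
                       kernel_fwhm_multiple=kernel_fwhm_multiple)


def stack_contrast(stack_data, psf_fwhm_px: float,
                   kernel_fwhm_multiple: float = DEFAULT_KERNEL_MULTIPLE) -> ContrastMap:
    """Convenience: per-plane background estimate + contrast in one call."""
    bg = estimate_background(stack_data, psf_fwhm_px, kernel_fwhm_multiple)
    return contrast_map(stack_data, bg, kernel_fwhm_multiple=kernel_fwhm_multiple)


def background_from_region(stack_data, glass_mask):
    """Per-plane background from the median intensity of a bare-glass region.

    Where the field of view contains bare cover glass, its reflected
    intensity is the reference level directly; this avoids the bias a
    blurred background inherits from extended structures.  Returns an
    array broadcast to the stack shape.
    """
    data = np.asarray(stack_data, dtype=float)
    mask = np.asarray(glass_mask, dtype=bool)
    if mask.shape != data.shape[-2:]:
        raise ValueError("glass_mask must match the lateral stack shape")
    if not mask.any():
        raise ValueError("glass_mask is empty")
    med = np.median(data[..., mask], axis=-1)
    bg = np.broadcast_to(med[..., None, None], data.shape).copy()
    if np.any(bg <= 0):
        raise ValueError("non-positive background median")
    return bg


def flat_field(image, reference):
    """Divide a wide-field image by its illumination profile, mean-1 normalised."""
    image = np.asarray(image, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if image.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    if np.any(reference == 0):
        raise ValueError("reference contains zero pixels")
    out = image / reference
    return out / out.mean()
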