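"""Label-free nanoparticle tracking and tubule segmentation in contrast movies.

Point-like scatterers (clathrin-coated pits, virions) are localised with
the radial variance transform (RVT): for every pixel, the mean intensity
over concentric annuli is computed and the variance of those annular
means across radius scores radial symmetry.  Because the variance is
blind to the sign of the contrast, detection survives the contrast
inversions an iSCAT particle undergoes as it moves axially.

Detections are linked frame-to-frame by optimal assignment within a
search radius; trajectories shorter than a minimum number of
localisations (default 25) are discarded.  A contrast-to-height
calibration — the maximum species contrast c_max and the axial distance
for one full contrast inversion (λ/4n_eff, 110 nm at 445 nm) — converts
each trajectory's contrast time series into relative axial displacement.

Tubular structures (ER) are segmented by a Hessian-eigenvalue ridge
filter at the tubule scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import linear_sum_assignment
from scipy.signal import fftconvolve
from skimage.feature import hessian_matrix, hessian_matrix_eigvals, peak_local_max
from skimage.morphology import remove_small_objects, disk, binary_dilation

from .optics import IPSFModel, OpticalConfig, full_inversion_distance


class CalibrationViolation(ValueError):
    """Measured contrast exceeds the calibrated species maximum."""


@dataclass
class Detection:
    """One particle localisation: frame, sub-pixel position (nm), contrast."""

    t: int
    x: float
    y: float
    contrast: float = 0.0
    score: float = 0.0


@dataclass
class Trajectory:
    """A linked particle track with optional contrast-derived axial path."""

    detections: list[Detection]
    trajectory_id: int = 0
    z_rel: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.t for d in self.detections])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[d.x, d.y] for d in self.detections])

    @property
    def contrast(self) -> np.ndarray:
        return np.array([d.contrast for d in self.detections])


@dataclass
class Calibration:
    """Contrast-to-axial-position calibration for one particle species.

    ``c_max`` is the species' maximum absolute contrast (0.20 for
    clathrin-coated pits); ``full_inversion_nm`` the axial displacement
    producing one full contrast inversion (a π phase change).
    """

    c_max: float = 0.20
    full_inversion_nm: float = full_inversion_distance(OpticalConfig(), 1.0)
    direction_prior: str = "free"  # or "inward_only"

    def __post_init__(self) -> None:
        if self.c_max <= 0 or self.full_inversion_nm <= 0:
            raise ValueError("c_max and full_inversion_nm must be positive")
        if self.direction_prior not in ("free", "inward_only"):
            raise ValueError("direction_prior must be 'free' or 'inward_only'")

    @classmethod
    def from_model(cls, ipsf: IPSFModel, c_max: float = 0.20,
                   at_defocus: float = 0.0, **kw) -> "Calibration":
        """Calibrate from the model's local phase slope dphi/dz at a defocus."""
        z = at_defocus
        slope = (ipsf.axial_wavevector
                 + (1.0 / ipsf.gouy_range) / (1.0 + (z / ipsf.gouy_range) ** 2)
                 + 3.0 * ipsf.sa_coefficient * z**2 / ipsf.envelope_scale**3)
        return cls(c_max=c_max, full_inversion_nm=np.pi / slope, **kw)


# ---------------------------------------------------------------------------
# segmentation

def hessian_ridge_segment(image, scale_px: float, threshold: float,
                          polarity: str = "auto", min_size: int = 8):
    """Binary ridge mask from the principal Hessian eigenvalue at one scale.

    ``scale_px`` should match the tubule half-width in pixels; ``threshold``
    is on the (scale-normalised) ridge response.  ``polarity`` selects
    bright ridges, dark ridges, or the stronger of the two (``auto``);
    connected components smaller than ``min_size`` pixels are dropped.
    """
    image = np.asarray(image, dtype=float)
    H = hessian_matrix(image, sigma=scale_px, order="rc", use_gaussian_derivatives=False)
    ev = hessian_matrix_eigvals(H)  # ev[0] >= ev[1]
    bright = -ev[1] * scale_px**2  # strongly negative curvature across a bright line
    dark = ev[0] * scale_px**2
    if polarity == "bright":
        resp = bright
    elif polarity == "dark":
        resp = dark
    elif polarity == "auto":
        resp = bright if bright.max() >= dark.max() else dark
    elif polarity == "both":
        resp = np.maximum(bright, dark)
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    mask = resp > threshold
    return remove_small_objects(mask, max_size=min_size - 1)


# ---------------------------------------------------------------------------
# radial variance transform

def _ring_kernel(radius: int) -> np.ndarray:
    half = radius + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    d = np.sqrt(yy**2 + xx**2)
    ring = (d >= radius - 0.5) & (d < radius + 0.5)
    k = ring.astype(float)
    return k / k.sum()


def radial_variance_transform(image, r_min: int, r_max: int,
                              normalize: bool = False) -> np.ndarray:
    """Radial variance transform: variance of annular means across radius.

    For each pixel, the mean intensity over concentric 1-px-wide annuli
    of radius r_min..r_max is computed; the output is the variance of
    those means across radius.  Centres of ringed, radially symmetric
    patterns (iPSFs of either contrast sign) appear as maxima.  With
    ``normalize``, the variance is divided by the local intensity
    variance over the largest annulus footprint, making the score
    contrast-amplitude independent.
    """
    image = np.asarray(image, dtype=float)
    if not 0 <= r_min < r_max:
        raise ValueError("need 0 <= r_min < r_max")
    if 2 * r_max + 1 > min(image.shape):
        raise ValueError(f"r_max {r_max} too large for image {image.shape}")
    radii = np.arange(r_min, r_max + 1)
    ones = np.ones_like(image)
    means = np.empty((len(radii),) + image.shape)
    for j, rho in enumerate(radii):
        k = _ring_kernel(int(rho))
        # edge-corrected annular mean: normalise by the in-bounds ring area
        m = fftconvolve(image, k, mode="same")
        w = np.clip(fftconvolve(ones, k, mode="same"), 1e-12, None)
        means[j] = m / w
    # two-pass variance across radii (one-pass cancels catastrophically
    # when an intensity offset dwarfs the annular-mean spread)
    var = np.mean((means - means.mean(axis=0)) ** 2, axis=0)
    if normalize:
        half = int(r_max)
        box = np.ones((2 * half + 1, 2 * half + 1))
        box /= box.sum()
        local_mean = fftconvolve(image, box, mode="same")
        local_sq = fftconvolve(image**2, box, mode="same")
        local_var = np.clip(local_sq - local_mean**2, 1e-12, None)
        var = var / local_var
    return var


def localize_particles(score_map, contrast_image, threshold: float,
                       min_separation_px: float = 5.0,
                       pixel_size: float = 30.0, t: int = 0) -> list[Detection]:
    """Sub-pixel particle detections from an RVT score map.

    Local maxima above ``threshold`` with non-maximum suppression at
    ``min_separation_px`` are refined by a quadratic fit to the 3x3
    neighbourhood; the contrast is read from ``contrast_image`` at the
    refined position by bilinear interpolation.  Coordinates are in nm.
    """
    score_map = np.asarray(score_map, dtype=float)
    contrast_image = np.asarray(contrast_image, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks = peak_local_max(score_map, min_distance=max(1, int(round(min_separation_px))),
                           threshold_abs=threshold, exclude_border=1)
    out: list[Detection] = []
    for py, px in peaks:
        patch = score_map[py - 1:py + 2, px - 1:px + 2]
        dy = _parabola_1d(patch[0, 1], patch[1, 1], patch[2, 1])
        dx = _parabola_1d(patch[1, 0], patch[1, 1], patch[1, 2])
        ry, rx = py + dy, px + dx
        cval = float(map_coordinates(contrast_image, [[ry], [rx]], order=1)[0])
        out.append(Detection(t=t, x=rx * pixel_size, y=ry * pixel_size,
                             contrast=cval, score=float(score_map[py, px])))
    return out


def _parabola_1d(a, b, c) -> float:
    denom = a - 2.0 * b + c
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))


# ---------------------------------------------------------------------------
# linking

def link_trajectories(detections: list[Detection], max_disp_nm: float,
                      memory_frames: int = 0, min_length: int = 25) -> list[Trajectory]:
    """Link per-frame detections into trajectories by optimal assignment.

    Within each frame, active tracks are matched to detections by
    minimising total displacement (Hungarian assignment) among candidate
    pairs closer than ``max_disp_nm``; tracks missing for more than
    ``memory_frames`` frames are closed.  Trajectories with fewer than
    ``min_length`` localisations are discarded.
    """
    if max_disp_nm <= 0:
        raise ValueError("max_disp_nm must be positive")
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(int(d.t), []).append(d)
    active: list[dict] = []  # {'dets': [...], 'last': Detection, 'last_t': int}
    closed: list[list[Detection]] = []
    big = 1e18
    for t in sorted(by_frame):
        dets = by_frame[t]
        # retire tracks beyond memory
        still = []
        for tr in active:
            if t - tr["last_t"] > memory_frames + 1:
                closed.append(tr["dets"])
            else:
                still.append(tr)
        active = still
        if active and dets:
            cost = np.full((len(active), len(dets)), big)
            for i, tr in enumerate(active):
                lx, ly = tr["last"].x, tr["last"].y
                for j, d in enumerate(dets):
                    dist = np.hypot(d.x - lx, d.y - ly)
                    if dist <= max_disp_nm:
                        cost[i, j] = dist
            rows, cols = linear_sum_assignment(cost)
            matched_tracks, matched_dets = set(), set()
            for i, j in zip(rows, cols):
                if cost[i, j] < big:
                    active[i]["dets"].append(dets[j])
                    active[i]["last"] = dets[j]
                    active[i]["last_t"] = t
                    matched_tracks.add(i)
                    matched_dets.add(j)
            unmatched = [d for j, d in enumerate(dets) if j not in matched_dets]
        else:
            unmatched = list(dets)
        for d in unmatched:
            active.append({"dets": [d], "last": d, "last_t": t})
    closed.extend(tr["dets"] for tr in active)
    trajs = [Trajectory(detections=dets, trajectory_id=i)
             for i, dets in enumerate(d for d in closed if len(d) >= min_length)]
    return trajs


# ---------------------------------------------------------------------------
# contrast-to-height inversion

def contrast_to_dz(contrast, cal: Calibration,
                   initial_phase: float | None = None) -> np.ndarray:
    """Convert a contrast time series into relative axial displacement (nm).

    Inverts C(t) = c_max cos(pi z(t) / full_inversion_nm + phi0) on a
    continuous phase branch: each frame's phase increment is the smallest
    consistent with the measured |C|, optionally constrained to be
    non-negative (``inward_only`` prior, appropriate for endocytic pits
    that can only move into the cell).  ``initial_phase`` pins the
    starting branch; by default the branch nearest focus (smallest
    non-negative phase) is assumed and recorded implicitly in the output
    being relative to the first frame.
    """
    c = np.asarray(contrast, dtype=float)
    over = np.abs(c) > cal.c_max
    if np.any(np.abs(c) > 1.1 * cal.c_max):
        raise CalibrationViolation(
            f"|C| exceeds c_max={cal.c_max} by more than 10%")
    if over.any():
        warnings.warn("contrast clipped to +-c_max", stacklevel=2)
    base = np.arccos(np.clip(c / cal.c_max, -1.0, 1.0))  # in [0, pi]
    psi = np.empty_like(base)
    if initial_phase is None:
        psi[0] = base[0]
    else:
        # anchor the measured phase on the branch nearest the supplied prior
        p0 = float(initial_phase)
        k0 = np.round(p0 / (2 * np.pi))
        cands0 = np.array([2 * np.pi * k + s * base[0]
                           for k in (k0 - 1, k0, k0 + 1) for s in (+1, -1)])
        psi[0] = cands0[np.argmin(np.abs(cands0 - p0))]
    for i in range(1, len(base)):
        k0 = np.round((psi[i - 1]) / (2 * np.pi))
        cands = []
        for k in (k0 - 1, k0, k0 + 1):
            cands.append(2 * np.pi * k + base[i])
            cands.append(2 * np.pi * k - base[i])
        cands = np.array(cands)
        if cal.direction_prior == "inward_only":
            ok = cands >= psi[i - 1] - 1e-9
            cands = cands[ok] if ok.any() else cands
        psi[i] = cands[np.argmin(np.abs(cands - psi[i - 1]))]
    return (psi - psi[0]) * cal.full_inversion_nm / np.pi


# ---------------------------------------------------------------------------
# statistics

def trajectory_stats(traj: Trajectory, frame_interval: float = 1.0) -> dict:
    """Per-trajectory summary: RMSD, contrast swing, mean speed.

    RMSD is about the mean lateral position; ``contrast_swing`` is
    |C_max - C_min|; ``mean_speed_nm_s`` the net displacement over the
    track duration.
    """
    xy = traj.xy
    centred = xy - xy.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))
    c = traj.contrast
    swing = float(c.max() - c.min()) if len(c) else 0.0
    duration = (traj.frames[-1] - traj.frames[0]) * frame_interval
    net = float(np.hypot(*(xy[-1] - xy[0])))
    speed = net / duration if duration > 0 else 0.0
    return {"rmsd_nm": rmsd, "contrast_swing": swing,
            "mean_speed_nm_s": speed, "n_points": len(traj)}


def ensemble_msd(trajectories: list[Trajectory], max_lag: int = 1,
                 frame_interval: float = 1.0):
    """Ensemble mean squared lateral displacement vs lag (nm^2).

    For Brownian motion in 2-D the MSD at lag tau is 4 D tau.
    Returns ``(lags_s, msd_nm2)``.
    """
    msd = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for tr in trajectories:
        xy = tr.xy
        for lag in range(1, max_lag + 1):
            if len(xy) > lag:
                d = xy[lag:] - xy[:-lag]
                msd[lag - 1] += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
                counts[lag - 1] += len(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        msd = np.where(counts > 0, msd / np.maximum(counts, 1), np.nan)
    lags = np.arange(1, max_lag + 1) * frame_interval
    return lags, msd


def colocalization_fraction(detections: list[Detection], reference_mask,
                            tolerance_nm: float = 0.0,
                            pixel_size: float = 30.0) -> float:
    """Fraction of detections inside a reference mask dilated by a tolerance."""
    if not detections:
        raise ValueError("undefined colocalization fraction: no detections")
    mask = np.asarray(reference_mask).astype(bool)
    tol_px = int(round(tolerance_nm / pixel_size))
    if tol_px > 0:
        mask = binary_dilation(mask, disk(tol_px))
    ny, nx = mask.shape
    hits = 0
    for d in detections:
        iy = int(round(d.y / pixel_size))
        ix = int(round(d.x / pixel_size))
        if 0 <= iy < ny and 0 <= ix < nx and mask[iy, ix]:
            hits += 1
    return hits / len(detections)
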