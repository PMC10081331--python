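"""Synthetic scenes ("phantoms") with the statistical structure of live-cell iSCAT data.

Three scene ingredients cover the structures the analysis pipeline is
designed for:

* **interfaces** — smooth membrane-like height fields z(x, y) (nuclear
  envelope, ER sheets), optionally oscillating in time;
* **tubules** — planar networks of thin cylinders (ER tubules,
  50-100 nm diameter) whose internal junctions are three-way;
* **particles** — point scatterers (clathrin-coated pits, virions)
  following Brownian motion with optional drift and a scripted axial
  path.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi


class AliasingError(ValueError):
    """Requested texture is finer than the sampling can represent."""


@dataclass
class Interface:
    """A membrane-like interface: height map (nm) and contrast amplitude.

    Optional sinusoidal time modulation emulates ER-sheet fluctuations:
    z(x, y, t) = heights + osc_amplitude * sin(2 pi osc_frequency t + osc_phase),
    where ``osc_amplitude`` may be a per-pixel map (zero entries are
    static "fluctuation nodes").
    """

    heights: np.ndarray
    amplitude: np.ndarray | float = 0.1  # scalar, or per-pixel map (0 = no interface)
    osc_amplitude: np.ndarray | float = 0.0
    osc_frequency: float = 0.0
    osc_phase: np.ndarray | float = 0.0

    def height_at(self, t: float) -> np.ndarray:
        if self.osc_frequency == 0.0 and np.all(np.asarray(self.osc_amplitude) == 0):
            return self.heights
        return self.heights + np.asarray(self.osc_amplitude) * np.sin(
            2.0 * np.pi * self.osc_frequency * t + np.asarray(self.osc_phase)
        )


@dataclass
class Tubule:
    """A tubule rendered as a polyline of given radius at height z."""

    polyline: np.ndarray  # (N, 2) x, y in nm
    radius: float = 37.5  # nm; default diameter 75 nm, mid 50-100 nm range
    amplitude: float = 0.12  # peak contrast; ER tubules show ~12 %
    z: float = 200.0  # nm above cover glass

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tubule radius must be positive")


@dataclass
class ParticleTrack:
    """A point scatterer with a precomputed trajectory (T, 3) in nm."""

    positions: np.ndarray
    amplitude: float = 0.02  # |s|/r ~ 0.1 -> ~20 % peak contrast at r = 0.2
    intrinsic_phase: float = 0.0


@dataclass
class Phantom:
    """A scene: interfaces + tubules + particles over a sampling domain."""

    shape: tuple[int, int] = (256, 256)  # (ny, nx) pixels
    pixel_size: float = 30.0  # nm
    interfaces: list[Interface] = dfield(default_factory=list)
    tubules: list[Tubule] = dfield(default_factory=list)
    particles: list[ParticleTrack] = dfield(default_factory=list)
    meta: dict = dfield(default_factory=dict)

    @property
    def extent_nm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)


@dataclass
class AcquisitionPlan:
    """What the virtual microscope records.

    ``focus_positions`` (nm) and ``frame_times`` (s) span the acquisition:
    a z-stack uses many focus positions at one time point, a constant-focus
    time series many time points at one focus.  ``photon_budget`` is the
    expected number of detected photons per pixel at background level;
    ``None`` renders noiselessly.
    """

    mode: str = "confocal"
    focus_positions: np.ndarray = dfield(default_factory=lambda: np.array([0.0]))
    frame_times: np.ndarray = dfield(default_factory=lambda: np.array([0.0]))
    photon_budget: float | None = 1.0e4

    def __post_init__(self) -> None:
        self.focus_positions = np.atleast_1d(np.asarray(self.focus_positions, float))
        self.frame_times = np.atleast_1d(np.asarray(self.frame_times, float))
        if self.mode not in ("confocal", "widefield"):
            raise ValueError("mode must be 'confocal' or 'widefield'")
        if self.photon_budget is not None and self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")


# ---------------------------------------------------------------------------
# generators

def make_membrane_phantom(shape=(256, 256), pixel_size=30.0, *,
                          ripple_rms=200.0, correlation_length=1000.0,
                          global_curvature=0.0, base_height=1000.0,
                          amplitude=0.1, seed=0) -> Phantom:
    """Rippled membrane interface: global bow plus band-limited random ripples.

    The ripple field is Gaussian white noise smoothed to the requested
    correlation length and rescaled to exactly the requested RMS amplitude
    (nm).  ``global_curvature`` (nm per nm^2) adds a parabolic bow across
    the field of view, emulating the large-scale sag of a nuclear envelope.
    """
    if ripple_rms < 0:
        raise ValueError("ripple_rms must be >= 0")
    if ripple_rms > 0 and correlation_length < 2 * pixel_size:
        raise AliasingError(
            f"correlation_length {correlation_length} nm is below twice the "
            f"pixel size ({2 * pixel_size} nm); ripples would alias"
        )
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float) * pixel_size
    cy, cx = yy.mean(), xx.mean()
    heights = base_height + global_curvature * ((yy - cy) ** 2 + (xx - cx) ** 2)
    if ripple_rms > 0:
        sigma_px = correlation_length / pixel_size
        noise = gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
        noise -= noise.mean()
        rms = np.sqrt(np.mean(noise**2))
        heights = heights + noise * (ripple_rms / rms)
    return Phantom(shape=shape, pixel_size=pixel_size,
                   interfaces=[Interface(heights=heights, amplitude=amplitude)],
                   meta={"seed": seed, "kind": "membrane",
                         "ripple_rms": ripple_rms,
                         "correlation_length": correlation_length})


def make_staircase_phantom(shape=(128, 128), pixel_size=30.0, *,
                           step_height=50.0, n_steps=5, base_height=500.0,
                           amplitude=0.1, margin_px=0) -> Phantom:
    """Nanofabricated-staircase stand-in: equal-height terraces along x.

    With ``margin_px`` > 0 a bare-glass border surrounds the staircase
    (interface amplitude zero there); the border mask is stored in
    ``meta['glass_mask']`` so the reflected intensity of the bare glass
    can serve as the contrast background.
    """
    ny, nx = shape
    step_idx = np.minimum((np.arange(nx) * n_steps) // nx, n_steps - 1)
    heights = np.broadcast_to(base_height + step_height * step_idx,
                              (ny, nx)).astype(float).copy()
    amp = np.full((ny, nx), float(amplitude))
    glass = np.zeros((ny, nx), dtype=bool)
    if margin_px > 0:
        glass[:margin_px, :] = glass[-margin_px:, :] = True
        glass[:, :margin_px] = glass[:, -margin_px:] = True
        amp[glass] = 0.0
    return Phantom(shape=shape, pixel_size=pixel_size,
                   interfaces=[Interface(heights=heights, amplitude=amp)],
                   meta={"kind": "staircase", "step_height": step_height,
                         "n_steps": n_steps, "glass_mask": glass,
                         "terrace_index": np.broadcast_to(step_idx, (ny, nx))})


def make_tubule_phantom(shape=(256, 256), pixel_size=30.0, *,
                        node_density=4e-8, radius_range=(25.0, 50.0),
                        amplitude=0.12, z=200.0, seed=0) -> Phantom:
    """Random planar tubule network whose internal junctions are three-way.

    Built from the Voronoi diagram of a random point set: Voronoi vertices
    generically have exactly three incident edges, reproducing the
    three-way junction topology of the ER.  ``node_density`` is seed points
    per nm^2; edge radii are sampled uniformly from ``radius_range`` (nm).
    """
    lo, hi = radius_range
    if not (0 < lo <= hi):
        raise ValueError("radius_range must satisfy 0 < lo <= hi")
    ny, nx = shape
    if ny == 0 or nx == 0:
        raise ValueError("empty domain")
    rng = np.random.default_rng(seed)
    ext_y, ext_x = ny * pixel_size, nx * pixel_size
    n_pts = max(4, int(node_density * ext_x * ext_y))
    # pad the point cloud beyond the domain so boundary effects stay outside
    pts = rng.uniform([-0.5 * ext_x, -0.5 * ext_y],
                      [1.5 * ext_x, 1.5 * ext_y], size=(n_pts * 4, 2))
    vor = Voronoi(pts)

    verts = vor.vertices
    in_domain = ((verts[:, 0] >= 0) & (verts[:, 0] <= ext_x)
                 & (verts[:, 1] >= 0) & (verts[:, 1] <= ext_y))
    degree = np.zeros(len(verts), dtype=int)
    edges = []
    for a, b in vor.ridge_vertices:
        if a < 0 or b < 0:
            continue
        degree[a] += 1
        degree[b] += 1
        if in_domain[a] or in_domain[b]:
            edges.append((a, b))

    tubules = []
    kept_degree: dict[int, int] = {}
    for a, b in edges:
        radius = rng.uniform(lo, hi)
        tubules.append(Tubule(polyline=np.array([verts[a], verts[b]]),
                              radius=radius, amplitude=amplitude, z=z))
        kept_degree[a] = kept_degree.get(a, 0) + 1
        kept_degree[b] = kept_degree.get(b, 0) + 1

    # internal nodes: in-domain vertices all of whose Voronoi edges were kept
    internal = [v for v, d in kept_degree.items()
                if in_domain[v] and d == degree[v]]
    return Phantom(shape=shape, pixel_size=pixel_size, tubules=tubules,
                   meta={"seed": seed, "kind": "tubule_network",
                         "node_positions": verts,
                         "internal_nodes": np.array(internal, dtype=int),
                         "node_degree": {v: kept_degree[v] for v in internal}})


def make_particle_ensemble(n=10, *, diffusion=1.0e4, drift=(0.0, 0.0, 0.0),
                           duration=10.0, dt=0.1, shape=(256, 256),
                           pixel_size=30.0, z0=200.0, amplitude=0.02,
                           seed=0) -> Phantom:
    """Brownian point scatterers with optional drift.

    Per axis, x(t + dt) = x(t) + drift dt + N(0, 2 D dt) with ``diffusion``
    D in nm^2/s and ``drift`` in nm/s.  Axial positions are reflected at
    the cover glass (z >= 0).  Starting positions are uniform over the
    field of view at height ``z0``.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    if diffusion < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt)) + 1
    ny, nx = shape
    ext = np.array([nx * pixel_size, ny * pixel_size])
    start = np.column_stack([rng.uniform(0, ext[0], n),
                             rng.uniform(0, ext[1], n),
                             np.full(n, float(z0))])
    steps = rng.normal(0.0, np.sqrt(2.0 * diffusion * dt), size=(n, n_steps - 1, 3))
    steps += np.asarray(drift, dtype=float) * dt
    paths = np.concatenate([start[:, None, :],
                            start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    paths[:, :, 2] = np.abs(paths[:, :, 2])  # reflect at the cover glass
    particles = [ParticleTrack(positions=paths[i], amplitude=amplitude)
                 for i in range(n)]
    return Phantom(shape=shape, pixel_size=pixel_size, particles=particles,
                   meta={"seed": seed, "kind": "particles", "dt": dt,
                         "diffusion": diffusion, "drift": tuple(drift)})
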