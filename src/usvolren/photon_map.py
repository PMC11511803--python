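"""Photon emission, tracing and storage in a flux grid.

The first pass of volumetric photon mapping: light packets leave the source
toward the volume (directions uniform over the solid angle the bounding box
subtends), interact at exponentially sampled free paths, and survive each
interaction by Russian roulette with probability equal to the local albedo
lambda_s / tau_t.  Every scatter deposits the photon's undiminished launch
flux into the flux grid by a trilinear splat — the roulette carries the
attenuation stochastically, so no per-bounce down-weighting is applied.  The
grid (the "indirect illumination volume") is congruent with the scalar
volume and is all the second pass needs; full photon records (position,
incident direction, flux) can optionally be kept for the conventional
nearest-neighbor density-estimation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels as _k
from .config import RenderConfig
from .optics import TransferFunction, hg_phase
from .volume_io import ScalarVolume


@dataclass
class Photon:
    """A light packet in flight."""

    position: np.ndarray
    direction: np.ndarray
    flux: np.ndarray  # rgb radiant power, >= 0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        self.flux = np.broadcast_to(
            np.asarray(self.flux, dtype=np.float64), (3,)).copy()
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("photon direction must be unit length")
        if np.any(self.flux < 0):
            raise ValueError("photon flux must be non-negative")


@dataclass
class Light:
    """A point light: position, per-photon flux (exposure) and budget."""

    position: tuple[float, float, float]
    exposure: float = 0.4
    n_photons: int = 100_000
    power: float = 1.0  # radiant intensity used by the single-scatter pass

    def __post_init__(self):
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")


@dataclass
class PhotonRecords:
    """Scatter-event records for the conventional KNN radiance estimator."""

    positions: np.ndarray   # (N, 3) world mm
    directions: np.ndarray  # (N, 3) incident propagation direction
    flux: np.ndarray        # (N, 3) rgb flux carried at the event

    def __len__(self):
        return self.positions.shape[0]

    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.positions)
        return self._tree


class FluxVolume:
    """Per-voxel accumulated scattered flux plus the photon counters."""

    def __init__(self, dims, spacing, origin):
        self.dims = tuple(int(n) for n in dims)
        self.spacing = tuple(float(s) for s in spacing)
        self.origin = tuple(float(o) for o in origin)
        # one contiguous grid per channel so the kernels deposit in place
        self._r = np.zeros(self.dims, dtype=np.float64)
        self._g = np.zeros(self.dims, dtype=np.float64)
        self._b = np.zeros(self.dims, dtype=np.float64)
        self.n_emitted = 0
        self.n_absorbed = 0
        self.n_escaped = 0
        self.n_oob = 0  # warning counter: deposits attempted outside the box

    @property
    def flux(self) -> np.ndarray:
        """Per-voxel rgb flux as one (nx, ny, nz, 3) array (a copy)."""
        return np.stack([self._r, self._g, self._b], axis=-1)

    @classmethod
    def zeros_like(cls, vol: ScalarVolume) -> "FluxVolume":
        return cls(vol.dims, vol.spacing, vol.origin)

    def congruent_with(self, vol: ScalarVolume) -> bool:
        return (self.dims == vol.dims
                and np.allclose(self.spacing, vol.spacing)
                and np.allclose(self.origin, vol.origin))

    @property
    def box_min(self) -> np.ndarray:
        return np.array(self.origin) - 0.5 * np.array(self.spacing)

    @property
    def box_max(self) -> np.ndarray:
        d = np.array(self.dims, dtype=float)
        return np.array(self.origin) + (d - 0.5) * np.array(self.spacing)

    def total_flux(self) -> np.ndarray:
        return np.array([self._r.sum(), self._g.sum(), self._b.sum()])

    def channels(self):
        """The live per-channel grids (kernels write these in place)."""
        return self._r, self._g, self._b


def deposit(flux: FluxVolume, position, phi) -> None:
    """Trilinear splat of rgb flux ``phi`` over the 8 nearest voxels.

    Weights sum to exactly 1; positions outside the bounding box are a no-op
    that increments the ``n_oob`` warning counter.
    """
    p = np.asarray(position, dtype=np.float64)
    phi = np.broadcast_to(np.asarray(phi, dtype=np.float64), (3,))
    if np.any(p < flux.box_min) or np.any(p > flux.box_max):
        flux.n_oob += 1
        return
    fr, fg, fb = flux.channels()
    _k._deposit_trilinear(fr, fg, fb, np.array(flux.origin),
                          np.array(flux.spacing), p[0], p[1], p[2],
                          phi[0], phi[1], phi[2])


def trace_photon(photon: Photon, vol: ScalarVolume, tf: TransferFunction,
                 flux: FluxVolume, rng: np.random.Generator,
                 max_bounces: int = 32, step: float | None = None,
                 g: float = 0.5, record: bool = False):
    """Trace one photon, updating the flux grid and counters in place.

    Returns the list of deposit positions when ``record`` is set, else None.
    The numba path consumes a dedicated substream seeded from ``rng`` so
    repeated calls with the same generator state are reproducible.
    """
    if not photon.alive:
        return [] if record else None
    grid = vol.values
    org = np.array(vol.origin)
    sp = np.array(vol.spacing)
    bmin, bmax = vol.box_min, vol.box_max
    if step is None:
        step = float(np.linalg.norm(bmax - bmin)) / 256.0
    cap = max_bounces if record else 1
    rec_pos = np.zeros((cap, 3))
    rec_dir = np.zeros((cap, 3))
    rec_flux = np.zeros((cap, 3))
    seed = int(rng.integers(0, 2**63 - 1))
    fr, fg, fb = flux.channels()
    fate, n_dep, rec_n, _ = _k.trace_photon_kernel(
        grid, org, sp, bmin, bmax, *tf.tables(),
        photon.position[0], photon.position[1], photon.position[2],
        photon.direction[0], photon.direction[1], photon.direction[2],
        photon.flux[0], photon.flux[1], photon.flux[2],
        fr, fg, fb, np.uint64(_k._rng_init(seed, 0)), max_bounces, step, g,
        rec_pos, rec_dir, rec_flux, 0, record)
    photon.alive = False
    if fate == 0:
        flux.n_absorbed += 1
    else:
        flux.n_escaped += 1
    if record:
        return [rec_pos[i].copy() for i in range(rec_n)]
    return None


def emit_photons(vol: ScalarVolume, tf: TransferFunction, light: Light,
                 cfg: RenderConfig, record: bool = False):
    """Emit and trace ``light.n_photons`` photons; returns the FluxVolume.

    Photons are generated by a deterministic sequential counter (photon i
    draws from RNG substream i of ``cfg.seed``), each starting at the light
    position with direction sampled uniformly over the solid angle subtended
    by the volume's bounding box and initial flux equal to the exposure.
    With ``record`` the scatter events are also returned as PhotonRecords.
    """
    if light.n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    flux = FluxVolume.zeros_like(vol)
    _, _, photon_step = cfg.resolve_steps(vol)
    fr, fg, fb = flux.channels()
    cap = light.n_photons * cfg.max_bounces if record else 1
    rec_pos = np.zeros((cap, 3))
    rec_dir = np.zeros((cap, 3))
    rec_flux = np.zeros((cap, 3))
    n_abs, n_esc, rec_n = _k.emit_photons_kernel(
        vol.values, np.array(vol.origin), np.array(vol.spacing),
        vol.box_min, vol.box_max, *tf.tables(),
        np.asarray(light.position, dtype=np.float64), float(light.exposure),
        int(light.n_photons), fr, fg, fb,
        int(cfg.seed) & 0x7FFFFFFFFFFFFFFF, int(cfg.max_bounces),
        float(photon_step), float(cfg.g),
        rec_pos, rec_dir, rec_flux, record)
    flux.n_emitted = light.n_photons
    flux.n_absorbed = int(n_abs)
    flux.n_escaped = int(n_esc)
    if record:
        recs = PhotonRecords(rec_pos[:rec_n].copy(), rec_dir[:rec_n].copy(),
                             rec_flux[:rec_n].copy())
        return flux, recs
    return flux


def knn_radiance(photons: PhotonRecords, x, omega_0, n: int,
                 g: float = 0.0) -> np.ndarray:
    """Conventional spherical-kernel density estimation at one point.

    The n nearest photon records set the kernel radius r (distance to the
    n-th neighbor); the multiply-scattered radiance is

        L_ms ~= sum_i p_HG(w_i . w_0, g) * Phi_i / ((4/3) pi r^3).

    This is the reference estimator the screen-space pass is validated
    against.  Returns rgb radiance; an empty record set gives zero.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if photons is None or len(photons) == 0:
        return np.zeros(3)
    if len(photons) < n:
        raise ValueError(f"need at least {n} photons, have {len(photons)}")
    x = np.asarray(x, dtype=np.float64)
    w0 = np.asarray(omega_0, dtype=np.float64)
    w0 = w0 / np.linalg.norm(w0)
    dist, idx = photons.tree.query(x, k=n)
    dist = np.atleast_1d(dist)
    idx = np.atleast_1d(idx)
    r = dist[-1]
    if r == 0.0:
        r = np.finfo(float).tiny ** (1.0 / 3.0)
    cos_t = photons.directions[idx] @ w0
    phase = hg_phase(cos_t, g)
    vol_sphere = (4.0 / 3.0) * np.pi * r ** 3
    return (phase[:, None] * photons.flux[idx]).sum(axis=0) / vol_sphere


def knn_radiance_batch(photons: PhotonRecords, points: np.ndarray,
                       omega_0: np.ndarray, n: int, g: float = 0.0,
                       chunk: int = 200_000) -> np.ndarray:
    """Vectorized ``knn_radiance`` over many query points.

    ``omega_0`` may be one direction or one per point.  Processes in chunks
    to bound the (points x n) index workspace.
    """
    points = np.asarray(points, dtype=np.float64)
    m = points.shape[0]
    w0 = np.asarray(omega_0, dtype=np.float64)
    if w0.ndim == 1:
        w0 = np.broadcast_to(w0, (m, 3))
    out = np.zeros((m, 3))
    if len(photons) == 0:
        return out
    if len(photons) < n:
        raise ValueError(f"need at least {n} photons, have {len(photons)}")
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        dist, idx = photons.tree.query(points[start:stop], k=n)
        if n == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        r = np.maximum(dist[:, -1], 1e-12)
        cos_t = np.einsum("pnc,pc->pn", photons.directions[idx],
                          w0[start:stop])
        phase = hg_phase(cos_t, g)
        vol_sphere = (4.0 / 3.0) * np.pi * r ** 3
        out[start:stop] = np.einsum(
            "pn,pnc->pc", phase, photons.flux[idx]) / vol_sphere[:, None]
    return out
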