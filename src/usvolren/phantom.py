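"""Seedable synthetic fetal-like phantoms with ultrasound speckle.

Real obstetric volumes are not redistributable, so the test bed renders
phantoms: nested ellipsoidal "tissue" bodies of distinct mean intensity
immersed in low-intensity "fluid", softened by a small Gaussian kernel
(giving local illumination the gradient structure it needs) and corrupted by
multiplicative Rayleigh speckle, the standard first-order model of
fully-developed ultrasound speckle.  The speckle factor is normalized by the
Rayleigh mean so the operator preserves the mean intensity before clamping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume_io import ScalarVolume


@dataclass
class Ellipsoid:
    """One tissue body: an arbitrarily oriented ellipsoid.

    ``rotation`` is extrinsic x-y-z Euler angles in degrees; ``intensity``
    is the body's mean intensity in [0, 1].
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive (mm)")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("body intensity must lie in [0, 1]")


@dataclass
class PhantomSpec:
    """Recipe for one synthetic volume; identical spec + seed is bit-stable."""

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bodies: list[Ellipsoid] = field(default_factory=list)
    background: float = 0.05
    speckle_sigma: float = 0.15
    smooth_sigma: float = 1.0  # voxels
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.dims):
            raise ValueError("every dimension must have at least 2 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background intensity must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ValueError("speckle sigma must be non-negative")
        if self.smooth_sigma < 0:
            raise ValueError("smoothing sigma must be non-negative")


def generate_phantom(spec: PhantomSpec) -> ScalarVolume:
    """Rasterize the bodies, smooth the boundaries, then add speckle.

    Each voxel takes the intensity of the last body containing it (later
    bodies override earlier ones), else the background.
    """
    nx, ny, nz = spec.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1) * np.array(spec.spacing) + np.array(
        spec.origin)
    vol = np.full(spec.dims, spec.background, dtype=np.float64)
    for body in spec.bodies:
        rot = Rotation.from_euler("xyz", body.rotation, degrees=True)
        local = (pts - np.array(body.center)) @ rot.as_matrix()
        d2 = np.sum((local / np.array(body.semi_axes)) ** 2, axis=-1)
        vol[d2 <= 1.0] = body.intensity
    if spec.smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, spec.smooth_sigma, mode="nearest")
    out = ScalarVolume(np.clip(vol, 0.0, 1.0), spec.spacing, spec.origin)
    if spec.speckle_sigma > 0:
        out = add_speckle(out, spec.speckle_sigma, spec.seed)
    return out


def add_speckle(vol: ScalarVolume, sigma: float, seed: int) -> ScalarVolume:
    """Multiplicative Rayleigh speckle, mean-normalized.

    out = clamp(vol * R / E[R], 0, 1) with R i.i.d. Rayleigh(sigma) and
    E[R] = sigma * sqrt(pi/2), so the operator is mean-preserving before
    clamping; sigma = 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("speckle sigma must be non-negative")
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    r = rng.rayleigh(scale=sigma, size=vol.dims)
    factor = r / (sigma * math.sqrt(math.pi / 2.0))
    return ScalarVolume(np.clip(vol.values * factor, 0.0, 1.0),
                        vol.spacing, vol.origin)


def fetal_phantom(dims=(64, 64, 64), spacing=(1.0, 1.0, 1.0), seed: int = 0,
                  speckle_sigma: float = 0.15) -> ScalarVolume:
    """The package's stock phantom: a crude fetus in amniotic fluid.

    A tilted elliptical trunk, a spherical head with a lower-intensity
    interior (ventricle-like), and a small limb bud, all over a dark fluid
    background.  Dimensions are voxels; the geometry scales with ``dims``.
    """
    nx, ny, nz = dims
    sx, sy, sz = spacing
    cx, cy, cz = (nx - 1) * sx / 2, (ny - 1) * sy / 2, (nz - 1) * sz / 2
    u = min(nx * sx, ny * sy, nz * sz)  # box scale, mm
    bodies = [
        Ellipsoid(center=(cx, cy - 0.08 * u, cz),
                  semi_axes=(0.28 * u, 0.20 * u, 0.18 * u),
                  intensity=0.55, rotation=(0, 0, 20)),
        Ellipsoid(center=(cx + 0.16 * u, cy + 0.18 * u, cz),
                  semi_axes=(0.14 * u, 0.14 * u, 0.14 * u),
                  intensity=0.65),
        Ellipsoid(center=(cx + 0.16 * u, cy + 0.18 * u, cz),
                  semi_axes=(0.06 * u, 0.06 * u, 0.06 * u),
                  intensity=0.35),
        Ellipsoid(center=(cx - 0.22 * u, cy + 0.10 * u, cz + 0.08 * u),
                  semi_axes=(0.10 * u, 0.05 * u, 0.05 * u),
                  intensity=0.60, rotation=(0, 30, -30)),
    ]
    spec = PhantomSpec(dims=dims, spacing=spacing, bodies=bodies,
                       background=0.05, speckle_sigma=speckle_sigma,
                       smooth_sigma=1.0, seed=seed)
    return generate_phantom(spec)
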