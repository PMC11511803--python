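"""Optical classification and scattering/transport primitives.

The transfer function maps normalized intensity to color, extinction tau_t
(per mm) and single-scattering albedo a, from which the absorption and
scattering coefficients follow as lambda_a = (1-a)*tau_t and
lambda_s = a*tau_t — so lambda_a + lambda_s = tau_t holds by construction at
every lookup.

Scattering anisotropy uses the Henyey-Greenstein phase function

    p(cos t) = (1/4pi) (1 - g^2) / (1 + g^2 - 2 g cos t)^{3/2}

normalized over the sphere, with mean scattering cosine equal to g.
Transmittance between two points is Beer-Lambert, exp(-integral tau_t),
approximated by a midpoint-rule Riemann sum with a configurable step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .volume_io import ScalarVolume


@dataclass(frozen=True)
class OpticalSample:
    """Optical coefficients of the medium at one world position."""

    position: tuple[float, float, float]
    lambda_a: float
    lambda_s: float
    tau_t: float
    color: tuple[float, float, float]


class TransferFunction:
    """Piecewise-linear map from intensity to (color, tau_t, albedo).

    Parameters
    ----------
    breakpoints : sequence of (intensity, rgb, extinction, albedo)
        Intensities in [0, 1], strictly increasing after sorting; rgb
        components in [0, 1]; extinction >= 0 per mm; albedo in [0, 1].
        Missing endpoints at intensity 0 and 1 are added by clamping.
    """

    def __init__(self, breakpoints):
        bps = sorted(breakpoints, key=lambda b: b[0])
        if not bps:
            raise ValueError("at least one breakpoint is required")
        xs = [float(b[0]) for b in bps]
        if any(x2 <= x1 for x1, x2 in zip(xs, xs[1:])):
            raise ValueError("breakpoint intensities must be distinct")
        if xs[0] < 0.0 or xs[-1] > 1.0:
            raise ValueError("breakpoint intensities must lie in [0, 1]")
        for _, rgb, ext, alb in bps:
            if len(rgb) != 3 or any(c < 0 or c > 1 for c in rgb):
                raise ValueError("rgb components must lie in [0, 1]")
            if ext < 0:
                raise ValueError("extinction must be non-negative")
            if alb < 0 or alb > 1:
                raise ValueError("albedo must lie in [0, 1]")
        if xs[0] > 0.0:
            bps.insert(0, (0.0, bps[0][1], bps[0][2], bps[0][3]))
        if bps[-1][0] < 1.0:
            bps.append((1.0, bps[-1][1], bps[-1][2], bps[-1][3]))
        self.intensities = np.array([b[0] for b in bps], dtype=np.float64)
        self.colors = np.array([b[1] for b in bps], dtype=np.float64)
        self.extinction = np.array([b[2] for b in bps], dtype=np.float64)
        self.albedo = np.array([b[3] for b in bps], dtype=np.float64)

    @classmethod
    def uniform(cls, color=(1.0, 1.0, 1.0), extinction=1.0, albedo=1.0):
        """A transfer function constant over the whole intensity range."""
        return cls([(0.0, tuple(color), extinction, albedo)])

    @classmethod
    def ramp(cls, color=(1.0, 1.0, 1.0), extinction=1.0, albedo=1.0):
        """Vacuum at intensity 0 rising linearly to the given coefficients."""
        return cls([(0.0, tuple(color), 0.0, albedo),
                    (1.0, tuple(color), extinction, albedo)])

    def lookup(self, intensity):
        """Vectorized lookup: returns (color, tau_t, albedo)."""
        s = np.clip(np.asarray(intensity, dtype=np.float64), 0.0, 1.0)
        tau = np.interp(s, self.intensities, self.extinction)
        alb = np.interp(s, self.intensities, self.albedo)
        color = np.stack([np.interp(s, self.intensities, self.colors[:, c])
                          for c in range(3)], axis=-1)
        return color, tau, alb

    def tables(self):
        """Contiguous float64 arrays consumed by the numba kernels."""
        return (self.intensities, self.colors, self.extinction, self.albedo)


def _vol_arrays(vol: ScalarVolume):
    return (vol.values, np.array(vol.origin), np.array(vol.spacing),
            vol.box_min, vol.box_max)


def classify(vol: ScalarVolume, tf: TransferFunction,
             position) -> OpticalSample:
    """Optical coefficients at a world position (vacuum outside the box).

    Intensity is the trilinear interpolation of the 8 surrounding voxels
    (clamp-to-edge inside the half-voxel boundary shell); the transfer
    function then yields the coefficients.  Total function: positions outside
    the bounding box return tau_t = 0.
    """
    p = np.asarray(position, dtype=np.float64)
    grid, org, sp, bmin, bmax = _vol_arrays(vol)
    if np.any(p < bmin) or np.any(p > bmax):
        return OpticalSample(tuple(p), 0.0, 0.0, 0.0, (0.0, 0.0, 0.0))
    s = _k._trilinear(grid, org, sp, bmin, bmax, p[0], p[1], p[2])
    color, tau, alb = tf.lookup(s)
    lam_s = float(alb * tau)
    lam_a = float((1.0 - alb) * tau)
    return OpticalSample(tuple(p), lam_a, lam_s, float(tau), tuple(color))


def hg_phase(cos_theta, g: float):
    """Henyey-Greenstein phase density per steradian (normalized form)."""
    if abs(g) >= 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    ct = np.asarray(cos_theta, dtype=np.float64)
    denom = 1.0 + g * g - 2.0 * g * ct
    out = (1.0 - g * g) / (4.0 * np.pi * denom ** 1.5)
    return out if out.ndim else float(out)

def sample_hg(omega_in, g: float, rng: np.random.Generator):
    """Draw a scattered direction about ``omega_in`` from the HG density.

    Uses the inverse CDF for cos(theta) (uniform over the sphere when g = 0)
    with a uniform azimuth, rotated into the frame of the incoming
    propagation direction; the result is unit length.
    """
    if abs(g) >= 1.0:
        raise ValueError("anisotropy g must satisfy |g| < 1")
    w = np.asarray(omega_in, dtype=np.float64)
    n = np.linalg.norm(w)
    if n == 0.0:
        raise ValueError("omega_in must be a non-zero direction")
    w = w / n
    u1, u2 = rng.random(2)
    if abs(g) < 1e-9:
        cos_t = 1.0 - 2.0 * u1
    else:
        sq = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        cos_t = np.clip((1.0 + g * g - sq * sq) / (2.0 * g), -1.0, 1.0)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * np.pi * u2
    helper = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.999 else np.array(
        [1.0, 0.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    out = sin_t * (np.cos(phi) * u + np.sin(phi) * v) + cos_t * w
    return out / np.linalg.norm(out)


def transmittance(vol: ScalarVolume, tf: TransferFunction,
                  x_i, x_j, step: float = 0.05) -> float:
    """Beer-Lambert transmittance between two world points, in (0, 1].

    Midpoint-rule approximation of exp(-integral tau_t) along the segment;
    exactly 1 for coincident endpoints or an all-vacuum path.
    """
    if step <= 0:
        raise ValueError("step must be positive (mm)")
    a = np.asarray(x_i, dtype=np.float64)
    b = np.asarray(x_j, dtype=np.float64)
    grid, org, sp, bmin, bmax = _vol_arrays(vol)
    tf_x, tf_rgb, tf_tau, tf_alb = tf.tables()
    return float(_k._transmittance(grid, org, sp, bmin, bmax,
                                   tf_x, tf_rgb, tf_tau, tf_alb,
                                   a[0], a[1], a[2], b[0], b[1], b[2], step))
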