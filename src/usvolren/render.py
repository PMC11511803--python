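"""The two-pass global-illumination ray caster.

Emission is neglected, so per-pixel radiance splits into

    L = L_bg * T(ray)  +  direct (single scattering)  +  indirect (multiple
    scattering),

each term a front-to-back Riemann sum over the eye ray.  The direct pass is
deterministic: in single-scatter geometry both the incident direction (from
the light) and the outgoing direction (to the eye) are fixed, so the phase
function is evaluated at the exact eye-light angle instead of being sampled.
The indirect pass reads the photon-mapped flux grid, converts flux density
to in-scattered radiance under isotropic collection
(sigma_s * L_ms = Phi_local / (4 pi V_voxel)), and finishes with a separable
screen-space Gaussian — the density-estimation low-pass kernel realized in
2D image space.  The two HDR images are strictly additive; Reinhard's global
operator maps the sum to the display range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels as _k
from .config import RenderConfig
from .optics import TransferFunction
from .photon_map import FluxVolume, Light, PhotonRecords, emit_photons, \
    knn_radiance_batch
from .volume_io import ScalarVolume

__all__ = [
    "Camera", "RadianceImage", "RenderConfig", "render", "render_direct",
    "render_indirect", "render_indirect_reference", "render_local",
    "gaussian_blur_separable", "tone_map",
]


@dataclass
class Camera:
    """Pinhole camera; pixel (0, 0) is top-left, rays pass pixel centers."""

    eye: tuple[float, float, float]
    look_at: tuple[float, float, float]
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    vfov: float = 45.0
    width: int = 128
    height: int = 128

    def __post_init__(self):
        if not 0.0 < self.vfov < 180.0:
            raise ValueError("vfov must lie in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        fwd = np.asarray(self.look_at, float) - np.asarray(self.eye, float)
        n = np.linalg.norm(fwd)
        if n == 0:
            raise ValueError("look_at must differ from eye")
        if np.linalg.norm(np.cross(fwd / n, np.asarray(self.up, float))) < 1e-9:
            raise ValueError("up must not be parallel to the view direction")

    def basis(self):
        """Returns (eye, right, up, forward, tan(vfov/2), aspect)."""
        eye = np.asarray(self.eye, dtype=np.float64)
        fwd = np.asarray(self.look_at, float) - eye
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, np.asarray(self.up, dtype=np.float64))
        right /= np.linalg.norm(right)
        up = np.cross(right, fwd)
        tan_half = np.tan(np.radians(self.vfov) / 2.0)
        return eye, right, up, fwd, tan_half, self.width / self.height

    def ray_directions(self) -> np.ndarray:
        """(H, W, 3) unit ray directions (vectorized mirror of the kernels)."""
        eye, right, up, fwd, tan_half, aspect = self.basis()
        i = np.arange(self.width)
        j = np.arange(self.height)
        px = (2.0 * (i + 0.5) / self.width - 1.0) * tan_half * aspect
        py = 1.0 - 2.0 * (j + 0.5) / self.height
        py = py * tan_half
        d = (fwd[None, None, :]
             + px[None, :, None] * right[None, None, :]
             + py[:, None, None] * up[None, None, :])
        return d / np.linalg.norm(d, axis=-1, keepdims=True)


@dataclass
class RadianceImage:
    """HDR per-pixel radiance, plus the tone-mapped LDR buffer once made."""

    hdr: np.ndarray
    ldr: np.ndarray | None = None

    def __post_init__(self):
        self.hdr = np.asarray(self.hdr, dtype=np.float64)
        if self.hdr.ndim != 3 or self.hdr.shape[2] != 3:
            raise ValueError("hdr must be an (H, W, 3) array")
        if not np.all(np.isfinite(self.hdr)):
            raise ValueError("hdr radiance must be finite")
        if self.hdr.min() < 0:
            raise ValueError("hdr radiance must be non-negative")


def _scene_arrays(vol: ScalarVolume, tf: TransferFunction):
    return (vol.values, np.array(vol.origin), np.array(vol.spacing),
            vol.box_min, vol.box_max) + tf.tables()


def render_direct(vol: ScalarVolume, tf: TransferFunction, camera: Camera,
                  light: Light, cfg: RenderConfig) -> RadianceImage:
    """Single-scattering (direct illumination) pass.

    Per sample x' along each eye ray the contribution is
    T_eye(x0, x') * lambda_s(x') * p_HG(cos theta) * color(x') * P_light *
    T(x_l, x') * ds, where T(x_l, x') is a midpoint-rule shadow march.  The
    background radiance is added attenuated by the full-ray transmittance.
    """
    eye, right, up, fwd, tan_half, aspect = camera.basis()
    _, shadow_step, _ = cfg.resolve_steps(vol)
    hdr = _k.render_direct_kernel(
        *_scene_arrays(vol, tf), eye, right, up, fwd, tan_half, aspect,
        camera.width, camera.height,
        np.asarray(light.position, dtype=np.float64), float(light.power),
        np.asarray(cfg.background, dtype=np.float64),
        int(cfg.samples_per_ray), float(shadow_step), float(cfg.g),
        float(cfg.min_transmittance))
    return RadianceImage(hdr)


def render_indirect(vol: ScalarVolume, tf: TransferFunction,
                    flux: FluxVolume, camera: Camera,
                    cfg: RenderConfig) -> RadianceImage:
    """Multiple-scattering (indirect illumination) pass.

    Marches each eye ray through the photon flux grid, accumulating
    T_eye * Phi_local / (4 pi V_voxel) * ds, then applies the separable
    screen-space Gaussian blur that realizes the density-estimation kernel.
    """
    if not flux.congruent_with(vol):
        raise ValueError("flux grid must be congruent with the volume")
    eye, right, up, fwd, tan_half, aspect = camera.basis()
    fr, fg, fb = flux.channels()
    inv_4pi_v = 1.0 / (4.0 * np.pi * vol.voxel_volume)
    hdr = _k.render_indirect_kernel(
        *_scene_arrays(vol, tf), fr, fg, fb, inv_4pi_v,
        eye, right, up, fwd, tan_half, aspect,
        camera.width, camera.height, int(cfg.samples_per_ray))
    return gaussian_blur_separable(RadianceImage(hdr), cfg.delta, cfg.kernel)


def gaussian_taps(delta: float, kernel: int) -> np.ndarray:
    """1-D Gaussian taps G(r) = exp(-r^2 / 2 delta^2) / sqrt(2 pi delta^2)
    at integer offsets, renormalized to sum to 1."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.arange(kernel) - kernel // 2
    taps = np.exp(-r ** 2 / (2.0 * delta ** 2)) / np.sqrt(
        2.0 * np.pi * delta ** 2)
    return taps / taps.sum()


def gaussian_blur_separable(img, delta: float = 1.0, kernel: int = 3):
    """Separable Gaussian blur: a horizontal then a vertical 1-D pass.

    Identical to convolving with the outer-product 2-D kernel but in
    O(n*M*N) + O(m*M*N) instead of O(n*m*M*N).  Edges use clamp-to-edge.
    Accepts a RadianceImage or a raw (H, W, C) / (H, W) array and returns
    the same type.
    """
    taps = gaussian_taps(delta, kernel)
    is_image = isinstance(img, RadianceImage)
    data = img.hdr if is_image else np.asarray(img, dtype=np.float64)
    out = ndimage.correlate1d(data, taps, axis=1, mode="nearest")
    out = ndimage.correlate1d(out, taps, axis=0, mode="nearest")
    return RadianceImage(out) if is_image else out


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def tone_map(img: RadianceImage, key: float = 0.4) -> RadianceImage:
    """Reinhard's global operator: L_d = key*L / (1 + key*L) on luminance.

    The same curve applies to every pixel (a spatially uniform, global
    operator); chrominance is preserved by scaling all three channels by
    L_d / L.  Output lies in [0, 1); key*L = 1 maps to exactly 0.5.
    """
    if key <= 0:
        raise ValueError("tone-map key must be positive")
    if not np.all(np.isfinite(img.hdr)):
        raise ValueError("HDR radiance must be finite")
    lum = img.hdr @ _LUMA
    scaled = key * lum
    ld = scaled / (1.0 + scaled)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(lum > 0, ld / np.where(lum > 0, lum, 1.0), 0.0)
    ldr = np.clip(img.hdr * gain[..., None], 0.0, 1.0)
    return RadianceImage(img.hdr, ldr)


def render_local(vol: ScalarVolume, tf: TransferFunction, camera: Camera,
                 light: Light, cfg: RenderConfig) -> RadianceImage:
    """Gradient-shaded local-illumination baseline.

    Front-to-back emission-absorption compositing with Blinn-Phong shading;
    the surface normal is the negated normalized central-difference gradient
    of the intensity field, with ambient-only shading where the gradient
    magnitude is below ``cfg.grad_eps``.
    """
    gx, gy, gz = np.gradient(vol.values, *vol.spacing)
    eye, right, up, fwd, tan_half, aspect = camera.basis()
    hdr = _k.render_local_kernel(
        vol.values, np.ascontiguousarray(gx), np.ascontiguousarray(gy),
        np.ascontiguousarray(gz), np.array(vol.origin),
        np.array(vol.spacing), vol.box_min, vol.box_max, *tf.tables(),
        eye, right, up, fwd, tan_half, aspect, camera.width, camera.height,
        np.asarray(light.position, dtype=np.float64), float(light.power),
        np.asarray(cfg.background, dtype=np.float64),
        int(cfg.samples_per_ray), float(cfg.ambient), float(cfg.diffuse),
        float(cfg.specular), float(cfg.shininess), float(cfg.grad_eps),
        float(cfg.min_transmittance))
    return RadianceImage(hdr)


def render(vol: ScalarVolume, tf: TransferFunction, camera: Camera,
           light: Light, cfg: RenderConfig, mode: str = "global",
           flux: FluxVolume | None = None) -> RadianceImage:
    """Top-level dispatch: ``local``, ``direct`` or ``global``.

    Global mode sums the direct and indirect HDR images (the two scattering
    orders are strictly additive) and tone-maps the result; direct mode
    omits the indirect term; local mode runs the gradient-shaded baseline.
    When no flux grid is supplied in global mode the photon pass runs first
    with ``cfg.seed``.
    """
    if mode == "local":
        return tone_map(render_local(vol, tf, camera, light, cfg),
                        cfg.tonemap_key)
    if mode == "direct":
        return tone_map(render_direct(vol, tf, camera, light, cfg),
                        cfg.tonemap_key)
    if mode == "global":
        if flux is None:
            flux = emit_photons(vol, tf, light, cfg)
        direct = render_direct(vol, tf, camera, light, cfg)
        indirect = render_indirect(vol, tf, flux, camera, cfg)
        return tone_map(RadianceImage(direct.hdr + indirect.hdr),
                        cfg.tonemap_key)
    raise ValueError(f"unknown render mode {mode!r}")


def render_indirect_reference(vol: ScalarVolume, tf: TransferFunction,
                              records: PhotonRecords, camera: Camera,
                              cfg: RenderConfig,
                              n_neighbors: int = 50) -> RadianceImage:
    """Indirect image by conventional spherical-kernel (KNN) estimation.

    Replaces the flux-grid read at every ray sample with the n-nearest-
    neighbor radiance estimate over the full photon records — the reference
    discretization the screen-space estimator is checked against.  Pure
    numpy/scipy; shares nothing with the compiled screen-space path beyond
    the scene definition.
    """
    dirs = camera.ray_directions()
    h, w, _ = dirs.shape
    eye = np.asarray(camera.eye, dtype=np.float64)
    bmin, bmax = vol.box_min, vol.box_max
    flat_dirs = dirs.reshape(-1, 3)
    # slab-method intersection, vectorized
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (bmin[None, :] - eye[None, :]) / flat_dirs
        t_hi = (bmax[None, :] - eye[None, :]) / flat_dirs
    t_near = np.minimum(t_lo, t_hi)
    t_far = np.maximum(t_lo, t_hi)
    par = np.abs(flat_dirs) < 1e-15
    inside = (eye[None, :] >= bmin) & (eye[None, :] <= bmax)
    t_near[par] = -np.inf
    t_far[par] = np.inf
    t_near[par & ~inside] = np.inf  # parallel miss
    t0 = np.maximum(t_near.max(axis=1), 0.0)
    t1 = t_far.min(axis=1)
    hit = t1 > t0
    n_s = cfg.samples_per_ray
    hdr = np.zeros((h * w, 3))
    idx_hit = np.nonzero(hit)[0]
    if idx_hit.size:
        d_hit = flat_dirs[idx_hit]
        ds = (t1[idx_hit] - t0[idx_hit]) / n_s
        sx, sy, sz = vol.spacing
        grid_org = np.array(vol.origin)
        trans = np.ones(idx_hit.size)
        acc = np.zeros((idx_hit.size, 3))
        for s in range(n_s):
            t = t0[idx_hit] + (s + 0.5) * ds
            pts = eye[None, :] + d_hit * t[:, None]
            # extinction at the sample (clamp-to-edge trilinear)
            u = (pts - grid_org) / np.array([sx, sy, sz])
            u = np.clip(u, 0, np.array(vol.dims) - 1)
            intens = ndimage.map_coordinates(vol.values, u.T, order=1,
                                             mode="nearest")
            _, tau, _ = tf.lookup(intens)
            lms = knn_radiance_batch(records, pts, -d_hit, n_neighbors,
                                     cfg.g)
            t_mid = trans * np.exp(-tau * ds * 0.5)
            acc += (t_mid * ds)[:, None] * lms
            trans = trans * np.exp(-tau * ds)
        hdr[idx_hit] = acc
    return RadianceImage(hdr.reshape(h, w, 3))
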