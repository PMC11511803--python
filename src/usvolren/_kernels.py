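"""Numba-compiled inner loops shared by the optics, photon-map and render modules.

Everything here operates on plain float64 arrays so a single implementation
of trilinear sampling, transfer-function lookup and transmittance marching
backs both the Python-level API (``optics.classify``, ``optics.transmittance``)
and the per-pixel / per-photon loops.

Conventions (fixed package-wide):
  * voxel (i, j, k) is centered at origin + (i*sx, j*sy, k*sz); indices 0-based
  * the medium's bounding box extends half a voxel beyond the outer centers
  * inside the box, trilinear interpolation uses clamp-to-edge coordinates;
    outside the box every sample is vacuum (tau_t = 0)
"""

import math

import numpy as np
from numba import njit

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


# ---------------------------------------------------------------------------
# counter-based RNG: splitmix64, one independent stream per photon
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rng_next(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    z = z ^ (z >> _U64(31))
    return state, z


@njit(cache=True)
def _rng_uniform(state):
    """Uniform double in [0, 1) and the advanced state."""
    state, z = _rng_next(state)
    return state, float(z >> _U64(11)) * _INV53


@njit(cache=True)
def _rng_init(seed, stream):
    # decorrelate streams by scrambling (seed, stream) through two rounds
    state = _U64(seed) * _MIX1 + _U64(stream + 1) * _GOLDEN
    state, _ = _rng_next(state)
    state, _ = _rng_next(state)
    return state


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------

@njit(cache=True)
def _trilinear(grid, org, sp, bmin, bmax, px, py, pz):
    """Clamp-to-edge trilinear sample; 0.0 outside the bounding box."""
    if (px < bmin[0] or px > bmax[0] or py < bmin[1] or py > bmax[1]
            or pz < bmin[2] or pz > bmax[2]):
        return 0.0
    nx, ny, nz = grid.shape
    ux = (px - org[0]) / sp[0]
    uy = (py - org[1]) / sp[1]
    uz = (pz - org[2]) / sp[2]
    if ux < 0.0:
        ux = 0.0
    elif ux > nx - 1.0:
        ux = nx - 1.0
    if uy < 0.0:
        uy = 0.0
    elif uy > ny - 1.0:
        uy = ny - 1.0
    if uz < 0.0:
        uz = 0.0
    elif uz > nz - 1.0:
        uz = nz - 1.0
    i0 = int(ux)
    j0 = int(uy)
    k0 = int(uz)
    if i0 > nx - 2:
        i0 = nx - 2
    if j0 > ny - 2:
        j0 = ny - 2
    if k0 > nz - 2:
        k0 = nz - 2
    fx = ux - i0
    fy = uy - j0
    fz = uz - k0
    c000 = grid[i0, j0, k0]
    c100 = grid[i0 + 1, j0, k0]
    c010 = grid[i0, j0 + 1, k0]
    c110 = grid[i0 + 1, j0 + 1, k0]
    c001 = grid[i0, j0, k0 + 1]
    c101 = grid[i0 + 1, j0, k0 + 1]
    c011 = grid[i0, j0 + 1, k0 + 1]
    c111 = grid[i0 + 1, j0 + 1, k0 + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def _tf_eval(tf_x, tf_rgb, tf_tau, tf_alb, s):
    """Piecewise-linear transfer-function lookup, clamped at the ends.

    Returns (r, g, b, tau_t, albedo).
    """
    n = tf_x.shape[0]
    if s <= tf_x[0]:
        return tf_rgb[0, 0], tf_rgb[0, 1], tf_rgb[0, 2], tf_tau[0], tf_alb[0]
    if s >= tf_x[n - 1]:
        return (tf_rgb[n - 1, 0], tf_rgb[n - 1, 1], tf_rgb[n - 1, 2],
                tf_tau[n - 1], tf_alb[n - 1])
    hi = 1
    while tf_x[hi] < s:
        hi += 1
    lo = hi - 1
    w = (s - tf_x[lo]) / (tf_x[hi] - tf_x[lo])
    r = tf_rgb[lo, 0] * (1 - w) + tf_rgb[hi, 0] * w
    g = tf_rgb[lo, 1] * (1 - w) + tf_rgb[hi, 1] * w
    b = tf_rgb[lo, 2] * (1 - w) + tf_rgb[hi, 2] * w
    tau = tf_tau[lo] * (1 - w) + tf_tau[hi] * w
    alb = tf_alb[lo] * (1 - w) + tf_alb[hi] * w
    return r, g, b, tau, alb


@njit(cache=True)
def _tau_at(grid, org, sp, bmin, bmax, tf_x, tf_rgb, tf_tau, tf_alb,
            px, py, pz):
    if (px < bmin[0] or px > bmax[0] or py < bmin[1] or py > bmax[1]
            or pz < bmin[2] or pz > bmax[2]):
        return 0.0
    s = _trilinear(grid, org, sp, bmin, bmax, px, py, pz)
    _, _, _, tau, _ = _tf_eval(tf_x, tf_rgb, tf_tau, tf_alb, s)
    return tau


@njit(cache=True)
def _transmittance(grid, org, sp, bmin, bmax, tf_x, tf_rgb, tf_tau, tf_alb,
                   ax, ay, az, bx, by, bz, step):
    """Midpoint-rule Beer-Lambert transmittance exp(-integral of tau_t)."""
    dx = bx - ax
    dy = by - ay
    dz = bz - az
    dist = math.sqrt(dx * dx + dy * dy + dz * dz)
    if dist == 0.0:
        return 1.0
    ix = dx / dist
    iy = dy / dist
    iz = dz / dist
    # outside the bounding box the medium is vacuum: integrate only the
    # clipped in-box portion of the segment
    t0, t1, hit = _ray_box(ax, ay, az, ix, iy, iz, bmin, bmax)
    if not hit:
        return 1.0
    s0 = t0 if t0 > 0.0 else 0.0
    s1 = t1 if t1 < dist else dist
    if s1 <= s0:
        return 1.0
    n = int(math.ceil((s1 - s0) / step))
    if n < 1:
        n = 1
    ds = (s1 - s0) / n
    acc = 0.0
    for i in range(n):
        t = s0 + (i + 0.5) * ds
        acc += _tau_at(grid, org, sp, bmin, bmax, tf_x, tf_rgb, tf_tau,
                       tf_alb, ax + ix * t, ay + iy * t, az + iz * t)
    return math.exp(-acc * ds)


@njit(cache=True)
def _ray_box(ox, oy, oz, dx, dy, dz, bmin, bmax):
    """Slab-method ray/AABB intersection; returns (t0, t1, hit)."""
    t0 = -1.0e30
    t1 = 1.0e30
    for a in range(3):
        if a == 0:
            o, d, lo, hi = ox, dx, bmin[0], bmax[0]
        elif a == 1:
            o, d, lo, hi = oy, dy, bmin[1], bmax[1]
        else:
            o, d, lo, hi = oz, dz, bmin[2], bmax[2]
        if abs(d) < 1.0e-15:
            if o < lo or o > hi:
                return 0.0, 0.0, False
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 < t0:
        return 0.0, 0.0, False
    return t0, t1, True


@njit(cache=True)
def _hg_pdf(cos_t, g):
    denom = 1.0 + g * g - 2.0 * g * cos_t
    return (1.0 - g * g) / (4.0 * math.pi * denom * math.sqrt(denom))


@njit(cache=True)
def _sample_hg_dir(wx, wy, wz, g, state):
    """Draw a Henyey-Greenstein direction about propagation axis (wx,wy,wz)."""
    state, u1 = _rng_uniform(state)
    state, u2 = _rng_uniform(state)
    if abs(g) < 1.0e-9:
        cos_t = 1.0 - 2.0 * u1
    else:
        sq = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        cos_t = (1.0 + g * g - sq * sq) / (2.0 * g)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * math.pi * u2
    # orthonormal frame around w
    if abs(wz) < 0.999:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    ux = ay * wz - az * wy
    uy = az * wx - ax * wz
    uz = ax * wy - ay * wx
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= un
    uy /= un
    uz /= un
    vx = wy * uz - wz * uy
    vy = wz * ux - wx * uz
    vz = wx * uy - wy * ux
    cp = math.cos(phi)
    sp_ = math.sin(phi)
    ox = sin_t * (cp * ux + sp_ * vx) + cos_t * wx
    oy = sin_t * (cp * uy + sp_ * vy) + cos_t * wy
    oz = sin_t * (cp * uz + sp_ * vz) + cos_t * wz
    n = math.sqrt(ox * ox + oy * oy + oz * oz)
    return state, ox / n, oy / n, oz / n


# ---------------------------------------------------------------------------
# render passes
# ---------------------------------------------------------------------------

@njit(cache=True)
def render_direct_kernel(grid, org, sp, bmin, bmax,
                         tf_x, tf_rgb, tf_tau, tf_alb,
                         eye, right, up, fwd, tan_half, aspect, width, height,
                         light_pos, light_power, bg,
                         n_samples, shadow_step, g, min_t):
    """Single-scattering pass: deterministic front-to-back Riemann sum.

    Per sample x' at ray parameter t:
        dL = T_eye(mid) * lambda_s * p_HG(w_i . w_0) * color * P * T_light * ds
    with w_i the light propagation direction at x', w_0 the direction of the
    scattered radiance (toward the eye), and T_light a midpoint-rule shadow
    march from the light position.  The background radiance enters attenuated
    by the transmittance over the full ray.
    """
    img = np.zeros((height, width, 3))
    for j in range(height):
        for i in range(width):
            px = (2.0 * (i + 0.5) / width - 1.0) * tan_half * aspect
            py = (1.0 - 2.0 * (j + 0.5) / height) * tan_half
            dx = fwd[0] + px * right[0] + py * up[0]
            dy = fwd[1] + px * right[1] + py * up[1]
            dz = fwd[2] + px * right[2] + py * up[2]
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dn
            dy /= dn
            dz /= dn
            t0, t1, hit = _ray_box(eye[0], eye[1], eye[2], dx, dy, dz,
                                   bmin, bmax)
            if not hit or t1 <= 0.0:
                img[j, i, 0] = bg[0]
                img[j, i, 1] = bg[1]
                img[j, i, 2] = bg[2]
                continue
            if t0 < 0.0:
                t0 = 0.0
            ds = (t1 - t0) / n_samples
            trans = 1.0
            ar = 0.0
            ag = 0.0
            ab = 0.0
            for s in range(n_samples):
                t = t0 + (s + 0.5) * ds
                x = eye[0] + dx * t
                y = eye[1] + dy * t
                z = eye[2] + dz * t
                intens = _trilinear(grid, org, sp, bmin, bmax, x, y, z)
                cr, cg, cb, tau, alb = _tf_eval(tf_x, tf_rgb, tf_tau,
                                                tf_alb, intens)
                lam_s = alb * tau
                if lam_s > 0.0 and light_power > 0.0 and trans >= min_t:
                    lx = x - light_pos[0]
                    ly = y - light_pos[1]
                    lz = z - light_pos[2]
                    ln = math.sqrt(lx * lx + ly * ly + lz * lz)
                    if ln > 0.0:
                        wix = lx / ln
                        wiy = ly / ln
                        wiz = lz / ln
                        cos_t = -(wix * dx + wiy * dy + wiz * dz)
                        phase = _hg_pdf(cos_t, g)
                        t_light = _transmittance(
                            grid, org, sp, bmin, bmax, tf_x, tf_rgb,
                            tf_tau, tf_alb, light_pos[0], light_pos[1],
                            light_pos[2], x, y, z, shadow_step)
                        t_mid = trans * math.exp(-tau * ds * 0.5)
                        w = t_mid * lam_s * phase * light_power * t_light * ds
                        ar += w * cr
                        ag += w * cg
                        ab += w * cb
                trans *= math.exp(-tau * ds)
            img[j, i, 0] = ar + bg[0] * trans
            img[j, i, 1] = ag + bg[1] * trans
            img[j, i, 2] = ab + bg[2] * trans
    return img


@njit(cache=True)
def render_indirect_kernel(grid, org, sp, bmin, bmax,
                           tf_x, tf_rgb, tf_tau, tf_alb,
                           flux_r, flux_g, flux_b, inv_4pi_v,
                           eye, right, up, fwd, tan_half, aspect,
                           width, height, n_samples):
    """Multiple-scattering pass before screen-space smoothing.

    In-scattered radiance per sample is read from the photon flux grid under
    isotropic collection: sigma_s * L_ms = Phi_local / (4 pi V_voxel); the
    accumulation uses the same front-to-back transmittance weights as the
    direct pass.  No background term (that belongs to the direct image).
    """
    img = np.zeros((height, width, 3))
    for j in range(height):
        for i in range(width):
            px = (2.0 * (i + 0.5) / width - 1.0) * tan_half * aspect
            py = (1.0 - 2.0 * (j + 0.5) / height) * tan_half
            dx = fwd[0] + px * right[0] + py * up[0]
            dy = fwd[1] + px * right[1] + py * up[1]
            dz = fwd[2] + px * right[2] + py * up[2]
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dn
            dy /= dn
            dz /= dn
            t0, t1, hit = _ray_box(eye[0], eye[1], eye[2], dx, dy, dz,
                                   bmin, bmax)
            if not hit or t1 <= 0.0:
                continue
            if t0 < 0.0:
                t0 = 0.0
            ds = (t1 - t0) / n_samples
            trans = 1.0
            ar = 0.0
            ag = 0.0
            ab = 0.0
            for s in range(n_samples):
                t = t0 + (s + 0.5) * ds
                x = eye[0] + dx * t
                y = eye[1] + dy * t
                z = eye[2] + dz * t
                intens = _trilinear(grid, org, sp, bmin, bmax, x, y, z)
                _, _, _, tau, _ = _tf_eval(tf_x, tf_rgb, tf_tau, tf_alb,
                                           intens)
                fr = _trilinear(flux_r, org, sp, bmin, bmax, x, y, z)
                fg = _trilinear(flux_g, org, sp, bmin, bmax, x, y, z)
                fb = _trilinear(flux_b, org, sp, bmin, bmax, x, y, z)
                t_mid = trans * math.exp(-tau * ds * 0.5)
                w = t_mid * inv_4pi_v * ds
                ar += w * fr
                ag += w * fg
                ab += w * fb
                trans *= math.exp(-tau * ds)
            img[j, i, 0] = ar
            img[j, i, 1] = ag
            img[j, i, 2] = ab
    return img


@njit(cache=True)
def render_local_kernel(grid, gx, gy, gz, org, sp, bmin, bmax,
                        tf_x, tf_rgb, tf_tau, tf_alb,
                        eye, right, up, fwd, tan_half, aspect, width, height,
                        light_pos, light_power, bg, n_samples,
                        ambient, diffuse, specular, shininess, grad_eps,
                        min_t):
    """Gradient-shaded emission-absorption baseline (Blinn-Phong).

    Normals are the negated normalized intensity gradient; voxels whose
    gradient magnitude falls below grad_eps get ambient shading only.
    """
    img = np.zeros((height, width, 3))
    for j in range(height):
        for i in range(width):
            px = (2.0 * (i + 0.5) / width - 1.0) * tan_half * aspect
            py = (1.0 - 2.0 * (j + 0.5) / height) * tan_half
            dx = fwd[0] + px * right[0] + py * up[0]
            dy = fwd[1] + px * right[1] + py * up[1]
            dz = fwd[2] + px * right[2] + py * up[2]
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx /= dn
            dy /= dn
            dz /= dn
            t0, t1, hit = _ray_box(eye[0], eye[1], eye[2], dx, dy, dz,
                                   bmin, bmax)
            if not hit or t1 <= 0.0:
                img[j, i, 0] = bg[0]
                img[j, i, 1] = bg[1]
                img[j, i, 2] = bg[2]
                continue
            if t0 < 0.0:
                t0 = 0.0
            ds = (t1 - t0) / n_samples
            trans = 1.0
            ar = 0.0
            ag = 0.0
            ab = 0.0
            for s in range(n_samples):
                if trans < min_t:
                    break
                t = t0 + (s + 0.5) * ds
                x = eye[0] + dx * t
                y = eye[1] + dy * t
                z = eye[2] + dz * t
                intens = _trilinear(grid, org, sp, bmin, bmax, x, y, z)
                cr, cg, cb, tau, _ = _tf_eval(tf_x, tf_rgb, tf_tau, tf_alb,
                                              intens)
                if tau <= 0.0:
                    continue
                alpha = 1.0 - math.exp(-tau * ds)
                nx_ = _trilinear(gx, org, sp, bmin, bmax, x, y, z)
                ny_ = _trilinear(gy, org, sp, bmin, bmax, x, y, z)
                nz_ = _trilinear(gz, org, sp, bmin, bmax, x, y, z)
                gn = math.sqrt(nx_ * nx_ + ny_ * ny_ + nz_ * nz_)
                if gn < grad_eps:
                    sr = ambient * cr
                    sg = ambient * cg
                    sb = ambient * cb
                else:
                    nx_ = -nx_ / gn
                    ny_ = -ny_ / gn
                    nz_ = -nz_ / gn
                    lx = light_pos[0] - x
                    ly = light_pos[1] - y
                    lz = light_pos[2] - z
                    ln = math.sqrt(lx * lx + ly * ly + lz * lz)
                    lx /= ln
                    ly /= ln
                    lz /= ln
                    ndl = nx_ * lx + ny_ * ly + nz_ * lz
                    if ndl < 0.0:
                        ndl = 0.0
                    hx = lx - dx
                    hy = ly - dy
                    hz = lz - dz
                    hn = math.sqrt(hx * hx + hy * hy + hz * hz)
                    spec = 0.0
                    if hn > 0.0:
                        ndh = (nx_ * hx + ny_ * hy + nz_ * hz) / hn
                        if ndh > 0.0:
                            spec = ndh ** shininess
                    kd = ambient + diffuse * ndl * light_power
                    ks = specular * spec * light_power
                    sr = kd * cr + ks
                    sg = kd * cg + ks
                    sb = kd * cb + ks
                ar += trans * alpha * sr
                ag += trans * alpha * sg
                ab += trans * alpha * sb
                trans *= 1.0 - alpha
            img[j, i, 0] = ar + bg[0] * trans
            img[j, i, 1] = ag + bg[1] * trans
            img[j, i, 2] = ab + bg[2] * trans
    return img


# ---------------------------------------------------------------------------
# photon tracing
# ---------------------------------------------------------------------------

@njit(cache=True)
def _deposit_trilinear(fr, fg, fb, org, sp, px, py, pz, phi_r, phi_g, phi_b):
    """Trilinear splat over the 8 surrounding voxels (weights sum to 1)."""
    nx, ny, nz = fr.shape
    ux = (px - org[0]) / sp[0]
    uy = (py - org[1]) / sp[1]
    uz = (pz - org[2]) / sp[2]
    i0 = int(math.floor(ux))
    j0 = int(math.floor(uy))
    k0 = int(math.floor(uz))
    if i0 < 0:
        i0 = 0
    elif i0 > nx - 2:
        i0 = nx - 2
    if j0 < 0:
        j0 = 0
    elif j0 > ny - 2:
        j0 = ny - 2
    if k0 < 0:
        k0 = 0
    elif k0 > nz - 2:
        k0 = nz - 2
    fx = ux - i0
    fy = uy - j0
    fz = uz - k0
    if fx < 0.0:
        fx = 0.0
    elif fx > 1.0:
        fx = 1.0
    if fy < 0.0:
        fy = 0.0
    elif fy > 1.0:
        fy = 1.0
    if fz < 0.0:
        fz = 0.0
    elif fz > 1.0:
        fz = 1.0
    for di in range(2):
        wx = fx if di == 1 else 1.0 - fx
        for dj in range(2):
            wy = fy if dj == 1 else 1.0 - fy
            for dk in range(2):
                wz = fz if dk == 1 else 1.0 - fz
                w = wx * wy * wz
                fr[i0 + di, j0 + dj, k0 + dk] += w * phi_r
                fg[i0 + di, j0 + dj, k0 + dk] += w * phi_g
                fb[i0 + di, j0 + dj, k0 + dk] += w * phi_b
    return 0


@njit(cache=True)
def _emit_direction(light_pos, bmin, bmax, state):
    """Direction from the light, uniform over the solid angle of the box.

    Rejection-samples a cone that bounds the box's bounding sphere and keeps
    directions whose ray actually hits the box; a light inside the box emits
    isotropically.
    """
    inside = (bmin[0] <= light_pos[0] <= bmax[0]
              and bmin[1] <= light_pos[1] <= bmax[1]
              and bmin[2] <= light_pos[2] <= bmax[2])
    cx = 0.5 * (bmin[0] + bmax[0])
    cy = 0.5 * (bmin[1] + bmax[1])
    cz = 0.5 * (bmin[2] + bmax[2])
    ex = bmax[0] - cx
    ey = bmax[1] - cy
    ez = bmax[2] - cz
    rad = math.sqrt(ex * ex + ey * ey + ez * ez)
    wx = cx - light_pos[0]
    wy = cy - light_pos[1]
    wz = cz - light_pos[2]
    dist = math.sqrt(wx * wx + wy * wy + wz * wz)
    if inside or dist <= rad:
        # isotropic
        state, u1 = _rng_uniform(state)
        state, u2 = _rng_uniform(state)
        ct = 1.0 - 2.0 * u1
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * u2
        return state, st * math.cos(phi), st * math.sin(phi), ct, True
    wx /= dist
    wy /= dist
    wz /= dist
    cos_cone = math.sqrt(max(0.0, 1.0 - (rad / dist) ** 2))
    for _ in range(10000):
        state, u1 = _rng_uniform(state)
        state, u2 = _rng_uniform(state)
        ct = cos_cone + (1.0 - cos_cone) * u1
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        phi = 2.0 * math.pi * u2
        # frame around w
        if abs(wz) < 0.999:
            ax, ay, az = 0.0, 0.0, 1.0
        else:
            ax, ay, az = 1.0, 0.0, 0.0
        ux = ay * wz - az * wy
        uy = az * wx - ax * wz
        uz = ax * wy - ay * wx
        un = math.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= un
        uy /= un
        uz /= un
        vx = wy * uz - wz * uy
        vy = wz * ux - wx * uz
        vz = wx * uy - wy * ux
        dx = st * (math.cos(phi) * ux + math.sin(phi) * vx) + ct * wx
        dy = st * (math.cos(phi) * uy + math.sin(phi) * vy) + ct * wy
        dz = st * (math.cos(phi) * uz + math.sin(phi) * vz) + ct * wz
        t0, t1, hit = _ray_box(light_pos[0], light_pos[1], light_pos[2],
                               dx, dy, dz, bmin, bmax)
        if hit and t1 > 0.0:
            return state, dx, dy, dz, True
    return state, wx, wy, wz, True


@njit(cache=True)
def trace_photon_kernel(grid, org, sp, bmin, bmax,
                        tf_x, tf_rgb, tf_tau, tf_alb,
                        px, py, pz, dx, dy, dz,
                        phi_r, phi_g, phi_b,
                        flux_r, flux_g, flux_b,
                        state, max_bounces, step, g,
                        rec_pos, rec_dir, rec_flux, rec_n, do_record):
    """March one photon through the medium; returns (fate, n_deposits, rec_n).

    fate: 0 = absorbed, 1 = escaped.

    Free paths are sampled per marching segment with the exact per-segment
    exponential inversion: the segment's tau_t (midpoint value) gives the
    interaction probability p = 1 - exp(-tau*seg); conditional on ksi < p the
    interaction distance within the segment is -log(1-ksi)/tau, which composes
    to exact exponential sampling in piecewise-constant media.  At an
    interaction, Russian roulette with survival probability = local albedo
    decides scatter (deposit the undiminished flux, draw a Henyey-Greenstein
    direction) versus absorption.
    """
    n_dep = 0
    # advance onto the box if starting outside
    if (px < bmin[0] or px > bmax[0] or py < bmin[1] or py > bmax[1]
            or pz < bmin[2] or pz > bmax[2]):
        t0, t1, hit = _ray_box(px, py, pz, dx, dy, dz, bmin, bmax)
        if not hit or t1 <= 0.0:
            return 1, n_dep, rec_n, state
        if t0 < 0.0:
            t0 = 0.0
        px += dx * t0
        py += dy * t0
        pz += dz * t0
    bounces = 0
    while True:
        t0, t1, hit = _ray_box(px, py, pz, dx, dy, dz, bmin, bmax)
        if not hit:
            return 1, n_dep, rec_n, state
        remaining = t1  # photon is inside (t0 <= 0)
        travelled = 0.0
        interacted = False
        ix = px
        iy = py
        iz = pz
        while travelled < remaining - 1.0e-12:
            seg = step
            if travelled + seg > remaining:
                seg = remaining - travelled
            mx = px + dx * (travelled + 0.5 * seg)
            my = py + dy * (travelled + 0.5 * seg)
            mz = pz + dz * (travelled + 0.5 * seg)
            tau = _tau_at(grid, org, sp, bmin, bmax, tf_x, tf_rgb, tf_tau,
                          tf_alb, mx, my, mz)
            state, u = _rng_uniform(state)
            if tau > 0.0:
                p_int = 1.0 - math.exp(-tau * seg)
                if u < p_int:
                    d_in = -math.log(1.0 - u) / tau
                    ix = px + dx * (travelled + d_in)
                    iy = py + dy * (travelled + d_in)
                    iz = pz + dz * (travelled + d_in)
                    interacted = True
                    break
            travelled += seg
        if not interacted:
            return 1, n_dep, rec_n, state
        # Russian roulette at the interaction point
        s = _trilinear(grid, org, sp, bmin, bmax, ix, iy, iz)
        _, _, _, _, alb = _tf_eval(tf_x, tf_rgb, tf_tau, tf_alb, s)
        state, u = _rng_uniform(state)
        if u >= alb:
            return 0, n_dep, rec_n, state  # absorbed
        # scatter: deposit the photon's current (undiminished) flux
        _deposit_trilinear(flux_r, flux_g, flux_b, org, sp, ix, iy, iz,
                           phi_r, phi_g, phi_b)
        n_dep += 1
        if do_record:
            rec_pos[rec_n, 0] = ix
            rec_pos[rec_n, 1] = iy
            rec_pos[rec_n, 2] = iz
            rec_dir[rec_n, 0] = dx
            rec_dir[rec_n, 1] = dy
            rec_dir[rec_n, 2] = dz
            rec_flux[rec_n, 0] = phi_r
            rec_flux[rec_n, 1] = phi_g
            rec_flux[rec_n, 2] = phi_b
            rec_n += 1
        bounces += 1
        if bounces >= max_bounces:
            return 0, n_dep, rec_n, state  # hard stop counts as absorbed
        state, dx, dy, dz = _sample_hg_dir(dx, dy, dz, g, state)
        px = ix
        py = iy
        pz = iz


@njit(cache=True)
def emit_photons_kernel(grid, org, sp, bmin, bmax,
                        tf_x, tf_rgb, tf_tau, tf_alb,
                        light_pos, exposure, n_photons,
                        flux_r, flux_g, flux_b,
                        seed, max_bounces, step, g,
                        rec_pos, rec_dir, rec_flux, do_record):
    """Sequential photon loop with one RNG substream per photon.

    Returns (n_absorbed, n_escaped, n_records).
    """
    n_abs = 0
    n_esc = 0
    rec_n = 0
    for i in range(n_photons):
        state = _rng_init(seed, i)
        state, dx, dy, dz, ok = _emit_direction(light_pos, bmin, bmax, state)
        fate, _, rec_n, state = trace_photon_kernel(
            grid, org, sp, bmin, bmax, tf_x, tf_rgb, tf_tau, tf_alb,
            light_pos[0], light_pos[1], light_pos[2], dx, dy, dz,
            exposure, exposure, exposure,
            flux_r, flux_g, flux_b,
            state, max_bounces, step, g,
            rec_pos, rec_dir, rec_flux, rec_n, do_record)
        if fate == 0:
            n_abs += 1
        else:
            n_esc += 1
    return n_abs, n_esc, rec_n
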