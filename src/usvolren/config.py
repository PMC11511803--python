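"""Rendering configuration shared by the ray-casting and photon passes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RenderConfig:
    """Knobs of the two-pass renderer.

    Attributes
    ----------
    samples_per_ray : int
        Riemann-sum samples per eye ray (>= 2); 800 matches the sample
        counts used on clinical volumes.
    step : float or None
        Eye-ray step in mm; derived as box diagonal / samples_per_ray when
        None (informational — the passes always place exactly
        ``samples_per_ray`` samples on the in-box segment).
    shadow_step, photon_step : float or None
        Marching steps (mm) for light-path transmittance and photon free
        paths; derived from the box diagonal (diag/128 and diag/256) when
        None.
    g : float
        Henyey-Greenstein anisotropy, |g| < 1; forward-peaked 0.5 default.
    delta : float
        Standard deviation (pixels) of the screen-space Gaussian used as the
        density-estimation low-pass kernel.
    kernel : int
        Odd Gaussian tap count; 3 gives the 3x3 separable blur.
    seed : int
        Master seed for photon tracing; photon i uses substream i.
    max_bounces : int
        Hard cap on scatter events per photon (counts as absorption).
    tonemap_key : float
        Exposure scale of the global tone-mapping operator.
    background : rgb
        Background radiance entering the volume from behind.
    """

    samples_per_ray: int = 800
    step: float | None = None
    shadow_step: float | None = None
    photon_step: float | None = None
    g: float = 0.5
    delta: float = 1.0
    kernel: int = 3
    seed: int = 0
    max_bounces: int = 32
    tonemap_key: float = 0.4
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # local-illumination (Blinn-Phong) baseline coefficients
    ambient: float = 0.2
    diffuse: float = 0.7
    specular: float = 0.2
    shininess: float = 32.0
    grad_eps: float = 1.0e-4
    min_transmittance: float = 0.005

    def __post_init__(self):
        if self.samples_per_ray < 2:
            raise ValueError("samples_per_ray must be >= 2")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd and >= 1")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if abs(self.g) >= 1.0:
            raise ValueError("anisotropy g must satisfy |g| < 1")
        if self.max_bounces < 1:
            raise ValueError("max_bounces must be >= 1")

    def resolve_steps(self, vol) -> tuple[float, float, float]:
        """Concrete (eye, shadow, photon) steps in mm for a given volume."""
        diag = float(np.linalg.norm(vol.box_max - vol.box_min))
        eye = self.step if self.step is not None else diag / self.samples_per_ray
        shadow = self.shadow_step if self.shadow_step is not None else diag / 128.0
        photon = self.photon_step if self.photon_step is not None else diag / 256.0
        return eye, shadow, photon
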