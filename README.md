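# usvolren

Global-illumination volume rendering for 3D fetal ultrasound, as a CPU
reference implementation: direct (single-scattering) and indirect
(multiple-scattering) illumination are computed separately, the indirect
term by volumetric photon mapping with a screen-space density estimation,
plus speckle-aware preprocessing and HDR tone mapping.

## Who this is for

3D obstetric ultrasound is usually rendered with local (gradient-shaded)
illumination, which produces plastic-looking surfaces, is hypersensitive to
speckle noise, and conveys little depth. Treating the volume as a
*participating medium* — tissue that absorbs and scatters light — produces
skin-like translucency, soft shadows and usable depth cues. This package
implements that pipeline end to end in testable Python (numpy + numba),
for people who want to study, verify or extend the method rather than run
it at clinical frame rates.

## The model

Emission is neglected, and per-pixel radiance splits exactly into

    L(x_s, ω₀) = L₀ T(x₀, x_s)
               + ∫ λ_s(x′) L_ss(x′, ω₀) T(x′, x_s) dx′    — direct
               + ∫ λ_s(x′) L_ms(x′, ω₀) T(x′, x_s) dx′    — indirect

with transmittance `T(a,b) = exp(−∫ τ_t dt)`, extinction `τ_t`, scattering
coefficient `λ_s = a·τ_t` (albedo `a`), and the Henyey–Greenstein phase
function `p(cosθ) = (1/4π)(1−g²)/(1+g²−2g cosθ)^{3/2}` for anisotropy `g`.

* **Direct pass** — deterministic ray casting: at every sample the phase
  function is evaluated at the exact eye–light angle and the light is
  attenuated by a shadow march.
* **Photon pass** — photons leave the light toward the volume, interact at
  exponentially sampled free paths, survive by Russian roulette with
  probability equal to the local albedo, and deposit their flux into a
  voxel grid (the indirect illumination volume).
* **Indirect pass** — eye rays integrate the stored flux density
  (`σ_s L_ms = Φ_local / 4π V_voxel`) and a separable 3×3 Gaussian in
  image space completes the density estimation.
* **Tone map** — Reinhard's global operator `L_d = kL/(1+kL)` compresses
  the HDR sum for display.

Everything is seedable and bit-reproducible; the conventional
nearest-neighbor (spherical-kernel) photon estimator is included as an
independent cross-check of the screen-space estimator. Details and design
rationale are in [docs/methods.md](docs/methods.md).

## Worked example

No clinical data ship with the package; the phantom generator produces
fetal-like speckled volumes instead:

```bash
usvolren phantom --dims 64,64,64 --seed 7 --out fetus.mhd
usvolren render --volume fetus.mhd --mode global \
    --photons 100000 --samples 400 --size 128x128 --seed 7 \
    --denoise-iters 10 --out fetus.png --hdr fetus.pfm
```

which logs

```
INFO usvolren: phantom (64, 64, 64) written to fetus.mhd (0.12 s)
INFO usvolren: loaded volume (64, 64, 64) in 0.01 s
INFO usvolren: denoise: 10 iterations in 0.11 s
INFO usvolren: photons: emitted=100000 absorbed=11723 escaped=88277 (3.42 s)
INFO usvolren: render (global, 128x128): 16.06 s
INFO usvolren: wrote fetus.png
```

Reading the numbers: all 100 000 photons are accounted for
(`absorbed + escaped = emitted` — the conservation law the tests enforce);
~12% terminate inside tissue while the rest exit the box after zero or more
scatters, each scatter having deposited the photon's 0.4 exposure into the
flux grid. The PNG is the tone-mapped sum of the direct and indirect HDR
images; the PFM holds the raw radiance. Rerunning either command with the
same seed reproduces both files byte for byte.

The same pipeline is available as a library:

```python
import usvolren as u

vol   = u.fetal_phantom(dims=(64, 64, 64), seed=7)
tf    = u.TransferFunction.ramp(extinction=2.0, albedo=0.9)
light = u.Light(position=(-80, -80, 120), exposure=0.4, n_photons=100_000)
cam   = u.Camera(eye=(31.5, -150, 60), look_at=(31.5, 31.5, 31.5),
                 width=128, height=128)
cfg   = u.RenderConfig(seed=7, g=0.5)

flux = u.emit_photons(vol, tf, light, cfg)      # indirect illumination volume
img  = u.render(vol, tf, cam, light, cfg, mode="global", flux=flux)
u.write_image(img, "fetus.png")
```

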