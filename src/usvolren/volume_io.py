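"""Volume, transfer-function and image I/O.

The canonical volume format is uncompressed MetaImage (.mhd header + .raw
payload), read and written through SimpleITK; NIfTI (.nii/.nii.gz) is
supported read-only.  Voxel (i, j, k) is centered at
``origin + (i*sx, j*sy, k*sz)`` with 0-based indices and x-fastest raw
storage order (the MetaImage convention).

Output images are 8-bit PNG for tone-mapped (LDR) buffers and PFM (portable
float map) for raw HDR radiance.  The PFM codec is implemented here: the
format is a three-line text header followed by raw little-endian float32
scanlines, bottom row first.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk
import yaml


class VolumeFormatError(ValueError):
    """Header/payload inconsistency or unsupported volume layout."""


class TransferFunctionFormatError(ValueError):
    """Malformed or invalid transfer-function config file."""


@dataclass
class ScalarVolume:
    """A 3D scalar intensity field on a regular voxel grid (the medium).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite intensities in [0, 1].
    spacing : 3-tuple of float
        Voxel edge lengths in mm, all > 0.
    origin : 3-tuple of float
        World position (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        if any(n < 2 for n in self.values.shape):
            raise ValueError("every dimension must have at least 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        if len(self.origin) != 3:
            raise ValueError("origin must be a 3-vector (mm)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("volume values must lie in [0, 1]; "
                             "read with normalize=True or rescale first")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def box_min(self) -> np.ndarray:
        """Lower corner of the medium's bounding box (half a voxel out)."""
        return np.array(self.origin) - 0.5 * np.array(self.spacing)

    @property
    def box_max(self) -> np.ndarray:
        d = np.array(self.dims, dtype=float)
        return np.array(self.origin) + (d - 0.5) * np.array(self.spacing)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_center(self, i: int, j: int, k: int) -> np.ndarray:
        return np.array(self.origin) + np.array([i, j, k]) * np.array(
            self.spacing)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.values.copy(), self.spacing, self.origin)


def read_volume(path: str, normalize: bool = True) -> ScalarVolume:
    """Read a MetaImage (.mhd) or NIfTI (.nii/.nii.gz) volume.

    With ``normalize`` the values are min-max mapped to [0, 1]; a constant
    volume (min == max) maps to all zeros.  Spacing and origin default to
    (1,1,1) mm / (0,0,0) when the header lacks them (SimpleITK fills these).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise VolumeFormatError(
            f"expected a 3D volume, got {arr.ndim} dimensions")
    values = np.ascontiguousarray(arr.transpose(2, 1, 0), dtype=np.float64)
    if normalize:
        lo = values.min()
        hi = values.max()
        if hi > lo:
            values = (values - lo) / (hi - lo)
        else:
            values = np.zeros_like(values)
    return ScalarVolume(values, tuple(img.GetSpacing()),
                        tuple(img.GetOrigin()))


def write_volume(vol: ScalarVolume, path: str) -> None:
    """Write an uncompressed MetaImage pair (float32 payload).

    The header records dims, spacing and origin; two writes of the same
    volume are byte-identical.
    """
    arr = vol.values.astype(np.float32).transpose(2, 1, 0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    try:
        sitk.WriteImage(img, path, useCompression=False)
    except RuntimeError as exc:
        raise IOError(f"cannot write volume to {path!r}: {exc}") from exc


def read_transfer_function(path: str):
    """Read a transfer-function config (YAML/JSON).

    The file holds a list of breakpoints, either top-level or under the key
    ``breakpoints``, each a mapping with ``intensity``, ``rgb`` (3 floats),
    ``extinction`` (tau_t per mm) and ``albedo``.  Validation and endpoint
    clamping happen in :class:`usvolren.optics.TransferFunction`.
    """
    from .optics import TransferFunction

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("breakpoints")
    if not isinstance(data, list) or not data:
        raise TransferFunctionFormatError(
            "transfer-function file must contain a non-empty breakpoint list")
    bps = []
    for entry in data:
        try:
            bps.append((float(entry["intensity"]),
                        tuple(float(c) for c in entry["rgb"]),
                        float(entry["extinction"]),
                        float(entry["albedo"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise TransferFunctionFormatError(
                f"malformed breakpoint {entry!r}: {exc}") from exc
    try:
        return TransferFunction(bps)
    except ValueError as exc:
        raise TransferFunctionFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

class ImageStateError(RuntimeError):
    """LDR output requested before tone mapping."""


def write_image(img, path: str, mode: str = "ldr") -> None:
    """Write a rendered image: ``ldr`` -> 8-bit PNG, ``hdr`` -> float PFM."""
    if mode == "ldr":
        if img.ldr is None:
            raise ImageStateError(
                "LDR buffer absent: run render.tone_map before writing PNG")
        data = np.clip(np.rint(img.ldr * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(path, data, extension=os.path.splitext(path)[1] or ".png")
    elif mode == "hdr":
        if not np.all(np.isfinite(img.hdr)):
            raise ValueError("HDR radiance must be finite")
        write_pfm(path, img.hdr)
    else:
        raise ValueError(f"unknown image mode {mode!r}")


def write_pfm(path: str, data: np.ndarray) -> None:
    """Write a color PFM (little-endian float32, bottom row first)."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("PFM writer expects an (H, W, 3) array")
    h, w, _ = arr.shape
    with open(path, "wb") as fh:
        fh.write(b"PF\n")
        fh.write(f"{w} {h}\n".encode())
        fh.write(b"-1.0\n")  # negative scale => little endian
        fh.write(arr[::-1].tobytes())


def read_pfm(path: str) -> np.ndarray:
    """Read a PFM image back into an (H, W, 3) float32 array."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic not in (b"PF", b"Pf"):
            raise VolumeFormatError(f"not a PFM file: {path!r}")
        w, h = (int(v) for v in fh.readline().split())
        scale = float(fh.readline())
        n_chan = 3 if magic == b"PF" else 1
        count = w * h * n_chan
        payload = fh.read(count * 4)
        if len(payload) != count * 4:
            raise VolumeFormatError("truncated PFM payload")
        dt = "<f4" if scale < 0 else ">f4"
        arr = np.frombuffer(payload, dtype=dt).reshape(h, w, n_chan)
        return np.ascontiguousarray(arr[::-1]).astype(np.float32)
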