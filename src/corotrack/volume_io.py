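"""3-D scalar volumes: file I/O, world/voxel transforms, interpolated sampling.

All public coordinates are world millimetres.  Voxel indices are 0-based and
voxel ``(i, j, k)`` has its center at ``origin + spacing * (i, j, k)``; the
array is indexed ``data[i, j, k]`` in the same axis order as ``spacing``.
Only axis-aligned volumes are supported — a file whose direction matrix is not
a permutation-free identity is rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

SUPPORTED_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd", ".nrrd")


class VolumeFormatError(RuntimeError):
    """Raised when a volume file cannot be read or has an unsupported layout."""


@dataclass
class Volume:
    """A 3-D intensity grid with physical spacing and origin.

    Parameters
    ----------
    data:
        3-D float array, indexed ``[i, j, k]``.
    spacing:
        Per-axis voxel size in mm, all components > 0.
    origin:
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    fill_value:
        Intensity returned for out-of-bounds samples.  Defaults to the
        global minimum of ``data`` (the tracker probes freely near edges).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    fill_value: float | None = None
    _interp: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must all be > 0")
        if self.fill_value is None:
            self.fill_value = float(self.data.min())

    # ------------------------------------------------------------------ #
    # coordinate transforms
    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, p) -> np.ndarray:
        """Continuous voxel coordinates of world point(s) ``p`` (mm)."""
        return (np.asarray(p, dtype=np.float64) - self.origin) / self.spacing

    def voxel_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel index."""
        return self.origin + np.asarray(idx, dtype=np.float64) * self.spacing

    def contains(self, p, margin_vox: float = 0.0) -> bool:
        """True when ``p`` lies inside the voxel-center bounding box."""
        v = self.world_to_voxel(p)
        hi = np.array(self.shape) - 1
        return bool(np.all(v >= -margin_vox) and np.all(v <= hi + margin_vox))

    # ------------------------------------------------------------------ #
    # sampling
    # ------------------------------------------------------------------ #
    def sample_trilinear(self, p):
        """Trilinear interpolation at world point(s) ``p``.

        Out-of-bounds points get ``fill_value``.  Accepts a single point
        (shape ``(3,)``) or an array of points (shape ``(n, 3)``); returns a
        scalar or an ``(n,)`` array correspondingly.
        """
        vals, _ = self.sample_trilinear_flagged(p)
        return vals

    def sample_trilinear_flagged(self, p):
        """Like :meth:`sample_trilinear` but also returns an out-of-bounds mask."""
        from scipy.interpolate import RegularGridInterpolator

        if self._interp is None:
            axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
                    for a in range(3)]
            self._interp = RegularGridInterpolator(
                axes, self.data, method="linear",
                bounds_error=False, fill_value=self.fill_value)
        pts = np.atleast_2d(np.asarray(p, dtype=np.float64))
        vals = self._interp(pts)
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        oob = np.any((pts < lo) | (pts > hi), axis=1)
        if np.asarray(p).ndim == 1:
            return float(vals[0]), bool(oob[0])
        return vals, oob

    def _ball_indices(self, c, r: float):
        """Voxel index grids (i, j, k arrays) of the bbox around sphere (c, r)."""
        c = np.asarray(c, dtype=np.float64)
        lo = np.maximum(np.floor(self.world_to_voxel(c - r)).astype(int), 0)
        hi = np.minimum(np.ceil(self.world_to_voxel(c + r)).astype(int),
                        np.array(self.shape) - 1)
        if np.any(lo > hi):
            return None
        grids = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)],
                            indexing="ij")
        return grids

    def mean_in_sphere(self, c, r: float) -> float:
        """Mean intensity over voxel centers within world distance ``r`` of ``c``.

        Falls back to trilinear sampling at ``c`` when no voxel center lies
        inside the sphere (sub-voxel radius).
        """
        if r <= 0:
            raise ValueError("sphere radius must be > 0")
        grids = self._ball_indices(c, r)
        if grids is not None:
            c = np.asarray(c, dtype=np.float64)
            d2 = sum(((g * self.spacing[a] + self.origin[a]) - c[a]) ** 2
                     for a, g in enumerate(grids))
            inside = d2 <= r * r
            if inside.any():
                return float(self.data[grids[0][inside], grids[1][inside],
                                       grids[2][inside]].mean())
        return float(self.sample_trilinear(c))

    def mean_in_shell(self, c, r_in: float, r_out: float) -> float:
        """Mean intensity over voxel centers with ``r_in < dist ≤ r_out``.

        An empty shell is widened once by one voxel diagonal; if still empty
        an error is raised.
        """
        if not (r_out > r_in > 0):
            raise ValueError("require r_out > r_in > 0")
        diag = float(np.linalg.norm(self.spacing))
        for outer in (r_out, r_out + diag):
            grids = self._ball_indices(c, outer)
            if grids is None:
                continue
            c_arr = np.asarray(c, dtype=np.float64)
            d2 = sum(((g * self.spacing[a] + self.origin[a]) - c_arr[a]) ** 2
                     for a, g in enumerate(grids))
            inside = (d2 > r_in * r_in) & (d2 <= outer * outer)
            if inside.any():
                return float(self.data[grids[0][inside], grids[1][inside],
                                       grids[2][inside]].mean())
        raise ValueError("shell contains no voxel centers even after widening")


def default_shell_outer(r_in: float, spacing) -> float:
    """Default background-shell outer radius: r_in + max(1 voxel diag, 0.5·r_in)."""
    diag = float(np.linalg.norm(np.asarray(spacing, dtype=np.float64)))
    return r_in + max(diag, 0.5 * r_in)


# ---------------------------------------------------------------------- #
# file I/O
# ---------------------------------------------------------------------- #
def _check_extension(path: str) -> None:
    low = str(path).lower()
    if not any(low.endswith(ext) for ext in SUPPORTED_EXTENSIONS):
        raise VolumeFormatError(
            f"unsupported volume format for {path!r}; "
            f"expected one of {SUPPORTED_EXTENSIONS}")


def read_volume(path: str) -> Volume:
    """Read a volume from NIfTI / MetaImage / NRRD.

    Header spacing and origin are honored; intensities are unmodified.
    Raises :class:`VolumeFormatError` for missing, truncated or
    non-axis-aligned files.
    """
    _check_extension(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path!r}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeFormatError(
            f"{path!r} has a non-axis-aligned direction matrix; only "
            "identity orientation is supported")
    # SimpleITK arrays come back [z, y, x]; transpose to [x, y, z] so that
    # data[i, j, k] matches spacing/origin component order.
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data=data,
                  spacing=np.asarray(img.GetSpacing()),
                  origin=np.asarray(img.GetOrigin()))


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume in the format implied by the file extension."""
    _check_extension(path)
    img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))
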