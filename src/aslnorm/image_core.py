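"""Volumetric image container, NIfTI I/O, resampling, smoothing, percentile normalization.

Conventions
-----------
* World coordinates are millimetres on RAS+ axes; voxel indices are 0-based.
* All parametric transforms map FIXED (standard-space) world coordinates to
  MOVING (native-space) world coordinates — the pull-back convention — so an
  output image is produced with a single interpolation and no transform
  inversion.
* Coordinates that fall outside the source volume sample as 0 (CBF outside
  the head is essentially zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    DimensionalityError,
    GeometryError,
    ParameterError,
)

__all__ = [
    "ImageGeometry",
    "VolumetricImage",
    "TissueTemplate",
    "read_volume",
    "write_volume",
    "resample",
    "gaussian_smooth",
    "percentile_normalize",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ImageGeometry:
    """Shape plus voxel-to-world affine of a 3-D scalar grid.

    Parameters
    ----------
    shape
        Grid size in voxels, three positive integers.
    voxel_to_world
        4x4 homogeneous matrix mapping 0-based voxel indices to world
        millimetres (RAS+).
    """

    shape: tuple[int, int, int]
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ParameterError(f"shape must be 3 positive integers, got {self.shape}")
        mat = np.asarray(self.voxel_to_world, dtype=float)
        if mat.shape != (4, 4):
            raise ParameterError("voxel_to_world must be a 4x4 matrix")
        if abs(np.linalg.det(mat[:3, :3])) < 1e-12:
            raise ParameterError("voxel_to_world must be invertible")
        sizes = np.linalg.norm(mat[:3, :3], axis=0)
        if np.any(sizes <= 0):
            raise ParameterError("derived voxel sizes must be strictly positive")
        mat = mat.copy()
        mat.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_to_world", mat)

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    @property
    def world_to_voxel(self) -> np.ndarray:
        return np.linalg.inv(self.voxel_to_world)

    def voxel_to_world_points(self, ijk: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.voxel_to_world[:3, :3].T + self.voxel_to_world[:3, 3]

    def world_to_voxel_points(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to fractional voxel indices."""
        inv = self.world_to_voxel
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre; shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = idx.reshape(3, -1).T
        return self.voxel_to_world_points(pts).reshape(self.shape + (3,))

    def approx_equal(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.voxel_to_world, other.voxel_to_world, atol=tol)
        )

    def __eq__(self, other: object) -> bool:  # exact comparison
        if not isinstance(other, ImageGeometry):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.voxel_to_world, other.voxel_to_world)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_to_world.tobytes()))


def centered_geometry(shape: Iterable[int], voxel_mm: Iterable[float]) -> ImageGeometry:
    """Axis-aligned RAS+ geometry with the world origin at the volume centre."""
    shape = tuple(int(s) for s in shape)
    voxel = np.asarray(tuple(voxel_mm), dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = -voxel * (np.asarray(shape) - 1) / 2.0
    return ImageGeometry(shape, affine)


_PAYLOAD_KINDS = ("cbf_ml_per_100g_min", "probability", "mask", "arbitrary")


@dataclass(frozen=True)
class VolumetricImage:
    """A scalar 3-D volume with its grid geometry and a payload tag.

    ``payload_kind`` is one of ``cbf_ml_per_100g_min`` (perfusion in
    ml/100 g/min), ``probability`` (values in [0, 1]), ``mask`` (values in
    {0, 1}) or ``arbitrary``.
    """

    geometry: ImageGeometry
    voxels: np.ndarray
    payload_kind: str = "arbitrary"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.shape != self.geometry.shape:
            raise GeometryError(
                f"voxel array shape {vox.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(vox)):
            raise ParameterError("voxel values must all be finite")
        if self.payload_kind not in _PAYLOAD_KINDS:
            raise ParameterError(f"unknown payload_kind {self.payload_kind!r}")
        if self.payload_kind == "probability" and (
            vox.min() < -1e-6 or vox.max() > 1 + 1e-6
        ):
            raise ParameterError("probability payload must lie in [0, 1]")
        if self.payload_kind == "mask" and not np.all(np.isin(vox, (0.0, 1.0))):
            raise ParameterError("mask payload must contain only 0 and 1")
        object.__setattr__(self, "voxels", vox)

    def with_voxels(self, voxels: np.ndarray, payload_kind: str | None = None) -> "VolumetricImage":
        return VolumetricImage(
            self.geometry, voxels, payload_kind or self.payload_kind
        )

    def mask_array(self) -> np.ndarray:
        return self.voxels > 0.5


@dataclass(frozen=True)
class TissueTemplate:
    """Standard-space GM/WM(/CSF) probability maps plus brain mask on one grid."""

    gm: VolumetricImage
    wm: VolumetricImage
    csf: VolumetricImage | None = None
    brain_mask: VolumetricImage = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        parts = [self.gm, self.wm] + ([self.csf] if self.csf is not None else [])
        geo = self.gm.geometry
        for p in parts:
            if not p.geometry.approx_equal(geo):
                raise GeometryError("all template components must share one geometry")
        total = self.gm.voxels + self.wm.voxels
        if self.csf is not None:
            total = total + self.csf.voxels
        if total.max() > 1 + 1e-6:
            raise ParameterError("tissue probabilities must sum to <= 1 voxelwise")
        if self.brain_mask is None:
            mask = (total > 0.5).astype(float)
            object.__setattr__(
                self, "brain_mask", VolumetricImage(geo, mask, "mask")
            )
        elif not self.brain_mask.geometry.approx_equal(geo):
            raise GeometryError("brain mask must share the template geometry")

    @property
    def geometry(self) -> ImageGeometry:
        return self.gm.geometry


def read_volume(path: str | Path, payload_kind: str = "arbitrary") -> VolumetricImage:
    """Read a NIfTI-1 scalar volume.

    Scaling slope/intercept is applied; the file's affine becomes the
    voxel-to-world matrix. Trailing singleton dimensions are squeezed; a true
    4-D input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim > 3:
        extra = [d for d in range(3, data.ndim) if data.shape[d] > 1]
        if extra:
            raise DimensionalityError(
                f"expected a 3-D volume, got {data.ndim}-D with axis {extra[0]} "
                f"of length {data.shape[extra[0]]}"
            )
        data = data.reshape(data.shape[:3])
    geometry = ImageGeometry(data.shape, np.asarray(img.affine, dtype=float))
    return VolumetricImage(geometry, data, payload_kind)


def write_volume(image: VolumetricImage, path: str | Path) -> None:
    """Write a NIfTI-1 file; masks as uint8, everything else as float32."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    dtype = np.uint8 if image.payload_kind == "mask" else np.float32
    out = nib.Nifti1Image(
        image.voxels.astype(dtype), np.asarray(image.geometry.voxel_to_world)
    )
    out.header.set_data_dtype(dtype)
    nib.save(out, str(path))


def _mapping_coords(target: ImageGeometry, mapping) -> np.ndarray:
    """Native-space world coordinates for every target voxel, shape (N, 3)."""
    if hasattr(mapping, "coords"):  # DeformationField
        if tuple(mapping.geometry.shape) != tuple(target.shape) or not mapping.geometry.approx_equal(target):
            raise GeometryError("deformation field geometry must equal the target geometry")
        return np.asarray(mapping.coords, dtype=float).reshape(-1, 3)
    pts = target.world_grid().reshape(-1, 3)
    return np.asarray(mapping.apply(pts), dtype=float)


def resample(
    image: VolumetricImage,
    target: ImageGeometry,
    mapping,
    order: int = 1,
) -> VolumetricImage:
    """Pull ``image`` onto ``target`` through ``mapping`` with ONE interpolation.

    ``mapping`` is either a parametric transform (anything with an
    ``apply(points)`` method taking/returning world mm) or a dense
    ``DeformationField`` on the target grid. However many parametric steps the
    mapping composes, the source volume is interpolated exactly once.
    Coordinates outside the source sample as 0.
    """
    if order not in (0, 1, 3):
        raise ParameterError(f"interpolation order must be 0, 1 or 3, got {order}")
    native_pts = _mapping_coords(target, mapping)
    vox = image.geometry.world_to_voxel_points(native_pts)
    out = ndimage.map_coordinates(
        image.voxels,
        vox.T,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=(order > 1),
    ).reshape(target.shape)
    kind = image.payload_kind
    if kind == "mask" and order > 0:
        kind = "arbitrary"
    elif kind == "probability" and order > 1:
        out = np.clip(out, 0.0, 1.0)
    return VolumetricImage(target, out, kind)


def gaussian_smooth(image: VolumetricImage, fwhm_mm) -> VolumetricImage:
    """Separable Gaussian smoothing with per-axis FWHM given in millimetres.

    sigma = FWHM / (2*sqrt(2 ln 2)) per axis, converted to voxels through the
    geometry's voxel sizes. FWHM 0 on every axis is the identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ParameterError("FWHM must be nonnegative")
    if np.all(fwhm == 0):
        return replace(image)
    sigma_vox = fwhm * FWHM_TO_SIGMA / image.geometry.voxel_sizes_mm
    out = ndimage.gaussian_filter(image.voxels, sigma_vox, mode="constant", cval=0.0)
    return image.with_voxels(out)


def percentile_normalize(
    image: VolumetricImage,
    mask: VolumetricImage,
    p: float = 97.0,
) -> tuple[VolumetricImage, VolumetricImage]:
    """Normalize to the p-th percentile within a mask, excluding brighter voxels.

    Negative values (ASL noise) are clipped to 0 first. The percentile P uses
    linear interpolation between order statistics. Returns the normalized
    image (clipped / P) and the inclusion mask: the input mask minus voxels
    whose clipped value exceeds P.
    """
    if not mask.geometry.approx_equal(image.geometry):
        raise GeometryError("mask and image must share a geometry")
    m = mask.mask_array()
    if not m.any():
        raise DegenerateInputError("mask is empty")
    clipped = np.maximum(image.voxels, 0.0)
    vals = clipped[m]
    if vals.max() <= 0:
        raise DegenerateInputError("image is nonpositive everywhere within the mask")
    P = float(np.percentile(vals, p))
    if P <= 0:
        raise DegenerateInputError(f"{p}th percentile within mask is nonpositive")
    normalized = image.with_voxels(clipped / P, "arbitrary")
    included = m & ~(clipped > P)
    return normalized, VolumetricImage(image.geometry, included.astype(float), "mask")
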