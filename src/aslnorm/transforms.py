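"""Parametric spatial transforms and their composition into a deformation field.

All transforms map fixed (standard-space) world coordinates in mm to moving
(native-space) world coordinates — the pull-back convention used throughout
the package.

The nonlinear warp is parameterized by a small tensor product of
low-frequency discrete-cosine basis functions (order ``K`` per axis, 16 by
default), the classic low-dimensional basis for brain spatial normalization.
The warp acts as::

    native = Affine(fixed + u(fixed))

where the displacement ``u`` is expressed on the fixed grid and composed
inside the affine part.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .errors import ParameterError
from .image_core import ImageGeometry

__all__ = [
    "RigidParams",
    "AffineParams",
    "DCTWarp",
    "DeformationField",
    "SpatialTransform",
    "rigid_matrix",
    "affine_matrix",
    "dct_basis",
    "dct_basis_at",
    "warp_displacement",
    "compose_to_field",
    "save_transform_chain",
    "load_transform_chain",
]

CONTAINER_VERSION = 1


def _rotation_matrices(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


@dataclass(frozen=True)
class RigidParams:
    """Rigid-body transform: translation (mm) and rotation (radians).

    Rotations are applied as Rx @ Ry @ Rz about the world axes; the full
    matrix is T(translation) @ Rx @ Ry @ Rz.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.translation)
        r = tuple(float(v) for v in self.rotation)
        if len(t) != 3 or len(r) != 3:
            raise ParameterError("translation and rotation must have 3 components")
        if not all(np.isfinite(t + r)):
            raise ParameterError("rigid parameters must be finite")
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "rotation", r)

    def matrix(self) -> np.ndarray:
        return rigid_matrix(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        M = self.matrix()
        pts = np.asarray(points, dtype=float)
        return pts @ M[:3, :3].T + M[:3, 3]


@dataclass(frozen=True)
class AffineParams:
    """12-parameter affine: T @ R @ Shear @ Scale (factor order fixed)."""

    rigid: RigidParams = field(default_factory=RigidParams)
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shears: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        s = tuple(float(v) for v in self.scales)
        h = tuple(float(v) for v in self.shears)
        if any(v <= 0 for v in s):
            raise ParameterError(f"scales must be positive, got {s}")
        object.__setattr__(self, "scales", s)
        object.__setattr__(self, "shears", h)

    def matrix(self) -> np.ndarray:
        return affine_matrix(self)

    def apply(self, points: np.ndarray) -> np.ndarray:
        M = self.matrix()
        pts = np.asarray(points, dtype=float)
        return pts @ M[:3, :3].T + M[:3, 3]


def rigid_matrix(params: RigidParams) -> np.ndarray:
    """4x4 homogeneous matrix T(translation) @ Rx @ Ry @ Rz."""
    M = np.eye(4)
    M[:3, :3] = _rotation_matrices(*params.rotation)
    M[:3, 3] = params.translation
    return M


def affine_matrix(params: AffineParams) -> np.ndarray:
    """4x4 homogeneous matrix T @ R @ Shear @ Scale."""
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = params.shears
    M = np.eye(4)
    M[:3, :3] = (
        _rotation_matrices(*params.rigid.rotation) @ shear @ np.diag(params.scales)
    )
    M[:3, 3] = params.rigid.translation
    return M


def dct_basis(K: int, N: int) -> np.ndarray:
    """N x K matrix of orthonormal DCT-II basis columns.

    Column 0 is the constant sqrt(1/N); column k>0 is
    sqrt(2/N) * cos(pi * (2i + 1) * k / (2N)).
    """
    if not 1 <= K <= N:
        raise ParameterError(f"need 1 <= K <= N, got K={K}, N={N}")
    return dct_basis_at(K, N, np.arange(N, dtype=float))


def dct_basis_at(K: int, N: int, positions: np.ndarray) -> np.ndarray:
    """Continuous extension of :func:`dct_basis` at fractional grid positions."""
    if K < 1 or N < 1:
        raise ParameterError("K and N must be >= 1")
    i = np.asarray(positions, dtype=float)[:, None]
    k = np.arange(K, dtype=float)[None, :]
    B = np.sqrt(2.0 / N) * np.cos(np.pi * (2.0 * i + 1.0) * k / (2.0 * N))
    B[:, 0] = np.sqrt(1.0 / N)
    return B


@dataclass(frozen=True)
class DCTWarp:
    """Nonlinear warp: affine composed with a DCT-basis displacement field.

    ``coeffs`` has shape (3, K, K, K): mm of displacement per world axis as
    coefficients of the tensor-product basis defined on ``fixed_geometry``.
    All-zero coefficients reduce the warp exactly to its affine part.
    """

    affine_part: AffineParams
    coeffs: np.ndarray
    fixed_geometry: ImageGeometry

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=float)
        if c.ndim != 4 or c.shape[0] != 3:
            raise ParameterError("coeffs must have shape (3, K, K, K)")
        if c.shape[1] < 1:
            raise ParameterError("basis order K must be >= 1")
        if not np.all(np.isfinite(c)):
            raise ParameterError("coefficients must be finite")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "coeffs", c)

    @property
    def order(self) -> int:
        return self.coeffs.shape[1]

    def _bases(self) -> list[np.ndarray]:
        K = self.order
        return [dct_basis(K, n) for n in self.fixed_geometry.shape]

    def displacement_grid(self) -> np.ndarray:
        """Displacement (mm) at every fixed-grid voxel; shape (3,) + shape."""
        Bx, By, Bz = self._bases()
        u = np.einsum("ik,dkmn->dimn", Bx, self.coeffs)
        u = np.einsum("jm,dimn->dijn", By, u)
        return np.einsum("ln,dijn->dijl", Bz, u)

    def displacement_at(self, fixed_points_world: np.ndarray) -> np.ndarray:
        """Displacement (mm) at arbitrary fixed-space world points, (N, 3)."""
        vox = self.fixed_geometry.world_to_voxel_points(fixed_points_world)
        K = self.order
        Ns = self.fixed_geometry.shape
        bx = dct_basis_at(K, Ns[0], vox[:, 0])
        by = dct_basis_at(K, Ns[1], vox[:, 1])
        bz = dct_basis_at(K, Ns[2], vox[:, 2])
        return np.einsum("pk,pm,pn,dkmn->pd", bx, by, bz, self.coeffs, optimize=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.affine_part.apply(pts + self.displacement_at(pts))


SpatialTransform = Union[RigidParams, AffineParams, DCTWarp]


@dataclass(frozen=True)
class DeformationField:
    """Dense per-voxel map from a standard grid to native world coordinates."""

    geometry: ImageGeometry
    coords: np.ndarray  # shape + (3,), mm

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != self.geometry.shape + (3,):
            raise ParameterError(
                f"coords shape {c.shape} must be geometry shape + (3,)"
            )
        if not np.all(np.isfinite(c)):
            raise ParameterError("coordinates must be finite")
        object.__setattr__(self, "coords", c)


def warp_displacement(warp: DCTWarp, voxel_indices: Sequence[Sequence[int]]) -> np.ndarray:
    """Displacement vectors (mm) at integer voxel indices of the fixed grid.

    The displacement along axis d at voxel (i, j, l) is the separable triple
    sum sum_kmn coeffs[d,k,m,n] * Bx[i,k] * By[j,m] * Bz[l,n].
    """
    idx = np.atleast_2d(np.asarray(voxel_indices, dtype=int))
    shape = warp.fixed_geometry.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise ParameterError("voxel index outside the fixed grid")
    K = warp.order
    bx = dct_basis_at(K, shape[0], idx[:, 0].astype(float))
    by = dct_basis_at(K, shape[1], idx[:, 1].astype(float))
    bz = dct_basis_at(K, shape[2], idx[:, 2].astype(float))
    return np.einsum("pk,pm,pn,dkmn->pd", bx, by, bz, warp.coeffs, optimize=True)


def compose_to_field(
    chain: Sequence[SpatialTransform], target: ImageGeometry
) -> DeformationField:
    """Compose an ordered transform chain into one dense deformation field.

    Each target voxel's world coordinate is pushed through every transform in
    order; the result is the "single joint transformation" that lets the
    image be produced with a single interpolation. Runs of consecutive
    matrix (rigid/affine) transforms are pre-multiplied into one matrix and
    applied once, so a chain of linear maps is numerically identical to its
    single composite.
    """
    if len(chain) == 0:
        raise ParameterError("transform chain must be nonempty")
    pts = target.world_grid().reshape(-1, 3)
    pending: np.ndarray | None = None
    for t in chain:
        if isinstance(t, (RigidParams, AffineParams)):
            M = t.matrix()
            pending = M if pending is None else M @ pending
        else:
            if pending is not None:
                pts = pts @ pending[:3, :3].T + pending[:3, 3]
                pending = None
            pts = t.apply(pts)
    if pending is not None:
        pts = pts @ pending[:3, :3].T + pending[:3, 3]
    return DeformationField(target, pts.reshape(target.shape + (3,)))


# ---------------------------------------------------------------------------
# Serialization: JSON transform container


def _geometry_to_dict(g: ImageGeometry) -> dict:
    return {"shape": list(g.shape), "voxel_to_world": np.asarray(g.voxel_to_world).tolist()}


def _geometry_from_dict(d: dict) -> ImageGeometry:
    return ImageGeometry(tuple(d["shape"]), np.asarray(d["voxel_to_world"]))


def transform_to_dict(t: SpatialTransform) -> dict:
    if isinstance(t, RigidParams):
        return {"kind": "rigid", "translation": list(t.translation), "rotation": list(t.rotation)}
    if isinstance(t, AffineParams):
        return {
            "kind": "affine",
            "rigid": transform_to_dict(t.rigid),
            "scales": list(t.scales),
            "shears": list(t.shears),
        }
    if isinstance(t, DCTWarp):
        return {
            "kind": "dct_warp",
            "affine_part": transform_to_dict(t.affine_part),
            "order": t.order,
            "coeffs": np.asarray(t.coeffs).tolist(),
            "fixed_geometry": _geometry_to_dict(t.fixed_geometry),
        }
    raise ParameterError(f"unknown transform type {type(t).__name__}")


def transform_from_dict(d: dict) -> SpatialTransform:
    kind = d["kind"]
    if kind == "rigid":
        return RigidParams(tuple(d["translation"]), tuple(d["rotation"]))
    if kind == "affine":
        rigid = transform_from_dict(d["rigid"])
        return AffineParams(rigid, tuple(d["scales"]), tuple(d["shears"]))
    if kind == "dct_warp":
        return DCTWarp(
            transform_from_dict(d["affine_part"]),
            np.asarray(d["coeffs"]),
            _geometry_from_dict(d["fixed_geometry"]),
        )
    raise ParameterError(f"unknown transform kind {kind!r}")


def save_transform_chain(
    chain: Sequence[SpatialTransform], path: str | Path, provenance: Sequence[str] = ()
) -> None:
    """Write a transform chain to a versioned JSON container."""
    doc = {
        "format_version": CONTAINER_VERSION,
        "provenance": list(provenance),
        "chain": [transform_to_dict(t) for t in chain],
    }
    Path(path).write_text(json.dumps(doc))


def load_transform_chain(path: str | Path) -> tuple[list[SpatialTransform], list[str]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != CONTAINER_VERSION:
        raise ParameterError("unsupported transform container version")
    return [transform_from_dict(d) for d in doc["chain"]], list(doc.get("provenance", []))
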