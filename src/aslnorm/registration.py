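"""Intensity-based registration of native CBF images to pseudo-CBF targets.

The similarity metric is scaled SSD: sum of squared differences after a
closed-form global least-squares intensity scaling, normalized by the fixed
image's masked energy so values are dimensionless. Rigid (6 dof) and affine
(12 dof) stages use a derivative-free Powell search on pre-smoothed images;
the nonlinear stage optimizes the DCT-basis displacement coefficients with
L-BFGS and an analytic gradient, under a bending-energy penalty, with the
affine part frozen.

The nonlinear ``dct`` strategy runs in two iterations: tissue perfusion is
first estimated from the CBF image after a rough rigid+affine alignment, and
a subject-specific pseudo-CBF target is rebuilt from those estimates before
the nonlinear fit. All stages are combined into a single joint deformation
field so the output CBF image is produced with one interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field


import numpy as np
from scipy import ndimage, optimize

from .errors import DegenerateInputError, GeometryError, InputError, ParameterError
from .image_core import (
    ImageGeometry,
    TissueTemplate,
    VolumetricImage,
    gaussian_smooth,
    resample,
)
from .pseudo_cbf import PseudoCBFParams, build_pseudo_cbf, estimate_tissue_cbf
from .transforms import (
    AffineParams,
    DCTWarp,
    DeformationField,
    RigidParams,
    SpatialTransform,
    compose_to_field,
    dct_basis,
)

__all__ = [
    "RegistrationOptions",
    "NormalizationResult",
    "registration_cost",
    "register_rigid",
    "register_affine",
    "register_dct",
    "normalize_asl",
    "normalize_via_structural",
    "bending_energy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistrationOptions:
    """Optimizer knobs.

    presmooth_fwhm_linear_mm / presmooth_fwhm_dct_mm widen the capture range
    of the rigid/affine and nonlinear stages respectively; sample_step
    subsamples the fixed grid used for the cost (the images are smoothed well
    beyond the resulting sample spacing); lambda_reg weights the bending
    energy of the displacement field (dimensionless, on normalized
    intensities).
    """

    cost: str = "scaled_ssd"
    presmooth_fwhm_linear_mm: float = 8.0
    presmooth_fwhm_dct_mm: float = 4.0
    max_iter: int = 64
    tol: float = 1e-6
    dct_order: int = 16
    #: L-BFGS iteration cap for the nonlinear stage; its steps act on ~12k
    #: coefficients and are much weaker than the Powell outer iterations
    #: max_iter counts, so the stage gets its own budget.
    dct_max_iter: int = 300
    lambda_reg: float = 1.0
    seed: int = 0
    sample_step: int = 2
    com_init: bool = True

    def __post_init__(self) -> None:
        if self.cost != "scaled_ssd":
            raise ParameterError(f"unsupported cost {self.cost!r}")
        if self.max_iter < 1 or self.tol <= 0 or self.lambda_reg < 0:
            raise ParameterError("need max_iter >= 1, tol > 0, lambda_reg >= 0")
        if self.sample_step < 1:
            raise ParameterError("sample_step must be >= 1")


@dataclass(frozen=True)
class NormalizationResult:
    """Everything a normalization strategy produced for one subject."""

    strategy: str
    transform_chain: tuple[SpatialTransform, ...]
    field: DeformationField
    cbf_std: VolumetricImage
    tissue_cbf_used: tuple[float, float]
    cost_trace: dict[str, tuple[float, ...]]
    provenance: tuple[str, ...]
    subject_id: str | None = None


def _bending_weights(geometry: ImageGeometry, K: int) -> np.ndarray:
    """Diagonal bending-energy weights in DCT-coefficient space.

    The second derivative of cosine basis function k along an axis of length
    N*h mm scales it by -omega_k^2 with omega_k = pi*k/(N*h); the Laplacian
    bending energy is therefore diagonal in coefficient space:
    w[k,m,n] = (wx_k^2 + wy_m^2 + wz_n^2)^2, normalized per voxel.
    """
    sizes = geometry.voxel_sizes_mm
    omegas = [
        (np.pi * np.arange(K) / (n * h)) ** 2
        for n, h in zip(geometry.shape, sizes)
    ]
    w = (
        omegas[0][:, None, None] + omegas[1][None, :, None] + omegas[2][None, None, :]
    ) ** 2
    return w / float(np.prod(geometry.shape))


def bending_energy(warp: DCTWarp) -> float:
    """Per-voxel mean squared Laplacian of the warp's displacement field."""
    w = _bending_weights(warp.fixed_geometry, warp.order)
    return float(np.sum(warp.coeffs**2 * w[None]))


def _sample_moving(moving: VolumetricImage, native_pts: np.ndarray) -> np.ndarray:
    vox = moving.geometry.world_to_voxel_points(native_pts)
    return ndimage.map_coordinates(
        moving.voxels, vox.T, order=1, mode="constant", cval=0.0, prefilter=False
    )


def _scaled_ssd(f: np.ndarray, m: np.ndarray, denom: float) -> tuple[float, float]:
    """Return (cost, s) for cost = sum (f - s*m)^2 / sum f^2 at optimal s."""
    mm = float(m @ m)
    s = float(f @ m) / mm if mm > 0 else 0.0
    r = f - s * m
    return float(r @ r) / denom, s


def registration_cost(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    mapping,
    mask: VolumetricImage,
    lambda_reg: float = 0.0,
    warp: DCTWarp | None = None,
) -> float:
    """Scaled-SSD cost of ``moving`` pulled through ``mapping`` against ``fixed``.

    cost = sum_mask (fixed - s * moving(mapping(x)))^2 / sum_mask fixed^2 with
    s the closed-form least-squares intensity scale, plus
    lambda_reg * bending_energy(warp) when a warp is given.
    """
    if not mask.geometry.approx_equal(fixed.geometry):
        raise GeometryError("mask must be on the fixed geometry")
    msel = mask.mask_array()
    if not msel.any():
        raise DegenerateInputError("cost mask is empty")
    pts = fixed.geometry.world_grid()[msel]
    if hasattr(mapping, "coords"):
        native = np.asarray(mapping.coords)[msel]
    else:
        native = mapping.apply(pts)
    f = fixed.voxels[msel]
    denom = float(f @ f)
    if denom == 0:
        raise DegenerateInputError("fixed image is zero within the mask")
    m = _sample_moving(moving, native)
    cost, _ = _scaled_ssd(f, m, denom)
    if warp is not None and lambda_reg > 0:
        cost += lambda_reg * bending_energy(warp)
    return cost


def _default_mask(fixed: VolumetricImage) -> np.ndarray:
    """Support mask of the (pseudo-)CBF fixed image: >5% of its maximum."""
    return fixed.voxels > 0.05 * fixed.voxels.max()


#: Gaussian-equivalent FWHM of the triangle kernel applied by trilinear
#: sampling, per unit of source voxel size (matched variance).
_INTERP_FWHM_PER_VOXEL = 2.0 * np.sqrt(2.0 * np.log(2.0)) / np.sqrt(6.0)


def _presmooth_pair(
    moving: VolumetricImage, fixed: VolumetricImage, fwhm: float
) -> tuple[VolumetricImage, VolumetricImage]:
    """Pre-smooth both images, matching the fixed image to the moving one's
    effective sampled resolution.

    Trilinear sampling of the moving image during cost evaluation convolves
    it with a triangle kernel of its own voxel size; the fixed image is
    therefore smoothed by that kernel's Gaussian equivalent in addition to
    the common capture-range FWHM, so the two images compare at the same
    resolution and the optimizer cannot trade geometry for blur.
    """
    mov_s = gaussian_smooth(moving, (fwhm,) * 3)
    interp = _INTERP_FWHM_PER_VOXEL * moving.geometry.voxel_sizes_mm
    fix_s = gaussian_smooth(fixed, np.sqrt(fwhm**2 + interp**2))
    return mov_s, fix_s


class _Trace:
    """Running best-cost recorder; nonincreasing by construction."""

    def __init__(self) -> None:
        self.values: list[float] = []
        self.best = np.inf

    def record(self, cost: float) -> None:
        self.best = min(self.best, cost)
        self.values.append(self.best)


class _LinearEngine:
    """Masked, subsampled scaled-SSD evaluator for rigid/affine stages."""

    def __init__(
        self,
        moving: VolumetricImage,
        fixed: VolumetricImage,
        mask: np.ndarray,
        step: int,
    ) -> None:
        sub = np.zeros(fixed.geometry.shape, dtype=bool)
        sub[::step, ::step, ::step] = True
        sel = mask & sub
        if not sel.any():
            raise DegenerateInputError("registration mask is empty after subsampling")
        self.pts = fixed.geometry.world_grid()[sel]
        self.f = fixed.voxels[sel]
        self.denom = float(self.f @ self.f)
        if self.denom == 0:
            raise DegenerateInputError("fixed image is zero within the mask")
        self.moving = moving

    def cost(self, transform) -> float:
        m = _sample_moving(self.moving, transform.apply(self.pts))
        return _scaled_ssd(self.f, m, self.denom)[0]


def _com_world(img: VolumetricImage) -> np.ndarray:
    w = np.maximum(img.voxels, 0.0)
    total = w.sum()
    if total == 0:
        return np.zeros(3)
    idx = np.array(ndimage.center_of_mass(w))
    return img.geometry.voxel_to_world_points(idx[None])[0]


_RIGID_SCALE = np.array([1.0, 1.0, 1.0, 0.02, 0.02, 0.02])
_AFFINE_SCALE = np.concatenate([_RIGID_SCALE, [0.02] * 6])


def _rigid_from_vec(x: np.ndarray) -> RigidParams:
    p = x * _RIGID_SCALE
    return RigidParams(tuple(p[:3]), tuple(p[3:6]))


def _affine_from_vec(x: np.ndarray) -> AffineParams:
    p = x * _AFFINE_SCALE
    return AffineParams(
        RigidParams(tuple(p[:3]), tuple(p[3:6])),
        tuple(np.exp(p[6:9])),
        tuple(p[9:12]),
    )


def _powell(fun, x0: np.ndarray, opts: RegistrationOptions, trace: _Trace):
    def wrapped(x):
        c = fun(x)
        trace.record(c)
        return c

    res = optimize.minimize(
        wrapped,
        x0,
        method="Powell",
        options={"maxiter": opts.max_iter, "ftol": opts.tol, "xtol": 1e-4},
    )
    # Powell's reported optimum never exceeds the initial cost.
    return res.x if res.fun <= fun(x0) else x0


def register_rigid(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    opts: RegistrationOptions | None = None,
    init: RigidParams | None = None,
    mask: VolumetricImage | None = None,
    trace: _Trace | None = None,
) -> RigidParams:
    """Estimate a rigid transform (fixed world -> moving world) by scaled SSD."""
    opts = opts or RegistrationOptions()
    mask_arr = mask.mask_array() if mask is not None else _default_mask(fixed)
    mov_s, fix_s = _presmooth_pair(moving, fixed, opts.presmooth_fwhm_linear_mm)
    engine = _LinearEngine(mov_s, fix_s, mask_arr, opts.sample_step)
    if init is None:
        t0 = np.zeros(3)
        if opts.com_init:
            t0 = _com_world(mov_s) - _com_world(fix_s)
        init = RigidParams(tuple(t0))
    x0 = np.concatenate([init.translation, init.rotation]) / _RIGID_SCALE
    c0 = engine.cost(_rigid_from_vec(x0))
    if not np.isfinite(c0):
        raise InputError("registration cost is not finite at the initial transform")
    trace = trace if trace is not None else _Trace()
    x = _powell(lambda v: engine.cost(_rigid_from_vec(v)), x0, opts, trace)
    return _rigid_from_vec(x)


def register_affine(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    opts: RegistrationOptions | None = None,
    init: RigidParams | None = None,
    mask: VolumetricImage | None = None,
    trace: _Trace | None = None,
) -> AffineParams:
    """Estimate a 12-dof affine, initialized from a rigid solution."""
    opts = opts or RegistrationOptions()
    if init is None:
        init = register_rigid(moving, fixed, opts, mask=mask)
    mask_arr = mask.mask_array() if mask is not None else _default_mask(fixed)
    mov_s, fix_s = _presmooth_pair(moving, fixed, opts.presmooth_fwhm_linear_mm)
    engine = _LinearEngine(mov_s, fix_s, mask_arr, opts.sample_step)
    x0 = np.concatenate([init.translation, init.rotation, np.zeros(6)]) / _AFFINE_SCALE
    trace = trace if trace is not None else _Trace()
    x = _powell(lambda v: engine.cost(_affine_from_vec(v)), x0, opts, trace)
    return _affine_from_vec(x)


class _DCTEngine:
    """Scaled-SSD cost + analytic gradient in DCT-coefficient space.

    Operates on a subsampled fixed grid; the gradient back-projection uses
    the separability of the tensor-product basis so each evaluation is a few
    small einsums plus one trilinear sampling pass.
    """

    def __init__(
        self,
        moving: VolumetricImage,
        fixed: VolumetricImage,
        mask: np.ndarray,
        affine: AffineParams,
        K: int,
        step: int,
        lambda_reg: float,
    ) -> None:
        geo = fixed.geometry
        self.K = K
        self.shape = tuple(len(range(0, n, step)) for n in geo.shape)
        idx = [np.arange(0, n, step) for n in geo.shape]
        self.B = [dct_basis(K, n)[ix] for n, ix in zip(geo.shape, idx)]
        grid = np.stack(np.meshgrid(*idx, indexing="ij"), axis=-1).reshape(-1, 3)
        self.pts = geo.voxel_to_world_points(grid).reshape(self.shape + (3,))
        self.mask = mask[np.ix_(*idx)]
        if not self.mask.any():
            raise DegenerateInputError("registration mask is empty after subsampling")
        self.f = fixed.voxels[np.ix_(*idx)][self.mask]
        self.denom = float(self.f @ self.f)
        if self.denom == 0:
            raise DegenerateInputError("fixed image is zero within the mask")
        self.A = affine.matrix()
        self.L = self.A[:3, :3]
        self.moving = moving.voxels
        self.winv = moving.geometry.world_to_voxel
        # moving-image gradient per voxel index; converted to world units on the fly
        self.gvox = np.stack(np.gradient(self.moving), axis=0)
        self.lw = lambda_reg * _bending_weights(geo, K)

    def _displacement(self, C: np.ndarray) -> np.ndarray:
        u = np.einsum("ik,dkmn->dimn", self.B[0], C)
        u = np.einsum("jm,dimn->dijn", self.B[1], u)
        return np.einsum("ln,dijn->dijl", self.B[2], u)

    def cost_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        C = x.reshape(3, self.K, self.K, self.K)
        u = self._displacement(C)
        native = (self.pts + np.moveaxis(u, 0, -1)).reshape(-1, 3) @ self.L.T + self.A[:3, 3]
        vox = native @ self.winv[:3, :3].T + self.winv[:3, 3]
        coords = vox.T
        m = ndimage.map_coordinates(
            self.moving, coords, order=1, mode="constant", cval=0.0, prefilter=False
        ).reshape(self.shape)
        g = np.stack(
            [
                ndimage.map_coordinates(
                    gv, coords, order=1, mode="constant", cval=0.0, prefilter=False
                )
                for gv in self.gvox
            ],
            axis=-1,
        )  # (N, 3) gradient wrt voxel index
        gw = (g @ self.winv[:3, :3]).reshape(self.shape + (3,))  # wrt world mm
        mv = m[self.mask]
        cost, s = _scaled_ssd(self.f, mv, self.denom)
        r = np.zeros(self.shape)
        r[self.mask] = self.f - s * mv
        # d cost / d u_d = (-2 s / denom) * r * (grad_world . L[:, d])
        w = (-2.0 * s / self.denom) * r[..., None] * (gw @ self.L)  # (..., 3)
        w = np.moveaxis(w, -1, 0)
        gC = np.einsum("dijl,ik->dkjl", w, self.B[0])
        gC = np.einsum("dkjl,jm->dkml", gC, self.B[1])
        gC = np.einsum("dkml,ln->dkmn", gC, self.B[2])
        cost += float(np.sum(C**2 * self.lw[None]))
        gC += 2.0 * C * self.lw[None]
        return cost, gC.ravel()

    def curvature_diag(self, x: np.ndarray) -> np.ndarray:
        """Gauss-Newton diagonal of the penalized cost at ``x``.

        Data part: H[d,k,m,n] ~ (2 s^2/denom) * sum_vox (grad_w . L[:,d])^2
        * Bx^2 By^2 Bz^2 — separable, so three small contractions. Used as a
        preconditioner; high-frequency penalty curvature is added exactly.
        """
        C = x.reshape(3, self.K, self.K, self.K)
        u = self._displacement(C)
        native = (self.pts + np.moveaxis(u, 0, -1)).reshape(-1, 3) @ self.L.T + self.A[:3, 3]
        vox = native @ self.winv[:3, :3].T + self.winv[:3, 3]
        coords = vox.T
        m = ndimage.map_coordinates(
            self.moving, coords, order=1, mode="constant", cval=0.0, prefilter=False
        ).reshape(self.shape)
        g = np.stack(
            [
                ndimage.map_coordinates(
                    gv, coords, order=1, mode="constant", cval=0.0, prefilter=False
                )
                for gv in self.gvox
            ],
            axis=-1,
        )
        gw = (g @ self.winv[:3, :3]).reshape(self.shape + (3,))
        _, s = _scaled_ssd(self.f, m[self.mask], self.denom)
        q = np.moveaxis((gw @ self.L) ** 2, -1, 0) * self.mask[None]
        q *= 2.0 * s**2 / self.denom
        B2 = [b**2 for b in self.B]
        D = np.einsum("dijl,ik->dkjl", q, B2[0])
        D = np.einsum("dkjl,jm->dkml", D, B2[1])
        D = np.einsum("dkml,ln->dkmn", D, B2[2])
        D += 2.0 * self.lw[None]
        return D.ravel()


def register_dct(
    moving: VolumetricImage,
    fixed: VolumetricImage,
    opts: RegistrationOptions | None = None,
    init: AffineParams | None = None,
    mask: VolumetricImage | None = None,
    trace: _Trace | None = None,
) -> DCTWarp:
    """Estimate DCT-basis displacement coefficients with the affine frozen.

    Coefficients start at zero (the affine solution) and are optimized by
    L-BFGS under the bending-energy penalty, so the final penalized cost
    never exceeds the affine-only cost.
    """
    opts = opts or RegistrationOptions()
    if init is None:
        init = AffineParams()
    mask_arr = mask.mask_array() if mask is not None else _default_mask(fixed)
    mov_s, fix_s = _presmooth_pair(moving, fixed, opts.presmooth_fwhm_dct_mm)
    K = opts.dct_order
    engine = _DCTEngine(
        mov_s, fix_s, mask_arr, init, K, opts.sample_step, opts.lambda_reg
    )
    trace = trace if trace is not None else _Trace()
    x0 = np.zeros(3 * K**3)
    c0, _ = engine.cost_grad(x0)
    scale = max(c0, 1e-12)  # normalize so the stage cost starts at 1

    # Diagonal (Gauss-Newton + penalty) preconditioner: without it the mixed
    # curvature scales of data-driven and penalty-dominated modes make
    # quasi-Newton progress crawl.
    D = engine.curvature_diag(x0)
    P = np.sqrt(np.maximum(D, 1e-6 * D.max()))

    def fun(z):
        c, g = engine.cost_grad(z / P)
        trace.record(c)
        return c / scale, g / (P * scale)

    # Convergence = relative cost decrease below `tol` per iteration,
    # measured against the current cost (scipy's ftol is effectively
    # absolute once the cost drops below 1, stopping far too early).
    last = [np.inf]

    def stop_on_small_relative_decrease(xk):
        cur = trace.best
        if last[0] - cur < opts.tol * max(cur, 1e-30):
            raise StopIteration
        last[0] = cur

    res = optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=stop_on_small_relative_decrease,
        options={"maxiter": opts.dct_max_iter, "ftol": 0.0, "gtol": 1e-12},
    )
    x = res.x / P if res.fun * scale <= c0 else x0
    return DCTWarp(init, x.reshape(3, K, K, K), fixed.geometry)


_STAGE_NAMES = {"rigid": 1, "affine": 2, "dct": 3}


def normalize_asl(
    cbf_native: VolumetricImage,
    template: TissueTemplate,
    strategy: str = "dct",
    params: PseudoCBFParams | None = None,
    opts: RegistrationOptions | None = None,
    subject_id: str | None = None,
) -> NormalizationResult:
    """Normalize a native CBF image to template space via a pseudo-CBF target.

    strategy ``rigid``: rigid-only registration to the default 60/20
    pseudo-CBF; ``affine``: rigid then full affine; ``dct``: rigid+affine
    rough alignment, subject tissue CBF estimated from the roughly aligned
    image, pseudo-CBF rebuilt with those values, then the nonlinear DCT fit.
    The final standard-space CBF is produced by composing all stages into one
    deformation field and resampling once (cubic).
    """
    if strategy not in _STAGE_NAMES:
        raise ParameterError(f"unknown strategy {strategy!r}; use rigid, affine or dct")
    params = params or PseudoCBFParams()
    opts = opts or RegistrationOptions()
    pseudo = build_pseudo_cbf(template, params)
    mask = template.brain_mask
    traces: dict[str, _Trace] = {}
    tissue_used = (params.v_gm, params.v_wm)

    traces["rigid"] = _Trace()
    rigid = register_rigid(cbf_native, pseudo, opts, mask=mask, trace=traces["rigid"])
    chain: list[SpatialTransform] = [rigid]
    provenance = ["rigid"]

    if strategy in ("affine", "dct"):
        traces["affine"] = _Trace()
        aff = register_affine(
            cbf_native, pseudo, opts, init=rigid, mask=mask, trace=traces["affine"]
        )
        chain = [aff]
        provenance.append("affine")

    if strategy == "dct":
        # Iteration 1: estimate subject tissue CBF after the rough alignment.
        aligned = resample(cbf_native, template.geometry, aff, order=1)
        try:
            tissue_used = estimate_tissue_cbf(
                aligned,
                template,
                psf_fwhm_mm=params.smoothing_fwhm_mm,
                data_voxel_mm=tuple(cbf_native.geometry.voxel_sizes_mm),
            )
        except DegenerateInputError:
            log.warning("tissue CBF estimation failed; keeping default pseudo-CBF")
            tissue_used = (params.v_gm, params.v_wm)
        # Iteration 2: subject-specific target for the nonlinear fit.
        params2 = PseudoCBFParams(
            v_gm=tissue_used[0],
            v_wm=tissue_used[1],
            smoothing_fwhm_mm=params.smoothing_fwhm_mm,
        )
        pseudo2 = build_pseudo_cbf(template, params2)
        traces["dct"] = _Trace()
        warp = register_dct(
            cbf_native, pseudo2, opts, init=aff, mask=mask, trace=traces["dct"]
        )
        chain = [warp]
        provenance.append("dct")

    fld = compose_to_field(chain, template.geometry)
    cbf_std = resample(cbf_native, template.geometry, fld, order=3)
    return NormalizationResult(
        strategy=strategy,
        transform_chain=tuple(chain),
        field=fld,
        cbf_std=cbf_std,
        tissue_cbf_used=(float(tissue_used[0]), float(tissue_used[1])),
        cost_trace={k: tuple(t.values) for k, t in traces.items()},
        provenance=tuple(provenance),
        subject_id=subject_id,
    )


def normalize_via_structural(
    cbf_native: VolumetricImage,
    m0: VolumetricImage,
    subject_tissues: TissueTemplate | None,
    template: TissueTemplate,
    params: PseudoCBFParams | None = None,
    opts: RegistrationOptions | None = None,
    subject_id: str | None = None,
) -> NormalizationResult:
    """Structural-mediated normalization: M0 -> structural -> template.

    The M0 image is rigidly aligned to a synthetic 60/20 perfusion-contrast
    image built from the subject's (externally produced) tissue
    segmentations; the structural-to-template stage registers the subject
    tissue pseudo-CBF to the template pseudo-CBF with affine + DCT stages.
    The joint chain is applied to the CBF image with one interpolation.
    """
    if subject_tissues is None:
        raise InputError(
            "structural strategy needs native tissue segmentations; "
            "use the direct ASL strategies (rigid/affine/dct) instead"
        )
    params = params or PseudoCBFParams()
    opts = opts or RegistrationOptions()
    traces = {"rigid": _Trace(), "affine": _Trace(), "dct": _Trace()}

    # Same-subject rigid link: M0 (ASL space) to the structural frame.
    struct_ref = build_pseudo_cbf(subject_tissues, params)
    rigid_m0 = register_rigid(m0, struct_ref, opts, trace=traces["rigid"])

    # Structural to template: tissue pseudo-CBF against template pseudo-CBF.
    tmpl_pseudo = build_pseudo_cbf(template, params)
    mask = template.brain_mask
    rigid_s = register_rigid(struct_ref, tmpl_pseudo, opts, mask=mask)
    aff = register_affine(
        struct_ref, tmpl_pseudo, opts, init=rigid_s, mask=mask, trace=traces["affine"]
    )
    warp = register_dct(
        struct_ref, tmpl_pseudo, opts, init=aff, mask=mask, trace=traces["dct"]
    )

    chain: list[SpatialTransform] = [warp, rigid_m0]
    fld = compose_to_field(chain, template.geometry)
    cbf_std = resample(cbf_native, template.geometry, fld, order=3)
    return NormalizationResult(
        strategy="structural",
        transform_chain=tuple(chain),
        field=fld,
        cbf_std=cbf_std,
        tissue_cbf_used=(params.v_gm, params.v_wm),
        cost_trace={k: tuple(t.values) for k, t in traces.items()},
        provenance=("rigid", "affine", "dct"),
        subject_id=subject_id,
    )
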