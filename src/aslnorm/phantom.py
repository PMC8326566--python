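"""Synthetic pediatric-like brain phantoms for end-to-end testing.

The generator produces (i) a smooth ellipsoidal tissue template — cortical
GM shell, WM core, CSF rim and ventricles — as probability maps on a
standard-space grid; (ii) ground-truth deformations, including a
trigonocephaly-like frontal narrowing, expressed exactly in the same
DCT-warp parameterization the registration uses (so representability never
confounds optimizer error); and (iii) noisy native-space CBF volumes on a
coarse ASL grid (3.75 x 3.75 x 4.0 mm) with GM ~ 3x WM perfusion contrast.

The native CBF image is rendered by inverting the ground-truth
standard-to-native transform with a fixed-point iteration per voxel, pulling
the template tissues into native space, forming v_gm*GM + v_wm*WM, blurring
to the ASL point spread (Gaussian at voxel-size FWHM — a simplification of
the spiral readout blur) and adding white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ParameterError
from .image_core import (
    ImageGeometry,
    TissueTemplate,
    VolumetricImage,
    centered_geometry,
    gaussian_smooth,
    resample,
)
from .transforms import (
    AffineParams,
    DCTWarp,
    DeformationField,
    RigidParams,
    dct_basis,
)

__all__ = [
    "PhantomSpec",
    "SyntheticSubject",
    "make_template",
    "trigono_warp",
    "random_warp",
    "make_subject",
    "render_native_cbf",
    "cohort_specs",
    "displacement_error",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic subject.

    Defaults: 64^3 template grid at 2 mm, ASL voxels 3.75 x 3.75 x 4.0 mm,
    GM/WM perfusion 60/20 ml/100 g/min, additive noise sigma 5 ml/100 g/min,
    a smooth random warp of 4 mm peak amplitude in an order-8 DCT basis, and
    a small rigid offset (<= 5 mm / 5 degrees).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    template_voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    native_voxel_mm: tuple[float, float, float] = (3.75, 3.75, 4.0)
    v_gm: float = 60.0
    v_wm: float = 20.0
    noise_sd: float = 5.0
    warp_amplitude_mm: float = 4.0
    warp_order: int = 8
    trigono_severity: float = 0.0
    rigid_offset: RigidParams = field(
        default_factory=lambda: RigidParams(
            translation=(3.0, -2.0, 2.0),
            rotation=(np.deg2rad(2.0), np.deg2rad(-1.0), np.deg2rad(2.0)),
        )
    )
    #: Subject brain size relative to the template: infants scanned before
    #: the template age have smaller brains, the mismatch a rigid transform
    #: cannot absorb.
    scale_offset: tuple[float, float, float] = (0.94, 0.97, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warp_amplitude_mm < 0 or self.noise_sd < 0:
            raise ParameterError("warp amplitude and noise sigma must be nonnegative")
        if not 0.0 <= self.trigono_severity <= 1.0:
            raise ParameterError("trigono_severity must lie in [0, 1]")

    def template_geometry(self) -> ImageGeometry:
        return centered_geometry(self.grid_shape, self.template_voxel_mm)


@dataclass(frozen=True)
class SyntheticSubject:
    """Native CBF volume plus the ground truth that generated it."""

    native_cbf: VolumetricImage
    true_transform: DCTWarp  # standard world -> native world; rigid offset in affine_part
    template: TissueTemplate
    spec: PhantomSpec


def _normalized_coords(geometry: ImageGeometry) -> list[np.ndarray]:
    """Per-axis coordinates scaled to [-1, 1] across the grid."""
    return [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) / ((n - 1) / 2.0)
        for n in geometry.shape
    ]


def make_template(spec: PhantomSpec | None = None) -> TissueTemplate:
    """Smooth brain template: lumpy GM shell, WM core, deep GM nuclei, CSF
    rim + ventricles.

    The cortical surface carries a low-order angular modulation (a crude
    gyral-scale lumpiness) and the WM interior contains two deep-GM nuclei;
    both break the rotational near-symmetry of a plain ellipsoid so that
    every rigid degree of freedom is identifiable from perfusion contrast.
    """
    spec = spec or PhantomSpec()
    geo = spec.template_geometry()
    grid = geo.world_grid()
    x, y, z = grid[..., 0], grid[..., 1], grid[..., 2]

    # low-order angular modulation of the cortical boundary radius
    r_xy = np.sqrt(x**2 + y**2) + 1e-9
    phi = np.arctan2(y, x)
    theta = np.arctan2(z, r_xy)
    lump = (
        1.0
        + 0.07 * np.cos(3.0 * phi) * np.cos(theta) ** 2
        + 0.05 * np.cos(5.0 * phi) * np.sin(theta) * np.cos(theta)
        + 0.04 * np.sin(2.0 * theta) * np.cos(phi)
    )

    def rho(rx, ry, rz, cx=0.0, cy=0.0, cz=0.0, mod=None):
        r = np.sqrt(
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        )
        return r / mod if mod is not None else r

    outer = rho(46.0, 56.0, 42.0, mod=lump) <= 1.0  # full head of CSF+brain
    gm_out = rho(43.0, 53.0, 39.0, mod=lump) <= 1.0  # inside the 3 mm CSF rim
    wm_core = rho(35.0, 45.0, 31.0, mod=lump) <= 1.0  # inside the ~8 mm GM shell
    vent = (rho(7.0, 16.0, 8.0, cx=-11.0, cy=-6.0, cz=4.0) <= 1.0) | (
        rho(7.0, 16.0, 8.0, cx=11.0, cy=-6.0, cz=4.0) <= 1.0
    )
    # deep GM nuclei (thalamus/basal-ganglia-like), perfused like cortex
    nuclei = (rho(8.0, 11.0, 8.0, cx=-15.0, cy=6.0, cz=-3.0) <= 1.0) | (
        rho(8.0, 11.0, 8.0, cx=15.0, cy=6.0, cz=-3.0) <= 1.0
    )

    labels = np.zeros(geo.shape, dtype=int)  # 0 background
    labels[outer] = 1  # csf rim
    labels[gm_out] = 2  # gm shell
    labels[wm_core] = 3  # wm
    labels[wm_core & nuclei] = 2  # deep gm
    labels[wm_core & vent] = 1  # ventricular csf

    sigma_vox = 2.0 / np.asarray(spec.template_voxel_mm)
    from scipy.ndimage import gaussian_filter

    probs = []
    for lab in (1, 2, 3):
        probs.append(gaussian_filter((labels == lab).astype(float), sigma_vox))
    bg = gaussian_filter((labels == 0).astype(float), sigma_vox)
    total = bg + sum(probs)
    csf, gm, wm = (np.clip(p / total, 0.0, 1.0) for p in probs)

    return TissueTemplate(
        gm=VolumetricImage(geo, gm, "probability"),
        wm=VolumetricImage(geo, wm, "probability"),
        csf=VolumetricImage(geo, csf, "probability"),
    )


def _project_to_dct(u: np.ndarray, geometry: ImageGeometry, K: int) -> np.ndarray:
    """Exact orthonormal projection of a (3,)+shape displacement field onto
    the order-K tensor DCT basis; returns coefficients (3, K, K, K)."""
    Bs = [dct_basis(K, n) for n in geometry.shape]
    c = np.einsum("ik,dijl->dkjl", Bs[0], u)
    c = np.einsum("jm,dkjl->dkml", Bs[1], c)
    return np.einsum("ln,dkml->dkmn", Bs[2], c)


def _coeff_field_max(coeffs: np.ndarray, geometry: ImageGeometry) -> float:
    warp = DCTWarp(AffineParams(), coeffs, geometry)
    u = warp.displacement_grid()
    return float(np.sqrt((u**2).sum(axis=0)).max())


def trigono_warp(
    severity: float, geometry: ImageGeometry, order: int = 8
) -> DCTWarp:
    """Trigonocephaly-like deformation in DCT parameterization.

    Medially directed lateral compression confined to the anterior third of
    the head, a small anterior midline protrusion, and mild posterior lateral
    widening. The lateral component is left-right antisymmetric about the
    midsagittal plane, and the peak displacement magnitude is
    ``severity * 8 mm``.
    """
    if not 0.0 <= severity <= 1.0:
        raise ParameterError("severity must lie in [0, 1]")
    K = order
    zeros = np.zeros((3, K, K, K))
    if severity == 0.0:
        return DCTWarp(AffineParams(), zeros, geometry)
    xs, ys, zs = _normalized_coords(geometry)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    lateral_odd = X * np.exp(-((X / 0.6) ** 2))  # antisymmetric in X
    anterior = np.exp(-(((Y - 0.75) / 0.35) ** 2))  # frontal third
    posterior = np.exp(-(((Y + 0.6) / 0.4) ** 2))
    axial = np.exp(-((Z / 0.8) ** 2))
    u = np.zeros((3,) + geometry.shape)
    u[0] = (-1.0 * lateral_odd * anterior + 0.3 * lateral_odd * posterior) * axial
    u[1] = 0.5 * np.exp(-((X / 0.25) ** 2)) * anterior * axial
    coeffs = _project_to_dct(u, geometry, K)
    peak = _coeff_field_max(coeffs, geometry)
    coeffs *= severity * 8.0 / peak
    return DCTWarp(AffineParams(), coeffs, geometry)


def random_warp(
    amplitude_mm: float,
    geometry: ImageGeometry,
    order: int = 8,
    rng: np.random.Generator | None = None,
) -> DCTWarp:
    """Smooth random warp with peak displacement ``amplitude_mm``.

    Coefficients are white-noise draws shaded by 1/(1 + k + m + n)^2 — low
    spatial frequencies dominate, but with a substantial genuinely nonlinear
    (non-affine) component; the pure-constant term is zeroed so the warp
    carries no net translation confound.
    """
    if amplitude_mm < 0:
        raise ParameterError("amplitude must be nonnegative")
    K = order
    rng = rng or np.random.default_rng(0)
    coeffs = rng.standard_normal((3, K, K, K))
    k = np.arange(K, dtype=float)
    shade = 1.0 / (1.0 + k[:, None, None] + k[None, :, None] + k[None, None, :]) ** 2
    coeffs *= shade[None]
    coeffs[:, 0, 0, 0] = 0.0
    if amplitude_mm == 0:
        return DCTWarp(AffineParams(), np.zeros_like(coeffs), geometry)
    coeffs *= amplitude_mm / _coeff_field_max(coeffs, geometry)
    return DCTWarp(AffineParams(), coeffs, geometry)


def _native_geometry(spec: PhantomSpec, margin_mm: float = 14.0) -> ImageGeometry:
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.template_voxel_mm)
    extent = extent + 2 * margin_mm
    shape = np.ceil(extent / np.asarray(spec.native_voxel_mm)).astype(int)
    return centered_geometry(tuple(shape), spec.native_voxel_mm)


def _invert_warp(
    warp: DCTWarp, native_points: np.ndarray, n_iter: int = 20, tol: float = 1e-3
) -> np.ndarray:
    """Fixed-point inversion of native = A(x + u(x)) for x, per point.

    The displacement is evaluated once on the fixed grid (separable tensor
    contraction) and interpolated trilinearly during the iteration; the
    field is smooth at the grid scale, so the interpolation error is far
    below the fixed-point tolerance.
    """
    from scipy.ndimage import map_coordinates

    Ainv = np.linalg.inv(warp.affine_part.matrix())
    base = native_points @ Ainv[:3, :3].T + Ainv[:3, 3]
    if not warp.coeffs.any():
        return base
    ug = warp.displacement_grid()
    geo = warp.fixed_geometry

    def u_at(pts: np.ndarray) -> np.ndarray:
        vox = geo.world_to_voxel_points(pts).T
        return np.stack(
            [map_coordinates(ug[d], vox, order=1, mode="nearest") for d in range(3)],
            axis=-1,
        )

    x = base.copy()
    for _ in range(n_iter):
        x_new = base - u_at(x)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


def render_native_cbf(
    template: TissueTemplate, truth: DCTWarp, spec: PhantomSpec
) -> VolumetricImage:
    """Render the noisy native-space CBF image implied by a ground-truth warp."""
    native_geo = _native_geometry(spec)
    # fine grid at template resolution; shape parity matched to the template
    # grid so both centered grids share voxel-centre positions exactly
    fine_shape = []
    for n, v, t, nt in zip(
        native_geo.shape, spec.native_voxel_mm, spec.template_voxel_mm, spec.grid_shape
    ):
        m = int(np.ceil(n * v / t))
        if (m - nt) % 2:
            m += 1
        fine_shape.append(m)
    fine_geo = centered_geometry(tuple(fine_shape), spec.template_voxel_mm)
    pts = fine_geo.world_grid().reshape(-1, 3)
    fixed_pts = _invert_warp(truth, pts)

    class _PointMap:
        def apply(self, p):  # resample expects fixed->moving world mapping
            return fixed_pts

    gm = resample(template.gm, fine_geo, _PointMap(), order=3)
    wm = resample(template.wm, fine_geo, _PointMap(), order=3)
    cbf_fine = VolumetricImage(
        fine_geo,
        spec.v_gm * gm.voxels + spec.v_wm * wm.voxels,
        "cbf_ml_per_100g_min",
    )
    cbf_fine = gaussian_smooth(cbf_fine, spec.native_voxel_mm)  # ASL point spread

    class _Identity:
        def apply(self, p):
            return np.asarray(p, dtype=float)

    cbf_native = resample(cbf_fine, native_geo, _Identity(), order=3)
    rng = np.random.default_rng(spec.seed)
    noisy = cbf_native.voxels + rng.normal(0.0, spec.noise_sd, cbf_native.geometry.shape) if spec.noise_sd > 0 else cbf_native.voxels
    return VolumetricImage(native_geo, noisy, "cbf_ml_per_100g_min")


def make_subject(spec: PhantomSpec | None = None) -> SyntheticSubject:
    """Generate a synthetic subject: template, ground-truth warp, native CBF.

    The ground truth composes the rigid offset with the trigonocephaly
    and/or random warp into one DCT warp (rigid offset as the affine part,
    displacement coefficients summed), identical in structure to what the
    nonlinear registration estimates.
    """
    spec = spec or PhantomSpec()
    template = make_template(spec)
    geo = template.geometry
    rng = np.random.default_rng(spec.seed)
    coeffs = np.zeros((3, spec.warp_order, spec.warp_order, spec.warp_order))
    if spec.trigono_severity > 0:
        coeffs = coeffs + trigono_warp(spec.trigono_severity, geo, spec.warp_order).coeffs
    if spec.warp_amplitude_mm > 0:
        coeffs = coeffs + random_warp(
            spec.warp_amplitude_mm, geo, spec.warp_order, rng
        ).coeffs
    truth = DCTWarp(
        AffineParams(rigid=spec.rigid_offset, scales=spec.scale_offset), coeffs, geo
    )
    native_cbf = render_native_cbf(template, truth, spec)
    return SyntheticSubject(native_cbf, truth, template, spec)


def cohort_specs(
    n_subjects: int = 8,
    master_seed: int = 0,
    patient_fraction: float = 0.69,
    severity_range: tuple[float, float] = (0.4, 0.8),
    base: PhantomSpec | None = None,
) -> list[PhantomSpec]:
    """Specs for a mixed cohort of trigonocephaly-like patients and controls.

    About ``patient_fraction`` of the subjects (the study population was
    roughly two-thirds patients) receive a trigonocephaly warp with severity
    drawn uniformly from ``severity_range``; the rest are controls
    (severity 0). All subjects keep the base spec's random warp, size
    offset and noise. Per-subject seeds derive deterministically from
    ``master_seed``.
    """
    base = base or PhantomSpec()
    n_patients = int(round(patient_fraction * n_subjects))
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects)
    rng = np.random.default_rng(ss.spawn(1)[0])
    specs = []
    for i, child in enumerate(children):
        severity = (
            float(rng.uniform(*severity_range)) if i < n_patients else 0.0
        )
        specs.append(
            replace(
                base,
                seed=int(child.generate_state(1)[0] % 2**31),
                trigono_severity=severity,
            )
        )
    return specs


def displacement_error(
    estimated: DeformationField, truth: DeformationField, mask: VolumetricImage
) -> tuple[float, float]:
    """Mean and max Euclidean distance (mm) between two coordinate maps."""
    if not estimated.geometry.approx_equal(truth.geometry) or not mask.geometry.approx_equal(truth.geometry):
        raise GeometryError("fields and mask must share one geometry")
    m = mask.mask_array()
    d = np.linalg.norm(estimated.coords - truth.coords, axis=-1)[m]
    return float(d.mean()), float(d.max())
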