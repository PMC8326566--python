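"""Pseudo-CBF registration targets built from tissue-probability maps.

A pseudo-CBF image mimics the perfusion contrast of an ASL CBF map by
weighting the gray- and white-matter probability maps with reference tissue
perfusion values (60 and 20 ml/100 g/min by default) and smoothing the result
to the effective ASL resolution. It serves as the fixed image for direct
CBF-to-template registration. CSF contributes zero perfusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GeometryError, ParameterError
from .image_core import TissueTemplate, VolumetricImage, gaussian_smooth

__all__ = ["PseudoCBFParams", "build_pseudo_cbf", "estimate_tissue_cbf"]

log = logging.getLogger(__name__)

#: Reference tissue perfusion in ml/100 g/min.
DEFAULT_V_GM = 60.0
DEFAULT_V_WM = 20.0
#: ASL acquisition voxel size (mm); "smoothing to the ASL resolution" uses a
#: Gaussian with this FWHM per axis.
DEFAULT_ASL_FWHM_MM = (3.75, 3.75, 4.0)


@dataclass(frozen=True)
class PseudoCBFParams:
    """Tissue reference perfusion values and target smoothing.

    v_gm / v_wm are in ml/100 g/min; smoothing_fwhm_mm is the per-axis
    Gaussian FWHM used to bring the template-resolution pseudo-CBF image down
    to the effective ASL resolution.
    """

    v_gm: float = DEFAULT_V_GM
    v_wm: float = DEFAULT_V_WM
    smoothing_fwhm_mm: tuple[float, float, float] = DEFAULT_ASL_FWHM_MM

    def __post_init__(self) -> None:
        if not (self.v_gm > self.v_wm >= 0):
            raise ParameterError(
                f"need v_gm > v_wm >= 0, got v_gm={self.v_gm}, v_wm={self.v_wm}"
            )
        fwhm = tuple(float(f) for f in self.smoothing_fwhm_mm)
        if any(f < 0 for f in fwhm):
            raise ParameterError("smoothing FWHM must be nonnegative")
        object.__setattr__(self, "smoothing_fwhm_mm", fwhm)


def build_pseudo_cbf(
    template: TissueTemplate, params: PseudoCBFParams | None = None
) -> VolumetricImage:
    """v_gm * GM + v_wm * WM, smoothed to the ASL resolution."""
    params = params or PseudoCBFParams()
    if not template.gm.geometry.approx_equal(template.wm.geometry):
        raise GeometryError("GM and WM maps must share a geometry")
    raw = params.v_gm * template.gm.voxels + params.v_wm * template.wm.voxels
    img = VolumetricImage(template.geometry, raw, "cbf_ml_per_100g_min")
    return gaussian_smooth(img, params.smoothing_fwhm_mm)


#: Gaussian-equivalent FWHM of the triangular kernel implied by linear
#: interpolation of a grid with unit voxel size (matched variance: the
#: triangle of half-width v has variance v^2/6, so FWHM = 2.355 * v/sqrt(6)).
_LINEAR_INTERP_FWHM_PER_VOXEL = 2.0 * np.sqrt(2.0 * np.log(2.0)) / np.sqrt(6.0)


def estimate_tissue_cbf(
    cbf_aligned: VolumetricImage,
    template: TissueTemplate,
    psf_fwhm_mm: tuple[float, float, float] = DEFAULT_ASL_FWHM_MM,
    data_voxel_mm: tuple[float, float, float] | None = DEFAULT_ASL_FWHM_MM[:3],
) -> tuple[float, float]:
    """Estimate subject GM/WM perfusion by least squares against tissue maps.

    Fits ``cbf ~ a * GM + b * WM`` over brain-mask voxels of a roughly
    aligned CBF image and returns ``(a, b)`` in ml/100 g/min — the values
    used to rebuild a subject-specific pseudo-CBF target for the second
    registration iteration. Because smoothing is linear,
    ``blur(a*GM + b*WM) = a*blur(GM) + b*blur(WM)``, the tissue regressors
    are smoothed to the effective resolution of the aligned CBF data —
    ``psf_fwhm_mm`` (the acquisition point spread) combined in quadrature
    with the blur of linearly interpolating the native voxel grid
    (``data_voxel_mm``) onto the template grid. Regressing on sharp maps
    would otherwise attenuate the estimated GM/WM contrast. A
    physiologically implausible fit (b > a or a <= 0) falls back to the
    (60, 20) defaults with a warning.
    """
    if not cbf_aligned.geometry.approx_equal(template.geometry):
        raise GeometryError("aligned CBF must be on the template geometry")
    m = template.brain_mask.mask_array()
    if not m.any():
        raise DegenerateInputError("template brain mask is empty")
    fwhm = np.asarray(psf_fwhm_mm, dtype=float)
    if data_voxel_mm is not None:
        interp = _LINEAR_INTERP_FWHM_PER_VOXEL * np.asarray(data_voxel_mm, dtype=float)
        fwhm = np.sqrt(fwhm**2 + interp**2)
    gm = gaussian_smooth(template.gm, fwhm).voxels
    wm = gaussian_smooth(template.wm, fwhm).voxels
    X = np.column_stack([gm[m], wm[m]])
    if np.linalg.matrix_rank(X.T @ X) < 2 or np.linalg.cond(X.T @ X) > 1e10:
        raise DegenerateInputError(
            "GM and WM maps are collinear over the brain mask; cannot separate tissue CBF"
        )
    y = cbf_aligned.voxels[m]
    (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(a), float(b)
    if b > a or a <= 0:
        msg = (
            f"implausible tissue CBF estimate (GM={a:.1f}, WM={b:.1f}); "
            f"falling back to defaults ({DEFAULT_V_GM:.0f}, {DEFAULT_V_WM:.0f})"
        )
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return DEFAULT_V_GM, DEFAULT_V_WM
    return a, b
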