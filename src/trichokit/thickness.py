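"""Mean hair thickness from contour eigenvalues.

The thickness-branch feature image has been dark-dilated by the
grayscale erosion, so the raw hair area overstates the true hair area.
The estimate works from three ingredients:

* ``area`` — the number of hair pixels;
* the external contour of every 8-connected hair component, whose 2x2
  coordinate covariance has a leading eigenvalue that grows with how far
  the component stretches across the image (the reason the working image
  must be square: a non-square frame would stretch the eigenvalue
  anisotropically);
* the GLS hair count ``h`` for the same frame.

The mean leading eigenvalue, normalized by a hyperparameter ``p`` into
[0, 1), is mapped through

    Lambda_p = (1 - ln(1 - lambda_bar)) / e

and scales the erosion-correction term

    E_p = Lambda_p * h * s / c,        s = erosion_size * side * 2

subtracted from the per-hair area before the micrometer calibration:

    t = alpha * (area / h - E_p)

``alpha`` converts pixels to micrometers and must be calibrated to the
microscope; the default is a placeholder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .preprocess import BinaryFeatureImage

__all__ = [
    "ContourSet",
    "EigenSummary",
    "ThicknessParams",
    "ThicknessEstimate",
    "feature_area",
    "detect_contours",
    "contour_eigenvalue",
    "lambda_transform",
    "erosion_correction",
    "estimate_thickness",
    "thickness_from_mask",
]


@dataclass(frozen=True)
class ContourSet:
    """External boundary pixels of each 8-connected component."""

    contours: tuple[np.ndarray, ...]  # each (m, 2) int array of (row, col)

    @property
    def c(self) -> int:
        return len(self.contours)


@dataclass(frozen=True)
class EigenSummary:
    eigenvalues: tuple[float, ...]  # per-contour leading eigenvalue, px^2
    p: float
    lambda_bar: float               # mean normalized eigenvalue, in [0, 1)
    lambda_p: float                 # transformed value Lambda_p


@dataclass(frozen=True)
class ThicknessParams:
    """Calibration constants for the thickness chain.

    ``s`` defaults to erosion_size * side * 2, the approximate number of
    pixels the erosion adds per hair; ``p`` defaults to side^2 / 6, the
    leading eigenvalue of a full-diagonal line, so any in-image hair has
    a normalized eigenvalue below 1.
    """

    alpha: float = 0.15
    erosion_size: int = 3
    side: int = 512
    p: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.p is not None and self.p <= 0:
            raise ValueError("p must be > 0")
        if self.s is not None and self.s <= 0:
            raise ValueError("s must be > 0")

    @property
    def p_value(self) -> float:
        return self.p if self.p is not None else self.side**2 / 6.0

    @property
    def s_value(self) -> float:
        return self.s if self.s is not None else self.erosion_size * self.side * 2.0


@dataclass(frozen=True)
class ThicknessEstimate:
    area: int
    e_p: float | None
    t: float | None          # micrometers; None when undefined
    lambda_bar: float | None = None


def feature_area(mask: BinaryFeatureImage | np.ndarray) -> int:
    """Number of hair (True) pixels."""
    m = mask.mask if isinstance(mask, BinaryFeatureImage) else np.asarray(mask, dtype=bool)
    return int(np.count_nonzero(m))


def detect_contours(mask: BinaryFeatureImage | np.ndarray) -> ContourSet:
    """External boundary pixels of every 8-connected component.

    The boundary of a component is its pixels with at least one
    non-feature 8-neighbor (image border counts as background); holes
    inside a component are ignored for the count c.
    """
    m = mask.mask if isinstance(mask, BinaryFeatureImage) else np.asarray(mask, dtype=bool)
    lbl, n = measure.label(m, connectivity=2, return_num=True)
    if n == 0:
        return ContourSet(contours=())
    interior = ndimage.binary_erosion(m, structure=np.ones((3, 3), bool), border_value=0)
    boundary = m & ~interior
    coords = np.argwhere(boundary)
    labels_at = lbl[boundary]
    order = np.argsort(labels_at, kind="stable")
    coords, labels_at = coords[order], labels_at[order]
    splits = np.searchsorted(labels_at, np.arange(2, n + 1))
    return ContourSet(contours=tuple(np.split(coords, splits)))


def _leading_eigenvalue(contour: np.ndarray) -> float:
    """Unnormalized leading eigenvalue of the contour covariance, px^2."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 2:
        return 0.0
    cov = np.cov(pts.T, bias=True)
    return float(np.linalg.eigvalsh(cov)[-1])


def contour_eigenvalue(contour: np.ndarray, p: float) -> float:
    """Leading eigenvalue of the contour-point covariance, normalized by p.

    Uses the population (ddof=0) 2x2 covariance of the boundary pixel
    coordinates; result is clamped to [0, 1 - 1e-9]. Contours with fewer
    than two points carry no spread and return 0.
    """
    if p <= 0:
        raise ValueError("p must be > 0")
    lead = _leading_eigenvalue(contour)
    return float(np.clip(lead / p, 0.0, 1.0 - 1e-9))


def lambda_transform(lambda_bar: float) -> float:
    """Lambda_p = (1 - ln(1 - lambda_bar)) / e, increasing on [0, 1)."""
    if not 0 <= lambda_bar < 1:
        raise ValueError("lambda_bar must lie in [0, 1)")
    return (1.0 - np.log(1.0 - lambda_bar)) / np.e


def erosion_correction(lambda_p: float, h: float, s: float, c: int) -> float:
    """E_p = Lambda_p * h * s / c, the dilation area charged per hair."""
    if c < 1:
        raise ValueError("erosion correction undefined for c = 0 contours")
    return lambda_p * h * s / c


def estimate_thickness(area: int, h: float, e_p: float, alpha: float) -> ThicknessEstimate:
    """t = alpha * (area / h - E_p), clamped at zero.

    ``h`` = 0 leaves the thickness undefined (reported as missing).
    """
    if h <= 0:
        raise ValueError("thickness undefined for h <= 0")
    raw = alpha * (area / h - e_p)
    if raw < 0:
        warnings.warn("thickness clamped to 0 (erosion correction exceeds per-hair area)", stacklevel=2)
    return ThicknessEstimate(area=area, e_p=e_p, t=max(0.0, raw))


def thickness_from_mask(
    mask: BinaryFeatureImage,
    h: float,
    params: ThicknessParams | None = None,
) -> tuple[ThicknessEstimate, EigenSummary | None]:
    """Full thickness chain on a thickness-branch feature image.

    Returns a missing estimate (t = None) for empty images or h <= 0.
    """
    params = params or ThicknessParams(side=mask.side)
    area = feature_area(mask)
    contours = detect_contours(mask)
    if contours.c == 0 or h <= 0:
        return ThicknessEstimate(area=area, e_p=None, t=None), None
    p = params.p_value
    eigs = tuple(_leading_eigenvalue(cont) for cont in contours.contours)
    lam_each = [contour_eigenvalue(cont, p) for cont in contours.contours]
    lambda_bar = float(np.clip(np.mean(lam_each), 0.0, 1.0 - 1e-9))
    lam_p = lambda_transform(lambda_bar)
    e_p = erosion_correction(lam_p, h, params.s_value, contours.c)
    est = estimate_thickness(area, h, e_p, params.alpha)
    summary = EigenSummary(eigenvalues=eigs, p=p, lambda_bar=lambda_bar, lambda_p=lam_p)
    return ThicknessEstimate(area=est.area, e_p=est.e_p, t=est.t, lambda_bar=lambda_bar), summary
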