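"""Classical image-processing comparators.

Two pre-deep-learning detectors the segmentation network is compared
against:

* a multiscale Hessian (Frangi) vesselness filter for wrinkles — responds
  to curvilinear ridges via the eigenvalues of the scale-normalized
  Hessian;
* a high-pass + k-means + morphology pipeline for pores — clusters the
  high-frequency residual, keeps the darkest cluster, and cleans it up with
  an opening and component-area limits.

Both operate on [0, 1] grayscale images and can be restricted to a region
of interest, matching how such baselines are evaluated on pre-cropped
target areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening
from sklearn.cluster import KMeans

__all__ = [
    "FrangiParams",
    "PoreBaselineParams",
    "frangi_vesselness",
    "frangi_wrinkle_detect",
    "pore_detect_classical",
]


@dataclass(frozen=True)
class FrangiParams:
    """Multiscale vesselness settings.

    ``beta`` penalizes blob-like structures (R_B = |l1|/|l2|), ``c``
    controls structureness sensitivity (S = sqrt(l1^2 + l2^2)); both act on
    [0, 1] intensity images. ``dark_ridge`` keeps responses only where the
    larger-magnitude eigenvalue is positive (dark lines on bright skin).
    """

    scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    beta: float = 0.5
    c: float = 0.08
    polarity: str = "dark_ridge"
    binarize_threshold: float = 0.2

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("scales must be non-empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError("all scales must be > 0")
        if self.beta <= 0 or self.c <= 0:
            raise ValueError("beta and c must be > 0")
        if self.polarity not in ("dark_ridge", "bright_ridge"):
            raise ValueError("polarity must be 'dark_ridge' or 'bright_ridge'")


@dataclass(frozen=True)
class PoreBaselineParams:
    highpass_sigma: float = 3.0
    k: int = 3
    opening_radius: int = 1
    min_area: int = 2
    max_area: int = 200
    kmeans_seed: int = 0
    kmeans_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.opening_radius < 0 or self.min_area < 0 or self.max_area < 0:
            raise ValueError("radii and areas must be >= 0")
        if self.min_area > self.max_area:
            raise ValueError("min_area must be <= max_area")


def frangi_vesselness(gray: np.ndarray, params: FrangiParams) -> np.ndarray:
    """Continuous vesselness response, maximum over scales.

    Per scale s the Hessian is computed with Gaussian derivative filters
    and normalized by s^2; with eigenvalues |l1| <= |l2|, vesselness is
    exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2)) where R_B = l1/l2 and
    S = sqrt(l1^2 + l2^2), zeroed wherever the sign of l2 conflicts with
    the requested polarity (dark ridges require l2 > 0). The explicit sign
    gate suppresses ideal straight ridges of the wrong polarity even where
    the tangential eigenvalue vanishes exactly.
    """
    gray = np.asarray(gray, dtype=float)
    out = np.zeros_like(gray)
    dark = params.polarity == "dark_ridge"
    for s in params.scales:
        hrr = ndimage.gaussian_filter(gray, s, order=(2, 0), mode="reflect") * s**2
        hcc = ndimage.gaussian_filter(gray, s, order=(0, 2), mode="reflect") * s**2
        hrc = ndimage.gaussian_filter(gray, s, order=(1, 1), mode="reflect") * s**2
        half_diff = np.sqrt(((hrr - hcc) / 2.0) ** 2 + hrc**2)
        mid = (hrr + hcc) / 2.0
        e_lo, e_hi = mid - half_diff, mid + half_diff
        swap = np.abs(e_lo) > np.abs(e_hi)
        lam1 = np.where(swap, e_hi, e_lo)
        lam2 = np.where(swap, e_lo, e_hi)
        rb2 = (lam1 / np.where(lam2 == 0.0, np.inf, lam2)) ** 2
        s2 = lam1**2 + lam2**2
        v = np.exp(-rb2 / (2.0 * params.beta**2)) * (
            1.0 - np.exp(-s2 / (2.0 * params.c**2))
        )
        v = np.where(lam2 > 0.0 if dark else lam2 < 0.0, v, 0.0)
        out = np.maximum(out, v)
    return out


def frangi_wrinkle_detect(
    gray: np.ndarray, params: FrangiParams, roi: np.ndarray | None = None
) -> np.ndarray:
    """Binary wrinkle mask: vesselness thresholded, optionally ROI-limited."""
    mask = frangi_vesselness(gray, params) > params.binarize_threshold
    if roi is not None:
        mask &= np.asarray(roi, dtype=bool)
    return mask


def pore_detect_classical(
    gray: np.ndarray, params: PoreBaselineParams, roi: np.ndarray | None = None
) -> np.ndarray:
    """High-pass residual -> k-means -> darkest cluster -> opening ->
    component-area filter.

    Degenerate inputs (fewer distinct residual values than clusters, e.g. a
    uniform image) yield an empty mask.
    """
    gray = np.asarray(gray, dtype=float)
    highpass = gray - ndimage.gaussian_filter(gray, params.highpass_sigma, mode="reflect")
    values = highpass.reshape(-1, 1)
    if np.unique(values).size < params.k:
        return np.zeros(gray.shape, dtype=bool)
    km = KMeans(
        n_clusters=params.k,
        init="k-means++",
        n_init=5,
        max_iter=params.kmeans_max_iter,
        random_state=params.kmeans_seed,
    )
    labels = km.fit_predict(values).reshape(gray.shape)
    darkest = int(np.argmin(km.cluster_centers_.ravel()))
    mask = labels == darkest
    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    lab, n = ndimage.label(mask)
    if n:
        areas = np.bincount(lab.ravel())[1:]
        keep = np.flatnonzero((areas >= params.min_area) & (areas <= params.max_area)) + 1
        mask = np.isin(lab, keep)
    if roi is not None:
        mask &= np.asarray(roi, dtype=bool)
    return mask
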