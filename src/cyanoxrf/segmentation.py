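"""Cytoplasm delineation and elemental cluster segmentation.

The cell outline is taken from the K map (the most abundant cytosolic
element), clusters are separated from cytosol either by unsupervised
two-class k-means thresholding of the intensity values or by a fixed
concentration threshold, and the two boundaries are combined into a
consensus core (intersection) with an uncertainty band (symmetric
difference).  All thresholding operates on raw concentration values, so the
whole stage is equivariant under positive rescaling of a map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from skimage import measure, morphology

from .core import ElementMap


class DegenerateInputError(ValueError):
    """Raised when values cannot support a two-class split."""


def kmeans_1d(
    values: np.ndarray, k: int = 2, max_iter: int = 200
) -> tuple[np.ndarray, float]:
    """Exact Lloyd k-means on 1-D data; returns (sorted centroids, threshold).

    Deterministic.  For k = 2 the globally optimal split is found directly
    (see below); for k > 2, Lloyd iterations run to an exact fixed point
    from centroids at equally spaced interior percentiles plus the maximum
    (anchoring the top class on the bright tail, which on intensity maps is
    a small cluster population that percentile-only inits miss).  The
    threshold is the midpoint of the two highest sorted centroids.  Raises
    :class:`DegenerateInputError` when fewer than k distinct values exist.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if np.unique(v).size < k:
        raise DegenerateInputError(f"need at least {k} distinct values")
    if k == 2:
        # exact global optimum by scanning all ordered splits with prefix
        # sums; the optimum is itself a Lloyd fixed point (each centroid is
        # its class mean and the class boundary lies at their midpoint), so
        # this is Lloyd converged to the best basin rather than the nearest.
        vs = np.sort(v)
        n = vs.size
        c1 = np.cumsum(vs)
        c2 = np.cumsum(vs**2)
        i = np.arange(1, n)  # class sizes of the lower class
        sse_lo = c2[i - 1] - c1[i - 1] ** 2 / i
        sse_hi = (c2[-1] - c2[i - 1]) - (c1[-1] - c1[i - 1]) ** 2 / (n - i)
        best = int(np.argmin(sse_lo + sse_hi)) + 1
        centroids = np.array([c1[best - 1] / best, (c1[-1] - c1[best - 1]) / (n - best)])
        return centroids, float(centroids.mean())
    qs = np.linspace(25, 75, k - 1)
    centroids = np.append(np.percentile(v, qs), v.max())
    # nudge coincident initial centroids apart so every class is populated
    if np.unique(centroids).size < k:
        centroids = np.linspace(v.min(), v.max(), k + 2)[1:-1]
    for _ in range(max_iter):
        edges = 0.5 * (centroids[:-1] + centroids[1:])
        labels = np.searchsorted(edges, v)
        new = centroids.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new[j] = v[sel].mean()
        if np.array_equal(new, centroids):
            break
        centroids = new
    centroids = np.sort(centroids)
    threshold = float(0.5 * (centroids[-2] + centroids[-1]))
    return centroids, threshold


@dataclass
class CytoplasmMask:
    """Binary cell-footprint mask with its provenance."""

    mask: np.ndarray
    element: str
    threshold: float

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _drop_small_components(mask: np.ndarray, min_size_px: int) -> np.ndarray:
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size_px
    keep[0] = False
    return keep[lab]


def cytoplasm_mask(
    k_map: ElementMap, min_size_px: int = 25, closing_radius: int = 1
) -> CytoplasmMask:
    """Delineate the cytoplasm by intensity-thresholding the K map.

    A K map has three intensity populations — off-cell background, cytosol,
    and bright P/K clusters — so the field is split into three k-means
    classes and the cell outline taken as everything above the midpoint of
    the two *lowest* centroids (a plain two-class split would separate the
    clusters from the rest and swallow the cytosol into the background).
    The thresholded foreground is morphologically closed (radius 1) and
    cleaned of connected components below ``min_size_px``.
    """
    values = k_map.values
    try:
        cents, _ = kmeans_1d(values, k=3)
    except DegenerateInputError:
        try:
            cents, _ = kmeans_1d(values, k=2)
        except DegenerateInputError:
            warnings.warn("K map is degenerate; returning an empty cytoplasm mask")
            return CytoplasmMask(
                np.zeros(k_map.shape, bool), k_map.element, float("nan")
            )
    cents = np.sort(cents)
    thr = float(0.5 * (cents[0] + cents[1]))
    fg = np.where(np.isfinite(values), values, -np.inf) > thr
    fg = morphology.closing(fg, morphology.disk(closing_radius))
    fg = _drop_small_components(fg, min_size_px)
    if not fg.any():
        warnings.warn("empty cytoplasm foreground after cleaning")
    return CytoplasmMask(fg, k_map.element, thr)


def cluster_mask_kmeans(
    emap: ElementMap, cyto: CytoplasmMask
) -> tuple[np.ndarray, bool]:
    """Cluster/non-cluster split of in-cytoplasm values by 1-D k-means.

    In-cell intensities are often trimodal rather than bimodal — vegetative
    cytosol, heterocyst cytosol (severalfold higher for Fe, Ca, K), and the
    clusters proper — so three classes are fitted and the cluster side of
    the *largest centroid gap* is taken: if the top two centroids are closer
    to each other than to the bottom one, both upper classes are clusters
    (a plain bimodal map whose bright mode was split in two); otherwise only
    the top class is.  Falls back to a two-class split when the values
    cannot support three.

    Returns (mask, degenerate_flag); the mask is always a subset of the
    cytoplasm.  A degenerate value distribution yields an empty mask with
    the flag set.
    """
    if not cyto.mask.any():
        raise ValueError("cytoplasm mask is empty")
    inside = emap.values[cyto.mask]
    thr = None
    try:
        cents, _ = kmeans_1d(inside, k=3)
        c1, c2, c3 = np.sort(cents)
        thr = 0.5 * (c2 + c3) if (c3 - c2) > (c2 - c1) else 0.5 * (c1 + c2)
    except DegenerateInputError:
        try:
            _, thr = kmeans_1d(inside, k=2)
        except DegenerateInputError:
            return np.zeros(emap.shape, bool), True
    mask = np.zeros(emap.shape, bool)
    mask[cyto.mask] = np.where(np.isfinite(inside), inside, -np.inf) > thr
    return mask, False


def cluster_mask_fixed(
    emap: ElementMap, cyto: CytoplasmMask, threshold: float
) -> np.ndarray:
    """In-cytoplasm pixels at or above a fixed concentration threshold."""
    if threshold <= 0:
        raise ValueError("fixed threshold must be positive")
    vals = np.where(np.isfinite(emap.values), emap.values, -np.inf)
    return cyto.mask & (vals >= threshold)


def robust_fixed_threshold(
    emap: ElementMap, cyto: CytoplasmMask, n_sigma: float = 3.0
) -> float:
    """Default fixed threshold: cytosol mean + n_sigma·SD.

    The cytosol is the cytoplasm minus the k-means cluster class of the same
    map, so the estimate is not inflated by the clusters themselves.
    """
    km, degenerate = cluster_mask_kmeans(emap, cyto)
    cytosol = cyto.mask & ~km
    vals = emap.values[cytosol]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no cytosol pixels to estimate a threshold from")
    return float(vals.mean() + n_sigma * vals.std())


def consensus_mask(
    m_kmeans: np.ndarray, m_fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-method consensus: core = intersection, band = symmetric difference.

    Averaging concentrations over the core discounts the uncertain cluster
    boundary on which the two methods disagree.
    """
    if m_kmeans.shape != m_fixed.shape:
        raise ValueError("masks must share one shape")
    a = np.asarray(m_kmeans, bool)
    b = np.asarray(m_fixed, bool)
    return a & b, a ^ b


@dataclass
class ROI:
    """One connected cluster region with its tight bounding box."""

    label: int
    element: str
    method: str  # kmeans | fixed | consensus
    rows: np.ndarray
    cols: np.ndarray
    bbox: tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), half-open
    extra: dict = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[self.rows, self.cols] = True
        return m

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def label_rois(
    mask: np.ndarray,
    element: str = "",
    method: str = "",
    connectivity: int = 8,
    min_size_px: int = 2,
) -> list[ROI]:
    """Connected components of a binary mask as ROI records.

    8-connectivity by default (diagonal-touching pixels merge); labels follow
    row-major discovery order; components below ``min_size_px`` are dropped.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = measure.label(np.asarray(mask, bool), connectivity=1 if connectivity == 4 else 2)
    rois = []
    for region in measure.regionprops(lab):
        if region.num_pixels < min_size_px:
            continue
        coords = region.coords
        rmin, cmin, rmax, cmax = region.bbox
        rois.append(
            ROI(
                label=len(rois) + 1,
                element=element,
                method=method,
                rows=coords[:, 0],
                cols=coords[:, 1],
                bbox=(rmin, cmin, rmax, cmax),
            )
        )
    return rois
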