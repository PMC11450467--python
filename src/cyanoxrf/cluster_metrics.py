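"""Per-cluster and per-region quantities from segmented elemental maps.

Covers the morphometric and colocalization statistics reported for the
filament maps: cluster areas and equivalent-circle diameters,
background-subtracted mean concentrations per region, per-ROI Pearson
correlations between element pairs, relative overlap fractions, and the
geometric classification of clusters into P/K-with-Ca, P/K-with-Fe, Ca-only
and Fe-only families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ElementMap, ScanConfig
from .segmentation import ROI


def cluster_area(roi: ROI, scan: ScanConfig) -> float:
    """Cluster area in µm²: pixel count × (step_nm/1000)²."""
    return roi.n_pixels * scan.pixel_area_um2


def equivalent_diameter(roi: ROI, scan: ScanConfig) -> float:
    """Equivalent-circle diameter in µm: 2·√(area/π)."""
    return 2.0 * float(np.sqrt(cluster_area(roi, scan) / np.pi))


@dataclass
class RegionConcentration:
    """Background-subtracted mean concentration over one region."""

    region: str
    element: str
    mean: float
    sd: float
    n_pixels: int
    background: float


def region_mean_concentration(
    emap: ElementMap,
    region_mask: np.ndarray,
    background_mask: np.ndarray | None = None,
    region: str = "",
) -> RegionConcentration:
    """Mean of (value − median(background)) over a region, clamped at 0.

    The background value is the median over ``background_mask`` (typically
    the off-cytoplasm substrate/ice); an empty background mask degrades to a
    background of 0, i.e. the raw mean.
    """
    region_mask = np.asarray(region_mask, bool)
    vals = emap.values[region_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("region is empty")
    bg = 0.0
    if background_mask is not None and np.asarray(background_mask, bool).any():
        bvals = emap.values[np.asarray(background_mask, bool)]
        bvals = bvals[np.isfinite(bvals)]
        if bvals.size:
            bg = float(np.median(bvals))
    sub = vals - bg
    return RegionConcentration(
        region=region,
        element=emap.element,
        mean=max(float(sub.mean()), 0.0),
        sd=float(sub.std(ddof=1)) if sub.size > 1 else 0.0,
        n_pixels=int(vals.size),
        background=bg,
    )


@dataclass
class CorrelationRecord:
    """Pearson correlation of two element maps over one ROI's bounding box."""

    element_a: str
    element_b: str
    roi_label: int
    pearson_r: float
    n_pixels: int
    defined: bool = True


def roi_pearson(
    map_a: ElementMap, map_b: ElementMap, roi: ROI
) -> CorrelationRecord:
    """Sample Pearson r over the pixels of the ROI's bounding box.

    The box (rather than only in-cluster pixels) keeps anti-colocalization
    detectable.  Zero variance in either map is flagged undefined (r = NaN).
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share one shape")
    rmin, cmin, rmax, cmax = roi.bbox
    a = map_a.values[rmin:rmax, cmin:cmax].ravel()
    b = map_b.values[rmin:rmax, cmin:cmax].ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationRecord(
            map_a.element, map_b.element, roi.label, float("nan"), int(a.size), False
        )
    r = float(stats.pearsonr(a, b).statistic)
    return CorrelationRecord(map_a.element, map_b.element, roi.label, r, int(a.size))


@dataclass
class OverlapRecord:
    """Relative overlap of two pixel sets under both normalizations."""

    element_a: str
    element_b: str
    overlap_min: float
    jaccard: float
    n_intersection: int


def overlap_fraction(
    roi_a: ROI, roi_b: ROI, element_a: str = "", element_b: str = ""
) -> OverlapRecord:
    """|A∩B|/min(|A|,|B|) and |A∩B|/|A∪B|; symmetric in its arguments.

    ``overlap_min`` reads through size mismatches (a small cluster fully
    inside a big one scores 1), which is why it is the primary statistic for
    element pairs whose clusters differ systematically in size.
    """
    sa, sb = roi_a.pixel_set(), roi_b.pixel_set()
    inter = len(sa & sb)
    union = len(sa | sb)
    om = inter / min(len(sa), len(sb)) if sa and sb else 0.0
    jc = inter / union if union else 0.0
    return OverlapRecord(
        element_a or roi_a.element,
        element_b or roi_b.element,
        overlap_min=om,
        jaccard=jc,
        n_intersection=inter,
    )


def _mask_overlap_min(pixels: set, mask: np.ndarray) -> float:
    """Best overlap_min of a pixel set against any connected component of a
    mask: |cand ∩ comp| / min(|cand|, |comp|), maximized over components.

    The min-normalization lets a small aggregate sitting fully inside (or
    fully containing) a cluster of another element score 1 even when the
    two differ greatly in size.
    """
    if not pixels or not mask.any():
        return 0.0
    from skimage import measure as _measure

    lab = _measure.label(np.asarray(mask, bool), connectivity=2)
    sizes = np.bincount(lab.ravel())
    hits: dict[int, int] = {}
    for r, c in pixels:
        l = int(lab[r, c])
        if l:
            hits[l] = hits.get(l, 0) + 1
    if not hits:
        return 0.0
    return max(
        n_int / min(len(pixels), int(sizes[l])) for l, n_int in hits.items()
    )


def classify_cluster(
    pixels: set[tuple[int, int]],
    masks: dict[str, np.ndarray],
    min_overlap: float = 0.5,
) -> str:
    """Assign a family tag from co-registered P/K/Ca/Fe cluster masks.

    A P/K core requires the candidate pixels to overlap both the P and the K
    cluster masks by at least ``min_overlap`` (fraction of the candidate's
    pixels).  A core is then associated with Ca or Fe by the same criterion
    against the Ca/Fe masks (Ca wins ties, being the geometrically larger
    wrapper); remaining clusters are Ca_only/Fe_only if they overlap a single
    element's mask, else unclassified.  Tags are geometric labels only — no
    chemical identity is implied.
    """
    ov = {el: _mask_overlap_min(pixels, m) for el, m in masks.items()}
    p_ok = ov.get("P", 0.0) >= min_overlap
    k_ok = ov.get("K", 0.0) >= min_overlap
    if p_ok and k_ok:
        ca, fe = ov.get("Ca", 0.0), ov.get("Fe", 0.0)
        if ca >= min_overlap and ca >= fe:
            return "PK_Ca"
        if fe >= min_overlap:
            return "PK_Fe"
        return "unclassified"
    if ov.get("Ca", 0.0) >= min_overlap and ov.get("Fe", 0.0) < min_overlap:
        return "Ca_only"
    if ov.get("Fe", 0.0) >= min_overlap and ov.get("Ca", 0.0) < min_overlap:
        return "Fe_only"
    return "unclassified"
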