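"""End-to-end orchestration: phantom → measurement → maps → clusters → stats.

Two measurement routes feed the same downstream stages:

* the **spectral route** (full per-pixel spectra, SNIP stripping, EMG
  fitting, thin-film calibration) — the complete quantification chain, used
  for the fixed-seed concentration-recovery runs;
* the **count-map route** (per-element Poisson counts divided by
  sensitivity × dwell) — statistically equivalent input to segmentation at a
  fraction of the cost, used for the multi-filament cluster-size pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_metrics import (
    classify_cluster,
    cluster_area,
    equivalent_diameter,
    region_mean_concentration,
    roi_pearson,
)
from .core import DetectorModel, ElementMap
from .phantom import (
    PhantomConfig,
    PhantomTruth,
    counts_to_concentration,
    default_standard_densities,
    generate_filament,
    make_paper_preset,
    simulate_counts,
    simulate_spectra,
    simulate_standard_spectrum,
)
from .segmentation import (
    CytoplasmMask,
    ROI,
    cluster_mask_fixed,
    cluster_mask_kmeans,
    consensus_mask,
    cytoplasm_mask,
    label_rois,
    robust_fixed_threshold,
)
from .spectra import CalibrationStandard, calibrate_sensitivities, quantify_map

CLUSTER_ELEMENTS = ("P", "K", "Ca", "Fe")


# --------------------------------------------------------------------------
# measurement routes
# --------------------------------------------------------------------------

def noisy_concentration_maps(
    truth: PhantomTruth, det: DetectorModel, seed: int
) -> dict[str, ElementMap]:
    """Count-map route: Poisson counts inverted by the known sensitivity."""
    counts = simulate_counts(truth, det=det, seed=seed)
    return counts_to_concentration(counts, truth.config.scan, det)


def spectral_concentration_maps(
    truth: PhantomTruth,
    det: DetectorModel,
    seed: int,
    standard_densities: dict[str, float] | None = None,
) -> dict[str, ElementMap]:
    """Spectral route: simulate spectra, strip, fit, calibrate, quantify."""
    cube = simulate_spectra(truth, det=det, seed=seed)
    densities = standard_densities or default_standard_densities()
    std_spec = simulate_standard_spectrum(
        densities, det, live_time_ms=5000.0, seed=seed + 1
    )
    sens = calibrate_sensitivities(
        CalibrationStandard(densities=densities, spectrum=std_spec), det
    )
    elements = sorted(truth.element_maps)
    return quantify_map(cube, sens, elements=elements, det=det)


# --------------------------------------------------------------------------
# segmentation bundle
# --------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Cytoplasm plus per-element cluster masks and labelled ROIs."""

    cyto: CytoplasmMask
    kmeans_masks: dict[str, np.ndarray] = field(default_factory=dict)
    fixed_masks: dict[str, np.ndarray] = field(default_factory=dict)
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    consensus_cores: dict[str, np.ndarray] = field(default_factory=dict)
    consensus_bands: dict[str, np.ndarray] = field(default_factory=dict)
    rois: dict[str, list[ROI]] = field(default_factory=dict)


def segment_maps(
    maps: dict[str, ElementMap],
    elements: tuple[str, ...] = CLUSTER_ELEMENTS,
    cyto_element: str = "K",
) -> SegmentationResult:
    """Cytoplasm from the K map, then k-means/fixed/consensus per element."""
    cyto = cytoplasm_mask(maps[cyto_element])
    out = SegmentationResult(cyto=cyto)
    for el in elements:
        if el not in maps:
            continue
        km, degenerate = cluster_mask_kmeans(maps[el], cyto)
        out.kmeans_masks[el] = km
        if degenerate:
            out.fixed_masks[el] = km.copy()
            out.fixed_thresholds[el] = float("nan")
        else:
            thr = robust_fixed_threshold(maps[el], cyto)
            out.fixed_thresholds[el] = thr
            out.fixed_masks[el] = cluster_mask_fixed(maps[el], cyto, thr)
        core, band = consensus_mask(out.kmeans_masks[el], out.fixed_masks[el])
        out.consensus_cores[el] = core
        out.consensus_bands[el] = band
        out.rois[el] = label_rois(out.kmeans_masks[el], element=el, method="kmeans")
    return out


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def cluster_size_table(
    seg: SegmentationResult, maps: dict[str, ElementMap]
) -> pd.DataFrame:
    """One row per k-means cluster ROI: pixels, area, equivalent diameter."""
    rows = []
    for el, rois in seg.rois.items():
        scan_like = maps[el]
        for roi in rois:
            area = roi.n_pixels * scan_like.pixel_area_um2
            rows.append(
                {
                    "element": el,
                    "label": roi.label,
                    "method": roi.method,
                    "n_pixels": roi.n_pixels,
                    "area_um2": area,
                    "equiv_diameter_um": 2.0 * np.sqrt(area / np.pi),
                    "centroid_row": roi.centroid[0],
                    "centroid_col": roi.centroid[1],
                    "bbox": "/".join(map(str, roi.bbox)),
                }
            )
    return pd.DataFrame(rows)


def consensus_concentration(
    maps: dict[str, ElementMap], seg: SegmentationResult, element: str = "Ca"
):
    """Background-subtracted mean concentration over the consensus core."""
    core = seg.consensus_cores[element]
    if not core.any():
        raise ValueError(f"empty consensus core for {element}")
    return region_mean_concentration(
        maps[element], core, background_mask=~seg.cyto.mask,
        region=f"{element}_clusters_consensus",
    )


def cytosol_concentration_table(
    maps: dict[str, ElementMap], truth: PhantomTruth, seg: SegmentationResult
) -> pd.DataFrame:
    """Per-cell, per-element cytosolic means (clusters excluded).

    Cell identities come from the phantom's cell-label map: cell-type
    assignment is an input to this analysis, not an inference.
    """
    rows = []
    bg = ~seg.cyto.mask
    for cell in truth.cells:
        cell_mask = truth.cell_label_map == cell.cell_id
        for el, emap in sorted(maps.items()):
            region = cell_mask & seg.cyto.mask
            cl = seg.kmeans_masks.get(el)
            if cl is not None:
                region = region & ~cl
            if not region.any():
                continue
            rc = region_mean_concentration(
                emap, region, background_mask=bg,
                region=f"cell{cell.cell_id}_{cell.kind}_cytosol",
            )
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "kind": cell.kind,
                    "element": el,
                    "mean_conc": rc.mean,
                    "sd": rc.sd,
                    "n_pixels": rc.n_pixels,
                    "background": rc.background,
                }
            )
    return pd.DataFrame(rows)


def colocalization_tables(
    maps: dict[str, ElementMap],
    seg: SegmentationResult,
    pairs: tuple[tuple[str, str], ...] = (("P", "K"), ("K", "Ca"), ("K", "Fe"), ("P", "Ca")),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI Pearson correlations and overlap fractions for element pairs.

    Correlations are computed over each ROI of the first element of a pair;
    overlaps compare that ROI against the second element's cluster mask.
    Both the per-ROI values and the pooled (all-ROI-pixels) correlation are
    reported, since either reduction is defensible.
    """
    from .cluster_metrics import OverlapRecord, overlap_fraction  # noqa: F401

    corr_rows, ov_rows = [], []
    for el_a, el_b in pairs:
        if el_a not in seg.rois or el_b not in maps:
            continue
        mask_b = seg.kmeans_masks[el_b]
        for roi in seg.rois[el_a]:
            rec = roi_pearson(maps[el_a], maps[el_b], roi)
            corr_rows.append(
                {
                    "element_a": el_a,
                    "element_b": el_b,
                    "roi": roi.label,
                    "pearson_r": rec.pearson_r,
                    "n_pixels": rec.n_pixels,
                    "defined": rec.defined,
                    "reduction": "per_roi",
                }
            )
            pix = roi.pixel_set()
            inter = sum(1 for (r, c) in pix if mask_b[r, c])
            n_b = int(mask_b.sum())
            ov_rows.append(
                {
                    "element_a": el_a,
                    "element_b": el_b,
                    "roi": roi.label,
                    "overlap_min": inter / min(len(pix), n_b) if n_b else 0.0,
                    "jaccard": inter / (len(pix) + n_b - inter) if (len(pix) + n_b - inter) else 0.0,
                    "n_pixels_a": len(pix),
                }
            )
        # pooled reduction: single r over all ROI-bounding-box pixels
        sel = np.zeros(maps[el_a].shape, bool)
        for roi in seg.rois[el_a]:
            rmin, cmin, rmax, cmax = roi.bbox
            sel[rmin:rmax, cmin:cmax] = True
        a = maps[el_a].values[sel]
        b = maps[el_b].values[sel]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() > 2 and np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:
            r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            corr_rows.append(
                {
                    "element_a": el_a,
                    "element_b": el_b,
                    "roi": 0,
                    "pearson_r": r,
                    "n_pixels": int(ok.sum()),
                    "defined": True,
                    "reduction": "pooled",
                }
            )
    return pd.DataFrame(corr_rows), pd.DataFrame(ov_rows)


def classify_table(seg: SegmentationResult) -> pd.DataFrame:
    """Family tag for every K-cluster ROI from the co-registered masks."""
    masks = {el: seg.kmeans_masks[el] for el in seg.kmeans_masks}
    rows = []
    for roi in seg.rois.get("K", []):
        fam = classify_cluster(roi.pixel_set(), masks)
        rows.append({"element": "K", "roi": roi.label, "family": fam})
    for el in ("Ca", "Fe"):
        for roi in seg.rois.get(el, []):
            fam = classify_cluster(roi.pixel_set(), masks)
            rows.append({"element": el, "roi": roi.label, "family": fam})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# multi-filament pooling and recovery
# --------------------------------------------------------------------------

def pooled_cluster_sizes(
    config: PhantomConfig,
    det: DetectorModel,
    seeds: list[int],
    elements: tuple[str, ...] = ("K", "Fe"),
) -> dict[str, pd.DataFrame]:
    """Segmented cluster sizes pooled over independently simulated filaments.

    Uses the count-map measurement route; returns one size table per
    element with a ``seed`` column identifying the filament.
    """
    tables: dict[str, list[pd.DataFrame]] = {el: [] for el in elements}
    for s in seeds:
        truth = generate_filament(config, seed=s)
        maps = noisy_concentration_maps(truth, det, seed=s + 500_000)
        seg = segment_maps(maps, elements=tuple(elements))
        tab = cluster_size_table(seg, maps)
        for el in elements:
            sub = tab[tab.element == el].copy()
            sub["seed"] = s
            tables[el].append(sub)
    return {el: pd.concat(t, ignore_index=True) for el, t in tables.items() if t}


def recovery_run(
    seed: int,
    config: PhantomConfig | None = None,
    det: DetectorModel | None = None,
    n_filaments: int = 20,
) -> dict[str, float]:
    """Recover the preset's printed values from simulated measurements.

    Returns the three headline recoveries: consensus Ca-cluster
    concentration (µg/cm², spectral route, fixed seed), pooled mean K-cluster
    equivalent diameter (µm) and pooled mean Fe-cluster area (µm²) over
    ``n_filaments`` filaments.
    """
    config = config or make_paper_preset()
    det = det or DetectorModel()
    truth = generate_filament(config, seed=seed * 10_000 + 1)
    maps = spectral_concentration_maps(truth, det, seed=seed * 10_000 + 2)
    seg = segment_maps(maps)
    ca = consensus_concentration(maps, seg, "Ca")
    seeds = [seed * 10_000 + 100 + i for i in range(n_filaments)]
    pools = pooled_cluster_sizes(config, det, seeds, elements=("K", "Fe"))
    return {
        "ca_cluster_conc_ug_cm2": ca.mean,
        "k_cluster_mean_diameter_um": float(pools["K"].equiv_diameter_um.mean()),
        "fe_cluster_mean_area_um2": float(pools["Fe"].area_um2.mean()),
        "n_k_clusters": int(len(pools["K"])),
        "n_fe_clusters": int(len(pools["Fe"])),
    }
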