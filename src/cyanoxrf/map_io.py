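"""HDF5 map bundles, display scaling, and image export.

Raw concentration data is never clipped on disk; percentile clipping is a
display-only transform (98th percentile for general contrast, 99.9th for
cluster-emphasis figures), mirroring the separation between quantification
and visualization in the underlying workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import ElementMap


@dataclass(frozen=True)
class DisplayScale:
    """Display normalization: min fixed at 0, max at a data percentile."""

    clip_percentile: float = 98.0

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_percentile <= 100.0):
            raise ValueError("clip_percentile must be in (0, 100]")


#: cluster-emphasis scale used when exporting segmentation figures
EMPHASIS_SCALE = DisplayScale(clip_percentile=99.9)


def write_bundle(
    maps: dict[str, ElementMap],
    path: str | Path,
    dwell_ms: float | None = None,
    seed: int | None = None,
    group: str = "truth",
) -> None:
    """Write element maps to HDF5: one dataset per element under ``group``.

    step_nm (and optionally dwell_ms, seed) are stored as attributes; NaN
    encodes missing pixels and round-trips losslessly.
    """
    if not maps:
        raise ValueError("no maps to write")
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        for el, emap in maps.items():
            if el in g:
                del g[el]
            g.create_dataset(el, data=emap.values, compression="gzip")
        g.attrs["step_nm"] = next(iter(maps.values())).step_nm
        if dwell_ms is not None:
            g.attrs["dwell_ms"] = dwell_ms
        if seed is not None:
            g.attrs["seed"] = seed


def read_bundle(path: str | Path, group: str = "truth") -> dict[str, ElementMap]:
    """Read an element-map bundle written by :func:`write_bundle`."""
    with h5py.File(path, "r") as f:
        if group not in f:
            raise KeyError(f"group {group!r} not found in {path}")
        g = f[group]
        if "step_nm" not in g.attrs:
            raise KeyError(
                f"group {group!r} in {path} lacks the required step_nm attribute"
            )
        step_nm = float(g.attrs["step_nm"])
        return {
            el: ElementMap(element=el, values=g[el][()], step_nm=step_nm)
            for el in g.keys()
        }


def percentile_clip(emap: ElementMap, scale: DisplayScale = DisplayScale()) -> np.ndarray:
    """Normalize a map to [0, 1]: min(values, P)/P with P the stated percentile.

    The percentile is computed over finite pixels only (linear-interpolation
    definition); values above P saturate at 1.  Invariant under positive
    rescaling of the map.
    """
    finite = emap.values[np.isfinite(emap.values)]
    if finite.size == 0:
        raise ValueError("cannot display an all-missing map")
    p = float(np.percentile(finite, scale.clip_percentile))
    if p <= 0:
        # degenerate all-zero (or zero-percentile) map: render black
        out = np.zeros_like(emap.values)
        out[~np.isfinite(emap.values)] = np.nan
        return out
    return np.minimum(emap.values, p) / p


def export_overlay(
    maps: tuple[ElementMap, ElementMap, ElementMap],
    scale: DisplayScale = DisplayScale(),
) -> np.ndarray:
    """Three-element color overlay: each channel independently clipped."""
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("overlay channels must share one shape")
    return np.stack([percentile_clip(m, scale) for m in maps], axis=-1)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save a [0,1] image (grey or RGB) as 16-bit TIFF/PNG; NaN renders as 0."""
    arr = np.nan_to_num(np.asarray(image, dtype=float), nan=0.0)
    arr16 = np.clip(arr * 65535.0, 0, 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        from PIL import Image

        if arr16.ndim == 2:
            Image.fromarray(arr16, mode="I;16").save(path)
        else:  # PNG RGB is 8-bit per channel
            Image.fromarray(np.clip(arr * 255, 0, 255).astype(np.uint8)).save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Save a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
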