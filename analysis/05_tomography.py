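#!/usr/bin/env python
"""Missing-wedge SIRT tomography of a core/shell cell volume.

Builds a small 3-D phantom volume (extruded cell disk containing a K-rich
core wrapped in a larger Ca-rich shell, mirroring the peripheral cluster
architecture seen in 2-D), acquires 51 parallel-beam projections from −82°
to 70° per scan row, reconstructs slice by slice with SIRT (100 iterations,
nonnegativity), and characterizes wedge artifacts via correlation with the
known volume and radial profiles.  Outputs under results/05_tomo/.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from cyanoxrf.map_io import save_image
from cyanoxrf.tomo import (
    paper_wedge_config,
    project_volume,
    reconstruct_volume,
)

SEED = 1
N = 64
N_SLICES = 8
OUT = Path(__file__).resolve().parent.parent / "results" / "05_tomo"


def build_volume(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:N, 0:N]
    cy, cx = N / 2 + rng.uniform(-2, 2), N / 2 + rng.uniform(-2, 2)
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    cell = r2 <= (N / 2.6) ** 2
    core = r2 <= (N / 9) ** 2
    shell = (r2 <= (N / 6) ** 2) & ~core
    k_slice = cell * 0.28 + core * 1.2
    ca_slice = cell * 0.03 + shell * 1.3
    return {
        "K": np.stack([k_slice] * N_SLICES).astype(float),
        "Ca": np.stack([ca_slice] * N_SLICES).astype(float),
    }


def radial_profile(img: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    r = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
    return np.array(
        [img[(r >= b) & (r < b + 1)].mean() for b in range(int(img.shape[0] / 2))]
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = paper_wedge_config(detector_bins=N)
    volumes = build_volume(SEED)
    report = {}
    recons = {}
    for el, vol in volumes.items():
        sinos = project_volume(vol, cfg, element=el)
        rec = reconstruct_volume(sinos, n_iter=100)
        recons[el] = rec
        r = float(np.corrcoef(rec.ravel(), vol.ravel())[0, 1])
        axial = rec.sum(axis=(1, 2))
        report[el] = {
            "pearson_r_vs_truth": r,
            "axial_profile_cv": float(axial.std() / axial.mean()),
        }
        save_image(rec[N_SLICES // 2] / rec.max(), OUT / f"recon_mid_{el}.tif")

    mid = N_SLICES // 2
    center = (N / 2, N / 2)
    prof_k = radial_profile(recons["K"][mid], center)
    prof_ca = radial_profile(recons["Ca"][mid], center)
    report["radial_peak_K_px"] = int(np.argmax(prof_k))
    report["radial_peak_Ca_px"] = int(np.argmax(prof_ca))
    report["ca_shell_outside_k_core"] = bool(
        np.argmax(prof_ca) > np.argmax(prof_k)
    )
    np.savetxt(OUT / "radial_profiles.csv",
               np.column_stack([prof_k, prof_ca]), delimiter=",",
               header="K,Ca", comments="")
    (OUT / "tomo_report.json").write_text(json.dumps(report, indent=2))

    print(f"51 projections, −82°…70° wedge, {N}×{N} slices × {N_SLICES} rows")
    for el in volumes:
        print(f"{el}: r(recon, truth) = {report[el]['pearson_r_vs_truth']:.3f}, "
              f"axial CV = {report[el]['axial_profile_cv']:.3%}")
    print(f"Ca radial peak at {report['radial_peak_Ca_px']} px vs "
          f"K at {report['radial_peak_K_px']} px "
          f"(shell resolved outside core: {report['ca_shell_outside_k_core']})")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
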