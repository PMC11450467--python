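"""Phantom generator: preset values, geometry invariants, forward models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from cyanoxrf.core import DetectorModel, ScanConfig
from cyanoxrf.phantom import (
    GeometryError,
    SizeDist,
    generate_filament,
    make_paper_preset,
    simulate_counts,
    simulate_spectra,
)


class TestPaperPreset:
    def test_encodes_reported_concentrations(self, paper_cfg):
        het = paper_cfg.heterocyst.cytosol_conc
        veg = paper_cfg.vegetative.cytosol_conc
        assert het["K"] == pytest.approx(0.452)
        assert het["Fe"] == pytest.approx(0.095)
        assert het["Ca"] == pytest.approx(0.073)
        assert veg["K"] == pytest.approx(0.277)
        assert veg["Fe"] == pytest.approx(0.027)
        assert veg["Ca"] == pytest.approx(0.029)
        # total Ca inside a Ca-rich cluster: cytosol + boost
        ca_shell = paper_cfg.clusters["PK_Ca"].shell_conc["Ca"] + veg["Ca"]
        assert ca_shell == pytest.approx(1.337)

    def test_encodes_reported_sizes_and_counts(self, paper_cfg):
        pk = paper_cfg.clusters["PK_Ca"].size_dist
        assert pk.mean == pytest.approx(0.99)
        assert pk.sd == pytest.approx(0.48)
        assert paper_cfg.clusters["Fe_only"].size_dist.mean == pytest.approx(0.050)
        assert paper_cfg.clusters["Ca_only"].size_dist.mean == pytest.approx(0.310)
        # 2-4 P/K clusters per vegetative cell, none in the heterocyst
        lo = sum(
            paper_cfg.cluster_count_range(f, "vegetative")[0]
            for f in ("PK_Ca", "PK_Fe")
        )
        hi = sum(
            paper_cfg.cluster_count_range(f, "vegetative")[1]
            for f in ("PK_Ca", "PK_Fe")
        )
        assert (lo, hi) == (2, 4)
        for fam in ("PK_Ca", "PK_Fe"):
            assert paper_cfg.cluster_count_range(fam, "heterocyst") == (0, 0)
        assert paper_cfg.vegetative.envelope_nm == pytest.approx(345.0)
        assert paper_cfg.scan.pixel_area_um2 == pytest.approx(0.01)


class TestSizeDist:
    def test_moment_matched_mean_despite_truncation(self):
        # heavy lower truncation: naive truncation would inflate the mean
        dist = SizeDist(mean=0.050, sd=0.095, lower=0.02, upper=0.45, kind="area_um2")
        x = dist.sample(20_000, np.random.default_rng(0))
        assert x.min() >= 0.02 and x.max() <= 0.45
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 0.050) < 4 * se

    def test_pooled_truth_diameters_match_nominal_mean(self, paper_cfg):
        diams = []
        for s in range(30, 45):
            truth = generate_filament(paper_cfg, seed=s)
            diams += [
                2 * np.sqrt(c.area_um2 / np.pi)
                for c in truth.clusters
                if c.role == "core"
            ]
        assert len(diams) > 200
        assert np.mean(diams) == pytest.approx(0.99, rel=0.05)


class TestGenerateFilament:
    def test_deterministic_given_seed(self, paper_cfg):
        a = generate_filament(paper_cfg, seed=5)
        b = generate_filament(paper_cfg, seed=5)
        for el in a.element_maps:
            assert np.array_equal(a.element_maps[el].values, b.element_maps[el].values)
        assert a.registry_frame().equals(b.registry_frame())

    def test_zero_cluster_config_gives_pure_cytosol(self, paper_cfg):
        cfg = dataclasses.replace(paper_cfg, clusters={})
        truth = generate_filament(cfg, seed=2)
        assert truth.clusters == []
        k = truth.element_maps["K"].values
        assert set(np.unique(k)) <= {0.0, 0.277, 0.452}

    def test_registry_invariants(self, paper_truth):
        cfg = paper_truth.config
        px_area = cfg.scan.pixel_area_um2
        counts_per_cell: dict[tuple[int, str], int] = {}
        for cl in paper_truth.clusters:
            owners = np.unique(paper_truth.cell_label_map[cl.rows, cl.cols])
            assert owners.size == 1 and owners[0] == cl.cell_id
            assert cl.area_um2 == pytest.approx(cl.n_pixels * px_area)
            key = (cl.cell_id, cl.family)
            if cl.role in ("core", "disk", "blob"):
                counts_per_cell[key] = counts_per_cell.get(key, 0) + 1
        kinds = {c.cell_id: c.kind for c in paper_truth.cells}
        for (cell_id, fam), n in counts_per_cell.items():
            lo, hi = cfg.cluster_count_range(fam, kinds[cell_id])
            assert lo <= n <= hi
        het_id = next(c.cell_id for c in paper_truth.cells if c.kind == "heterocyst")
        assert not any(
            cl.cell_id == het_id and cl.family.startswith("PK")
            for cl in paper_truth.clusters
        )
        for el, emap in paper_truth.element_maps.items():
            assert (emap.values >= 0).all()

    def test_ca_shell_encloses_core(self, paper_truth):
        cores = {
            (c.cell_id, c.cluster_id): c
            for c in paper_truth.clusters
            if c.family == "PK_Ca" and c.role == "core"
        }
        shells = [c for c in paper_truth.clusters if c.role == "shell"]
        assert shells
        for sh in shells:
            core = paper_truth.clusters[sh.cluster_id - 2]  # registered just before
            assert core.role == "core" and core.family == "PK_Ca"
            assert sh.n_pixels > core.n_pixels
            crow, ccol = int(round(core.rows.mean())), int(round(core.cols.mean()))
            assert (crow, ccol) in sh.pixel_set()

    def test_pk_registries_disjoint_from_solitary_families(self, paper_truth):
        pk_pixels = set()
        for cl in paper_truth.clusters:
            if cl.family.startswith("PK") and cl.role in ("core", "satellite"):
                pk_pixels |= cl.pixel_set()
        for cl in paper_truth.clusters:
            if cl.family in ("Ca_only", "Fe_only"):
                assert not (cl.pixel_set() & pk_pixels)

    def test_mass_conservation(self, paper_truth):
        cfg = paper_truth.config
        px_cm2 = (cfg.scan.step_nm * 1e-7) ** 2
        for el, emap in paper_truth.element_maps.items():
            total = emap.values.sum() * px_cm2
            assert total == pytest.approx(paper_truth.analytic_mass_ug[el], rel=1e-9)

    def test_overflowing_field_raises(self, paper_cfg):
        cfg = dataclasses.replace(
            paper_cfg, scan=ScanConfig(100.0, 200.0, (96, 120))
        )
        with pytest.raises(GeometryError):
            generate_filament(cfg, seed=1)


class TestSimulateCounts:
    def test_poisson_moments_on_uniform_map(self, paper_cfg, det):
        cfg = dataclasses.replace(paper_cfg, clusters={})
        truth = generate_filament(cfg, seed=3)
        truth.element_maps = {"K": truth.element_maps["K"]}
        truth.element_maps["K"].values[:] = 0.4
        counts = simulate_counts(truth, det=det, seed=4)["K"]
        lam = 0.4 * det.sensitivity("K") * cfg.scan.dwell_ms
        n = counts.size
        se = np.sqrt(lam / n)
        assert abs(counts.mean() - lam) < 3 * se

    def test_dwell_scales_expected_counts(self, paper_cfg, det):
        cfg = dataclasses.replace(paper_cfg, clusters={})
        truth = generate_filament(cfg, seed=3)
        c1 = simulate_counts(truth, det=det, seed=5)
        scan2 = dataclasses.replace(cfg.scan, dwell_ms=cfg.scan.dwell_ms * 2)
        c2 = simulate_counts(truth, scan=scan2, det=det, seed=6)
        sel = truth.cytoplasm_mask
        ratio = c2["K"][sel].mean() / c1["K"][sel].mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_zero_map_gives_zero_counts(self, paper_cfg, det):
        cfg = dataclasses.replace(paper_cfg, clusters={})
        truth = generate_filament(cfg, seed=3)
        for m in truth.element_maps.values():
            m.values[:] = 0.0
        counts = simulate_counts(truth, det=det, seed=7)
        assert all((c == 0).all() for c in counts.values())


class TestSimulateSpectra:
    def test_noiseless_peak_integral_matches_forward_area(self, small_cfg, det):
        cfg = dataclasses.replace(small_cfg, clusters={})
        truth = generate_filament(cfg, seed=8)
        truth.element_maps = {"K": truth.element_maps["K"]}
        cube = simulate_spectra(truth, det=det, seed=0, noise=False)
        r, c = [int(v) for v in truth.cells[0].center]
        spec = cube.counts[r, c].astype(float) - det.continuum(cfg.scan.dwell_ms)
        conc = truth.element_maps["K"].values[r, c]
        expected_ka = conc * det.sensitivity("K") * cfg.scan.dwell_ms
        ratio = det.catalog["K"].kb_ka_ratio
        assert spec.sum() == pytest.approx(expected_ka * (1 + ratio), rel=1e-3)

    def test_empty_truth_gives_continuum_only(self, small_cfg, det):
        cfg = dataclasses.replace(small_cfg, clusters={})
        truth = generate_filament(cfg, seed=8)
        for m in truth.element_maps.values():
            m.values[:] = 0.0
        cube = simulate_spectra(truth, det=det, seed=0, noise=False)
        cont = det.continuum(cfg.scan.dwell_ms)
        assert np.allclose(cube.counts[0, 0], cont, atol=1e-5)
        assert np.allclose(cube.counts[-1, -1], cont, atol=1e-5)

    def test_deterministic_given_seed(self, small_cfg, det):
        truth = generate_filament(small_cfg, seed=9)
        a = simulate_spectra(truth, det=det, seed=3)
        b = simulate_spectra(truth, det=det, seed=3)
        assert np.array_equal(a.counts, b.counts)
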