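"""Shared fixtures: one paper-preset phantom and its measured maps.

The expensive objects (spectral-route quantification, multi-filament pools)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import dataclasses

import pytest

from cyanoxrf.core import DetectorModel, ScanConfig
from cyanoxrf.phantom import generate_filament, make_paper_preset
from cyanoxrf.pipeline import (
    noisy_concentration_maps,
    segment_maps,
    spectral_concentration_maps,
)


@pytest.fixture(scope="session")
def det() -> DetectorModel:
    return DetectorModel()


@pytest.fixture(scope="session")
def paper_cfg():
    return make_paper_preset()


@pytest.fixture(scope="session")
def small_cfg(paper_cfg):
    """Two-cell filament on a compact field (fast spectral tests)."""
    return dataclasses.replace(
        paper_cfg,
        n_vegetative=1,
        scan=ScanConfig(step_nm=100.0, dwell_ms=200.0, field_shape=(96, 200)),
        margin_px=18,
    )


@pytest.fixture(scope="session")
def paper_truth(paper_cfg):
    return generate_filament(paper_cfg, seed=11)


@pytest.fixture(scope="session")
def count_maps(paper_truth, det):
    return noisy_concentration_maps(paper_truth, det, seed=13)


@pytest.fixture(scope="session")
def count_seg(count_maps):
    return segment_maps(count_maps)


@pytest.fixture(scope="session")
def spectral_maps(paper_truth, det):
    return spectral_concentration_maps(paper_truth, det, seed=12)


@pytest.fixture(scope="session")
def spectral_seg(spectral_maps):
    return segment_maps(spectral_maps)
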