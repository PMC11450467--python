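"""Shared containers for scan geometry, detector response, maps and cubes.

Units are fixed throughout the package: energies in keV, pixel pitch in nm,
dwell (live) time in ms, areal concentrations in µg/cm², areas in µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linecatalog import LineCatalog, default_catalog


@dataclass(frozen=True)
class ScanConfig:
    """Raster-scan geometry: pixel pitch, dwell time, field size.

    The instrument this emulates scans at 500 nm (coarse), 300 nm
    (intermediate) or 100 nm (high-resolution) pitch with 100–200 ms dwell.
    """

    step_nm: float
    dwell_ms: float
    field_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.dwell_ms <= 0:
            raise ValueError("dwell_ms must be positive")
        r, c = self.field_shape
        if r < 1 or c < 1:
            raise ValueError("field_shape must be at least 1×1")

    @property
    def pixel_area_um2(self) -> float:
        """Pixel area in µm²: (step_nm/1000)²."""
        return (self.step_nm / 1000.0) ** 2


@dataclass(frozen=True)
class DetectorModel:
    """Energy-dispersive detector response and per-element sensitivity.

    The line shape is an exponentially modified Gaussian with shared width
    ``resolution_eV`` (Gaussian σ) and tail constant ``tail_tau_eV`` for all
    lines.  ``flux_scale`` converts areal concentration to expected Kα peak
    area: counts = conc[µg/cm²] · sensitivity(Z) · dwell[ms], where
    sensitivity(Z) = flux_scale · exp(sens_slope · (Z − 19)) — a smooth,
    strictly monotone (hence injective) function of atomic number standing in
    for the empirically calibrated fluorescence yield / detection efficiency
    product.
    """

    incident_keV: float = 10.0
    bin_width_eV: float = 20.0
    resolution_eV: float = 65.0
    tail_tau_eV: float = 50.0
    #: (amplitude counts/ms/bin at 0 keV, exponential decay constant keV)
    continuum_params: tuple[float, float] = (0.02, 4.0)
    flux_scale: float = 5.0
    sens_slope: float = 0.05
    catalog: LineCatalog = field(default_factory=default_catalog)

    def __post_init__(self) -> None:
        if self.resolution_eV <= 0 or self.tail_tau_eV <= 0:
            raise ValueError("resolution_eV and tail_tau_eV must be positive")
        if self.bin_width_eV <= 0 or self.incident_keV <= 0:
            raise ValueError("bin_width_eV and incident_keV must be positive")

    @property
    def energy_axis(self) -> np.ndarray:
        """Bin centers in keV covering (0, incident_keV]."""
        w = self.bin_width_eV / 1000.0
        n = int(round(self.incident_keV / w))
        return (np.arange(n) + 0.5) * w

    def sensitivity(self, element: str) -> float:
        """Kα peak area per (µg/cm² · ms) for one element."""
        line = self.catalog[element]
        if line.ka_keV >= self.incident_keV:
            raise ValueError(
                f"{element} Kα at {line.ka_keV} keV is not excitable at "
                f"{self.incident_keV} keV incident energy"
            )
        return self.flux_scale * float(np.exp(self.sens_slope * (line.Z - 19)))

    def continuum(self, dwell_ms: float) -> np.ndarray:
        """Expected smooth continuum per bin (counts) for one dwell."""
        amp, decay = self.continuum_params
        return amp * dwell_ms * np.exp(-self.energy_axis / decay)


@dataclass
class ElementMap:
    """2D areal-concentration map (µg/cm²) of one element.

    Missing pixels (e.g. per-pixel fit failures) are stored as NaN; the
    boolean ``mask`` property marks them.
    """

    element: str
    values: np.ndarray
    step_nm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ElementMap values must be 2D")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("concentrations must be nonnegative or NaN")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel value is missing."""
        return ~np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_um2(self) -> float:
        return (self.step_nm / 1000.0) ** 2


@dataclass
class SpectrumCube:
    """Per-pixel energy-resolved counts: (rows, cols, bins)."""

    counts: np.ndarray
    energy_keV: np.ndarray
    step_nm: float
    dwell_ms: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.energy_keV = np.asarray(self.energy_keV, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("SpectrumCube counts must be 3D (rows, cols, bins)")
        if self.counts.shape[-1] != self.energy_keV.size:
            raise ValueError("energy axis length must match last counts axis")
        if np.any(np.diff(self.energy_keV) <= 0):
            raise ValueError("energy bins must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]
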