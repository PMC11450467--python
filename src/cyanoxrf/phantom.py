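"""Synthetic *Anabaena*-like filament phantoms with known elemental ground truth.

A phantom is a horizontal chain of elliptical vegetative cells with one round
heterocyst of equal area mid-filament, each wrapped in a thin Cl-bearing
envelope.  Vegetative cells carry 2–4 co-localized P/K clusters (none in the
heterocyst); a subset of these cores sits peripherally and is enclosed by a
larger Ca-rich disk, the rest associates with Fe.  Irregular Fe blobs occur
in both cell types, and occasional Ca-only disks in vegetative cells.
Cytosolic backgrounds, cluster concentrations and size distributions default
to the values reported for nitrogen-starved *Anabaena* sp. filaments
(``make_paper_preset``), so the registry emitted alongside the maps is a
usable ground truth for every downstream stage.

Two forward models turn a truth phantom into measurements: ``simulate_counts``
(per-element Poisson count maps) and ``simulate_spectra`` (full per-pixel
energy-dispersive spectra with continuum, EMG line shapes and Poisson noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import DetectorModel, ElementMap, ScanConfig, SpectrumCube
from .spectra import Spectrum, design_matrix


class GeometryError(ValueError):
    """Raised when cells or clusters cannot be placed in the field."""


# --------------------------------------------------------------------------
# size distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SizeDist:
    """Truncated-normal size distribution, moment-matched to its mean.

    ``mean``/``sd`` are the *realized* mean and the underlying Gaussian SD;
    the Gaussian location is solved so that the post-truncation expectation
    equals ``mean`` exactly.  (A naively truncated normal with a heavy lower
    tail would otherwise realize a mean well above the nominal one — for the
    small, broadly dispersed Fe blobs the inflation would exceed a factor of
    two.)  ``kind`` records whether values are equivalent diameters (µm) or
    areas (µm²).
    """

    mean: float
    sd: float
    lower: float
    upper: float
    kind: str = "diameter_um"  # or "area_um2"

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.mean <= 0:
            raise ValueError("mean and sd must be positive")
        if not (self.lower < self.mean < self.upper):
            raise ValueError("need lower < mean < upper for moment matching")

    def _loc(self) -> float:
        m, s, lo, hi = self.mean, self.sd, self.lower, self.upper

        def trunc_mean(mu: float) -> float:
            a, b = (lo - mu) / s, (hi - mu) / s
            return float(stats.truncnorm.mean(a, b, loc=mu, scale=s))

        return float(
            optimize.brentq(lambda mu: trunc_mean(mu) - m, m - 60 * s, m + 60 * s)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        mu = self._loc()
        a, b = (self.lower - mu) / self.sd, (self.upper - mu) / self.sd
        return stats.truncnorm.rvs(a, b, loc=mu, scale=self.sd, size=n, random_state=rng)


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSpec:
    """Geometry and cytosolic composition of one cell type."""

    kind: str  # "vegetative" | "heterocyst"
    axes_um: tuple[float, float]  # semi-axes (along filament, across)
    envelope_nm: float
    cytosol_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("vegetative", "heterocyst"):
            raise ValueError("kind must be vegetative or heterocyst")
        if self.envelope_nm < 0:
            raise ValueError("envelope_nm must be >= 0")
        if any(c < 0 for c in self.cytosol_conc.values()):
            raise ValueError("cytosol concentrations must be nonnegative")


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster family: counts per cell, sizes, composition, placement."""

    family: str  # PK_Ca | PK_Fe | Ca_only | Fe_only
    count_per_cell: tuple[int, int]
    size_dist: SizeDist
    conc_boost: dict[str, float]
    placement: str = "interior"  # interior | peripheral
    shape: str = "disk"  # disk | shell | irregular-blob
    cells: str = "vegetative"  # vegetative | both
    shell_area_factor: float = 1.8  # Ca disk area / PK core area (PK_Ca only)
    shell_conc: dict[str, float] = field(default_factory=dict)
    #: optional co-localized companion blob (e.g. the small Fe aggregate
    #: riding on a P/K core) with its own size distribution and composition
    satellite_size: SizeDist | None = None
    satellite_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.count_per_cell
        if lo < 0 or hi < lo:
            raise ValueError("count range must satisfy 0 <= lo <= hi")
        if self.family == "PK_Ca" and self.shell_area_factor <= 1.0:
            raise ValueError("Ca shell must be larger than its PK core")
        if any(b < 0 for b in self.conc_boost.values()):
            raise ValueError("concentration boosts must be nonnegative")


@dataclass(frozen=True)
class PhantomConfig:
    """Full phantom description: scan, cells, envelope, cluster families."""

    scan: ScanConfig
    n_vegetative: int
    vegetative: CellSpec
    heterocyst: CellSpec
    envelope_conc: dict[str, float]
    clusters: dict[str, ClusterSpec]
    cell_gap_px: int = 2
    margin_px: int = 20

    def __post_init__(self) -> None:
        if self.n_vegetative < 1:
            raise ValueError("need at least one vegetative cell")
        for fam in self.clusters:
            if fam.startswith("PK") and self.clusters[fam].cells != "vegetative":
                raise ValueError("P/K clusters are restricted to vegetative cells")

    def cluster_count_range(self, family: str, kind: str) -> tuple[int, int]:
        spec = self.clusters[family]
        if spec.cells == "vegetative" and kind == "heterocyst":
            return (0, 0)
        return spec.count_per_cell


def make_paper_preset(
    step_nm: float = 100.0, dwell_ms: float = 200.0
) -> PhantomConfig:
    """Configuration encoding the reported filament as ground truth.

    Cytosolic levels (µg/cm²): heterocyst K 0.452, Fe 0.095, Ca 0.073;
    vegetative K 0.277, Fe 0.027, Ca 0.029.  Ca-rich clusters at
    1.337 µg/cm² total Ca.  K/P cluster equivalent diameters 0.99 ± 0.48 µm,
    Fe blob areas 0.050 ± 0.095 µm², Ca-only disk areas 0.310 µm² mean;
    2–4 P/K clusters per vegetative cell, none in the heterocyst; Cl envelope
    345 nm thick.  Cytosolic S, Cl and P levels are not constrained by the
    study and are free choices at plausible trace levels.
    """
    px_um = step_nm / 1000.0
    px_area = px_um**2
    two_px_area = 2 * px_area
    two_px_diam = 2.0 * np.sqrt(two_px_area / np.pi)
    veg_cyto = {"K": 0.277, "Ca": 0.029, "Fe": 0.027, "P": 0.050, "S": 0.060, "Cl": 0.020}
    het_cyto = {"K": 0.452, "Ca": 0.073, "Fe": 0.095, "P": 0.050, "S": 0.060, "Cl": 0.020}
    pk_size = SizeDist(mean=0.99, sd=0.48, lower=max(two_px_diam, 0.16), upper=1.5)
    fe_size = SizeDist(
        mean=0.050, sd=0.095, lower=two_px_area, upper=0.45, kind="area_um2"
    )
    ca_total = 1.337
    clusters = {
        "PK_Ca": ClusterSpec(
            family="PK_Ca",
            count_per_cell=(1, 2),
            size_dist=pk_size,
            conc_boost={"K": 1.2, "P": 0.8},
            placement="peripheral",
            shape="disk",
            shell_area_factor=1.8,
            shell_conc={"Ca": ca_total - veg_cyto["Ca"]},
        ),
        "PK_Fe": ClusterSpec(
            family="PK_Fe",
            count_per_cell=(1, 2),
            size_dist=pk_size,
            conc_boost={"K": 1.2, "P": 0.8},
            placement="interior",
            shape="disk",
            # the associated Fe aggregate rides on the P/K core but has its
            # own (much smaller) size statistics
            satellite_size=fe_size,
            satellite_conc={"Fe": 0.45},
        ),
        "Ca_only": ClusterSpec(
            family="Ca_only",
            count_per_cell=(0, 1),
            size_dist=SizeDist(
                mean=0.310, sd=0.25, lower=two_px_area, upper=1.2, kind="area_um2"
            ),
            conc_boost={"Ca": ca_total - veg_cyto["Ca"]},
            placement="interior",
            shape="disk",
        ),
        "Fe_only": ClusterSpec(
            family="Fe_only",
            count_per_cell=(1, 2),
            size_dist=fe_size,
            conc_boost={"Fe": 0.45},
            placement="interior",
            shape="irregular-blob",
            cells="both",
        ),
    }
    n_veg = 6
    a_um, b_um = 3.0, 2.3
    a_px, b_px = a_um / px_um, b_um / px_um
    r_het = np.sqrt(a_px * b_px)
    width = 2 * 24 + n_veg * 2 * a_px + 2 * r_het + (n_veg + 1) * 2
    height = 2 * (b_px + 345.0 / step_nm) + 2 * 18
    scan = ScanConfig(
        step_nm=step_nm,
        dwell_ms=dwell_ms,
        field_shape=(int(np.ceil(height / 8) * 8), int(np.ceil(width / 8) * 8)),
    )
    return PhantomConfig(
        scan=scan,
        n_vegetative=n_veg,
        vegetative=CellSpec("vegetative", (a_um, b_um), 345.0, veg_cyto),
        heterocyst=CellSpec("heterocyst", (a_um, b_um), 345.0, het_cyto),
        envelope_conc={"Cl": 0.180},
        clusters=clusters,
        margin_px=24,
    )


# --------------------------------------------------------------------------
# truth containers
# --------------------------------------------------------------------------

@dataclass
class RegisteredCluster:
    """Ground-truth record of one painted cluster region."""

    cluster_id: int
    cell_id: int
    family: str
    role: str  # core | shell | blob | disk
    rows: np.ndarray
    cols: np.ndarray
    area_um2: float
    mean_conc: dict[str, float] = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return self.rows.size

    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


@dataclass
class PlacedCell:
    cell_id: int
    kind: str
    center: tuple[float, float]  # (row, col)
    axes_px: tuple[float, float]  # semi-axes (row, col); equal for heterocyst


@dataclass
class PhantomTruth:
    """Ground-truth maps, masks and cluster registry of one phantom."""

    config: PhantomConfig
    element_maps: dict[str, ElementMap]
    cytoplasm_mask: np.ndarray
    cell_label_map: np.ndarray
    cells: list[PlacedCell]
    clusters: list[RegisteredCluster]
    seed: int
    analytic_mass_ug: dict[str, float] = field(default_factory=dict)

    def registry_frame(self) -> pd.DataFrame:
        """Long-format registry: one row per cluster and element."""
        rows = []
        for cl in self.clusters:
            for el, conc in cl.mean_conc.items():
                rows.append(
                    {
                        "cluster_id": cl.cluster_id,
                        "cell_id": cl.cell_id,
                        "family": cl.family,
                        "role": cl.role,
                        "element": el,
                        "n_pixels": cl.n_pixels,
                        "area_um2": cl.area_um2,
                        "mean_conc": conc,
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_pixels(shape, center, radius) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[inside], cc[inside]


def _grow_blob(
    shape, center, n_px: int, rng: np.random.Generator, max_radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Eden-type random-walk aggregation: grow a connected irregular blob.

    Growth is confined to a disk of ``max_radius`` around the seed so the
    blob can never leave the exclusion zone reserved for it.
    """
    start = (int(round(center[0])), int(round(center[1])))
    blob = {start}
    frontier = {start}
    nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    while len(blob) < n_px:
        candidates = sorted(
            {
                (r + dr, c + dc)
                for (r, c) in frontier
                for dr, dc in nbrs
                if 0 <= r + dr < shape[0]
                and 0 <= c + dc < shape[1]
                and (r + dr - center[0]) ** 2 + (c + dc - center[1]) ** 2
                <= max_radius**2
            }
            - blob
        )
        if not candidates:
            break
        pick = candidates[rng.integers(len(candidates))]
        blob.add(pick)
        frontier.add(pick)
    arr = np.array(sorted(blob))
    return arr[:, 0], arr[:, 1]


def _feasible_center(
    cell: PlacedCell,
    r_out: float,
    placement: str,
    rng: np.random.Generator,
) -> tuple[float, float] | None:
    """Sample a cluster center whose outer disk stays inside the cell."""
    ar = cell.axes_px[0] - r_out - 1.0
    ac = cell.axes_px[1] - r_out - 1.0
    if ar <= 0.5 or ac <= 0.5:
        return None
    lo, hi = (0.60, 0.95) if placement == "peripheral" else (0.0, 0.85)
    f = np.sqrt(rng.uniform(lo**2, hi**2))
    theta = rng.uniform(0, 2 * np.pi)
    return (
        cell.center[0] + f * ar * np.sin(theta),
        cell.center[1] + f * ac * np.cos(theta),
    )


def generate_filament(config: PhantomConfig, seed: int) -> PhantomTruth:
    """Build one phantom: place cells, paint cytosol/envelope, place clusters.

    Deterministic given (config, seed).  Raises :class:`GeometryError` when
    the field cannot hold the requested filament or a cluster cannot be
    placed without overlap after exhausting retries.
    """
    rng = np.random.default_rng(seed)
    shape = config.scan.field_shape
    px_um = config.scan.step_nm / 1000.0
    px_area = px_um**2

    # --- cells along a horizontal filament, heterocyst mid-chain
    a_px = config.vegetative.axes_um[0] / px_um
    b_px = config.vegetative.axes_um[1] / px_um
    r_het = float(np.sqrt(a_px * b_px))  # circle of equal area
    n_cells = config.n_vegetative + 1
    het_index = n_cells // 2
    half_widths = [
        r_het if i == het_index else a_px for i in range(n_cells)
    ]
    gap = config.cell_gap_px
    row_c = shape[0] / 2.0
    env_px = config.vegetative.envelope_nm / config.scan.step_nm
    cells: list[PlacedCell] = []
    col = config.margin_px
    for i, w in enumerate(half_widths):
        col += w
        kind = "heterocyst" if i == het_index else "vegetative"
        axes = (r_het, r_het) if kind == "heterocyst" else (b_px, a_px)
        cells.append(PlacedCell(i + 1, kind, (row_c, col), axes))
        col += w + gap
    if col - gap + config.margin_px > shape[1]:
        raise GeometryError(
            f"filament needs {col - gap + config.margin_px:.0f} columns, "
            f"field has {shape[1]}"
        )
    if 2 * (max(b_px, r_het) + env_px) + 4 > shape[0]:
        raise GeometryError("field too short for the cell diameter")

    cell_label = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        m = _ellipse_mask(shape, cell.center, cell.axes_px)
        cell_label[m & (cell_label == 0)] = cell.cell_id
    cytoplasm = cell_label > 0
    envelope = np.zeros(shape, dtype=bool)
    for cell in cells:
        outer = _ellipse_mask(
            shape, cell.center, (cell.axes_px[0] + env_px, cell.axes_px[1] + env_px)
        )
        envelope |= outer
    envelope &= ~cytoplasm

    elements = sorted(
        set(config.vegetative.cytosol_conc)
        | set(config.heterocyst.cytosol_conc)
        | set(config.envelope_conc)
        | {el for cs in config.clusters.values() for el in cs.conc_boost}
        | {el for cs in config.clusters.values() for el in cs.shell_conc}
    )
    maps = {el: np.zeros(shape, dtype=float) for el in elements}
    mass = {el: 0.0 for el in elements}
    px_area_cm2 = (config.scan.step_nm * 1e-7) ** 2

    for cell in cells:
        spec = config.heterocyst if cell.kind == "heterocyst" else config.vegetative
        sel = cell_label == cell.cell_id
        n_sel = int(sel.sum())
        for el, conc in spec.cytosol_conc.items():
            maps[el][sel] += conc
            mass[el] += conc * n_sel * px_area_cm2  # µg/cm² × cm² = µg
    n_env = int(envelope.sum())
    for el, conc in config.envelope_conc.items():
        maps[el][envelope] += conc
        mass[el] += conc * n_env * px_area_cm2

    # --- clusters
    registry: list[RegisteredCluster] = []
    next_id = 1

    def _expected_outer_radius_px(cs: ClusterSpec) -> float:
        if cs.size_dist.kind == "diameter_um":
            r = (cs.size_dist.mean / 2.0) / px_um
        else:
            r = np.sqrt(cs.size_dist.mean / np.pi) / px_um
        if cs.family == "PK_Ca":
            r *= np.sqrt(cs.shell_area_factor)
        return r

    # within each cell, place the largest families first so the small ones
    # fill the gaps; clusters of different cells cannot collide (each lies
    # strictly inside its own cell), so exclusion lists are per cell
    family_order = sorted(
        config.clusters, key=lambda f: -_expected_outer_radius_px(config.clusters[f])
    )

    def place_region(cell, occupied, r_out, placement):
        for _ in range(200):
            ctr = _feasible_center(cell, r_out, placement, rng)
            if ctr is None:
                return None
            if all(
                (ctr[0] - orow) ** 2 + (ctr[1] - ocol) ** 2 >= (r_out + orad + 2.0) ** 2
                for orow, ocol, orad in occupied
            ):
                return ctr
        return None

    def place_cell_clusters(cell, counts):
        """One attempt to place all of a cell's clusters; None on failure."""
        occupied: list[tuple[float, float, float]] = []
        placed: list[tuple[ClusterSpec, tuple[float, float], float, float, int]] = []
        for family in family_order:
            cs = config.clusters[family]
            for _ in range(counts[family]):
                for _redraw in range(6):
                    size = float(cs.size_dist.sample(1, rng)[0])
                    if cs.size_dist.kind == "diameter_um":
                        core_r = (size / 2.0) / px_um
                    else:
                        core_r = np.sqrt(size / np.pi) / px_um
                    r_out = core_r
                    sat_px = 0
                    if cs.family == "PK_Ca":
                        r_out = core_r * np.sqrt(cs.shell_area_factor)
                    if cs.satellite_size is not None:
                        sat = float(cs.satellite_size.sample(1, rng)[0])
                        if cs.satellite_size.kind == "diameter_um":
                            sat_px = max(2, int(round(np.pi * (sat / 2 / px_um) ** 2)))
                        else:
                            sat_px = max(2, int(round(sat / px_area)))
                        r_out = max(r_out, np.sqrt(sat_px / np.pi) + 2.0)
                    if cs.shape == "irregular-blob":
                        n_px = max(2, int(round(size / px_area)))
                        core_r = float(n_px)  # reused as pixel count for blobs
                        r_out = np.sqrt(n_px / np.pi) + 2.0
                    ctr = place_region(cell, occupied, r_out, cs.placement)
                    if ctr is not None:
                        occupied.append((ctr[0], ctr[1], r_out))
                        placed.append((cs, ctr, core_r, r_out, sat_px))
                        break
                else:
                    return None
        return placed

    for cell in cells:
        counts = {
            family: (
                int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            )
            for family in family_order
            for lo, hi in [config.cluster_count_range(family, cell.kind)]
        }
        for _attempt in range(40):
            placed = place_cell_clusters(cell, counts)
            if placed is not None:
                break
        else:
            raise GeometryError(
                f"cannot place requested clusters in cell {cell.cell_id}"
            )
        for cs, ctr, core_r, r_out, sat_px in placed:
            if cs.shape == "irregular-blob":
                rr, cc = _grow_blob(shape, ctr, int(core_r), rng, max_radius=r_out)
            else:
                rr, cc = _disk_pixels(shape, ctr, core_r)
                if rr.size < 2:
                    rr, cc = _disk_pixels(shape, ctr, max(core_r, 0.85))
            for el, boost in cs.conc_boost.items():
                maps[el][rr, cc] += boost
                mass[el] += boost * rr.size * px_area_cm2
            role = "blob" if cs.shape == "irregular-blob" else (
                "core" if cs.family.startswith("PK") else "disk"
            )
            registry.append(
                RegisteredCluster(
                    cluster_id=next_id,
                    cell_id=cell.cell_id,
                    family=cs.family,
                    role=role,
                    rows=rr,
                    cols=cc,
                    area_um2=rr.size * px_area,
                )
            )
            next_id += 1
            if cs.family == "PK_Ca":
                srr, scc = _disk_pixels(shape, ctr, core_r * np.sqrt(cs.shell_area_factor))
                for el, boost in cs.shell_conc.items():
                    maps[el][srr, scc] += boost
                    mass[el] += boost * srr.size * px_area_cm2
                registry.append(
                    RegisteredCluster(
                        cluster_id=next_id,
                        cell_id=cell.cell_id,
                        family=cs.family,
                        role="shell",
                        rows=srr,
                        cols=scc,
                        area_um2=srr.size * px_area,
                    )
                )
                next_id += 1
            if sat_px:
                brr, bcc = _grow_blob(
                    shape, ctr, sat_px, rng, max_radius=r_out - 0.5
                )
                for el, boost in cs.satellite_conc.items():
                    maps[el][brr, bcc] += boost
                    mass[el] += boost * brr.size * px_area_cm2
                registry.append(
                    RegisteredCluster(
                        cluster_id=next_id,
                        cell_id=cell.cell_id,
                        family=cs.family,
                        role="satellite",
                        rows=brr,
                        cols=bcc,
                        area_um2=brr.size * px_area,
                    )
                )
                next_id += 1

    for cl in registry:
        cl.mean_conc = {el: float(maps[el][cl.rows, cl.cols].mean()) for el in elements}

    element_maps = {
        el: ElementMap(element=el, values=m, step_nm=config.scan.step_nm)
        for el, m in maps.items()
    }
    return PhantomTruth(
        config=config,
        element_maps=element_maps,
        cytoplasm_mask=cytoplasm,
        cell_label_map=cell_label,
        cells=cells,
        clusters=registry,
        seed=seed,
        analytic_mass_ug=mass,
    )


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------

def simulate_counts(
    truth: PhantomTruth,
    scan: ScanConfig | None = None,
    det: DetectorModel | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-element Poisson count maps: counts ~ Poisson(conc·sens·dwell)."""
    scan = scan or truth.config.scan
    det = det or DetectorModel()
    rng = np.random.default_rng(seed)
    out = {}
    for el, emap in truth.element_maps.items():
        conc = emap.values
        if (conc < 0).any():
            raise ValueError("negative concentration in truth map")
        lam = conc * det.sensitivity(el) * scan.dwell_ms
        out[el] = rng.poisson(lam)
    return out


def counts_to_concentration(
    counts: dict[str, np.ndarray],
    scan: ScanConfig,
    det: DetectorModel,
) -> dict[str, ElementMap]:
    """Invert the count forward model: conc = counts / (sens · dwell)."""
    return {
        el: ElementMap(
            element=el,
            values=np.asarray(c, dtype=float) / (det.sensitivity(el) * scan.dwell_ms),
            step_nm=scan.step_nm,
        )
        for el, c in counts.items()
    }


def simulate_spectra(
    truth: PhantomTruth,
    scan: ScanConfig | None = None,
    det: DetectorModel | None = None,
    seed: int = 0,
    noise: bool = True,
    row_block: int = 32,
) -> SpectrumCube:
    """Full spectral forward model: continuum + EMG K-lines + Poisson noise.

    Expected per-pixel spectrum is continuum(dwell) + Σ_el area_el·profile_el
    with area_el = conc·sensitivity·dwell and the same unit-area Kα+Kβ
    profiles the fitting stage uses.  Deterministic given seed; with
    ``noise=False`` the noiseless expectation is returned.
    """
    scan = scan or truth.config.scan
    det = det or DetectorModel()
    elements = sorted(truth.element_maps)
    for el in elements:
        if det.catalog[el].ka_keV >= det.incident_keV:
            raise ValueError(f"{el} has no excitable K line below "
                             f"{det.incident_keV} keV")
    energy = det.energy_axis
    A = design_matrix(
        energy, elements, det.catalog,
        det.resolution_eV / 1000.0, det.tail_tau_eV / 1000.0,
    ).astype(np.float32)  # (bins, nel)
    cont = det.continuum(scan.dwell_ms).astype(np.float32)
    rows, cols = truth.cytoplasm_mask.shape
    conc_stack = np.stack(
        [truth.element_maps[el].values for el in elements], axis=-1
    )  # (rows, cols, nel)
    sens = np.array([det.sensitivity(el) for el in elements])
    areas = (conc_stack * sens * scan.dwell_ms).astype(np.float32)
    rng = np.random.default_rng(seed)
    out = np.empty((rows, cols, energy.size), dtype=np.float32)
    for r0 in range(0, rows, row_block):
        r1 = min(r0 + row_block, rows)
        lam = areas[r0:r1].reshape(-1, len(elements)) @ A.T + cont
        if noise:
            block = rng.poisson(lam.astype(np.float64)).astype(np.float32)
        else:
            block = lam
        out[r0:r1] = block.reshape(r1 - r0, cols, energy.size)
    return SpectrumCube(
        counts=out, energy_keV=energy, step_nm=scan.step_nm, dwell_ms=scan.dwell_ms
    )


def simulate_standard_spectrum(
    densities: dict[str, float],
    det: DetectorModel,
    live_time_ms: float = 1000.0,
    seed: int = 0,
    noise: bool = True,
) -> Spectrum:
    """Forward-simulate the measured spectrum of a thin-film standard."""
    energy = det.energy_axis
    elements = sorted(densities)
    A = design_matrix(
        energy, elements, det.catalog,
        det.resolution_eV / 1000.0, det.tail_tau_eV / 1000.0,
    )
    areas = np.array(
        [densities[el] * det.sensitivity(el) * live_time_ms for el in elements]
    )
    lam = A @ areas + det.continuum(live_time_ms)
    counts = np.random.default_rng(seed).poisson(lam).astype(float) if noise else lam
    return Spectrum(energy_keV=energy, counts=counts, live_time_ms=live_time_ms)


def default_standard_densities() -> dict[str, float]:
    """Synthetic thin-film standard densities (µg/cm²).

    Stand-in for a certified multi-element reference foil; the real
    standard's composition is a required user input in any real analysis.
    """
    return {"S": 0.8, "Ca": 1.9, "Fe": 0.5, "Cu": 0.3}
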