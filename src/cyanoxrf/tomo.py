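"""Parallel-beam fluorescence tomography: projection and SIRT reconstruction.

The acquisition this emulates rotates the specimen over an angular range
that falls short of 180° (51 projections from −82° to +70°, a missing
wedge), collecting one translation line per projection per scan row.  Each
scan row is therefore an independent 2-D reconstruction problem, and a
volume is a stack of per-row SIRT slices.

The projector is a pixel-driven linear operator with bilinear detector
interpolation, materialized as a sparse matrix so the back projector is its
exact transpose — SIRT's convergence argument assumes an adjoint pair, and
the adjoint identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds here to machine precision.

SIRT iterates  x ← x + C·Aᵀ·R·(b − A·x)  with R and C the inverse row/column
sums of A (zero rows/columns are masked, never divided by), optionally
clamping x at zero after each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass(frozen=True)
class ProjectorConfig:
    """Acquisition geometry: projection angles and detector sampling."""

    angles_deg: np.ndarray = field(
        default_factory=lambda: np.linspace(-82.0, 70.0, 51)
    )
    detector_bins: int = 64
    step_nm: float = 100.0
    image_px: int | None = None  # square slice side; defaults to detector_bins

    def __post_init__(self) -> None:
        ang = np.asarray(self.angles_deg, dtype=float)
        object.__setattr__(self, "angles_deg", ang)
        if ang.ndim != 1 or ang.size < 2:
            raise ValueError("need at least two projection angles")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.detector_bins < 2:
            raise ValueError("detector_bins must be >= 2")

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @property
    def n_px(self) -> int:
        return self.image_px or self.detector_bins

    @property
    def missing_wedge_deg(self) -> float:
        """Angular coverage shortfall relative to a full 180° scan."""
        return 180.0 - float(self.angles_deg[-1] - self.angles_deg[0])


def paper_wedge_config(detector_bins: int = 64, step_nm: float = 100.0) -> ProjectorConfig:
    """51 equally spaced projections from −82° to 70° (3.04° spacing)."""
    return ProjectorConfig(
        angles_deg=np.linspace(-82.0, 70.0, 51),
        detector_bins=detector_bins,
        step_nm=step_nm,
    )


def system_matrix(config: ProjectorConfig) -> sparse.csr_matrix:
    """Sparse projector A: (n_angles·detector_bins) × (n_px²).

    Pixel-driven: each pixel center projects to detector coordinate
    t = x·cosθ + y·sinθ and deposits its value into the two neighbouring
    bins with linear weights.  Weights per pixel sum to 1 whenever the
    projection lands inside the detector, which yields per-angle mass
    conservation.
    """
    n = config.n_px
    bins = config.detector_bins
    half = (n - 1) / 2.0
    ys, xs = np.mgrid[0:n, 0:n]
    x = (xs - half).ravel()
    y = (ys - half).ravel()
    pix = np.arange(n * n)
    rows_all, cols_all, vals_all = [], [], []
    for k, ang in enumerate(np.deg2rad(config.angles_deg)):
        t = x * np.cos(ang) + y * np.sin(ang) + (bins - 1) / 2.0
        i0 = np.floor(t).astype(int)
        w1 = t - i0
        for i_bin, w in ((i0, 1.0 - w1), (i0 + 1, w1)):
            ok = (i_bin >= 0) & (i_bin < bins) & (w > 0)
            rows_all.append(k * bins + i_bin[ok])
            cols_all.append(pix[ok])
            vals_all.append(w[ok])
    A = sparse.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(config.n_angles * bins, n * n),
    )
    return A.tocsr()


@dataclass
class SinogramSet:
    """Projection data of one element: (angles × detector bins)."""

    element: str
    projections: np.ndarray
    config: ProjectorConfig

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        expected = (self.config.n_angles, self.config.detector_bins)
        if self.projections.shape != expected:
            raise ValueError(
                f"sinogram shape {self.projections.shape} != geometry {expected}"
            )


@dataclass
class ReconSlice:
    """One reconstructed slice with its iteration diagnostics."""

    element: str
    values: np.ndarray
    n_iter: int
    residuals: np.ndarray  # ‖b − Ax‖₂ after each iteration


def forward_project(
    slice2d: np.ndarray,
    config: ProjectorConfig,
    element: str = "",
    A: sparse.csr_matrix | None = None,
) -> SinogramSet:
    """Line integrals of a square slice over the configured angles."""
    slice2d = np.asarray(slice2d, dtype=float)
    n = config.n_px
    if slice2d.shape != (n, n):
        raise ValueError(f"slice must be {n}×{n} for this geometry")
    if A is None:
        A = system_matrix(config)
    sino = (A @ slice2d.ravel()).reshape(config.n_angles, config.detector_bins)
    return SinogramSet(element=element, projections=sino, config=config)


def sirt_reconstruct(
    sino: SinogramSet,
    n_iter: int = 100,
    nonneg: bool = True,
    A: sparse.csr_matrix | None = None,
) -> ReconSlice:
    """SIRT reconstruction of one slice from its sinogram."""
    b = sino.projections.ravel()
    if not np.all(np.isfinite(b)):
        raise ValueError("sinogram contains non-finite values")
    config = sino.config
    if A is None:
        A = system_matrix(config)
    row_sum = np.asarray(A.sum(axis=1)).ravel()
    col_sum = np.asarray(A.sum(axis=0)).ravel()
    R = np.where(row_sum > 0, 1.0 / np.where(row_sum > 0, row_sum, 1.0), 0.0)
    C = np.where(col_sum > 0, 1.0 / np.where(col_sum > 0, col_sum, 1.0), 0.0)
    n = config.n_px
    x = np.zeros(n * n)
    residuals = np.empty(n_iter)
    for it in range(n_iter):
        r = b - A @ x
        x = x + C * (A.T @ (R * r))
        if nonneg:
            np.maximum(x, 0.0, out=x)
        residuals[it] = np.linalg.norm(b - A @ x)
    return ReconSlice(
        element=sino.element,
        values=x.reshape(n, n),
        n_iter=n_iter,
        residuals=residuals,
    )


def reconstruct_volume(
    sinograms: list[SinogramSet],
    n_iter: int = 100,
    nonneg: bool = True,
) -> np.ndarray:
    """Stack per-scan-row SIRT slices into a volume (rows × n_px × n_px).

    All sinograms must share one geometry (the system matrix is built once).
    """
    if not sinograms:
        raise ValueError("no sinograms supplied")
    cfg0 = sinograms[0].config
    for s in sinograms[1:]:
        if not np.array_equal(s.config.angles_deg, cfg0.angles_deg) or (
            s.config.detector_bins != cfg0.detector_bins
            or s.config.n_px != cfg0.n_px
        ):
            raise ValueError("inconsistent projection geometries in volume")
    A = system_matrix(cfg0)
    return np.stack(
        [sirt_reconstruct(s, n_iter=n_iter, nonneg=nonneg, A=A).values for s in sinograms]
    )


def project_volume(
    volume: np.ndarray, config: ProjectorConfig, element: str = ""
) -> list[SinogramSet]:
    """Forward-project every slice of a volume (independent scan rows)."""
    A = system_matrix(config)
    return [
        forward_project(sl, config, element=element, A=A) for sl in np.asarray(volume)
    ]
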