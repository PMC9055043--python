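"""ALPS-index measurement: slice selection, ROI rasterisation and the
diffusivity ratio.

The ALPS (Analysis aLong the Perivascular Space) index quantifies water
diffusivity along the perivascular direction at the body of the lateral
ventricle.  Two 5-mm discs are placed on a single axial slice -- one in
the projection-fibre area, one in the association-fibre area of the
left hemisphere -- and six ROI-mean diffusivities are read off the Dx,
Dy and Dz maps.  The index is

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

The denominator deliberately uses only Dyproj and Dzassoc: in each
fibre population it is the diffusivity perpendicular to both the fibre
and the perivascular direction.  Dyassoc and Dzproj (parallel to the
fibres) are retained in the measurement record for audit but excluded
from the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tensor import ScalarMaps

__all__ = [
    "ROISpec",
    "ALPSMeasurement",
    "select_slice",
    "rasterise_roi",
    "extract_measurement",
    "compute_alps_index",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """A circular in-plane ROI on one axial slice.

    ``centre_mm`` is (x, y) in millimetres within the slice; voxel
    centres sit at (index + 0.5) * voxel_size.
    """

    slice_index: int
    centre_mm: tuple[float, float]
    diameter_mm: float = 5.0
    target: str = "projection"  # or "association"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.target not in ("projection", "association"):
            raise ValueError(f"unknown target fibre {self.target!r}")


@dataclass(frozen=True)
class ALPSMeasurement:
    """The six ROI-mean diffusivities and the derived index."""

    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dy_assoc: float
    dz_proj: float
    dz_assoc: float
    n_voxels_proj: int
    n_voxels_assoc: int
    rater: str = "rater1"

    def __post_init__(self) -> None:
        six = (self.dx_proj, self.dx_assoc, self.dy_proj,
               self.dy_assoc, self.dz_proj, self.dz_assoc)
        if any(v <= 0 for v in six):
            raise ValueError("all six ROI-mean diffusivities must be positive")
        if self.n_voxels_proj < 1 or self.n_voxels_assoc < 1:
            raise ValueError("each ROI must contain at least one voxel")

    @property
    def alps_index(self) -> float:
        return compute_alps_index(self)


def select_slice(
    maps: ScalarMaps | None = None,
    config_index: int | None = None,
) -> int:
    """Return the axial slice on which to measure.

    Phantom-derived maps carry their declared ALPS slice and it is used
    directly; otherwise the manually chosen ``config_index`` is required
    (slice selection on real data is an operator decision, not
    automated here).
    """
    if maps is not None and maps.alps_slice is not None:
        logger.info("using phantom-declared ALPS slice %d", maps.alps_slice)
        return int(maps.alps_slice)
    if config_index is not None:
        logger.info("using manually configured ALPS slice %d", config_index)
        return int(config_index)
    raise ValueError(
        "no ALPS slice available: supply a manual slice index for non-phantom data"
    )


def rasterise_roi(
    roi: ROISpec, voxel_size: float, grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean voxel mask of the ROI disc on its slice.

    A voxel belongs to the ROI iff its centre lies within
    ``diameter_mm / 2`` of the ROI centre (centre-in-disc membership;
    no partial-volume weighting).
    """
    nx, ny, nz = grid_shape
    if not (0 <= roi.slice_index < nz):
        raise ValueError(f"slice {roi.slice_index} outside volume (nz={nz})")
    cx, cy = roi.centre_mm
    if not (0 <= cx <= nx * voxel_size and 0 <= cy <= ny * voxel_size):
        raise ValueError(f"ROI centre {roi.centre_mm} outside image bounds")
    if roi.hemisphere == "left" and cx > nx * voxel_size / 2.0:
        raise ValueError(
            f"ROI centre x={cx:.1f} mm lies outside the left hemisphere "
            f"(midline at {nx * voxel_size / 2.0:.1f} mm)"
        )
    xc = (np.arange(nx) + 0.5) * voxel_size
    yc = (np.arange(ny) + 0.5) * voxel_size
    dist2 = (xc[:, None] - cx) ** 2 + (yc[None, :] - cy) ** 2
    disc = dist2 <= (roi.diameter_mm / 2.0) ** 2
    if not disc.any():
        raise ValueError(
            "ROI mask is empty: check the centre coordinates and diameter "
            f"(centre {roi.centre_mm} mm, diameter {roi.diameter_mm} mm, "
            f"voxel {voxel_size} mm)"
        )
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :, roi.slice_index] = disc
    return mask


def extract_measurement(
    dx: np.ndarray,
    dy: np.ndarray,
    dz: np.ndarray,
    proj_mask: np.ndarray,
    assoc_mask: np.ndarray,
    rater: str = "rater1",
) -> ALPSMeasurement:
    """ROI-mean Dx/Dy/Dz in the projection and association discs.

    All six means are recorded even though the index uses only four.
    """
    if np.any(proj_mask & assoc_mask):
        raise ValueError("projection and association ROIs overlap")
    proj_slices = np.unique(np.nonzero(proj_mask)[2])
    assoc_slices = np.unique(np.nonzero(assoc_mask)[2])
    if not np.array_equal(proj_slices, assoc_slices):
        raise ValueError("both ROIs must lie on the same axial slice")
    return ALPSMeasurement(
        dx_proj=float(dx[proj_mask].mean()),
        dx_assoc=float(dx[assoc_mask].mean()),
        dy_proj=float(dy[proj_mask].mean()),
        dy_assoc=float(dy[assoc_mask].mean()),
        dz_proj=float(dz[proj_mask].mean()),
        dz_assoc=float(dz[assoc_mask].mean()),
        n_voxels_proj=int(proj_mask.sum()),
        n_voxels_assoc=int(assoc_mask.sum()),
        rater=rater,
    )


def compute_alps_index(m: ALPSMeasurement) -> float:
    """mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)."""
    num = 0.5 * (m.dx_proj + m.dx_assoc)
    den = 0.5 * (m.dy_proj + m.dz_assoc)
    if den <= 0:
        raise ValueError("non-positive denominator diffusivities")
    return num / den


def measurement_row(subject_id: str, m: ALPSMeasurement) -> dict:
    """Flat record for the per-subject output CSV."""
    return {
        "subject_id": subject_id,
        "rater": m.rater,
        "Dxproj": m.dx_proj,
        "Dxassoc": m.dx_assoc,
        "Dyproj": m.dy_proj,
        "Dyassoc": m.dy_assoc,
        "Dzproj": m.dz_proj,
        "Dzassoc": m.dz_assoc,
        "n_voxels_proj": m.n_voxels_proj,
        "n_voxels_assoc": m.n_voxels_assoc,
        "alps_index": m.alps_index,
    }
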