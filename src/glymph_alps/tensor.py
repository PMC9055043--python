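"""Per-voxel diffusion tensor fitting and derived scalar maps.

The fit is the classical log-linear least-squares estimator on ln(S)
with the design row (1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy,
-2b gx gz, -2b gy gz); ``wls`` re-weights each observation by the
squared predicted signal for one iteration, which is the standard
variance-stabilising correction for log-transformed Rician magnitude
data.

Axis diffusivities Dx, Dy, Dz are the tensor's *diagonal elements* in
the scanner frame (the diffusivity along each laboratory axis), not
eigenvalue projections -- this is what the ALPS ROI semantics require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIVolume, GradientTable

__all__ = ["TensorMaps", "ScalarMaps", "fit_tensor", "eigen_scalars", "write_scalar_maps"]

logger = logging.getLogger(__name__)

# order of the six unique tensor elements throughout this module
ELEMENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

_EIGENVALUE_FLOOR = 1e-7  # mm^2/s, clamp for non-physical negative eigenvalues


@dataclass(frozen=True)
class TensorMaps:
    """Fitted tensor elements (..., 6) in ELEMENT_ORDER, fitted s0 and a
    validity mask (False where the b=0 signal was non-positive)."""

    elements: np.ndarray  # (nx, ny, nz, 6)
    s0: np.ndarray  # (nx, ny, nz)
    mask: np.ndarray  # (nx, ny, nz) bool
    voxel_size: float
    alps_slice: int | None = None

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (..., 3, 3) tensors."""
        e = self.elements
        t = np.empty(e.shape[:-1] + (3, 3))
        t[..., 0, 0] = e[..., 0]
        t[..., 1, 1] = e[..., 1]
        t[..., 2, 2] = e[..., 2]
        t[..., 0, 1] = t[..., 1, 0] = e[..., 3]
        t[..., 0, 2] = t[..., 2, 0] = e[..., 4]
        t[..., 1, 2] = t[..., 2, 1] = e[..., 5]
        return t


@dataclass(frozen=True)
class ScalarMaps:
    """Rotationally derived scalars plus the axis diffusivity maps."""

    fa: np.ndarray
    md: np.ndarray
    eigenvalues: np.ndarray  # (..., 3) sorted descending
    principal_eigenvector: np.ndarray  # (..., 3)
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    colour_fa: np.ndarray  # (..., 3) RGB in [0, 1]
    mask: np.ndarray
    voxel_size: float
    alps_slice: int | None = None
    n_clamped: int = 0


def design_matrix(gtab: GradientTable) -> np.ndarray:
    b = gtab.bvals
    gx, gy, gz = gtab.bvecs.T
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
        ]
    )


def fit_tensor(dwi: DWIVolume, method: str = "wls") -> TensorMaps:
    """Fit the diffusion tensor voxel-wise.

    Parameters
    ----------
    dwi
        4-D signal with its gradient table; needs >= 6 unique non-zero
        directions and >= 1 b=0 volume (enforced by the table itself).
    method
        ``"lls"`` for plain log-linear least squares, ``"wls"`` (default)
        for one re-weighting iteration with weights equal to the squared
        predicted signal.
    """
    if method not in ("lls", "wls"):
        raise ValueError(f"unknown fit method {method!r}")
    X = design_matrix(dwi.gtab)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient design: the gradient table "
            f"(n={dwi.gtab.n_volumes}, unique directions insufficient) "
            "cannot determine all six tensor elements"
        )
    shape = dwi.data.shape[:3]
    signals = dwi.data.reshape(-1, dwi.gtab.n_volumes).astype(float)

    b0_mean = signals[:, dwi.gtab.b0_mask].mean(axis=1)
    mask = b0_mean > 0

    # log of non-positive signals: clamp to the smallest positive value
    positive = signals[signals > 0]
    floor = positive.min() if positive.size else 1.0
    n_clamped = int(np.sum(signals <= 0))
    if n_clamped:
        logger.info("clamped %d non-positive signals before log", n_clamped)
    y = np.log(np.maximum(signals, floor))

    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T  # (nvox, 7)

    if method == "wls":
        # weights: squared predicted signal from the LLS pass, one iteration
        w = np.exp(2.0 * (beta @ X.T))  # (nvox, nvol)
        Xw = w[:, :, None] * X[None, :, :]  # (nvox, nvol, 7)
        lhs = np.einsum("vnp,nq->vpq", Xw, X)  # X^T W X
        rhs = np.einsum("vnp,vn->vp", Xw, y)  # X^T W y
        beta = np.linalg.solve(lhs, rhs[..., None])[..., 0]

    s0 = np.exp(beta[:, 0]).reshape(shape)
    elements = beta[:, 1:].reshape(shape + (6,))
    return TensorMaps(
        elements=elements,
        s0=s0,
        mask=mask.reshape(shape),
        voxel_size=dwi.voxel_size,
        alps_slice=dwi.alps_slice,
    )


def eigen_scalars(tm: TensorMaps) -> ScalarMaps:
    """Eigen-decompose the fitted tensors and derive FA, MD, colour-FA
    and the axis diffusivity maps.

    Negative eigenvalues (noise artefacts) are clamped to 1e-7 mm^2/s
    before the FA computation; the number of clamped values is logged
    and reported on the result.
    """
    t = tm.as_matrices()
    flat = t.reshape(-1, 3, 3)
    evals, evecs = np.linalg.eigh(flat)  # ascending
    evals = evals[:, ::-1]  # descending: l1 >= l2 >= l3
    evecs = evecs[:, :, ::-1]

    n_clamped = int(np.sum(evals < 0))
    if n_clamped:
        logger.info("clamped %d negative eigenvalues to %g", n_clamped, _EIGENVALUE_FLOOR)
    evals = np.maximum(evals, _EIGENVALUE_FLOOR)

    mean_ev = evals.mean(axis=1, keepdims=True)
    num = np.sqrt(((evals - mean_ev) ** 2).sum(axis=1))
    den = np.sqrt((evals**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    v1 = evecs[:, :, 0]
    colour = fa[:, None] * np.abs(v1)

    shape = tm.elements.shape[:-1]
    return ScalarMaps(
        fa=fa.reshape(shape),
        md=mean_ev.ravel().reshape(shape),
        eigenvalues=evals.reshape(shape + (3,)),
        principal_eigenvector=v1.reshape(shape + (3,)),
        dx=tm.elements[..., 0].copy(),
        dy=tm.elements[..., 1].copy(),
        dz=tm.elements[..., 2].copy(),
        colour_fa=np.clip(colour, 0.0, 1.0).reshape(shape + (3,)),
        mask=tm.mask,
        voxel_size=tm.voxel_size,
        alps_slice=tm.alps_slice,
        n_clamped=n_clamped,
    )


def write_scalar_maps(sm: ScalarMaps, out_dir: str | Path, stem: str = "dti") -> dict[str, Path]:
    """Write scalar maps as NIfTI with FSL DTIFIT-style suffixes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = sm.voxel_size

    volumes = {
        "FA": sm.fa,
        "MD": sm.md,
        "L1": sm.eigenvalues[..., 0],
        "L2": sm.eigenvalues[..., 1],
        "L3": sm.eigenvalues[..., 2],
        "V1": sm.principal_eigenvector,
        "Dx": sm.dx,
        "Dy": sm.dy,
        "Dz": sm.dz,
        "colourFA": sm.colour_fa,
    }
    paths: dict[str, Path] = {}
    for suffix, arr in volumes.items():
        p = out_dir / f"{stem}_{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff), p)
        paths[suffix] = p
    return paths


def read_axis_maps(
    dx_path: str | Path, dy_path: str | Path, dz_path: str | Path
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    imgs = [nib.load(str(p)) for p in (dx_path, dy_path, dz_path)]
    voxel = float(imgs[0].header.get_zooms()[0])
    dx, dy, dz = (np.asarray(i.dataobj, dtype=float) for i in imgs)
    return dx, dy, dz, voxel
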