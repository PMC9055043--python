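"""Synthetic periventricular diffusion-MRI phantom.

The phantom emulates the axial slab around the body of the lateral
ventricle where the ALPS index is measured: projection fibres running
head--foot (z), association fibres running anterior--posterior (y),
subcortical fibres running right--left (x), the ventricle itself (free
water) and a low-diffusivity background.  Perivascular flow along the
medullary veins is modelled as a non-negative additive diffusivity
excess on the Dxx tensor element (``pvs_weight``) inside the projection
and association regions only -- the PVS runs along x, perpendicular to
both fibre populations.

Coordinates follow the RAS convention: x = right--left, y =
anterior--posterior, z = inferior--superior.  All diffusivities are in
mm^2/s; b-values in s/mm^2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "RegionBox",
    "PhantomSpec",
    "TensorField",
    "DWIVolume",
    "make_gradient_table",
    "build_phantom",
    "simulate_signal",
    "default_phantom_spec",
    "write_dwi",
    "read_dwi",
    "write_tensor_field",
]

# free water at body temperature, the conventional ventricle value
VENTRICLE_DIFFUSIVITY = 3.0e-3
BACKGROUND_DIFFUSIVITY = 0.8e-3

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class GradientTable:
    """Diffusion-sensitising scheme: one b-value and unit direction per volume.

    b=0 entries carry a zero direction vector.  Written to disk in the
    FSL dialect (``bvals`` one row, ``bvecs`` three rows).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"shape mismatch: {bvals.size} b-values vs bvecs {bvecs.shape}"
            )
        nonzero = bvals > 0
        if not np.any(~nonzero):
            raise ValueError("gradient table needs at least one b=0 volume")
        norms = np.linalg.norm(bvecs[nonzero], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero b-vectors must be unit length")
        ndirs = np.unique(np.round(bvecs[nonzero], 6), axis=0).shape[0]
        if ndirs < 6:
            raise ValueError(
                f"only {ndirs} unique diffusion directions; "
                "at least 6 required for a tensor fit"
            )

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def to_files(self, bvals_path: str | Path, bvecs_path: str | Path) -> None:
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def from_files(
        cls, bvals_path: str | Path, bvecs_path: str | Path
    ) -> "GradientTable":
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        elif bvecs.shape == (3, 3):
            # ambiguous 3x3: FSL convention is one row per component
            bvecs = bvecs.T
        return cls(bvals=bvals, bvecs=bvecs)


def make_gradient_table(
    n_directions: int = 30, bvalue: float = 1000.0, n_b0: int = 1
) -> GradientTable:
    """Deterministic gradient scheme: ``n_b0`` b=0 volumes followed by
    ``n_directions`` directions on a spherical Fibonacci spiral.

    The spiral gives a reproducible, nearly uniform angular coverage,
    standing in for the scanner vendor's (unpublished) 30-direction set.
    """
    if n_directions < 6:
        raise ValueError(
            f"n_directions={n_directions} under-determines the tensor (need >= 6)"
        )
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    # hemisphere only: g and -g probe the same diffusion axis, so a
    # full-sphere spiral would waste directions on antipodal duplicates
    i = np.arange(n_directions)
    z = (i + 0.5) / n_directions
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


@dataclass(frozen=True)
class RegionBox:
    """Half-open axis-aligned voxel box [x0,x1) x [y0,y1) x [z0,z1)."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    def overlaps(self, other: "RegionBox") -> bool:
        def hit(a: tuple[int, int], b: tuple[int, int]) -> bool:
            return a[0] < b[1] and b[0] < a[1]

        return hit(self.x, other.x) and hit(self.y, other.y) and hit(self.z, other.z)


REGION_LABELS = {
    "background": 0,
    "ventricle": 1,
    "projection": 2,
    "association": 3,
    "subcortical": 4,
}

# principal diffusion axis of each fibre population (column index of Dxx/Dyy/Dzz)
_PRINCIPAL_AXIS = {"projection": 2, "association": 1, "subcortical": 0}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and diffusion parameters of the periventricular slab."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: float = 2.0
    regions: dict[str, RegionBox] = field(default_factory=dict)
    # (parallel, radial, radial) eigenvalues per fibre region, mm^2/s
    fibre_eigenvalues: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "projection": (1.7e-3, 0.3e-3, 0.3e-3),
            "association": (1.7e-3, 0.3e-3, 0.3e-3),
            "subcortical": (1.7e-3, 0.3e-3, 0.3e-3),
        }
    )
    ventricle_diffusivity: float = VENTRICLE_DIFFUSIVITY
    background_diffusivity: float = BACKGROUND_DIFFUSIVITY
    pvs_weight: float = 0.0
    s0: float = 1000.0
    noise_sigma: float = 25.0  # s0/40 unless overridden
    seed: int = 0
    alps_slice: int = 8  # axial slice on which the ALPS ROIs live

    def __post_init__(self) -> None:
        if not self.regions:
            object.__setattr__(self, "regions", _default_regions(self.grid_shape))
        if self.pvs_weight < 0:
            raise ValueError("pvs_weight must be non-negative")
        for name, (lpar, lr1, lr2) in self.fibre_eigenvalues.items():
            if min(lpar, lr1, lr2) <= 0:
                raise ValueError(f"non-positive eigenvalue in region {name!r}")
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.regions[a].overlaps(self.regions[b]):
                    raise ValueError(f"region boxes {a!r} and {b!r} overlap")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


def _default_regions(grid_shape: tuple[int, int, int]) -> dict[str, RegionBox]:
    nx, ny, nz = grid_shape
    # everything in the left hemisphere (x below the midline), ordered
    # medial->lateral: ventricle, projection, association, subcortical
    y = (ny // 5, ny - ny // 5)
    z = (nz // 8, nz - nz // 8)
    w = max(nx // 8, 2)
    return {
        "ventricle": RegionBox((1, 1 + w), y, z),
        "projection": RegionBox((1 + w, 1 + 2 * w), y, z),
        "association": RegionBox((1 + 2 * w, 1 + 3 * w), y, z),
        "subcortical": RegionBox((1 + 3 * w, 1 + 4 * w), y, z),
    }


def default_phantom_spec(**overrides) -> PhantomSpec:
    """The 32x32x16, 2-mm isotropic phantom used throughout the tests."""
    return PhantomSpec(**overrides)


@dataclass(frozen=True)
class TensorField:
    """Ground-truth per-voxel diffusion tensors plus region labels."""

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    labels: np.ndarray  # (nx, ny, nz) int, values of REGION_LABELS
    voxel_size: float
    alps_slice: int | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def is_positive_definite(self) -> bool:
        eigvals = np.linalg.eigvalsh(self.tensors.reshape(-1, 3, 3))
        return bool(np.all(eigvals > 0))


def build_phantom(spec: PhantomSpec) -> TensorField:
    """Assemble the ground-truth tensor field from a :class:`PhantomSpec`.

    Fibre tensors are axis-aligned diagonal: the parallel eigenvalue sits
    on the region's principal axis, the radial eigenvalues on the other
    two.  ``pvs_weight`` is added to Dxx in projection and association
    regions only.
    """
    nx, ny, nz = spec.grid_shape
    tensors = np.zeros((nx, ny, nz, 3, 3))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    iso = np.eye(3) * spec.background_diffusivity
    tensors[...] = iso

    for name, box in spec.regions.items():
        sl = box.slices()
        labels[sl] = REGION_LABELS[name]
        if name == "ventricle":
            tensors[sl] = np.eye(3) * spec.ventricle_diffusivity
            continue
        lpar, lr1, lr2 = spec.fibre_eigenvalues[name]
        axis = _PRINCIPAL_AXIS[name]
        diag = [lr1, lr2]
        diag.insert(axis, lpar)
        d = np.diag(diag).astype(float)
        if name in ("projection", "association"):
            d[0, 0] += spec.pvs_weight
        tensors[sl] = d

    fld = TensorField(
        tensors=tensors,
        labels=labels,
        voxel_size=spec.voxel_size,
        alps_slice=spec.alps_slice,
    )
    if not fld.is_positive_definite():
        raise ValueError("phantom produced a non-positive-definite tensor")
    return fld


@dataclass(frozen=True)
class DWIVolume:
    """4-D diffusion-weighted signal with its gradient table."""

    data: np.ndarray  # (nx, ny, nz, n_volumes)
    gtab: GradientTable
    voxel_size: float
    alps_slice: int | None = None

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.gtab.n_volumes:
            raise ValueError(
                f"{self.data.shape[-1]} volumes but {self.gtab.n_volumes} gradient entries"
            )
        if np.any(self.data < 0):
            raise ValueError("DWI signal must be non-negative")


def simulate_signal(
    fld: TensorField,
    gtab: GradientTable,
    s0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DWIVolume:
    """Mono-exponential tensor signal S = s0 * exp(-b g^T D g), with
    optional Rician noise.

    Rician corruption uses the two-channel magnitude construction
    ``sqrt((S + e1)^2 + e2^2)`` with e1, e2 ~ N(0, noise_sigma^2); with
    ``noise_sigma=0`` the exact model signal is returned.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    bvecs = gtab.bvecs  # (n, 3)
    bvals = gtab.bvals  # (n,)
    # quadratic form per voxel/volume: einsum over tensor dims
    gdg = np.einsum("ni,xyzij,nj->xyzn", bvecs, fld.tensors, bvecs)
    signal = s0 * np.exp(-bvals[None, None, None, :] * gdg)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, noise_sigma, size=signal.shape)
        e2 = rng.normal(0.0, noise_sigma, size=signal.shape)
        signal = np.sqrt((signal + e1) ** 2 + e2**2)
    return DWIVolume(
        data=signal,
        gtab=gtab,
        voxel_size=fld.voxel_size,
        alps_slice=fld.alps_slice,
    )


# ---------------------------------------------------------------------------
# NIfTI / FSL-dialect I/O


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_dwi(dwi: DWIVolume, out_dir: str | Path, stem: str = "dwi") -> dict[str, Path]:
    """Write the 4-D signal as NIfTI-1 plus FSL-style bvals/bvecs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": out_dir / f"{stem}.nii.gz",
        "bvals": out_dir / f"{stem}.bvals",
        "bvecs": out_dir / f"{stem}.bvecs",
    }
    img = nib.Nifti1Image(dwi.data.astype(np.float32), _affine(dwi.voxel_size))
    img.header.set_zooms((dwi.voxel_size,) * 3 + (1.0,))
    nib.save(img, paths["dwi"])
    dwi.gtab.to_files(paths["bvals"], paths["bvecs"])
    return paths


def read_dwi(
    dwi_path: str | Path,
    bvals_path: str | Path,
    bvecs_path: str | Path,
    alps_slice: int | None = None,
) -> DWIVolume:
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = float(img.header.get_zooms()[0])
    gtab = GradientTable.from_files(bvals_path, bvecs_path)
    return DWIVolume(data=data, gtab=gtab, voxel_size=voxel_size, alps_slice=alps_slice)


def write_tensor_field(fld: TensorField, out_dir: str | Path, stem: str = "truth") -> dict[str, Path]:
    """Ground truth to disk: 6-volume tensor NIfTI (lower-triangular order
    Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) and an integer region-label NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = fld.tensors
    lower = np.stack(
        [
            t[..., 0, 0],
            t[..., 0, 1],
            t[..., 1, 1],
            t[..., 0, 2],
            t[..., 1, 2],
            t[..., 2, 2],
        ],
        axis=-1,
    )
    paths = {
        "tensor": Path(out_dir) / f"{stem}_tensor.nii.gz",
        "labels": Path(out_dir) / f"{stem}_labels.nii.gz",
    }
    aff = _affine(fld.voxel_size)
    nib.save(nib.Nifti1Image(lower.astype(np.float32), aff), paths["tensor"])
    nib.save(nib.Nifti1Image(fld.labels.astype(np.int16), aff), paths["labels"])
    return paths
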