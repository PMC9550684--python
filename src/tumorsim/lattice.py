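"""Voxel lattice substrate: tissue labels, cell density, volume accounting, NIfTI I/O.

The simulation domain is a regular cubic lattice of voxels, each carrying a
tissue label and (inside the tumor) a cell density.  Clinical segmentations
arrive as NIfTI label volumes; synthetic phantoms are built directly.

Label coding (fixed): 0 = background, 1 = fat, 2 = fibroglandular,
3 = vessel, 4 = tumor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

BACKGROUND, FAT, FIBROGLANDULAR, VESSEL, TUMOR = 0, 1, 2, 3, 4
VALID_LABELS = frozenset({BACKGROUND, FAT, FIBROGLANDULAR, VESSEL, TUMOR})
LABEL_NAMES = {0: "background", 1: "fat", 2: "fibroglandular", 3: "vessel", 4: "tumor"}

#: native clinical resolution (mm); desk-scale default used by phantoms is 2.0
CLINICAL_VOXEL_SIDE_MM = 0.5
DEFAULT_VOXEL_SIDE_MM = 2.0


class LatticeError(ValueError):
    """Structural or label error in lattice construction."""


@dataclass
class TissueLattice:
    """Labeled 3D voxel grid.

    Parameters
    ----------
    labels : int ndarray, shape (nx, ny, nz)
        Per-voxel tissue class.
    voxel_side : float
        Cubic voxel edge length in mm.
    affine : (4, 4) ndarray
        Voxel-index -> physical-mm transform (NIfTI convention).
    anisotropic : bool
        Set when the source volume had anisotropic spacing and voxel_side
        is the geometric mean.
    """

    labels: np.ndarray
    voxel_side: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    anisotropic: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise LatticeError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LatticeError("labels must be an integer array")
        if self.voxel_side <= 0:
            raise LatticeError(f"voxel_side must be > 0, got {self.voxel_side}")
        unknown = set(np.unique(self.labels)) - VALID_LABELS
        if unknown:
            raise LatticeError(f"unknown label codes {sorted(unknown)}; valid: {sorted(VALID_LABELS)}")
        if self.affine is None:
            self.affine = np.diag([self.voxel_side] * 3 + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise LatticeError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_side ** 3

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == TUMOR

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.labels == VESSEL

    @property
    def body_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def tumor_voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels == TUMOR))

    def metadata(self) -> dict:
        counts = {LABEL_NAMES[k]: int(np.count_nonzero(self.labels == k)) for k in sorted(VALID_LABELS)}
        return {
            "shape": list(self.shape),
            "voxel_side_mm": self.voxel_side,
            "anisotropic": self.anisotropic,
            "label_counts": counts,
        }


@dataclass
class CellDensityField:
    """Tumor cell density on a lattice, as a fraction of carrying capacity.

    rho is normalized: rho_max is the per-voxel carrying capacity (default
    1.0, i.e. rho is an occupancy fraction).  rho_detect is the fraction of
    rho_max above which a voxel counts as imaging-detectable tumor.
    """

    rho: np.ndarray
    rho_max: float = 1.0
    rho_detect: float = 0.10

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho_max <= 0:
            raise LatticeError("rho_max must be > 0")
        if not (0.0 < self.rho_detect < 1.0):
            raise LatticeError("rho_detect must be in (0, 1)")
        if np.any(self.rho < 0) or np.any(self.rho > self.rho_max * (1 + 1e-12)):
            raise LatticeError("rho must lie in [0, rho_max]")

    def copy(self) -> "CellDensityField":
        return CellDensityField(self.rho.copy(), self.rho_max, self.rho_detect)


def build_lattice(labels_volume: np.ndarray, voxel_side: float,
                  affine: np.ndarray | None = None) -> TissueLattice:
    """Validate a label volume and wrap it as a :class:`TissueLattice`.

    Warns when the volume contains no tumor voxels (degenerate but legal).
    """
    lat = TissueLattice(np.asarray(labels_volume), voxel_side, affine)
    if lat.tumor_voxel_count() == 0:
        warnings.warn("lattice contains no tumor voxels", stacklevel=2)
    return lat


def tumor_volume(density: CellDensityField, lattice: TissueLattice) -> float:
    """Imaging-equivalent tumor volume in cm³.

    Counts voxels with rho >= rho_detect * rho_max and multiplies by the
    voxel volume.  Threshold counting stands in for the scan-derived
    segmentation volume the predictions are compared against.
    """
    if density.rho.shape != lattice.shape:
        raise LatticeError(
            f"density shape {density.rho.shape} != lattice shape {lattice.shape}")
    n = int(np.count_nonzero(density.rho >= density.rho_detect * density.rho_max))
    return n * lattice.voxel_volume_mm3 / 1000.0  # mm³ -> cm³


def read_mask_nifti(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read a NIfTI label volume -> (labels, voxel_side_mm, affine).

    Anisotropic spacing is accepted with a warning; voxel_side is then the
    geometric mean of the three spacings.  Float-valued data are rejected.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        raise LatticeError(f"mask NIfTI must hold integer data, got {data.dtype}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.allclose(zooms, zooms[0], rtol=1e-6):
        voxel_side = float(zooms[0])
    else:
        voxel_side = float(np.prod(zooms) ** (1.0 / 3.0))
        warnings.warn(
            f"anisotropic spacing {tuple(zooms)}; using geometric mean {voxel_side:.4g} mm",
            stacklevel=2)
    return data.astype(np.int16), voxel_side, np.asarray(img.affine)


def write_mask_nifti(lattice: TissueLattice, path, sidecar: bool = True) -> None:
    """Write a lattice as an int16 NIfTI volume (+ JSON metadata sidecar)."""
    img = nib.Nifti1Image(lattice.labels.astype(np.int16), lattice.affine)
    img.header.set_zooms((lattice.voxel_side,) * 3)
    nib.save(img, str(path))
    if sidecar:
        p = str(path)
        for suf in (".nii.gz", ".nii"):
            if p.endswith(suf):
                p = p[: -len(suf)]
                break
        with open(p + ".json", "w") as fh:
            json.dump(lattice.metadata(), fh, indent=1)
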