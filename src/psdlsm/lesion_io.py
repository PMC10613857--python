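"""Lesion mask I/O, the lesion design matrix, and overlap/volume summaries.

Binary lesion masks live on a shared voxel grid (all masks entering one
analysis must agree on shape and affine).  The analysis design matrix keeps
one column per voxel that is lesioned in at least ``min_overlap`` patients
-- the minimum lesion threshold that guarantees enough lesion coverage for
a voxel-wise statistic to be meaningful.  Voxel coordinates are 0-based
array indices throughout; world coordinates exist only through the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class LesionMask:
    """One patient's binary 3D lesion grid with geometry.

    Parameters
    ----------
    grid:
        3D array of {0, 1} (stored as ``uint8``).
    affine:
        4x4 voxel-to-world transform.
    voxel_size_mm:
        Edge lengths of one voxel in mm, derived from the affine on read.
    patient_id:
        Identifier used in error messages and output tables.
    """

    grid: np.ndarray
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(
                f"lesion mask for patient {self.patient_id!r} must be 3D, "
                f"got {self.grid.ndim}D"
            )
        vals = np.unique(self.grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(
                f"lesion mask for patient {self.patient_id!r} contains values "
                f"outside {{0, 1}}: {vals[:5]}"
            )
        self.grid = self.grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def n_lesioned(self) -> int:
        return int(self.grid.sum())

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class LesionMatrix:
    """Patients x analyzed-voxels binary design with voxel bookkeeping.

    ``data[i, j]`` is the lesion status of patient ``i`` at the voxel whose
    grid coordinate is ``voxel_index[j]``; columns are ordered
    lexicographically by (x, y, z).  ``overlap_counts[j]`` is the number of
    patients lesioned at that voxel (always >= the filter's ``min_overlap``),
    and ``lesion_volumes`` holds each patient's total lesion volume in cm^3
    (computed on the full grid, before voxel filtering).
    """

    data: np.ndarray
    voxel_index: np.ndarray
    overlap_counts: np.ndarray
    lesion_volumes: np.ndarray
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    min_overlap: int
    patient_ids: list[str] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-retained-voxel vector back onto the full 3D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} per-voxel values, got {values.shape}"
            )
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = values
        return out


def read_mask(path, patient_id: str = "") -> LesionMask:
    """Read a NIfTI lesion mask, binarizing values above 0.5.

    The 0.5 threshold tolerates probabilistic or interpolated masks;
    geometry (affine, voxel sizes) is preserved from the header.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel message passthrough
        raise OSError(f"could not read lesion mask {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"lesion mask {path!r} must be a 3D volume, got shape {data.shape}"
        )
    grid = (data > 0.5).astype(np.uint8)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(
        grid=grid,
        affine=np.asarray(img.affine),
        voxel_size_mm=zooms,
        patient_id=patient_id or str(path),
    )


def write_mask(mask_or_grid, path, affine: np.ndarray | None = None) -> None:
    """Write a LesionMask (or a bare 3D array + affine) as NIfTI."""
    if isinstance(mask_or_grid, LesionMask):
        grid, affine = mask_or_grid.grid, mask_or_grid.affine
    else:
        grid = np.asarray(mask_or_grid)
        if affine is None:
            affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def _check_shared_geometry(masks: list[LesionMask]) -> None:
    if not masks:
        raise ValueError("need at least one lesion mask")
    ref = masks[0]
    bad = [
        m.patient_id
        for m in masks
        if m.grid.shape != ref.grid.shape or not np.allclose(m.affine, ref.affine)
    ]
    if bad:
        raise ValueError(
            "lesion masks do not share grid shape/affine with "
            f"{ref.patient_id!r}: offending patients {bad}"
        )


def lesion_volume_cm3(mask: LesionMask) -> float:
    """Total lesion volume: lesioned-voxel count x voxel volume, in cm^3."""
    return mask.n_lesioned * mask.voxel_volume_mm3() / 1000.0


def overlap_map(masks: list[LesionMask]) -> np.ndarray:
    """Voxel-wise count of patients whose lesion covers each voxel."""
    _check_shared_geometry(masks)
    counts = np.zeros(masks[0].grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.grid
    return counts


def build_lesion_matrix(masks: list[LesionMask], min_overlap: int = 5) -> LesionMatrix:
    """Assemble the patients x voxels design, keeping sufficiently covered voxels.

    A voxel is retained iff it is lesioned in at least ``min_overlap``
    patients (five in the study design this package replicates).  Column
    order is lexicographic in (x, y, z) grid coordinates, which makes the
    matrix invariant to the order masks are supplied in (up to row
    permutation).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    _check_shared_geometry(masks)
    counts = overlap_map(masks)
    voxel_index = np.argwhere(counts >= min_overlap)  # lexicographic by construction
    data = np.empty((len(masks), len(voxel_index)), dtype=np.uint8)
    coords = tuple(voxel_index.T)
    for i, m in enumerate(masks):
        data[i] = m.grid[coords]
    ref = masks[0]
    volumes = np.array([lesion_volume_cm3(m) for m in masks])
    return LesionMatrix(
        data=data,
        voxel_index=voxel_index,
        overlap_counts=counts[coords],
        lesion_volumes=volumes,
        grid_shape=ref.grid.shape,
        affine=ref.affine,
        voxel_size_mm=ref.voxel_size_mm,
        min_overlap=min_overlap,
        patient_ids=[m.patient_id for m in masks],
    )
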