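"""Neuroimaging I/O: NIfTI volumes, FSL bval/bvec tables, TCK/TRK tractograms.

All streamline geometry in this package lives in world millimeters (RAS),
obtained from voxel indices through the NIfTI affine.  A world point ``p``
belongs to voxel ``floor(inv(affine) @ p)`` (half-open voxel cells); voxel
indices are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

__all__ = [
    "DWIFormatError",
    "DWIVolume",
    "GradientTable",
    "read_dwi",
    "read_tractogram",
    "write_scalar_map",
    "write_tractogram",
]

#: b-values below this (s/mm^2) are treated as b=0; scanners emit small
#: nonzero values for unweighted volumes.
B0_THRESHOLD = 50.0


class DWIFormatError(ValueError):
    """Raised when an on-disk DWI dataset is malformed or inconsistent."""


@dataclass
class GradientTable:
    """Per-volume diffusion weightings and gradient directions.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weighting per volume, s/mm^2.
    bvecs : (N, 3) array
        Unit gradient directions for diffusion-weighted volumes; the zero
        vector for b=0 volumes.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise DWIFormatError(f"bvecs must be (N, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise DWIFormatError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} directions"
            )
        b0 = self.bvals < self.b0_threshold
        if not b0.any():
            raise DWIFormatError("gradient table has no b=0 entry")
        # normalize weighted directions; zero out unweighted ones
        bvecs = self.bvecs.copy()
        bvecs[b0] = 0.0
        norms = np.linalg.norm(bvecs[~b0], axis=1)
        if np.any(norms < 1e-12):
            raise DWIFormatError("zero gradient direction on a b>0 volume")
        bvecs[~b0] /= norms[:, None]
        self.bvecs = bvecs
        if (~b0).sum() < 6 or not self._identifiable():
            raise DWIFormatError(
                "tensor not identifiable: need >=6 non-collinear b>0 directions"
            )

    def _identifiable(self) -> bool:
        from .dwi_model import design_matrix  # cycle-free at call time

        a = design_matrix(self)
        return np.linalg.matrix_rank(a) == 6

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DWIVolume:
    """4D diffusion-weighted image: shape (X, Y, Z, N) plus voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise DWIFormatError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise DWIFormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise DWIFormatError("affine is not invertible")
        if np.nanmin(self.data) < 0:
            raise DWIFormatError("negative signal intensities")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _load_bvecs(path: str | os.PathLike, n_volumes: int) -> np.ndarray:
    raw = np.loadtxt(path, dtype=float)
    if raw.ndim != 2:
        raw = np.atleast_2d(raw)
    # FSL dialect is 3 rows x N columns; accept N x 3 too and pick by shape
    if raw.shape[0] == 3 and raw.shape[1] != 3:
        vecs = raw.T
    elif raw.shape[1] == 3 and raw.shape[0] != 3:
        vecs = raw
    elif raw.shape == (3, 3):
        vecs = raw.T  # ambiguous; FSL convention wins
    else:
        raise DWIFormatError(f"bvec table has shape {raw.shape}, expected 3xN or Nx3")
    if len(vecs) != n_volumes:
        raise DWIFormatError(
            f"bvec table has {len(vecs)} directions but image has {n_volumes} volumes"
        )
    return vecs


def read_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> tuple[DWIVolume, GradientTable]:
    """Load a DWI series with its FSL-dialect gradient table.

    Returns the 4D volume and a :class:`GradientTable` whose length matches
    the number of volumes; b=0 entries get the zero direction vector.
    """
    img = nib.load(os.fspath(image_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DWIFormatError(f"expected a 4D image, got {data.ndim}D")
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    if len(bvals) != data.shape[3]:
        raise DWIFormatError(
            f"{len(bvals)} b-values but image has {data.shape[3]} volumes"
        )
    bvecs = _load_bvecs(bvec_path, data.shape[3])
    return DWIVolume(data, img.affine), GradientTable(bvals, bvecs)


def write_scalar_map(
    map_data: np.ndarray, affine: np.ndarray, path: str | os.PathLike
) -> None:
    """Write a 3D (or 4D multi-component) map as float32 NIfTI-1."""
    arr = np.asarray(map_data, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("scalar map contains non-finite values")
    nib.Nifti1Image(arr, np.asarray(affine, dtype=float)).to_filename(os.fspath(path))


def read_scalar_map(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(os.fspath(path))
    return np.asanyarray(img.dataobj, dtype=float), img.affine


def _trk_header(affine: np.ndarray, shape: tuple[int, int, int]) -> dict:
    from nibabel.streamlines.header import Field

    affine = np.asarray(affine, dtype=float)
    return {
        Field.VOXEL_TO_RASMM: affine,
        Field.VOXEL_SIZES: np.linalg.norm(affine[:3, :3], axis=0),
        Field.DIMENSIONS: np.asarray(shape, dtype=np.int16),
        Field.VOXEL_ORDER: "".join(nib.aff2axcodes(affine)),
    }


def write_tractogram(
    tractogram,
    path: str | os.PathLike,
    file_format: str | None = None,
) -> None:
    """Write a tractogram as TCK or TRK.

    Parameters
    ----------
    tractogram : ftactd.tracking.Tractogram
        Streamlines in world mm with the reference affine and grid shape.
    path : path
        Output filename; when ``file_format`` is None the extension decides.
    file_format : {"tck", "trk"}, optional

    TCK stores world-mm (RAS) coordinates directly; TRK is written with the
    reference header so readers can recover the same world coordinates.
    """
    path = os.fspath(path)
    if file_format is None:
        file_format = os.path.splitext(path)[1].lstrip(".").lower()
    points = [np.asarray(s.points, dtype=np.float32) for s in tractogram.streamlines]
    for pts in points:
        if not np.all(np.isfinite(pts)):
            raise ValueError("streamline contains non-finite points")
    nib_tg = _NibTractogram(points, affine_to_rasmm=np.eye(4))
    if file_format == "tck":
        TckFile(nib_tg).save(path)
    elif file_format == "trk":
        header = _trk_header(tractogram.affine, tractogram.shape)
        TrkFile(nib_tg, header=header).save(path)
    else:
        raise ValueError(f"unknown tractogram format {file_format!r}")


def read_tractogram(path: str | os.PathLike) -> list[np.ndarray]:
    """Read a TCK/TRK file; returns streamlines as float arrays in world mm."""
    tf = nib.streamlines.load(os.fspath(path))
    return [np.asarray(s, dtype=float) for s in tf.streamlines]
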