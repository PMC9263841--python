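"""File formats: NIfTI-1 volumes/masks/maps and the HDF5 connectome container.

Conventions: masks are read liberally (any nonzero voxel is a member) and
written strictly as uint8 {0, 1}; float maps use NaN as the no-data marker;
the connectome ships as a single hierarchical HDF5 file so one download is
one dataset.  All writes avoid HDF5 object timestamps so identical content
produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .core import (AcquisitionMatrix, BinaryMask, Connectome, NormconnError,
                   StatMap, VoxelGrid)

logger = logging.getLogger("normconn")

#: Version string written into every connectome container.
CONTAINER_FORMAT_VERSION = "normconn-connectome-1"


class FormatError(NormconnError):
    """A file is not in the expected format."""


class VersionError(FormatError):
    """A container was written by an incompatible format version."""


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _grid_from_image(img) -> VoxelGrid:
    affine = img.affine
    if affine is None:
        raise FormatError(f"{img.get_filename()}: NIfTI header has no affine")
    dims = img.shape[:3]
    return VoxelGrid(tuple(int(d) for d in dims), np.asarray(affine, dtype=float))


def read_nifti_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a 4-D NIfTI volume; returns (data, grid)."""
    img = nib.load(str(path))
    if len(img.shape) != 4:
        raise FormatError(f"{path}: expected a 4-D volume, found {len(img.shape)}-D")
    grid = _grid_from_image(img)
    return np.asarray(img.dataobj, dtype=float), grid


def read_nifti_mask(path) -> BinaryMask:
    """Read a 3-D NIfTI as a binary mask; nonzero voxels are members."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D mask, found {len(img.shape)}-D")
    grid = _grid_from_image(img)
    data = np.asarray(img.dataobj)
    return BinaryMask.from_dense(grid, data != 0)


def read_nifti_map(path, kind: str) -> StatMap:
    """Read a 3-D float NIfTI as a StatMap; NaN marks no-data.

    Contribution counts are not stored in NIfTI, so ``n_per_voxel`` is set
    to 1 at defined voxels (0 at no-data) unless a companion n-map is
    loaded separately.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D map, found {len(img.shape)}-D")
    grid = _grid_from_image(img)
    values = np.asarray(img.dataobj, dtype=float).ravel(order="F")
    n = np.where(np.isfinite(values), 1, 0).astype(np.int64)
    return StatMap(grid, values, kind, n)


def write_nifti_mask(mask: BinaryMask, path) -> None:
    """Write a mask as uint8 {0, 1}."""
    img = nib.Nifti1Image(mask.to_dense(dtype=np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def write_nifti_map(stat_map: StatMap, path) -> None:
    """Write a map as float32 with NaN at no-data voxels."""
    img = nib.Nifti1Image(stat_map.to_dense().astype(np.float32), stat_map.grid.affine)
    nib.save(img, str(path))


def write_nifti_nmap(stat_map: StatMap, path) -> None:
    """Write a map's per-voxel contribution counts as int32."""
    dense = stat_map.n_per_voxel.reshape(stat_map.grid.dims, order="F")
    img = nib.Nifti1Image(dense.astype(np.int32), stat_map.grid.affine)
    nib.save(img, str(path))


def write_nifti_volume(data: np.ndarray, grid: VoxelGrid, path) -> None:
    """Write a 4-D volume."""
    data = np.asarray(data)
    if data.ndim != 4 or data.shape[:3] != grid.dims:
        raise FormatError(f"expected 4-D data on grid {grid.dims}, got shape {data.shape}")
    nib.save(nib.Nifti1Image(data.astype(np.float32), grid.affine), str(path))


def acquisition_to_volume(acq: AcquisitionMatrix, fill: float = np.nan) -> np.ndarray:
    """Expand an acquisition matrix to a dense 4-D array (invalid voxels = fill)."""
    flat = np.full((acq.grid.voxel_count, acq.T), fill)
    flat[acq.voxel_indices] = acq.data
    return flat.reshape(acq.grid.dims + (acq.T,), order="F")


# ---------------------------------------------------------------------------
# Connectome container (HDF5)
# ---------------------------------------------------------------------------

def _create(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def save_connectome(conn: Connectome, path,
                    coverage: BinaryMask | None = None) -> None:
    """Write a connectome as a single hierarchical HDF5 container.

    Layout: root attrs ``format_version``, ``name``, datasets ``grid/dims``
    and ``grid/affine``; one group per acquisition under ``acquisitions/``
    (zero-padded positional names preserve order) holding ``id``,
    ``voxel_indices`` and ``data``; optionally a precomputed ``coverage``
    mask.
    """
    with h5py.File(str(path), "w", track_order=False) as f:
        f.attrs["format_version"] = CONTAINER_FORMAT_VERSION
        f.attrs["name"] = conn.name
        grid = f.create_group("grid")
        _create(grid, "dims", np.asarray(conn.grid.dims, dtype=np.int64))
        _create(grid, "affine", conn.grid.affine)
        acqs = f.create_group("acquisitions")
        for i, acq in enumerate(conn):
            g = acqs.create_group(f"{i:05d}")
            g.attrs["id"] = acq.acquisition_id
            _create(g, "voxel_indices", acq.voxel_indices)
            _create(g, "data", acq.data)
        if coverage is not None:
            _create(f, "coverage", coverage.members)
    logger.info("wrote connectome %s (%d acquisitions) to %s",
                conn.name, conn.n_acquisitions, path)


def load_connectome(path) -> tuple[Connectome, BinaryMask | None]:
    """Load a container written by :func:`save_connectome`.

    Returns ``(connectome, coverage_mask_or_None)``.  An unknown format
    version or a structurally incomplete file raises without returning a
    partial object.
    """
    path = Path(path)
    try:
        f = h5py.File(str(path), "r")
    except OSError as e:
        raise FormatError(f"{path}: not a readable HDF5 container ({e})") from None
    with f:
        version = f.attrs.get("format_version")
        if version != CONTAINER_FORMAT_VERSION:
            raise VersionError(
                f"{path}: container format {version!r} is not supported by this "
                f"version (expected {CONTAINER_FORMAT_VERSION!r})")
        try:
            dims = tuple(int(d) for d in f["grid/dims"][()])
            affine = np.asarray(f["grid/affine"][()], dtype=float)
            grid = VoxelGrid(dims, affine)
            acqs = []
            for key in sorted(f["acquisitions"]):
                g = f["acquisitions"][key]
                acqs.append(AcquisitionMatrix(
                    str(g.attrs["id"]), grid,
                    np.asarray(g["voxel_indices"][()]),
                    np.asarray(g["data"][()])))
            coverage = None
            if "coverage" in f:
                coverage = BinaryMask(grid, np.asarray(f["coverage"][()]))
            name = str(f.attrs.get("name", path.stem))
        except KeyError as e:
            raise FormatError(f"{path}: container is incomplete ({e})") from None
    return Connectome(grid, acqs, name=name), coverage


def export_acquisitions(conn: Connectome, directory) -> list[Path]:
    """One-matrix-per-file NIfTI export for interoperability."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for acq in conn:
        p = directory / f"{acq.acquisition_id}.nii.gz"
        write_nifti_volume(acquisition_to_volume(acq), acq.grid, p)
        paths.append(p)
    return paths


def sha256_of(path) -> str:
    """Hex digest of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
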