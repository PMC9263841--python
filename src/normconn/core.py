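"""Domain types and elementary statistics for normative-connectome analysis.

The objects here encode one fixed spatial contract: every mask, map and
voxel-by-time matrix lives on exactly one :class:`VoxelGrid`, and flat voxel
indices always use 0-based, x-fastest (Fortran-style over ``(x, y, z)``)
flattening.  Mixing grids is a hard error everywhere; no resampling is ever
performed, because the whole workflow operates in a single template space.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("normconn")

#: Element-wise tolerance (mm) when comparing grid affines for equality.
AFFINE_ATOL = 1e-4

#: |r| is clipped to 1 - R_CLIP_EPS before the Fisher transform in group maps,
#: so that numerically perfect correlations (e.g. a single-voxel seed with
#: itself) yield a large finite z instead of infinity.
R_CLIP_EPS = 1e-7


#: Relative peak-to-peak tolerance below which a timeseries is treated as
#: constant (no usable variance).  Catches rows that are constant up to
#: floating-point round-off, e.g. after I/O or reshaping.
CONSTANT_RTOL = 1e-12


def is_effectively_constant(x: np.ndarray, axis: int | None = None):
    """True where a series' spread is negligible relative to its magnitude."""
    x = np.asarray(x, dtype=float)
    ptp = x.max(axis=axis) - x.min(axis=axis)
    scale = np.maximum(np.abs(x).max(axis=axis), 1.0)
    return ptp <= CONSTANT_RTOL * scale


class NormconnError(Exception):
    """Base class for all errors raised by this package."""


class GridMismatchError(NormconnError):
    """Two objects that must share a voxel grid do not."""


class InvalidInputError(NormconnError, ValueError):
    """An input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Voxel grid and masks
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True, eq=False)
class VoxelGrid:
    """A shared 3-D sampling grid with a voxel-to-world affine (RAS+ mm).

    Parameters
    ----------
    dims
        ``(nx, ny, nz)`` voxel counts, each >= 1.
    affine
        4x4 matrix mapping voxel indices ``(i, j, k, 1)`` to world mm.
        Its upper-left 3x3 block must be invertible.
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise InvalidInputError(f"grid dims must be three integers >= 1, got {self.dims!r}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise InvalidInputError(f"affine must be 4x4, got shape {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise InvalidInputError("affine upper-left 3x3 block is singular")
        affine = affine.copy()
        affine.flags.writeable = False
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_count(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.dims == other.dims and bool(
            np.allclose(self.affine, other.affine, rtol=0.0, atol=AFFINE_ATOL)
        )

    def __ne__(self, other: object) -> bool:
        eq = self.__eq__(other)
        return NotImplemented if eq is NotImplemented else not eq

    __hash__ = None  # type: ignore[assignment]  # equality is tolerance-based

    def flat_index(self, i, j, k) -> np.ndarray:
        """Flat index of voxel ``(i, j, k)`` under x-fastest ordering."""
        nx, ny, _ = self.dims
        return np.asarray(i) + nx * (np.asarray(j) + ny * np.asarray(k))

    def unravel(self, flat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inverse of :meth:`flat_index`."""
        nx, ny, _ = self.dims
        flat = np.asarray(flat)
        return flat % nx, (flat // nx) % ny, flat // (nx * ny)


def require_same_grid(a: VoxelGrid, b: VoxelGrid, what: str = "objects") -> None:
    if a != b:
        raise GridMismatchError(f"{what} are defined on different voxel grids")


class BinaryMask:
    """A set of voxels on a grid, stored as sorted unique flat indices."""

    __slots__ = ("grid", "members")

    def __init__(self, grid: VoxelGrid, members: Iterable[int]):
        members = np.unique(np.asarray(list(members) if not isinstance(members, np.ndarray) else members, dtype=np.int64))
        if members.size and (members[0] < 0 or members[-1] >= grid.voxel_count):
            raise InvalidInputError("mask contains voxel indices outside the grid")
        members.flags.writeable = False
        self.grid = grid
        self.members = members

    @classmethod
    def from_dense(cls, grid: VoxelGrid, dense: np.ndarray) -> "BinaryMask":
        """Build from a 3-D array on the grid; nonzero voxels are members."""
        dense = np.asarray(dense)
        if dense.shape != grid.dims:
            raise InvalidInputError(f"dense array shape {dense.shape} != grid dims {grid.dims}")
        flat = dense.ravel(order="F")
        return cls(grid, np.flatnonzero(flat != 0))

    def to_dense(self, dtype=np.uint8) -> np.ndarray:
        """3-D {0,1} array on the grid (x-fastest flattening inverted)."""
        flat = np.zeros(self.grid.voxel_count, dtype=dtype)
        flat[self.members] = 1
        return flat.reshape(self.grid.dims, order="F")

    @property
    def cardinality(self) -> int:
        return int(self.members.size)

    def __len__(self) -> int:
        return self.cardinality

    def intersection(self, other: "BinaryMask") -> "BinaryMask":
        require_same_grid(self.grid, other.grid, "masks")
        return BinaryMask(self.grid, np.intersect1d(self.members, other.members, assume_unique=True))

    def union(self, other: "BinaryMask") -> "BinaryMask":
        require_same_grid(self.grid, other.grid, "masks")
        return BinaryMask(self.grid, np.union1d(self.members, other.members))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.grid == other.grid and np.array_equal(self.members, other.members)

    def __repr__(self) -> str:
        return f"BinaryMask(|X|={self.cardinality} on {self.grid.dims})"


# ---------------------------------------------------------------------------
# BOLD matrices and the connectome container
# ---------------------------------------------------------------------------

class AcquisitionMatrix:
    """One acquisition's BOLD timeseries, rows indexed into the grid.

    Rows that are non-finite or have zero sample variance are the voxels
    where a BOLD signal could not be calculated; they are excluded at
    construction so every stored row supports a Pearson correlation.

    Parameters
    ----------
    acquisition_id
        Unique identifier within a connectome.
    grid
        The shared spatial grid.
    voxel_indices
        Strictly increasing flat voxel indices, one per data row.
    data
        ``(len(voxel_indices), T)`` array of BOLD values (arbitrary units),
        with ``T >= 3`` volumes.
    """

    __slots__ = ("acquisition_id", "grid", "voxel_indices", "data")

    def __init__(self, acquisition_id: str, grid: VoxelGrid,
                 voxel_indices: np.ndarray, data: np.ndarray):
        voxel_indices = np.asarray(voxel_indices, dtype=np.int64)
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] != voxel_indices.size:
            raise InvalidInputError(
                f"data shape {data.shape} does not match {voxel_indices.size} voxel indices")
        if data.shape[1] < 3:
            raise InvalidInputError(f"need at least 3 volumes, got {data.shape[1]}")
        if voxel_indices.size == 0:
            raise InvalidInputError("acquisition has no voxels")
        if np.any(np.diff(voxel_indices) <= 0):
            raise InvalidInputError("voxel_indices must be strictly increasing")
        if voxel_indices[0] < 0 or voxel_indices[-1] >= grid.voxel_count:
            raise InvalidInputError("voxel index outside grid")
        valid = np.isfinite(data).all(axis=1) & ~is_effectively_constant(data, axis=1)
        if not valid.all():
            n_bad = int((~valid).sum())
            logger.debug("excluding %d invalid rows from acquisition %s", n_bad, acquisition_id)
            voxel_indices = voxel_indices[valid]
            data = data[valid]
            if voxel_indices.size == 0:
                raise InvalidInputError(
                    f"acquisition {acquisition_id!r}: no voxel has usable signal")
        voxel_indices.flags.writeable = False
        data.flags.writeable = False
        self.acquisition_id = str(acquisition_id)
        self.grid = grid
        self.voxel_indices = voxel_indices
        self.data = data

    @property
    def T(self) -> int:
        """Number of volumes in the timeseries."""
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.size

    def rows_for(self, mask: BinaryMask) -> np.ndarray:
        """Row positions of this acquisition's voxels that lie in ``mask``."""
        require_same_grid(self.grid, mask.grid, "acquisition and mask")
        return np.flatnonzero(np.isin(self.voxel_indices, mask.members, assume_unique=True))

    def __repr__(self) -> str:
        return (f"AcquisitionMatrix({self.acquisition_id!r}, "
                f"{self.n_voxels} voxels x {self.T} volumes)")


class Connectome:
    """An ordered collection of acquisitions on one grid.

    This is the distributable unit of a normative connectome: many subjects'
    voxel-by-time BOLD matrices collated into a single dataset, each with its
    own set of valid voxels.
    """

    __slots__ = ("grid", "acquisitions", "name")

    def __init__(self, grid: VoxelGrid, acquisitions: Sequence[AcquisitionMatrix],
                 name: str = "connectome"):
        acquisitions = list(acquisitions)
        if not acquisitions:
            raise InvalidInputError("a connectome needs at least one acquisition")
        ids = [a.acquisition_id for a in acquisitions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate acquisition ids: {dupes}")
        for a in acquisitions:
            require_same_grid(grid, a.grid, "connectome and acquisition")
        self.grid = grid
        self.acquisitions = acquisitions
        self.name = str(name)

    @property
    def n_acquisitions(self) -> int:
        return len(self.acquisitions)

    def __iter__(self):
        return iter(self.acquisitions)

    def __len__(self) -> int:
        return self.n_acquisitions

    def __repr__(self) -> str:
        return (f"Connectome({self.name!r}, {self.n_acquisitions} acquisitions "
                f"on {self.grid.dims})")


VALID_MAP_KINDS = ("mean_r", "z", "t", "p")


class StatMap:
    """Per-voxel scalar field with explicit no-data voxels.

    ``values`` holds one float per flat voxel index; NaN marks no-data.
    ``n_per_voxel`` records how many acquisitions contributed at each voxel
    and is 0 exactly at no-data voxels, so signal dropout is always
    distinguishable from a true zero statistic.
    """

    __slots__ = ("grid", "values", "kind", "n_per_voxel")

    def __init__(self, grid: VoxelGrid, values: np.ndarray, kind: str,
                 n_per_voxel: np.ndarray):
        if kind not in VALID_MAP_KINDS:
            raise InvalidInputError(f"kind must be one of {VALID_MAP_KINDS}, got {kind!r}")
        values = np.asarray(values, dtype=float)
        n_per_voxel = np.asarray(n_per_voxel, dtype=np.int64)
        if values.shape != (grid.voxel_count,) or n_per_voxel.shape != (grid.voxel_count,):
            raise InvalidInputError("values and n_per_voxel must be flat per-voxel arrays")
        defined = np.isfinite(values)
        if np.any(n_per_voxel[~defined] != 0):
            raise InvalidInputError("no-data voxels must have n_per_voxel = 0")
        if kind == "mean_r" and defined.any():
            v = values[defined]
            if v.min() < -1.0 - 1e-12 or v.max() > 1.0 + 1e-12:
                raise InvalidInputError("mean_r values must lie in [-1, 1]")
        if kind == "p" and defined.any():
            v = values[defined]
            if v.min() < 0.0 or v.max() > 1.0:
                raise InvalidInputError("p values must lie in [0, 1]")
        values = values.copy()
        values.flags.writeable = False
        n_per_voxel = n_per_voxel.copy()
        n_per_voxel.flags.writeable = False
        self.grid = grid
        self.values = values
        self.kind = kind
        self.n_per_voxel = n_per_voxel

    @property
    def defined(self) -> np.ndarray:
        """Boolean flat array: True where the map has data."""
        return np.isfinite(self.values)

    def to_dense(self) -> np.ndarray:
        """3-D float array on the grid with NaN at no-data voxels."""
        return self.values.reshape(self.grid.dims, order="F")

    def restrict(self, mask: BinaryMask) -> "StatMap":
        """Keep only voxels inside ``mask``; retained values are unchanged."""
        require_same_grid(self.grid, mask.grid, "map and mask")
        keep = np.zeros(self.grid.voxel_count, dtype=bool)
        keep[mask.members] = True
        values = np.where(keep, self.values, np.nan)
        n = np.where(keep, self.n_per_voxel, 0)
        return StatMap(self.grid, values, self.kind, n)

    def __repr__(self) -> str:
        return (f"StatMap(kind={self.kind!r}, {int(self.defined.sum())}/"
                f"{self.grid.voxel_count} voxels defined)")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation of two equal-length series.

    Both series must have length >= 3 and nonzero sample variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InvalidInputError("series must be 1-D and of equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples")
    if x.std() == 0.0 or y.std() == 0.0:
        raise InvalidInputError("zero-variance input to pearson_r")
    return float(_stats.pearsonr(x, y).statistic)


def fisher_z(r) -> float | np.ndarray:
    """Fisher variance-stabilizing transform z = arctanh(r), for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise InvalidInputError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def one_sample_t(values: Sequence[float]) -> tuple[float, int, float]:
    """One-sample t-test of the mean against 0.

    Returns ``(t, df, p_two_sided)`` with ``t = mean / (sd / sqrt(n))`` and
    ``df = n - 1``.  Requires n >= 2 and nonzero sample variance.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InvalidInputError("need at least 2 values")
    if values.std(ddof=1) == 0.0:
        raise InvalidInputError("zero sample variance in one_sample_t")
    res = _stats.ttest_1samp(values, popmean=0.0)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``.

    The rejection set is the largest k with ``p_(k) <= k * q / m`` and every
    smaller order statistic; of every 100 rejected hypotheses about ``100*q``
    are expected to be false positives.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1) | ~np.isfinite(pvalues)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise InvalidInputError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return np.asarray(reject, dtype=bool)
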