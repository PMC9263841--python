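"""Synthetic template-space rs-fMRI with planted correlated networks.

The generator emulates the structure of a normative connectome dataset:
many acquisitions on a shared grid, ~175 volumes each, spatially coherent
networks whose voxels share a latent signal, voxelwise signal dropout that
varies across acquisitions, and a DBS cohort whose clinical outcome is
linearly related to seed-ROI connectivity plus noise.

Model per acquisition: voxel v's series is

    sum_k  amplitude_k * s_k(t) * [v in mask_k]  +  eps_v(t)

where each s_k is an independent standard-normal latent series drawn fresh
per acquisition (normative aggregation is across subjects, not one shared
session) and eps_v is stationary AR(1) noise with parameter ``ar1_phi`` and
innovation standard deviation ``noise_sd``.  Overlapping network masks are
allowed; their signals add.  For phi = 0 and a single network of amplitude
``a`` the expected within-network correlation is a^2 / (a^2 + noise_sd^2);
in general the noise variance is noise_sd^2 / (1 - phi^2).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import (AcquisitionMatrix, BinaryMask, Connectome, InvalidInputError,
                   VoxelGrid, require_same_grid)

logger = logging.getLogger("normconn")


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """A planted network: a voxel mask sharing one latent signal.

    ``amplitude`` is the gain applied to the unit-variance latent series, in
    the same arbitrary units as the noise innovations.
    """

    mask: BinaryMask
    amplitude: float
    label: str = "network"

    def __post_init__(self) -> None:
        if self.mask.cardinality == 0:
            raise InvalidInputError(f"network {self.label!r}: mask is empty")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidInputError(f"network {self.label!r}: amplitude must be finite and >= 0")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated connectome.

    Defaults mirror the acquisition protocol the generator emulates:
    77 acquisitions of 175 volumes each.
    """

    grid: VoxelGrid
    T: int = 175
    n_acquisitions: int = 77
    networks: tuple[NetworkSpec, ...] = ()
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    dropout_masks: tuple[tuple[BinaryMask, float], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 3:
            raise InvalidInputError("need T >= 3 volumes")
        if self.n_acquisitions < 1:
            raise InvalidInputError("need at least one acquisition")
        if not self.noise_sd > 0:
            raise InvalidInputError("noise_sd must be > 0")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise InvalidInputError("ar1_phi must lie in [0, 1)")
        object.__setattr__(self, "networks", tuple(self.networks))
        object.__setattr__(self, "dropout_masks", tuple(self.dropout_masks))
        for spec in self.networks:
            require_same_grid(self.grid, spec.mask.grid, "config grid and network mask")
        for mask, p in self.dropout_masks:
            require_same_grid(self.grid, mask.grid, "config grid and dropout mask")
            if not 0.0 <= p <= 1.0:
                raise InvalidInputError("dropout probability must lie in [0, 1]")

    def noise_variance(self) -> float:
        """Stationary variance of the AR(1) noise, noise_sd^2 / (1 - phi^2)."""
        return self.noise_sd ** 2 / (1.0 - self.ar1_phi ** 2)


def amplitude_for_within_r(target_r: float, noise_sd: float = 1.0,
                           ar1_phi: float = 0.3) -> float:
    """Network amplitude giving expected within-network correlation ``target_r``.

    Inverts r = a^2 / (a^2 + sigma_eps^2) with sigma_eps^2 the stationary
    AR(1) noise variance.
    """
    if not 0.0 < target_r < 1.0:
        raise InvalidInputError("target_r must lie in (0, 1)")
    sigma2 = noise_sd ** 2 / (1.0 - ar1_phi ** 2)
    return float(np.sqrt(target_r / (1.0 - target_r) * sigma2))


def _acquisition_rng(rng_seed: int, index: int) -> np.random.Generator:
    # Seeding on (rng_seed, index) makes each acquisition reproducible on its
    # own and independent of the order acquisitions are generated in.
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed), int(index)]))


def _stationary_ar1(rng: np.random.Generator, n_series: int, T: int,
                    phi: float, innovation_sd: float) -> np.ndarray:
    """Exact stationary AR(1) sample paths, shape (n_series, T)."""
    eta = rng.standard_normal((n_series, T)) * innovation_sd
    if phi == 0.0:
        return eta
    eps = lfilter([1.0], [1.0, -phi], eta, axis=1)
    # Fold in a stationary initial state eps_{-1}: its contribution to eps_t
    # is phi^(t+1) * eps_{-1}, which makes every marginal exactly stationary.
    init = rng.standard_normal(n_series) * (innovation_sd / np.sqrt(1.0 - phi ** 2))
    eps += np.power(phi, np.arange(1, T + 1))[None, :] * init[:, None]
    return eps


def simulate_acquisition(config: SimulationConfig, index: int) -> AcquisitionMatrix:
    """Simulate acquisition ``index`` of the configured connectome.

    Fully reproducible from ``(config.rng_seed, index)``.  Voxels hit by a
    dropout mask are omitted from the acquisition's valid set with the
    stated per-acquisition probability.
    """
    if not 0 <= index < config.n_acquisitions:
        raise InvalidInputError(
            f"index {index} out of range for {config.n_acquisitions} acquisitions")
    rng = _acquisition_rng(config.rng_seed, index)
    grid = config.grid
    n_vox = grid.voxel_count

    # Draw in a fixed order (latents, dropout, noise) so outputs are stable.
    latents = rng.standard_normal((len(config.networks), config.T))

    dropped = np.zeros(n_vox, dtype=bool)
    for mask, p in config.dropout_masks:
        u = rng.random(mask.cardinality)
        dropped[mask.members[u < p]] = True
    keep = np.flatnonzero(~dropped)
    if keep.size == 0:
        raise InvalidInputError("dropout removed every voxel in this acquisition")

    data = _stationary_ar1(rng, keep.size, config.T, config.ar1_phi, config.noise_sd)
    if config.networks:
        pos_of = np.full(n_vox, -1, dtype=np.int64)
        pos_of[keep] = np.arange(keep.size)
        for spec, s in zip(config.networks, latents):
            rows = pos_of[spec.mask.members]
            rows = rows[rows >= 0]
            data[rows] += spec.amplitude * s[None, :]

    return AcquisitionMatrix(f"sim{index:03d}", grid, keep, data)


def simulate_connectome(config: SimulationConfig, name: str = "synthetic") -> Connectome:
    """Assemble ``config.n_acquisitions`` independent acquisitions."""
    acqs = [simulate_acquisition(config, i) for i in range(config.n_acquisitions)]
    return Connectome(config.grid, acqs, name=name)


# ---------------------------------------------------------------------------
# Canonical desk-scale configuration
# ---------------------------------------------------------------------------

def default_test_grid() -> VoxelGrid:
    """The 20 x 20 x 10 (4,000-voxel) desk-scale grid at 2 mm isotropic."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = (-20.0, -20.0, -10.0)
    return VoxelGrid((20, 20, 10), affine)


class PlantedScene(NamedTuple):
    """A default planted-network scene: config plus the ground-truth masks."""

    config: SimulationConfig
    network: BinaryMask
    seed: BinaryMask


def default_planted_scene(rng_seed: int = 0, within_r: float = 0.5,
                          dropout: Sequence[tuple[BinaryMask, float]] = (),
                          ) -> PlantedScene:
    """One 200-voxel planted network on the desk-scale grid.

    The network is a contiguous 5 x 8 x 5 block; the seed is a 10-voxel
    sub-block inside it.  The network amplitude is set so the expected
    within-network correlation equals ``within_r`` (default 0.5).
    """
    grid = default_test_grid()
    xs, ys, zs = np.meshgrid(np.arange(4, 9), np.arange(4, 12), np.arange(3, 8),
                             indexing="ij")
    network = BinaryMask(grid, grid.flat_index(xs.ravel(), ys.ravel(), zs.ravel()))
    sx, sy, sz = np.meshgrid(np.arange(4, 9), np.arange(6, 8), np.arange(5, 6),
                             indexing="ij")
    seed = BinaryMask(grid, grid.flat_index(sx.ravel(), sy.ravel(), sz.ravel()))
    assert seed.intersection(network) == seed
    amp = amplitude_for_within_r(within_r)
    config = SimulationConfig(
        grid=grid,
        networks=(NetworkSpec(network, amp, label="planted"),),
        dropout_masks=tuple(dropout),
        rng_seed=rng_seed,
    )
    return PlantedScene(config, network, seed)


# ---------------------------------------------------------------------------
# Synthetic VTA cohort
# ---------------------------------------------------------------------------

class VtaCohort(NamedTuple):
    """A simulated DBS cohort with known generative parameters."""

    records: list  # list[OutcomeRecord]
    truth: pd.DataFrame  # patient_id, connectivity (ground truth), outcome


def simulate_vta_cohort(connectome: Connectome, vta_masks: Sequence[BinaryMask],
                        roi_mask: BinaryMask, intercept: float, beta: float,
                        noise_sd: float, rng_seed: int,
                        connectivity: Sequence[float] | None = None) -> VtaCohort:
    """Outcomes linear in VTA-ROI connectivity plus Gaussian noise.

    ``outcome_i = intercept + beta * conn_i + N(0, noise_sd^2)`` where
    ``conn_i`` is the seed-map connectivity between patient i's VTA and the
    ROI on the given connectome.  The true connectivity values are returned
    alongside the outcomes as ground truth.

    ``connectivity`` may supply the ``vta_roi_connectivity`` values
    precomputed on the same connectome and masks (they are deterministic),
    to avoid recomputing every seed map when drawing many replicate cohorts.
    """
    from .vta_outcome import OutcomeRecord, vta_roi_connectivity

    if not vta_masks:
        raise InvalidInputError("need at least one VTA mask")
    for vta in vta_masks:
        if vta.cardinality == 0:
            raise InvalidInputError("VTA masks must be non-empty")
        require_same_grid(connectome.grid, vta.grid, "connectome and VTA mask")
    require_same_grid(connectome.grid, roi_mask.grid, "connectome and ROI mask")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0xC0F0]))
    if connectivity is None:
        conn = np.array([vta_roi_connectivity(connectome, vta, roi_mask)
                         for vta in vta_masks])
    else:
        conn = np.asarray(connectivity, dtype=float)
        if conn.shape != (len(vta_masks),):
            raise InvalidInputError("connectivity must have one value per VTA mask")
    outcomes = intercept + beta * conn + rng.standard_normal(conn.size) * noise_sd
    records = [OutcomeRecord(patient_id=f"pt{i:03d}", vta=vta, outcome=float(y))
               for i, (vta, y) in enumerate(zip(vta_masks, outcomes))]
    truth = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "connectivity": conn,
        "outcome": outcomes,
    })
    return VtaCohort(records, truth)


def default_vta_masks(grid: VoxelGrid, network: BinaryMask,
                      n_patients: int = 50) -> list[BinaryMask]:
    """2x2x2 VTA blocks sliding across the planted network's edge.

    Placement varies each patient's overlap with the network, so that
    VTA-network connectivity (hence the true predictor in the cohort model)
    varies across patients.
    """
    dense = network.to_dense().astype(bool)
    occupied = np.argwhere(dense)
    x0, y0, z0 = occupied.min(axis=0)
    x1, y1, z1 = occupied.max(axis=0)
    masks = []
    nx, ny, nz = grid.dims
    for i in range(n_patients):
        frac = i / max(n_patients - 1, 1)
        # slide from fully inside the network to fully outside along x
        cx = int(round(x0 + frac * (min(x1 + 4, nx - 2) - x0)))
        cy = (y0 + y1) // 2 + (i % 3) - 1
        cz = (z0 + z1) // 2 + ((i // 3) % 2)
        cx = int(np.clip(cx, 0, nx - 2))
        cy = int(np.clip(cy, 0, ny - 2))
        cz = int(np.clip(cz, 0, nz - 2))
        xs, ys, zs = np.meshgrid(np.arange(cx, cx + 2), np.arange(cy, cy + 2),
                                 np.arange(cz, cz + 2), indexing="ij")
        masks.append(BinaryMask(grid, grid.flat_index(xs.ravel(), ys.ravel(), zs.ravel())))
    return masks


def noise_sd_for_target_r(beta: float, connectivity: Sequence[float],
                          target_r: float) -> float:
    """Outcome noise giving population predicted-vs-actual correlation ``target_r``.

    Solves R^2 = beta^2 Var(conn) / (beta^2 Var(conn) + sigma^2) for sigma,
    using the sample variance of the supplied connectivity values.
    """
    if not 0.0 < target_r < 1.0:
        raise InvalidInputError("target_r must lie in (0, 1)")
    sd_conn = float(np.std(np.asarray(connectivity, dtype=float), ddof=1))
    if sd_conn == 0.0:
        raise InvalidInputError("connectivity values are constant")
    return abs(beta) * sd_conn * float(np.sqrt(1.0 / target_r ** 2 - 1.0))


def write_manifest(path, config: SimulationConfig, extra: dict | None = None) -> None:
    """Plain-text key-value ground-truth manifest for a simulation."""
    lines = [
        f"grid_dims = {config.grid.dims[0]} {config.grid.dims[1]} {config.grid.dims[2]}",
        f"T = {config.T}",
        f"n_acquisitions = {config.n_acquisitions}",
        f"noise_sd = {config.noise_sd!r}",
        f"ar1_phi = {config.ar1_phi!r}",
        f"rng_seed = {config.rng_seed}",
    ]
    for spec in config.networks:
        lines.append(f"network {spec.label} amplitude = {spec.amplitude!r} "
                     f"n_voxels = {spec.mask.cardinality}")
    for mask, p in config.dropout_masks:
        lines.append(f"dropout p = {p!r} n_voxels = {mask.cardinality}")
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
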