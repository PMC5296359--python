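"""Synthetic labeled 3D volumes of endocardial-like cells with ground truth.

Emulates the input the morphometry arm consumes: an integer label volume
(as produced by manual segmentation of a FIB-SEM stack) containing a
population of cells whose true shape descriptors are known.  Two phenotypes
are spanned by :class:`PhenotypeParams`: near-spherical, compact cells
(control endocardium) and elongated cells with capsule spikes (cells
adopting a migratory, mesenchymal shape under increased hemodynamic load).

Ground truth per cell is computed by brute force on a grid ``supersample``
times finer than the label grid: volume by fine-voxel counting, covariance
eigenvalues from fine-voxel centers, and surface area from an isosurface of
the fine binary mask.  Cells overlapping the volume boundary are truncated
on purpose (and their truth describes the truncated, face-capped solid),
mirroring real image volumes in which whole cells are rarely captured.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from ..morphometry import LabelVolume
from .shapes import (
    Capsule,
    Ellipsoid,
    ImplicitCell,
    ellipsoid_volume,
    random_rotation,
)

__all__ = ["PhenotypeParams", "CellTruth", "gen_label_volume", "truths_to_frame"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Shape-population parameters for one experimental group.

    ``axis_ratio`` is the ratio of largest to smallest semi-axis of the
    (prolate) ellipsoid body; 1 gives spheres.  Spikes are capsules of
    length drawn from an exponential with mean ``spike_length_mean`` and
    fixed ``spike_radius``, their count per cell Poisson-distributed.
    ``packing`` caps the expected occupied fraction of the grid.
    """

    axis_ratio_mean: float = 1.0
    axis_ratio_sd: float = 0.0
    spike_count_mean: float = 0.0
    spike_length_mean: float = 2.0  # µm
    spike_radius: float = 0.4  # µm
    cell_volume_mean: float = 150.0  # µm³
    cell_volume_sd: float = 30.0  # µm³
    packing: float = 0.3

    def __post_init__(self) -> None:
        if self.axis_ratio_mean < 1:
            raise ValueError("axis_ratio_mean must be >= 1")
        if min(self.spike_count_mean, self.spike_length_mean, self.spike_radius) < 0:
            raise ValueError("spike parameters must be non-negative")
        if self.cell_volume_mean <= 0 or self.cell_volume_sd < 0:
            raise ValueError("cell volumes must be positive")
        if not 0 < self.packing <= 1:
            raise ValueError("packing must lie in (0, 1]")


@dataclass(frozen=True)
class CellTruth:
    """Brute-force ground-truth descriptors for one generated cell."""

    cell_id: int
    volume: float  # fine-grid, µm³
    surface_area: float  # fine-grid isosurface, µm²
    sa_to_volume: float
    shape_factor: float
    eigenvalues: tuple[float, float, float]  # descending, µm²
    elongation_factor: float
    touches_boundary: bool
    overlap_fraction: float  # fraction of coarse voxels lost to earlier cells
    semi_axes: tuple[float, float, float]
    n_spikes: int
    center: tuple[float, float, float]
    volume_voxelized: float  # coarse-center count × voxel volume, µm³


def _voxel_centers(origin: np.ndarray, shape: tuple[int, ...], spacing: np.ndarray):
    axes = [origin[k] + (np.arange(shape[k]) + 0.5) * spacing[k] for k in range(3)]
    return axes


def _voxelize(cell: ImplicitCell, origin, shape, spacing, chunk: int = 8) -> np.ndarray:
    """Boolean voxelization of an implicit cell on a given grid (z slabs)."""
    az, ay, ax = _voxel_centers(np.asarray(origin, float), shape, np.asarray(spacing, float))
    out = np.empty(shape, dtype=bool)
    for z0 in range(0, shape[0], chunk):
        z1 = min(z0 + chunk, shape[0])
        Z, Y, X = np.meshgrid(az[z0:z1], ay, ax, indexing="ij")
        pts = np.stack([Z, Y, X], axis=-1).reshape(-1, 3)
        out[z0:z1] = cell.contains(pts).reshape(z1 - z0, len(ay), len(ax))
    return out


def _cell_truth(
    cell: ImplicitCell,
    extent: np.ndarray,
    spacing: np.ndarray,
    supersample: int,
    smoothing: float = 1.0,
) -> dict:
    """Fine-grid brute-force descriptors of the cell clipped to the volume."""
    h = spacing / supersample
    lo, hi = cell.bounds()
    clip_lo = np.maximum(lo - 2 * h, 0.0)
    clip_hi = np.minimum(hi + 2 * h, extent)
    # Snap the fine grid to the global lattice so volume faces fall exactly
    # on fine-voxel boundaries (clean caps for truncated cells).
    i_lo = np.floor(clip_lo / h).astype(int)
    i_hi = np.ceil(clip_hi / h).astype(int)
    shape = tuple(int(b - a) for a, b in zip(i_lo, i_hi))
    origin = i_lo * h
    mask = _voxelize(cell, origin, shape, h)

    n = int(mask.sum())
    fine_vol = float(np.prod(h))
    volume = n * fine_vol

    idx = np.argwhere(mask).astype(float)
    coords = origin + (idx + 0.5) * h
    cov = np.cov(coords.T, bias=True)
    cov -= np.diag(h * h) / 12.0
    eig = np.clip(np.linalg.eigvalsh(cov)[::-1], 0.0, None)

    pad = max(2, int(np.ceil(3 * smoothing)) + 1)
    field = gaussian_filter(np.pad(mask.astype(np.float32), pad), smoothing)
    verts, faces, _, _ = measure.marching_cubes(field, 0.5, spacing=tuple(h))
    sa = float(measure.mesh_surface_area(verts, faces))

    return {
        "volume": volume,
        "surface_area": sa,
        "sa_to_volume": sa / volume,
        "shape_factor": sa**3 / (36.0 * np.pi * volume**2),
        "eigenvalues": (float(eig[0]), float(eig[1]), float(eig[2])),
        "elongation_factor": float(eig[1] / eig[0]) if eig[0] > 0 else np.nan,
    }


def _sample_cell(params: PhenotypeParams, center: np.ndarray, rng: np.random.Generator) -> ImplicitCell:
    vol = max(rng.normal(params.cell_volume_mean, params.cell_volume_sd),
              0.2 * params.cell_volume_mean)
    ratio = max(rng.normal(params.axis_ratio_mean, params.axis_ratio_sd), 1.0)
    # Prolate body (a, b, b) with a/b = ratio and 4/3 π a b² = vol
    b = (3.0 * vol / (4.0 * np.pi * ratio)) ** (1.0 / 3.0)
    a = ratio * b
    rot = random_rotation(rng)
    body = Ellipsoid(center=center, semi_axes=np.array([a, b, b]), rotation=rot)

    n_spikes = int(rng.poisson(params.spike_count_mean)) if params.spike_count_mean > 0 else 0
    spikes = []
    for _ in range(n_spikes):
        direction = rng.normal(size=3)
        anchor, normal = body.surface_point_and_normal(direction)
        length = rng.exponential(params.spike_length_mean)
        # Inset the root slightly so the capsule is attached to the body.
        p0 = anchor - normal * params.spike_radius
        p1 = anchor + normal * length
        spikes.append(Capsule(p0=p0, p1=p1, radius=params.spike_radius))
    return ImplicitCell(body=body, spikes=tuple(spikes))


def gen_label_volume(
    params: PhenotypeParams,
    n_cells: int,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    seed: int,
    supersample: int = 8,
    max_tries: int = 50,
) -> tuple[LabelVolume, list[CellTruth]]:
    """Generate a labeled cell volume plus per-cell brute-force ground truth.

    Cells are placed sequentially with uniform random centers; the
    first-placed cell wins contested voxels, and a cell whose claimed
    volume falls below 50% of its intended voxelization is rejected and
    resampled (up to ``max_tries`` placements, after which the packing is
    declared infeasible).  Centers may fall near the volume faces, so some
    cells are truncated by the boundary on purpose.

    Returns the label volume and one :class:`CellTruth` per placed cell,
    computed on a ``supersample``-times finer grid from the implicit solid
    clipped to the volume bounds.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    spacing_arr = np.asarray(spacing, dtype=float)
    extent = np.asarray(grid_shape) * spacing_arr
    grid_volume = float(np.prod(extent))
    if n_cells * params.cell_volume_mean > params.packing * grid_volume:
        raise ValueError(
            f"infeasible packing: {n_cells} cells x {params.cell_volume_mean} µm³ "
            f"exceeds packing fraction {params.packing} of {grid_volume:.0f} µm³"
        )

    rng = np.random.default_rng(seed)
    labels = np.zeros(grid_shape, dtype=np.uint16)
    truths: list[CellTruth] = []

    for label in range(1, n_cells + 1):
        placed = False
        for _ in range(max_tries):
            center = rng.uniform(0.0, extent)
            cell = _sample_cell(params, center, rng)
            lo, hi = cell.bounds()
            i_lo = np.maximum(np.floor(lo / spacing_arr).astype(int), 0)
            i_hi = np.minimum(np.ceil(hi / spacing_arr).astype(int), grid_shape)
            if np.any(i_hi <= i_lo):
                continue
            region = tuple(slice(a, b) for a, b in zip(i_lo, i_hi))
            shape = tuple(int(b - a) for a, b in zip(i_lo, i_hi))
            mask = _voxelize(cell, i_lo * spacing_arr, shape, spacing_arr)
            full = int(mask.sum())
            if full == 0:
                continue
            free = mask & (labels[region] == 0)
            claimed = int(free.sum())
            if claimed < 0.5 * full:
                continue
            labels[region][free] = label
            truth = _cell_truth(cell, extent, spacing_arr, supersample)
            touches = (
                free[0].any() and i_lo[0] == 0
                or free[-1].any() and i_hi[0] == grid_shape[0]
                or free[:, 0].any() and i_lo[1] == 0
                or free[:, -1].any() and i_hi[1] == grid_shape[1]
                or free[:, :, 0].any() and i_lo[2] == 0
                or free[:, :, -1].any() and i_hi[2] == grid_shape[2]
            )
            truths.append(
                CellTruth(
                    cell_id=label,
                    touches_boundary=bool(touches),
                    overlap_fraction=1.0 - claimed / full,
                    semi_axes=tuple(float(s) for s in cell.body.semi_axes),
                    n_spikes=len(cell.spikes),
                    center=tuple(float(c) for c in center),
                    volume_voxelized=full * float(np.prod(spacing_arr)),
                    **truth,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place cell {label} after {max_tries} tries; "
                "packing infeasible for these parameters"
            )

    return LabelVolume(labels=labels, spacing=tuple(spacing_arr)), truths


def truths_to_frame(truths: list[CellTruth]) -> pd.DataFrame:
    """Flatten ground-truth records to a table."""
    rows = []
    for t in truths:
        d = asdict(t)
        lam = d.pop("eigenvalues")
        d["lambda_largest"], d["lambda_medium"], d["lambda_smallest"] = lam
        d["semi_a"], d["semi_b"], d["semi_c"] = d.pop("semi_axes")
        d["center_z"], d["center_y"], d["center_x"] = d.pop("center")
        rows.append(d)
    return pd.DataFrame(rows)
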