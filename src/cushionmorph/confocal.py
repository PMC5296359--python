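"""Quantification of outflow-tract cushion fluorescence patterns.

An endocardial cushion section is annotated with two polylines: the lumen
edge (the endocardium monolayer facing the blood) and the myocardium edge
(the outer muscle layer).  Between them lies the cardiac jelly that cells
invade during endothelial-to-mesenchymal transition.  The measures
implemented here summarize that process:

* phalloidin (F-actin) intensity profile across the cushion width, plus
  the mean over the innermost 25% adjacent to the endocardium;
* DAPI cell density in the 10 µm band next to the lumen edge (cells per
  1000 µm²);
* cell and VE-cadherin junction counts per 100 µm of endocardium length;
* periostin front extension as a percentage of the cushion width, measured
  from the myocardium edge.

Geometry is handled with "rays": segments from equally spaced points on
the lumen edge to the nearest point of the myocardium edge, whose lengths
are the local cushion widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter, map_coordinates
from shapely.geometry import LineString, Point
from skimage.draw import line as draw_line, polygon as draw_polygon

__all__ = [
    "CushionSlice",
    "IntensityProfile",
    "CushionMeasures",
    "Ray",
    "cushion_rays",
    "width_profile",
    "inner_fraction_mean",
    "subendocardial_density",
    "count_per_length",
    "periostin_front_pct",
    "measure_slice",
    "aggregate_embryo",
]


@dataclass(frozen=True)
class CushionSlice:
    """One annotated multichannel cushion section.

    ``channels`` maps channel names (e.g. ``nuclei``, ``actin``,
    ``junction``, ``periostin``) to 2D float rasters indexed (row=y,
    col=x).  Polylines are (N, 2) arrays of (x, y) world coordinates in
    µm; a pixel's center sits at ``(index + 0.5) * pixel_size``.
    """

    channels: dict
    pixel_size: float
    lumen_edge: np.ndarray
    myocardium_edge: np.ndarray
    cushion_label: str = "outer"
    embryo_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("lumen_edge", "myocardium_edge"):
            poly = np.asarray(getattr(self, name), dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise ValueError(f"{name} must be an (N>=2, 2) polyline")
            object.__setattr__(self, name, poly)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"channel {name!r} not in slice (has {sorted(self.channels)})")
        return self.channels[name]

    def sample(self, image: np.ndarray, points_um: np.ndarray) -> np.ndarray:
        """Bilinear image sampling at (x, y) µm points."""
        pts = np.asarray(points_um, dtype=float)
        rows = pts[:, 1] / self.pixel_size - 0.5
        cols = pts[:, 0] / self.pixel_size - 0.5
        return map_coordinates(image, [rows, cols], order=1, mode="nearest")


@dataclass(frozen=True)
class IntensityProfile:
    """Mean intensity vs normalized distance from the lumen edge (0 → 1)."""

    positions: np.ndarray
    mean_intensity: np.ndarray
    n_rays: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.size < 2 or np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be >= 2 strictly increasing values")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "mean_intensity", np.asarray(self.mean_intensity, float))


@dataclass(frozen=True)
class Ray:
    """Segment from a lumen-edge point to the nearest myocardium-edge point."""

    start: np.ndarray  # (x, y) µm, on lumen edge
    end: np.ndarray  # (x, y) µm, on myocardium edge

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.end - self.start)))


@dataclass(frozen=True)
class CushionMeasures:
    """Per-slice (or aggregated) cushion quantification results."""

    cell_density: float  # cells per 1000 µm²
    cells_per_length: float  # cells per 100 µm endocardium
    junctions_per_length: float  # junctions per 100 µm endocardium
    periostin_front_pct: float  # % of cushion width from the myocardium
    inner25_mean: float
    full_profile: IntensityProfile | None = None
    cushion_label: str = ""
    embryo_id: str = ""
    slice_index: int = 0


def cushion_rays(slc: CushionSlice, n_rays: int = 50) -> list[Ray]:
    """Rays from equal-arc-length lumen-edge points to the myocardium edge.

    Each ray's length is the local cushion width.  Rays whose endpoints
    fall outside the raster are dropped with a warning; fewer than 50%
    valid rays is an error.
    """
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    lumen = LineString(slc.lumen_edge)
    myo = LineString(slc.myocardium_edge)
    h, w = slc.shape
    extent = np.array([w, h]) * slc.pixel_size

    rays = []
    dropped = 0
    for k in range(n_rays):
        s = (k + 0.5) / n_rays * lumen.length
        p = lumen.interpolate(s)
        q = myo.interpolate(myo.project(p))
        start = np.array([p.x, p.y])
        end = np.array([q.x, q.y])
        if np.any(start < 0) or np.any(start > extent) or np.any(end < 0) or np.any(end > extent):
            dropped += 1
            continue
        rays.append(Ray(start=start, end=end))
    if dropped:
        warnings.warn(f"dropped {dropped}/{n_rays} rays outside the raster")
    if len(rays) < 0.5 * n_rays:
        raise ValueError(f"only {len(rays)}/{n_rays} rays valid; check annotations")
    return rays


def width_profile(
    slc: CushionSlice,
    channel: str,
    n_rays: int = 50,
    n_bins: int = 20,
    samples_per_bin: int = 4,
) -> IntensityProfile:
    """Mean intensity per normalized-position bin across the cushion width.

    Each ray is sampled bilinearly at ``n_bins * samples_per_bin`` evenly
    spaced points from the lumen edge (position 0) to the myocardium edge
    (position 1); bin means pool all samples over all rays.  Zero-length
    (degenerate) rays are skipped.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    img = slc.channel(channel)
    rays = cushion_rays(slc, n_rays)
    m = n_bins * samples_per_bin
    t = (np.arange(m) + 0.5) / m

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    used = 0
    for ray in rays:
        if ray.length == 0:
            continue
        pts = ray.start + t[:, None] * (ray.end - ray.start)
        vals = slc.sample(img, pts)
        bins = np.minimum((t * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, bins, vals)
        np.add.at(counts, bins, 1)
        used += 1
    if used == 0:
        raise ValueError("no non-degenerate rays")
    return IntensityProfile(
        positions=(np.arange(n_bins) + 0.5) / n_bins,
        mean_intensity=sums / counts,
        n_rays=used,
    )


def inner_fraction_mean(profile: IntensityProfile, fraction: float = 0.25) -> float:
    """Mean profile intensity over positions within ``fraction`` of the lumen edge."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    sel = profile.positions <= fraction
    if not sel.any():
        raise ValueError("no profile bins within the requested fraction")
    return float(profile.mean_intensity[sel].mean())


def _polyline_distance_map(slc: CushionSlice, polyline: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance (µm) to a rasterized polyline."""
    h, w = slc.shape
    edge = np.zeros((h, w), dtype=bool)
    px = slc.pixel_size
    ij = np.stack([polyline[:, 1] / px - 0.5, polyline[:, 0] / px - 0.5], axis=1)
    ij = np.clip(np.round(ij).astype(int), 0, [h - 1, w - 1])
    for (r0, c0), (r1, c1) in zip(ij[:-1], ij[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        edge[rr, cc] = True
    return distance_transform_edt(~edge) * px


def _cushion_polygon_mask(slc: CushionSlice) -> np.ndarray:
    """Pixel mask of the cushion interior (between the two polylines)."""
    h, w = slc.shape
    px = slc.pixel_size
    verts = np.vstack([slc.lumen_edge, slc.myocardium_edge[::-1]])
    rr, cc = draw_polygon(verts[:, 1] / px - 0.5, verts[:, 0] / px - 0.5, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


def subendocardial_density(
    slc: CushionSlice, centroids: np.ndarray, depth: float = 10.0
) -> float:
    """Cell density (per 1000 µm²) in the band ``depth`` µm into the cushion.

    The region is the set of cushion-interior pixels within ``depth`` of
    the lumen edge; its area comes from the pixel mask, and a centroid
    counts if it falls on a region pixel.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    region = _cushion_polygon_mask(slc) & (
        _polyline_distance_map(slc, slc.lumen_edge) <= depth
    )
    area = float(region.sum()) * slc.pixel_size**2
    if area == 0:
        raise ValueError("zero-area sub-endocardial region; check annotations")
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return 0.0
    rows = np.floor(pts[:, 1] / slc.pixel_size).astype(int)
    cols = np.floor(pts[:, 0] / slc.pixel_size).astype(int)
    h, w = region.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    count = int(region[rows[inside], cols[inside]].sum())
    return count / area * 1000.0


def count_per_length(
    slc: CushionSlice,
    points: np.ndarray,
    capture_dist: float = 5.0,
    kind: str = "cells",
) -> float:
    """Count of points near the endocardium per 100 µm of its length.

    A point counts if its distance to the lumen-edge polyline is at most
    ``capture_dist`` µm; the denominator is the polyline arc length.
    ``kind`` is metadata only ('cells' or 'junctions').
    """
    lumen = LineString(slc.lumen_edge)
    if lumen.length == 0:
        raise ValueError("lumen edge has zero arc length")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = sum(1 for p in pts if lumen.distance(Point(p)) <= capture_dist)
    return n / lumen.length * 100.0


def periostin_front_pct(
    slc: CushionSlice,
    channel: str = "periostin",
    n_rays: int = 50,
    smooth_sigma_um: float = 2.0,
    threshold_mode: str = "half-max",
    threshold_value: float | None = None,
    noise_floor: float = 0.0,
    samples_per_um: float = 2.0,
) -> float:
    """Periostin front extension as mean percent of cushion width.

    Per ray, the (Gaussian-smoothed) intensity is scanned from the
    myocardium end toward the lumen; the front is the farthest point from
    the myocardium whose intensity still reaches the threshold (half of
    that ray's maximum by default, or an absolute ``threshold_value``).
    Rays whose maximum falls below ``noise_floor`` are excluded; if every
    ray is excluded an error is raised.
    """
    if threshold_mode not in ("half-max", "absolute"):
        raise ValueError("threshold_mode must be 'half-max' or 'absolute'")
    if threshold_mode == "absolute" and threshold_value is None:
        raise ValueError("absolute mode needs threshold_value")
    img = slc.channel(channel)
    if smooth_sigma_um > 0:
        img = gaussian_filter(img.astype(float), smooth_sigma_um / slc.pixel_size)
    rays = cushion_rays(slc, n_rays)

    pcts = []
    for ray in rays:
        width = ray.length
        if width == 0:
            continue
        m = max(8, int(np.ceil(width * samples_per_um)))
        t = np.linspace(0.0, 1.0, m)  # 0 = myocardium end, 1 = lumen end
        pts = ray.end + t[:, None] * (ray.start - ray.end)
        vals = slc.sample(img, pts)
        ray_max = float(vals.max())
        if ray_max < noise_floor:
            continue
        thr = 0.5 * ray_max if threshold_mode == "half-max" else float(threshold_value)
        above = np.nonzero(vals >= thr)[0]
        front = t[above[-1]] * width if above.size else 0.0
        pcts.append(100.0 * front / width)
    if not pcts:
        raise ValueError("all rays excluded by the noise floor")
    return float(np.mean(pcts))


def measure_slice(
    slc: CushionSlice,
    jelly_centroids: np.ndarray,
    endo_centroids: np.ndarray,
    junction_points: np.ndarray,
    profile_channel: str = "actin",
    periostin_channel: str = "periostin",
    n_rays: int = 50,
    n_bins: int = 20,
    depth: float = 10.0,
    capture_dist: float = 5.0,
) -> CushionMeasures:
    """All per-slice cushion measures in one call."""
    profile = width_profile(slc, profile_channel, n_rays=n_rays, n_bins=n_bins)
    return CushionMeasures(
        cell_density=subendocardial_density(slc, jelly_centroids, depth=depth),
        cells_per_length=count_per_length(slc, endo_centroids, capture_dist, "cells"),
        junctions_per_length=count_per_length(slc, junction_points, capture_dist, "junctions"),
        periostin_front_pct=periostin_front_pct(slc, periostin_channel, n_rays=n_rays),
        inner25_mean=inner_fraction_mean(profile, 0.25),
        full_profile=profile,
        cushion_label=slc.cushion_label,
        embryo_id=slc.embryo_id,
        slice_index=slc.slice_index,
    )


_SCALAR_MEASURES = (
    "cell_density",
    "cells_per_length",
    "junctions_per_length",
    "periostin_front_pct",
    "inner25_mean",
)


def _mean_measures(measures: list[CushionMeasures]) -> dict:
    return {
        m: float(np.mean([getattr(x, m) for x in measures])) for m in _SCALAR_MEASURES
    }


def aggregate_embryo(measures: list[CushionMeasures]) -> dict:
    """Per-embryo aggregation: unweighted mean over slices and cushions.

    Returns the overall means plus per-cushion (inner/outer) sub-means for
    the inner-vs-outer comparison.
    """
    if not measures:
        raise ValueError("need at least one slice")
    labels = sorted({m.cushion_label for m in measures})
    return {
        "embryo_id": measures[0].embryo_id,
        "n_slices": len(measures),
        "overall": _mean_measures(measures),
        "per_cushion": {
            lab: _mean_measures([m for m in measures if m.cushion_label == lab])
            for lab in labels
        },
    }
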