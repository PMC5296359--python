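"""Synthetic annotated cushion sections with known ground truth.

Emulates a confocal section through the embryonic outflow tract at the
cushion level: an outer myocardium layer, a cardiac-jelly cushion bulging
into the lumen, and an endocardium monolayer along the lumen edge — one
cushion at the top of the frame ("outer") and one mirrored at the bottom
("inner").  Four fluorescence channels are rendered:

* ``nuclei``  — DAPI-like Gaussian blobs: jelly nuclei from a spatial
  Poisson process at a stated density plus endocardial nuclei spaced
  along the lumen edge;
* ``actin``   — phalloidin-like signal, brightest in a sub-endocardial
  band and decaying toward the myocardium;
* ``junction``— VE-cadherin-like puncta between a stated fraction of
  adjacent endocardial nuclei (junction completeness);
* ``periostin`` — a smoothed concentration front extending a stated
  fraction of the cushion width from the myocardium.

All channels receive Gaussian PSF blur and additive Gaussian noise.  The
myocardium edges are straight lines, so the true local cushion width at
lumen-edge x is exactly the seeded width function — which makes ray-based
width, density and front recovery exactly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..confocal import CushionSlice

__all__ = ["CushionSliceParams", "CushionGroundTruth", "gen_cushion_slice"]


@dataclass(frozen=True)
class CushionSliceParams:
    """Geometry, seeding and rendering parameters of a synthetic section.

    Lengths in µm; densities per 1000 µm²; intensities in arbitrary units.
    The cushion width profile along x is ``base_width + bulge *
    sin(pi * (x - x0) / span)`` — widest mid-section, tapering to
    ``base_width`` at the ends.
    """

    width_um: float = 300.0
    height_um: float = 300.0
    pixel_size: float = 0.5
    myocardium_inset: float = 30.0
    base_width: float = 40.0
    bulge: float = 40.0
    edge_margin: float = 4.0
    jelly_density: float = 8.0  # nuclei per 1000 µm² of cushion area
    endo_spacing: float = 10.0  # µm between endocardial nuclei
    endo_offset: float = 1.5  # nucleus center offset into the cushion
    junction_completeness: float = 0.9
    periostin_front_fraction: float = 0.5
    psf_sigma: float = 1.0  # µm
    noise_sd: float = 2.0
    nucleus_sigma: float = 2.0
    nucleus_amp: float = 200.0
    actin_amp: float = 150.0
    actin_base: float = 25.0
    actin_decay: float = 8.0  # µm, sub-endocardial band depth scale
    junction_amp: float = 200.0
    junction_sigma: float = 1.0
    periostin_amp: float = 150.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.periostin_front_fraction <= 1.0:
            raise ValueError("periostin_front_fraction must lie in [0, 1]")
        if not 0.0 <= self.junction_completeness <= 1.0:
            raise ValueError("junction_completeness must lie in [0, 1]")
        if self.jelly_density < 0 or self.pixel_size <= 0:
            raise ValueError("invalid density or pixel size")
        needed = 2 * (self.myocardium_inset + self.base_width + self.bulge)
        if needed >= self.height_um:
            raise ValueError("cushions would overlap: reduce widths or grow the frame")


@dataclass(frozen=True)
class CushionGroundTruth:
    """Seeded quantities of one generated cushion."""

    cushion_label: str
    jelly_centroids: np.ndarray  # (N, 2) (x, y) µm
    endo_centroids: np.ndarray
    jelly_density_true: float  # per 1000 µm²
    junction_positions: np.ndarray
    junction_completeness: float
    front_fraction: float  # of cushion width, from the myocardium
    cushion_area: float  # µm²
    widths: np.ndarray  # true width at each lumen-edge vertex, µm


def _width_fn(params: CushionSliceParams, x: np.ndarray) -> np.ndarray:
    x0 = params.edge_margin
    span = params.width_um - 2 * params.edge_margin
    return params.base_width + params.bulge * np.sin(np.pi * (x - x0) / span)


def _paint_blobs(img: np.ndarray, points: np.ndarray, sigma: float, amp: float, px: float) -> None:
    """Add Gaussian blobs at (x, y) µm points, in place."""
    if len(points) == 0:
        return
    h, w = img.shape
    s_px = sigma / px
    r = int(np.ceil(4 * s_px))
    for x, y in points:
        c, rrow = x / px - 0.5, y / px - 0.5
        c0, c1 = max(int(c) - r, 0), min(int(c) + r + 1, w)
        r0, r1 = max(int(rrow) - r, 0), min(int(rrow) + r + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        g = np.exp(
            -((rows[:, None] - rrow) ** 2 + (cols[None, :] - c) ** 2) / (2 * s_px**2)
        )
        img[r0:r1, c0:c1] += amp * g


def gen_cushion_slice(
    params: CushionSliceParams = CushionSliceParams(),
    seed: int = 0,
    embryo_id: str = "synthetic",
    slice_index: int = 0,
) -> tuple[list[CushionSlice], list[CushionGroundTruth]]:
    """Render one synthetic section with its two annotated cushions.

    Returns two :class:`~cushionmorph.confocal.CushionSlice` objects
    (labels ``outer`` = top, ``inner`` = bottom) sharing the same channel
    rasters, plus one ground-truth record per cushion.  Identical seed and
    parameters reproduce the output bit for bit.
    """
    rng = np.random.default_rng(seed)
    px = params.pixel_size
    w_px = int(round(params.width_um / px))
    h_px = int(round(params.height_um / px))

    cols_um = (np.arange(w_px) + 0.5) * px
    rows_um = (np.arange(h_px) + 0.5) * px
    X = np.broadcast_to(cols_um[None, :], (h_px, w_px))
    Y = np.broadcast_to(rows_um[:, None], (h_px, w_px))

    x_lo, x_hi = params.edge_margin, params.width_um - params.edge_margin
    w_of_x = _width_fn(params, cols_um)
    in_x = (X >= x_lo) & (X <= x_hi)

    channels = {
        name: np.full((h_px, w_px), params.background, dtype=np.float64)
        for name in ("nuclei", "actin", "junction", "periostin")
    }

    slices: list[CushionSlice] = []
    truths: list[CushionGroundTruth] = []

    vx = np.arange(x_lo, x_hi + 1e-9, 2.0)  # polyline vertices every 2 µm
    vw = _width_fn(params, vx)
    span = x_hi - x_lo
    area = float(params.base_width * span + params.bulge * span * 2.0 / np.pi)

    for label, top in (("outer", True), ("inner", False)):
        if top:
            y_myo = params.myocardium_inset
            y_lumen_v = y_myo + vw
            d_myo = Y - y_myo  # distance from the myocardium edge
            w_col = w_of_x[None, :]
            in_cushion = in_x & (d_myo >= 0) & (d_myo <= w_col)
            inward = -1.0  # from lumen edge into the cushion along y
        else:
            y_myo = params.height_um - params.myocardium_inset
            y_lumen_v = y_myo - vw
            d_myo = y_myo - Y
            w_col = w_of_x[None, :]
            in_cushion = in_x & (d_myo >= 0) & (d_myo <= w_col)
            inward = 1.0

        d_lumen = np.where(in_cushion, w_col - d_myo, np.inf)

        # actin: bright sub-endocardial band decaying toward the myocardium
        channels["actin"][in_cushion] += (
            params.actin_base
            + params.actin_amp * np.exp(-d_lumen[in_cushion] / params.actin_decay)
        )
        # periostin: front extends front_fraction of the width from the myocardium
        front_mask = in_cushion & (d_myo <= params.periostin_front_fraction * w_col)
        channels["periostin"][front_mask] += params.periostin_amp

        # jelly nuclei: spatial Poisson process in the cushion region
        n_jelly = rng.poisson(params.jelly_density / 1000.0 * area)
        jelly = []
        y_min = min(y_myo, y_myo + (1 if top else -1) * (params.base_width + params.bulge))
        y_max = max(y_myo, y_myo + (1 if top else -1) * (params.base_width + params.bulge))
        while len(jelly) < n_jelly:
            xs = rng.uniform(x_lo, x_hi)
            ys = rng.uniform(y_min, y_max)
            dm = (ys - y_myo) if top else (y_myo - ys)
            if 0 <= dm <= _width_fn(params, np.array([xs]))[0]:
                jelly.append((xs, ys))
        jelly = np.array(jelly).reshape(-1, 2)

        # endocardial nuclei: equally spaced along the lumen edge (arc length
        # ≈ x for the gentle bulge; place by x and project onto the edge)
        lumen_xy = np.stack([vx, y_lumen_v], axis=1)
        seg = np.diff(lumen_xy, axis=0)
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        total = arc[-1]
        n_endo = int(total // params.endo_spacing)
        s_pos = (np.arange(n_endo) + 0.5) * params.endo_spacing
        ex = np.interp(s_pos, arc, vx)
        ey = np.interp(s_pos, arc, y_lumen_v)
        anchors = np.stack([ex, ey], axis=1)
        endo = anchors.copy()
        endo[:, 1] += inward * params.endo_offset  # nudge nucleus center into the cushion
        # junction puncta between adjacent endocardial cells
        mids = 0.5 * (anchors[:-1] + anchors[1:])
        keep = rng.random(len(mids)) < params.junction_completeness
        junctions = mids[keep]

        _paint_blobs(channels["nuclei"], jelly, params.nucleus_sigma, params.nucleus_amp, px)
        _paint_blobs(channels["nuclei"], endo, params.nucleus_sigma, params.nucleus_amp, px)
        _paint_blobs(channels["junction"], junctions, params.junction_sigma, params.junction_amp, px)

        myo_xy = np.stack([vx, np.full_like(vx, y_myo)], axis=1)
        slices.append(
            CushionSlice(
                channels=channels,
                pixel_size=px,
                lumen_edge=lumen_xy,
                myocardium_edge=myo_xy,
                cushion_label=label,
                embryo_id=embryo_id,
                slice_index=slice_index,
            )
        )
        truths.append(
            CushionGroundTruth(
                cushion_label=label,
                jelly_centroids=jelly,
                endo_centroids=endo,
                jelly_density_true=params.jelly_density,
                junction_positions=junctions,
                junction_completeness=params.junction_completeness,
                front_fraction=params.periostin_front_fraction,
                cushion_area=area,
                widths=vw.copy(),
            )
        )

    # shared point-spread blur + noise, applied once to the shared rasters
    for name, img in channels.items():
        if params.psf_sigma > 0:
            img[:] = gaussian_filter(img, params.psf_sigma / px)
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
            np.clip(img, 0.0, None, out=img)
        channels[name] = img.astype(np.float32)

    # rebuild slices so they reference the final float32 rasters
    slices = [
        CushionSlice(
            channels=channels,
            pixel_size=px,
            lumen_edge=s.lumen_edge,
            myocardium_edge=s.myocardium_edge,
            cushion_label=s.cushion_label,
            embryo_id=s.embryo_id,
            slice_index=s.slice_index,
        )
        for s in slices
    ]
    return slices, truths
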