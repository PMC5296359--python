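"""Outflow-tract band tightness from pre/post-banding diameter traces.

Outflow tract banding constricts the embryonic outflow tract with a suture,
raising blood pressure and wall shear stress.  The severity of the
constriction is quantified from optical coherence tomography diameter
time-series as

    band tightness = 1 - Da / Db

where ``Da`` is the maximum external diameter of the outflow tract at the
band site after banding and ``Db`` the maximum at the same location before
banding.  A sham (control) embryo therefore has band tightness 0, and the
morphometry / proteomics arms of the study select embryos in the 30-45%
constriction window, where the hemodynamic perturbation is large and
roughly constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

__all__ = [
    "DiameterTrace",
    "BandTightness",
    "max_external_diameter",
    "band_tightness",
    "in_band_range",
]


@dataclass(frozen=True)
class DiameterTrace:
    """External outflow-tract diameter sampled over consecutive frames.

    Parameters
    ----------
    diameters:
        External diameter per frame, in micrometres.  Must be positive.
    fps:
        Acquisition frame rate in Hz (metadata; the maximum-diameter
        computation does not depend on it).
    """

    diameters: np.ndarray
    fps: float = 140.0

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("trace must contain at least one frame")
        if not np.all(d > 0):
            raise ValueError("all diameters must be positive")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "diameters", d)

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.diameters.size) / self.fps


@dataclass(frozen=True)
class BandTightness:
    """Result of the band-tightness computation.

    ``value`` is the dimensionless constriction fraction
    ``1 - d_a_max / d_b_max``; negative values indicate dilation rather
    than constriction and are flagged via :attr:`dilated`.
    """

    value: float
    d_a_max: float
    d_b_max: float

    @property
    def dilated(self) -> bool:
        return self.value < 0

    @property
    def percent(self) -> float:
        """Band tightness expressed in percent constriction."""
        return 100.0 * self.value


def max_external_diameter(trace: DiameterTrace, median_window: int = 0) -> float:
    """Maximum external diameter over the whole trace, in micrometres.

    The maximum is taken over all sampled frames (no per-cycle averaging).
    ``median_window`` optionally applies a running median of that odd width
    before taking the maximum, to suppress single-frame spikes; the default
    (0) uses the raw samples.
    """
    d = trace.diameters
    if median_window:
        if median_window % 2 == 0:
            raise ValueError("median_window must be odd")
        d = medfilt(d, median_window)
    return float(np.max(d))


def band_tightness(
    pre: DiameterTrace, post: DiameterTrace, median_window: int = 0
) -> BandTightness:
    """Degree of constriction from pre- and post-banding diameter traces.

    Computes ``1 - max(post) / max(pre)``.  Both traces must be in the same
    units (micrometres).  A negative result (post-banding dilation) is
    returned rather than raised, and is flagged on the result object.
    """
    d_b = max_external_diameter(pre, median_window)
    d_a = max_external_diameter(post, median_window)
    return BandTightness(value=1.0 - d_a / d_b, d_a_max=d_a, d_b_max=d_b)


def in_band_range(bt: BandTightness | float, lo: float = 0.30, hi: float = 0.45) -> bool:
    """Whether a band tightness falls in the selection window [lo, hi].

    The default window (30-45% constriction) is the range used to select
    embryos for electron microscopy and proteomics, where the increase in
    peak velocity and wall shear rate is large and approximately constant.
    Both endpoints are included.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    value = bt.value if isinstance(bt, BandTightness) else float(bt)
    return lo <= value <= hi
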