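"""Synthetic pulsatile outflow-tract diameter traces.

Emulates the OCT measurement protocol: ~200 tomographic frames at 140
frames per second spanning three to four cardiac cycles, acquired once
before and once after banding.  The post-banding trace is the pre-banding
waveform scaled by ``1 - tightness_true`` so that, before noise, the
maxima satisfy the band-tightness identity exactly.  Frame 0 lies on a
systolic peak, so the noise-free maximum equals ``baseline_max`` exactly
rather than to within sampling error.
"""

from __future__ import annotations

import numpy as np

from ..band_tightness import DiameterTrace

__all__ = ["gen_diameter_traces"]


def gen_diameter_traces(
    baseline_max: float = 700.0,
    tightness_true: float = 0.0,
    fps: float = 140.0,
    n_frames: int = 200,
    pulsatility: float = 0.25,
    noise_sd: float = 0.0,
    heart_rate_hz: float = 2.3,
    seed: int = 0,
) -> tuple[DiameterTrace, DiameterTrace]:
    """Generate matched pre- and post-banding diameter traces.

    Parameters
    ----------
    baseline_max:
        Pre-banding maximum external diameter, µm.
    tightness_true:
        Seeded constriction fraction in [0, 1); ``max(post) =
        (1 - tightness_true) * max(pre)`` before noise.
    pulsatility:
        Peak-to-peak diameter excursion as a fraction of the maximum.
    noise_sd:
        Additive Gaussian measurement noise, µm.
    heart_rate_hz:
        Cardiac frequency; the default gives ~3.3 cycles over 200 frames
        at 140 fps.

    Returns
    -------
    (pre, post) diameter traces.
    """
    if not 0 <= tightness_true < 1:
        raise ValueError("tightness_true must lie in [0, 1)")
    if not 0 <= pulsatility < 1:
        raise ValueError("pulsatility must lie in [0, 1)")
    if n_frames < 1 or fps <= 0 or baseline_max <= 0:
        raise ValueError("invalid trace parameters")

    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / fps
    waveform = 1.0 - 0.5 * pulsatility * (1.0 - np.cos(2.0 * np.pi * heart_rate_hz * t))
    pre = baseline_max * waveform
    post = (1.0 - tightness_true) * pre
    if noise_sd > 0:
        pre = pre + rng.normal(0.0, noise_sd, size=n_frames)
        post = post + rng.normal(0.0, noise_sd, size=n_frames)
        pre = np.clip(pre, 1e-6, None)
        post = np.clip(post, 1e-6, None)
    return DiameterTrace(pre, fps=fps), DiameterTrace(post, fps=fps)
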