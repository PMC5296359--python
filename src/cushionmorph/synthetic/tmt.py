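"""Synthetic 10-plex TMT PSM tables with spiked differential proteins.

Emulates the proteomics arm's design: five banded and five sham-control
samples labeled in one 10-plex, quantified at the peptide-spectrum-match
(PSM) level with ten reporter-ion intensities per PSM.  Reporter
intensities are log-normal around protein × channel means, with per-channel
loading factors (pipetting/labeling imbalance), occasional zero-intensity
dropouts, and a configurable fraction of quality-filter failures (high
q-value, large mass error, ambiguous protein match) so the downstream
filters are exercised.  Ground truth records each protein's true log2 fold
change (banded vs control).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["gen_tmt_dataset", "default_channel_map"]

N_CHANNELS = 10
_REPORTER_COLS = [f"reporter_{i}" for i in range(1, N_CHANNELS + 1)]


def default_channel_map() -> dict:
    """Channel → sample/group assignment: reporters 1-5 control, 6-10 banded."""
    cmap = {}
    for i in range(1, N_CHANNELS + 1):
        group = "control" if i <= 5 else "banded"
        idx = i if i <= 5 else i - 5
        cmap[f"reporter_{i}"] = {"sample": f"{group}_{idx}", "group": group}
    return cmap


def gen_tmt_dataset(
    n_proteins: int = 1000,
    psm_per_protein_mean: float = 4.0,
    n_differential: int = 50,
    log2fc_magnitude: float = 1.0,
    zero_rate: float = 0.01,
    channel_load_factors: np.ndarray | None = None,
    noise_cv: float = 0.2,
    seed: int = 0,
    base_intensity_median: float = 5000.0,
    base_intensity_sigma: float = 1.0,
    peptide_sigma: float = 0.5,
    bad_q_rate: float = 0.02,
    bad_mass_rate: float = 0.02,
    multi_match_rate: float = 0.02,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Generate a PSM-level reporter table, channel map and ground truth.

    Differential proteins (the first ``n_differential`` after a seeded
    shuffle) receive a true banded/control log2 fold change of
    ``±log2fc_magnitude`` with random sign.  ``channel_load_factors``
    (length 10) multiplies each channel's intensities; by default they are
    drawn log-normal with ~10% spread, which the channel normalization
    step should recover.

    Returns
    -------
    (psm_table, channel_map, ground_truth)
        ``psm_table`` has the documented PSM CSV columns;
        ``ground_truth`` one row per protein with ``true_log2fc``,
        ``is_differential`` and ``psm_count``.
    """
    if n_differential > n_proteins:
        raise ValueError("n_differential cannot exceed n_proteins")
    if not 0 <= zero_rate <= 1:
        raise ValueError("zero_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if channel_load_factors is None:
        channel_load_factors = np.exp(rng.normal(0.0, 0.1, size=N_CHANNELS))
    load = np.asarray(channel_load_factors, dtype=float)
    if load.shape != (N_CHANNELS,):
        raise ValueError("channel_load_factors must have length 10")

    protein_ids = np.array([f"P{i:05d}" for i in range(n_proteins)])
    order = rng.permutation(n_proteins)
    diff_idx = order[:n_differential]
    log2fc = np.zeros(n_proteins)
    log2fc[diff_idx] = rng.choice([-1.0, 1.0], size=n_differential) * log2fc_magnitude

    base = base_intensity_median * np.exp(rng.normal(0.0, base_intensity_sigma, size=n_proteins))
    psm_counts = rng.poisson(max(psm_per_protein_mean - 1.0, 0.0), size=n_proteins) + 1

    group_mult = np.ones((n_proteins, N_CHANNELS))
    group_mult[:, 5:] = 2.0 ** log2fc[:, None]

    sigma_ln = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    psm_id = 0
    for p in range(n_proteins):
        means = base[p] * group_mult[p] * load
        for _ in range(psm_counts[p]):
            pep = np.exp(rng.normal(0.0, peptide_sigma))
            reporters = means * pep * np.exp(rng.normal(0.0, sigma_ln, size=N_CHANNELS))
            reporters[rng.random(N_CHANNELS) < zero_rate] = 0.0

            if rng.random() < bad_q_rate:
                q = rng.uniform(0.0501, 0.5)
            else:
                q = rng.uniform(0.0, 0.05)
            if rng.random() < bad_mass_rate:
                mass = rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 40.0)
            else:
                mass = rng.normal(0.0, 5.0)
                mass = float(np.clip(mass, -19.9, 19.9))
            n_match = 2 if rng.random() < multi_match_rate else 1

            rows.append(
                (f"PSM{psm_id:07d}", f"PEP{psm_id:07d}", protein_ids[p],
                 q, mass, n_match, *np.round(reporters, 3))
            )
            psm_id += 1

    psm_table = pd.DataFrame(
        rows,
        columns=["psm_id", "peptide_seq", "protein_id", "q_value",
                 "mass_error_ppm", "n_protein_matches", *_REPORTER_COLS],
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "true_log2fc": log2fc,
            "is_differential": np.isin(np.arange(n_proteins), diff_idx),
            "psm_count": psm_counts,
        }
    )
    return psm_table, default_channel_map(), truth
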