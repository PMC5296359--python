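"""Shared statistics and the study-level report.

Group comparisons between sham-control and banded embryos use a two-sample
t-test (pooled-variance Student by default, Welch optionally — the banded
group's variance is typically inflated), band-tightness dose dependence is
summarized by ordinary least squares R², and protein-level multiple testing
uses Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "RegressionFit",
    "two_sample_t",
    "linear_fit",
    "benjamini_hochberg",
    "study_report",
    "boxplot_groups",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison of one metric between control and banded embryos."""

    metric: str
    mean_control: float
    mean_banded: float
    sd_control: float
    sd_banded: float
    fold: float
    t_statistic: float
    p_two_tail: float
    significant: bool
    n_control: int
    n_banded: int
    variant: str = "student"
    zero_variance: bool = False


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary-least-squares line fit with coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def two_sample_t(
    control: Sequence[float],
    banded: Sequence[float],
    variant: str = "student",
    alpha: float = 0.05,
    metric: str = "",
) -> GroupComparison:
    """Two-sample two-tailed t-test between control and banded values.

    ``variant`` selects the pooled-variance Student test (the study's
    convention) or the Welch unequal-variance test.  Degenerate inputs where
    both groups have zero variance and identical values return p = 1 with a
    flag; zero variance with unequal means raises, pointing at Welch (which
    is equally undefined but makes the caller's intent explicit).
    """
    c = np.asarray(control, dtype=float)
    b = np.asarray(banded, dtype=float)
    if c.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")

    zero_var = c.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if zero_var:
        if c.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            raise ValueError(
                "both groups have zero variance but unequal means; "
                "the t statistic is undefined (consider variant='welch' "
                "on data with replicate noise)"
            )
    else:
        t_stat, p = sps.ttest_ind(b, c, equal_var=(variant == "student"))
        t_stat, p = float(t_stat), float(p)

    mean_c, mean_b = float(c.mean()), float(b.mean())
    fold = mean_b / mean_c if mean_c != 0 else np.nan
    return GroupComparison(
        metric=metric,
        mean_control=mean_c,
        mean_banded=mean_b,
        sd_control=float(c.std(ddof=1)),
        sd_banded=float(b.std(ddof=1)),
        fold=float(fold),
        t_statistic=t_stat,
        p_two_tail=p,
        significant=bool(p < alpha),
        n_control=int(c.size),
        n_banded=int(b.size),
        variant=variant,
        zero_variance=zero_var,
    )


def linear_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares fit of y on x with R² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values (q-values) in the input order; monotonicity
    over the sorted sequence is enforced, and the result is stable under
    input reordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def study_report(
    embryos: pd.DataFrame,
    alpha: float = 0.05,
    regression_measures: Sequence[str] = ("cell_density", "periostin_front_pct"),
    tmt_results: pd.DataFrame | None = None,
    tmt_report_p: float = 0.1,
    variant: str = "student",
) -> dict:
    """Assemble the study-level report across analysis arms.

    Parameters
    ----------
    embryos:
        Per-embryo table with at least columns ``embryo_id``, ``group``
        ('control' or 'banded') and ``band_tightness`` (fraction), plus one
        column per aggregated measure.  This is the table an embryo-level
        confocal / morphometry aggregation produces.
    alpha:
        Significance threshold for imaging-arm comparisons.
    regression_measures:
        Measures regressed against band tightness over the banded + control
        embryos (dose dependence).
    tmt_results:
        Optional differential-abundance table (one row per protein with
        ``p_value`` and ``fdr``); proteins with ``p_value < tmt_report_p``
        are counted as differential, mirroring the proteomics reporting
        threshold.

    Returns
    -------
    dict with keys ``per_embryo`` (records), ``comparisons``,
    ``regressions`` and optionally ``tmt_summary``; every summary can be
    recomputed from the per-embryo records.
    """
    required = {"embryo_id", "group", "band_tightness"}
    missing = required - set(embryos.columns)
    if missing:
        raise ValueError(f"per-embryo table lacks columns: {sorted(missing)}")

    measures = [c for c in embryos.columns if c not in required]
    control = embryos[embryos["group"] == "control"]
    banded = embryos[embryos["group"] == "banded"]

    comparisons = []
    for m in measures:
        c = control[m].dropna().to_numpy()
        b = banded[m].dropna().to_numpy()
        if c.size >= 2 and b.size >= 2:
            comparisons.append(asdict(two_sample_t(c, b, variant=variant,
                                                   alpha=alpha, metric=m)))
        else:
            comparisons.append({"metric": m, "available": False})

    regressions = {}
    for m in regression_measures:
        if m not in embryos.columns:
            continue
        sub = embryos[["band_tightness", m]].dropna()
        if len(sub) >= 3 and np.ptp(sub["band_tightness"].to_numpy()) > 0:
            regressions[m] = asdict(linear_fit(sub["band_tightness"], sub[m]))

    report: dict = {
        "alpha": alpha,
        "t_test_variant": variant,
        "per_embryo": embryos.to_dict(orient="records"),
        "comparisons": comparisons,
        "regressions": regressions,
    }
    if tmt_results is not None:
        report["tmt_summary"] = {
            "n_proteins": int(len(tmt_results)),
            "report_p_threshold": tmt_report_p,
            "n_differential_p": int((tmt_results["p_value"] < tmt_report_p).sum()),
            "n_fdr_05": int((tmt_results["fdr"] < 0.05).sum()),
        }
    return report


def write_report(report: dict, json_path, embryo_csv=None, comparison_csv=None) -> None:
    """Write a study report to JSON (plus optional CSV side tables)."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if embryo_csv is not None:
        pd.DataFrame(report["per_embryo"]).to_csv(embryo_csv, index=False)
    if comparison_csv is not None:
        pd.DataFrame(report["comparisons"]).to_csv(comparison_csv, index=False)


def boxplot_groups(values: dict[str, Sequence[float]], ylabel: str, out_path) -> None:
    """Min/max-whisker box plot of per-group values (boxes = quartiles)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.0, 3.5))
    labels = list(values)
    ax.boxplot([np.asarray(values[k], dtype=float) for k in labels],
               tick_labels=labels, whis=(0, 100))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
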