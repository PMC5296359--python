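"""TMT pipeline: quality/reporter filters, rollup, normalization, testing."""

import numpy as np
import pandas as pd
import pytest

from cushionmorph.proteomics import (
    REPORTER_COLS,
    annotate_panel,
    differential_abundance,
    load_emt_panel,
    normalize_channels,
    psm_quality_filter,
    reporter_filter,
    rollup_protein,
    signed_fold,
)
from cushionmorph.synthetic import default_channel_map, gen_tmt_dataset


def make_psms(rows):
    """rows: list of (q, mass, n_match, reporters)."""
    recs = []
    for i, (q, mass, n_match, reporters) in enumerate(rows):
        recs.append(
            {"psm_id": f"p{i}", "peptide_seq": f"PEP{i}", "protein_id": f"PR{i}",
             "q_value": q, "mass_error_ppm": mass, "n_protein_matches": n_match,
             **dict(zip(REPORTER_COLS, reporters))}
        )
    return pd.DataFrame(recs)


GOOD = (0.01, 1.0, 1)


class TestQualityFilter:
    def test_boundaries(self):
        psms = make_psms([
            (0.05, 0.0, 1, [600.0] * 10),   # q exactly 0.05: retained (<=)
            (0.0501, 0.0, 1, [600.0] * 10),  # just over: rejected
            (0.01, 20.0, 1, [600.0] * 10),   # mass error exactly 20: rejected (<)
            (0.01, -19.99, 1, [600.0] * 10),  # |mass| < 20: retained
            (0.01, 0.0, 2, [600.0] * 10),    # ambiguous match: rejected
        ])
        kept, log = psm_quality_filter(psms)
        assert list(kept["psm_id"]) == ["p0", "p3"]
        assert log == {"input": 5, "rejected_q_value": 1, "rejected_mass_error": 1,
                       "rejected_multi_protein": 1, "retained": 2}


class TestReporterFilter:
    def test_all_600_pass_unchanged(self):
        psms = make_psms([(*GOOD, [600.0] * 10)])
        kept, log = reporter_filter(psms)
        assert log["retained"] == 1
        assert np.allclose(kept[REPORTER_COLS].to_numpy(), 600.0)

    def test_all_zero_fail(self):
        kept, log = reporter_filter(make_psms([(*GOOD, [0.0] * 10)]))
        assert log["rejected_low_signal"] == 1 and len(kept) == 0

    def test_nine_thousands_one_zero(self):
        # exclude the (first) 1000 as max and the 0 as min; remaining mean
        # is 1000 > 500 so the PSM passes and its zero becomes 150
        reporters = [1000.0] * 9 + [0.0]
        kept, _ = reporter_filter(make_psms([(*GOOD, reporters)]))
        vals = kept[REPORTER_COLS].to_numpy()[0]
        assert vals[-1] == 150.0
        assert np.allclose(vals[:9], 1000.0)

    def test_trimmed_mean_strictly_greater_than_500(self):
        # after trimming max 600 and min 400, mean of eight 500s is exactly
        # 500: fails the strict > test
        reporters = [500.0] * 8 + [600.0, 400.0]
        kept, _ = reporter_filter(make_psms([(*GOOD, reporters)]))
        assert len(kept) == 0
        reporters = [500.1] * 8 + [600.0, 400.0]
        kept, _ = reporter_filter(make_psms([(*GOOD, reporters)]))
        assert len(kept) == 1

    def test_trim_guards_against_single_huge_channel(self):
        # one enormous reporter cannot rescue an otherwise weak PSM
        reporters = [10.0] * 9 + [1e7]
        kept, _ = reporter_filter(make_psms([(*GOOD, reporters)]))
        assert len(kept) == 0


class TestRollup:
    def test_single_psm_identity(self):
        psms = make_psms([(*GOOD, list(range(100, 110)))])
        table = rollup_protein(psms)
        assert np.array_equal(table[REPORTER_COLS].to_numpy()[0], np.arange(100, 110))
        assert table["psm_count"].iloc[0] == 1

    def test_two_psms_sum(self):
        psms = make_psms([(*GOOD, [100.0] * 10), (*GOOD, [200.0] * 10)])
        psms["protein_id"] = "shared"
        table = rollup_protein(psms)
        assert np.allclose(table[REPORTER_COLS].to_numpy()[0], 300.0)

    def test_matches_bruteforce_aggregation(self):
        psms, _, _ = gen_tmt_dataset(n_proteins=40, n_differential=5, seed=6)
        kept, _ = psm_quality_filter(psms)
        kept, _ = reporter_filter(kept)
        table = rollup_protein(kept)
        # independent oracle: plain dict accumulation over rows
        acc: dict = {}
        for _, row in kept.iterrows():
            acc.setdefault(row["protein_id"], np.zeros(10))
            acc[row["protein_id"]] += row[REPORTER_COLS].to_numpy(dtype=float)
        for pid, vec in acc.items():
            assert np.allclose(table.loc[pid, REPORTER_COLS].to_numpy(dtype=float), vec)


class TestNormalization:
    def test_equal_totals_identity(self):
        table = rollup_protein(make_psms([(*GOOD, [700.0] * 10)]))
        normed, factors = normalize_channels(table)
        assert np.allclose(factors, 1.0)
        assert np.allclose(normed[REPORTER_COLS], table[REPORTER_COLS])

    def test_loading_factor_recovered(self):
        load = np.ones(10)
        load[3] = 2.0
        psms, _, _ = gen_tmt_dataset(
            n_proteins=300, n_differential=0, channel_load_factors=load,
            noise_cv=0.1, zero_rate=0.0, seed=7,
        )
        kept, _ = psm_quality_filter(psms)
        kept, _ = reporter_filter(kept)
        _, factors = normalize_channels(rollup_protein(kept))
        relative = factors / factors[np.arange(10) != 3].mean()
        assert relative[3] == pytest.approx(0.5, rel=0.01)

    def test_rank_order_preserved_within_channel(self):
        psms, _, _ = gen_tmt_dataset(n_proteins=30, n_differential=0, seed=8)
        table = rollup_protein(reporter_filter(psm_quality_filter(psms)[0])[0])
        normed, _ = normalize_channels(table)
        for col in REPORTER_COLS:
            assert np.array_equal(
                np.argsort(table[col].to_numpy()), np.argsort(normed[col].to_numpy())
            )


class TestDifferential:
    @staticmethod
    def _pipeline(psms, cmap):
        kept, _ = psm_quality_filter(psms)
        kept, _ = reporter_filter(kept)
        table, _ = normalize_channels(rollup_protein(kept))
        return differential_abundance(table, cmap)

    def test_spiked_halving_gives_negative_two_fold(self):
        # a background of unchanged proteins keeps channel normalization
        # honest; the single spiked protein is halved in the banded channels
        base = np.full(10, 4000.0)
        down = base.copy()
        down[5:] /= 2.0
        rng = np.random.default_rng(0)
        rows = [(*GOOD, list(down))] * 3 + [
            (*GOOD, list(base * (1 + 0.05 * rng.standard_normal(10))))
            for _ in range(60)
        ]
        psms = make_psms(rows)
        psms.loc[:2, "protein_id"] = "down"
        res = self._pipeline(psms, default_channel_map()).set_index("protein_id")
        assert res.loc["down", "signed_fold"] == pytest.approx(-2.0, rel=0.03)
        flat_fc = res.drop(index="down")["log2fc"]
        assert np.abs(flat_fc).max() < 0.2  # within 5%-CV sampling noise

    def test_signed_fold_convention(self):
        assert signed_fold(1.0) == 2.0
        assert signed_fold(-1.0) == -2.0
        assert signed_fold(np.log2(1 / 4.2)) == pytest.approx(-4.2)
        assert signed_fold(0.0) == 1.0

    def test_row_permutation_invariance(self):
        psms, cmap, _ = gen_tmt_dataset(n_proteins=50, n_differential=10, seed=9)
        res1 = self._pipeline(psms, cmap).set_index("protein_id").sort_index()
        shuffled = psms.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = self._pipeline(shuffled, cmap).set_index("protein_id").sort_index()
        assert np.allclose(res1["log2fc"], res2["log2fc"])
        assert np.allclose(res1["p_value"], res2["p_value"])

    def test_group_swap_negates_log2fc(self):
        psms, cmap, _ = gen_tmt_dataset(n_proteins=40, n_differential=10, seed=10)
        swapped = {
            ch: {"sample": v["sample"],
                 "group": "banded" if v["group"] == "control" else "control"}
            for ch, v in cmap.items()
        }
        res1 = self._pipeline(psms, cmap).set_index("protein_id").sort_index()
        res2 = self._pipeline(psms, swapped).set_index("protein_id").sort_index()
        assert np.allclose(res1["log2fc"], -res2["log2fc"])
        assert np.allclose(res1["p_value"], res2["p_value"])

    def test_fdr_controlled_under_mixed_simulation(self):
        # 10% spiked proteins: the realized false-discovery proportion at
        # q = 0.05 stays within 1.5× the nominal level across seeds
        false, discoveries = 0, 0
        for seed in range(10):
            psms, cmap, truth = gen_tmt_dataset(
                n_proteins=300, n_differential=30, log2fc_magnitude=1.0,
                noise_cv=0.2, seed=200 + seed,
            )
            res = self._pipeline(psms, cmap).merge(truth, on="protein_id")
            hits = res[res.fdr < 0.05]
            discoveries += len(hits)
            false += int((~hits.is_differential).sum())
        assert discoveries > 0
        assert false / discoveries <= 0.05 * 1.5

    def test_zero_variance_flagged(self):
        psms = make_psms([(*GOOD, [600.0] * 10)])
        table = rollup_protein(reporter_filter(psms)[0])
        res = differential_abundance(table, default_channel_map())
        assert res["zero_variance"].iloc[0]
        assert res["p_value"].iloc[0] == 1.0


class TestPanel:
    def test_fixture_panel_loads_29_proteins(self):
        panel = load_emt_panel()
        assert len(panel) == 29
        assert panel["protein"].is_unique
        assert set(panel["category"]) == {
            "ecm", "cell_type_marker", "emt_regulator", "other_emt"
        }

    def test_empty_panel(self):
        results = pd.DataFrame({"protein_id": ["A"], "log2fc": [1.0]})
        matched, unmatched = annotate_panel(results, pd.DataFrame({"protein": []}))
        assert len(matched) == 0 and unmatched == []

    def test_partial_match_reports_missing(self):
        results = pd.DataFrame(
            {"protein_id": ["A", "B"], "log2fc": [0.5, -1.5]}
        )
        panel = pd.DataFrame({"protein": ["A", "B", "C"]})
        matched, unmatched = annotate_panel(results, panel)
        assert list(matched["protein"]) == ["B", "A"]  # ordered by |log2fc|
        assert unmatched == ["C"]


class TestGenerator:
    def test_channel_count_and_determinism(self):
        p1, cmap, t1 = gen_tmt_dataset(n_proteins=20, n_differential=3, seed=11)
        p2, _, t2 = gen_tmt_dataset(n_proteins=20, n_differential=3, seed=11)
        assert p1.equals(p2) and t1.equals(t2)
        assert len([c for c in p1.columns if c.startswith("reporter_")]) == 10
        assert len(cmap) == 10

    def test_truth_invariants(self):
        _, _, truth = gen_tmt_dataset(n_proteins=100, n_differential=10, seed=12)
        assert (truth.loc[~truth.is_differential, "true_log2fc"] == 0).all()
        assert truth.is_differential.sum() == 10
        assert (truth.psm_count >= 1).all()

    def test_all_zero_psm_fails_signal_filter(self):
        psms, _, _ = gen_tmt_dataset(n_proteins=5, n_differential=0,
                                     zero_rate=1.0, seed=13)
        kept, log = reporter_filter(psms)
        assert len(kept) == 0
        assert log["rejected_low_signal"] == log["input"]

    def test_too_many_differential_rejected(self):
        with pytest.raises(ValueError):
            gen_tmt_dataset(n_proteins=5, n_differential=6)
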