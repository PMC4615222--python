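"""Signed fold-change convention, concordance filters, candidate selection
and categorization, each checked against brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirkd import filters as flt
from mirkd import quantify as qt

CFG = flt.PipelineConfig()


def _table(values: dict, genotypes=None) -> qt.ExpressionTable:
    """Expression table from feature -> per-sample values (6-sample design)."""
    samples = ["parent_A_rep1", "parent_A_rep2", "parent_B_rep1", "parent_B_rep2",
               "knockdown_rep1", "knockdown_rep2"]
    design = pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": ["parent_A", "parent_A", "parent_B", "parent_B",
                         "knockdown", "knockdown"],
            "replicate": [1, 2, 1, 2, 1, 2],
        }
    )
    df = pd.DataFrame(values, index=samples).T
    df.columns = samples
    return qt.ExpressionTable(df, design)


class TestSignedFoldChange:
    def test_identity(self):
        assert flt.signed_fold_change(5.0, 5.0) == pytest.approx(1.0)

    def test_decrease_convention(self):
        # a ratio of 0.4167 is reported as a -2.4-fold change
        assert flt.signed_fold_change(0.4167, 1.0) == pytest.approx(-2.4, abs=0.01)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="both means zero"):
            flt.signed_fold_change(0.0, 0.0)
        assert flt.signed_fold_change(0.0, 0.0, pseudocount=1.0) == pytest.approx(1.0)

    def test_one_side_zero_is_infinite(self):
        assert flt.signed_fold_change(3.0, 0.0) == math.inf
        assert flt.signed_fold_change(0.0, 3.0) == -math.inf

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry(self, a, b):
        fab = flt.signed_fold_change(a, b)
        fba = flt.signed_fold_change(b, a)
        assert abs(fab) >= 1 and abs(fba) >= 1
        if abs(fab) > 1:
            assert fab == pytest.approx(-fba, rel=1e-9)


class TestParentalConcordance:
    def test_identical_parents_all_retained(self):
        expr = _table({f"f{i}": [10, 10, 10, 10, 5, 5] for i in range(8)})
        res = flt.parental_concordance(expr, CFG)
        assert len(res.retained) == 8 and not res.excluded

    def test_printed_attrition_101_of_109(self):
        """101 of 109 features within 2-fold between parents -> 92.7% retained."""
        values = {f"ok{i}": [10, 10, 12, 12, 10, 10] for i in range(101)}
        values.update({f"bad{i}": [10, 10, 25, 25, 10, 10] for i in range(8)})
        res = flt.parental_concordance(_table(values), CFG)
        assert len(res.retained) == 101
        assert round(100 * len(res.retained) / 109, 1) == 92.7

    def test_threshold_is_strict(self):
        # exactly 2-fold between parental means is not "more than 2-fold"
        res = flt.parental_concordance(_table({"f": [10, 10, 20, 20, 1, 1]}), CFG)
        assert "f" in res.retained

    def test_whitelist_retained_with_flag(self):
        expr = _table({"hit": [30, 30, 5, 5, 100, 100]})
        cfg = flt.PipelineConfig(whitelist=frozenset({"hit"}))
        res = flt.parental_concordance(expr, cfg)
        assert "hit" in res.retained and "hit" in res.whitelisted
        # without the whitelist the same feature is excluded
        res2 = flt.parental_concordance(expr, CFG)
        assert "hit" in res2.excluded

    def test_missing_parent_is_design_error(self):
        design = pd.DataFrame(
            {"sample_id": ["a", "b"], "genotype": ["parent_A", "knockdown"], "replicate": [1, 1]}
        )
        expr = qt.ExpressionTable(pd.DataFrame({"a": [1.0], "b": [1.0]}), design)
        with pytest.raises(ValueError, match="parental"):
            flt.parental_concordance(expr, CFG)


class TestReplicateConcordance:
    def test_equal_replicates_retained(self):
        res = flt.replicate_concordance(_table({"f": [10, 10, 8, 8, 5, 5]}), CFG)
        assert "f" in res.retained

    def test_discordant_pair_excluded(self):
        # replicate pair (10, 25) gives 2.5 > 2 within one genotype
        res = flt.replicate_concordance(_table({"f": [10, 25, 8, 8, 5, 5]}), CFG)
        assert "f" in res.excluded

    def test_single_replicate_warns_and_skips(self):
        design = pd.DataFrame(
            {"sample_id": ["a", "b"], "genotype": ["parent_A", "parent_B"], "replicate": [1, 1]}
        )
        expr = qt.ExpressionTable(pd.DataFrame({"a": [1.0], "b": [9.0]}), design)
        with pytest.warns(UserWarning, match="single replicate"):
            res = flt.replicate_concordance(expr, CFG)
        assert len(res.retained) == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        values = {f"f{i}": rng.uniform(1, 40, size=6).tolist() for i in range(60)}
        expr = _table(values)
        res = flt.replicate_concordance(expr, CFG)
        genotype_cols = {
            "parent_A": ["parent_A_rep1", "parent_A_rep2"],
            "parent_B": ["parent_B_rep1", "parent_B_rep2"],
            "knockdown": ["knockdown_rep1", "knockdown_rep2"],
        }
        expected_excluded = set()
        for f, row in expr.values.iterrows():
            for cols in genotype_cols.values():
                v = sorted(row[c] for c in cols)
                if v[-1] / v[0] > 2:
                    expected_excluded.add(f)
        assert set(res.excluded) == expected_excluded


class TestCandidateSelection:
    def test_change_against_all_replicates(self):
        expr = _table({"f": [2, 2.4, 2.2, 2.5, 10, 10]})
        sel = flt.candidate_selection(expr, CFG)
        assert bool(sel.loc["f", "candidate"])
        assert sel.loc["f", "min_abs_fc"] == pytest.approx(10 / 2.5)

    def test_single_failing_replicate_blocks(self):
        expr = _table({"f": [2, 2, 2, 3, 5, 5]})
        sel = flt.candidate_selection(expr, CFG)
        assert not bool(sel.loc["f", "candidate"])  # 5/3 < 2

    def test_threshold_inclusive(self):
        expr = _table({"f": [5, 5, 5, 5, 10, 10]})
        assert bool(flt.candidate_selection(expr, CFG).loc["f", "candidate"])

    def test_matches_brute_force_all_replicate_check(self):
        rng = np.random.default_rng(11)
        values = {f"f{i}": rng.uniform(1, 30, size=6).tolist() for i in range(60)}
        expr = _table(values)
        sel = flt.candidate_selection(expr, CFG)
        parents = ["parent_A_rep1", "parent_A_rep2", "parent_B_rep1", "parent_B_rep2"]
        for f, row in expr.values.iterrows():
            kd = (row["knockdown_rep1"] + row["knockdown_rep2"]) / 2
            expected = all(
                max(kd / row[p], row[p] / kd) >= 2 for p in parents
            )
            assert bool(sel.loc[f, "candidate"]) == expected

    def test_grouped_fc_uses_mean_of_four_replicates(self):
        expr = _table({"f": [1, 2, 3, 4, 10, 10]})
        sel = flt.candidate_selection(expr, CFG)
        assert sel.loc["f", "grouped_fc"] == pytest.approx(10 / 2.5)


class TestCategorize:
    def test_printed_percentage_breakdown(self):
        """67 unchanged / 29 up / 13 down of 109 -> 61.5 / 26.6 / 11.9%,
        with 11 up >=2-fold (10.1%) and 6 down >=2-fold (5.5%)."""
        fc = (
            [1.2] * 67 + [1.7] * 18 + [2.5] * 11 + [-1.7] * 7 + [-2.5] * 6
        )
        summary = flt.categorize_all({f"f{i}": v for i, v in enumerate(fc)})
        assert summary.n_total == 109
        assert summary.counts == {
            "unchanged": 67, "up_1.5": 29, "down_1.5": 13, "up_2": 11, "down_2": 6
        }
        assert summary.percentages == {
            "unchanged": 61.5, "up_1.5": 26.6, "down_1.5": 11.9, "up_2": 10.1, "down_2": 5.5
        }

    def test_all_unity_is_all_unchanged(self):
        summary = flt.categorize_all({f"f{i}": 1.0 for i in range(20)})
        assert summary.percentages["unchanged"] == 100.0

    def test_empty_summary(self):
        summary = flt.categorize_all({})
        assert summary.n_total == 0 and sum(summary.counts.values()) == 0

    def test_category_labels(self):
        assert flt.categorize(1.4) == "unchanged"
        assert flt.categorize(1.5) == "up_1.5"
        assert flt.categorize(2.0) == "up_2"
        assert flt.categorize(-1.6) == "down_1.5"
        assert flt.categorize(-3.0) == "down_2"

    @given(st.lists(st.floats(min_value=1.0, max_value=60.0), min_size=1, max_size=60),
           st.lists(st.booleans(), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_counting(self, mags, signs):
        fc = {
            f"f{i}": (m if s else -m)
            for i, (m, s) in enumerate(zip(mags, signs + [True] * len(mags)))
        }
        summary = flt.categorize_all(fc)
        vals = list(fc.values())
        assert summary.counts["unchanged"] == sum(abs(v) < 1.5 for v in vals)
        assert summary.counts["up_1.5"] == sum(v >= 1.5 for v in vals)
        assert summary.counts["down_1.5"] == sum(v <= -1.5 for v in vals)
        assert summary.counts["up_2"] == sum(v >= 2 for v in vals)
        assert summary.counts["down_2"] == sum(v <= -2 for v in vals)
        # mutually exclusive top-level bins partition the universe
        assert (
            summary.counts["unchanged"] + summary.counts["up_1.5"] + summary.counts["down_1.5"]
            == summary.n_total
        )
        assert (
            summary.percentages["unchanged"]
            + summary.percentages["up_1.5"]
            + summary.percentages["down_1.5"]
            == pytest.approx(100.0, abs=0.2)
        )
        assert summary.counts["up_2"] <= summary.counts["up_1.5"]
        assert summary.counts["down_2"] <= summary.counts["down_1.5"]


class TestMonotonicity:
    def test_raising_thresholds_never_shrinks_retained_sets(self):
        rng = np.random.default_rng(13)
        values = {f"f{i}": rng.uniform(1, 30, size=6).tolist() for i in range(50)}
        expr = _table(values)
        prev_parental = prev_replicate = None
        prev_candidates = None
        for thr in (1.5, 2.0, 3.0, 5.0):
            cfg = flt.PipelineConfig(concordance_threshold=thr, candidate_threshold=thr)
            parental = flt.parental_concordance(expr, cfg).retained
            replicate = flt.replicate_concordance(expr, cfg).retained
            sel = flt.candidate_selection(expr, cfg)
            candidates = set(sel.index[sel["candidate"]])
            if prev_parental is not None:
                assert prev_parental <= parental
                assert prev_replicate <= replicate
                assert candidates <= prev_candidates
            prev_parental, prev_replicate, prev_candidates = parental, replicate, candidates


def test_config_validation():
    with pytest.raises(ValueError):
        flt.PipelineConfig(concordance_threshold=1.0)
    with pytest.raises(ValueError):
        flt.PipelineConfig(alpha=1.5)
    with pytest.raises(ValueError):
        flt.PipelineConfig(category_thresholds=(2.0, 1.5))
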