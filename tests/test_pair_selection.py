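import numpy as np
import pandas as pd
import pytest

from slforest.boruta_core import BorutaConfig, ForestConfig
from slforest.io_depmap import OmicsMatrix
from slforest.pair_selection import (
    apply_direction_filter,
    drop_self_pairs,
    empty_pair_table,
    essentiality_filter,
    pearson,
    prioritize_pairs,
    run_cohort,
    run_target,
    scale_by_group,
    target_seed,
)

from conftest import make_matrix

FAST_B = BorutaConfig(max_iter=15, importance_method="permutation_raw")
FAST_F = ForestConfig(n_trees=30, seed=0)


def pair_row(target="T", feature="F", ftype="mutation", method="permutation_raw",
             importance=1.0, pcc=0.5):
    return {
        "target_gene": target, "feature_gene": feature, "feature_type": ftype,
        "method": method, "importance": importance, "scaled_importance": np.nan,
        "pcc": pcc, "n_samples": 100,
    }


def pairs_df(*rows):
    return pd.DataFrame(list(rows), columns=empty_pair_table().columns)


class TestPearson:
    def test_perfect_positive(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_pairwise_complete(self):
        r = pearson([1, 2, 3, np.nan, 4], [2, 4, 6, 1, np.nan])
        assert r == pytest.approx(1.0)

    def test_constant_is_nan(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_too_short(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestDropSelfPairs:
    def test_removes_self(self):
        p = pairs_df(pair_row("A", "A"), pair_row("A", "B"))
        out = drop_self_pairs(p)
        assert out["feature_gene"].tolist() == ["B"]

    def test_identity_without_self(self):
        p = pairs_df(pair_row("A", "B"), pair_row("B", "C"))
        assert len(drop_self_pairs(p)) == 2

    def test_all_self(self):
        p = pairs_df(pair_row("A", "A"), pair_row("B", "B"))
        assert drop_self_pairs(p).empty


class TestDirectionFilter:
    def test_negative_mutation_dropped(self):
        p = pairs_df(pair_row(ftype="mutation", pcc=-0.3))
        assert apply_direction_filter(p).empty

    def test_negative_expression_kept(self):
        p = pairs_df(pair_row(ftype="expression", pcc=-0.4))
        assert len(apply_direction_filter(p)) == 1

    def test_positive_expression_dropped(self):
        p = pairs_df(pair_row(ftype="expression", pcc=0.4))
        assert apply_direction_filter(p).empty

    def test_bypass(self):
        p = pairs_df(pair_row(ftype="mutation", pcc=-0.3))
        out = apply_direction_filter(p, enabled=False)
        pd.testing.assert_frame_equal(out, p)


class TestScaleByGroup:
    def test_min_max(self):
        p = pairs_df(
            pair_row(feature="a", importance=2),
            pair_row(feature="b", importance=5),
            pair_row(feature="c", importance=10),
        )
        out = scale_by_group(p)
        assert out["scaled_importance"].tolist() == pytest.approx([0.0, 0.375, 1.0])

    def test_singleton_group(self):
        out = scale_by_group(pairs_df(pair_row(importance=7)))
        assert out["scaled_importance"].tolist() == [1.0]

    def test_zero_span_group(self):
        p = pairs_df(pair_row(feature="a", importance=3), pair_row(feature="b", importance=3))
        assert scale_by_group(p)["scaled_importance"].tolist() == [1.0, 1.0]

    def test_groups_scaled_independently(self):
        p = pairs_df(
            pair_row(feature="a", ftype="mutation", importance=1),
            pair_row(feature="b", ftype="mutation", importance=3),
            pair_row(feature="a", ftype="expression", importance=10),
            pair_row(feature="b", ftype="expression", importance=30),
        )
        out = scale_by_group(p)
        assert out["scaled_importance"].tolist() == pytest.approx([0, 1, 0, 1])

    def test_rank_preserved(self):
        rng = np.random.default_rng(0)
        imps = rng.exponential(size=9)
        p = pairs_df(*(pair_row(feature=f"g{i}", importance=v) for i, v in enumerate(imps)))
        out = scale_by_group(p)
        assert (
            out.sort_values("importance")["feature_gene"].tolist()
            == out.sort_values("scaled_importance")["feature_gene"].tolist()
        )


class TestEssentialityFilter:
    def test_essential_column(self):
        dep = make_matrix([[-1.0], [-0.9], [-1.1]], ["a", "b", "c"], ["G"])
        eligible, stats = essentiality_filter(dep)
        assert eligible == []
        assert stats.at["G", "cv"] == pytest.approx(0.1)
        assert bool(stats.at["G", "is_essential"])

    def test_variable_column(self):
        dep = make_matrix([[0.1], [0.9], [0.5]], ["a", "b", "c"], ["G"])
        eligible, stats = essentiality_filter(dep)
        assert eligible == ["G"]
        assert stats.at["G", "cv"] == pytest.approx(0.8)

    def test_zero_threshold_keeps_all(self, tiny_dependency):
        eligible, _ = essentiality_filter(tiny_dependency, cv_threshold=0.0)
        assert eligible == ["ESS", "VAR"]

    def test_stats_fields(self, tiny_dependency):
        _, stats = essentiality_filter(tiny_dependency)
        assert stats.at["ESS", "median_dependency"] == pytest.approx(-1.0)
        assert stats.at["ESS", "sd"] == pytest.approx(0.1)
        assert stats.at["ESS", "range"] == pytest.approx(0.2)

    def test_zero_mean_column_non_essential(self):
        dep = make_matrix([[-1.0], [1.0]], ["a", "b"], ["G"])
        eligible, stats = essentiality_filter(dep)
        assert eligible == ["G"]
        assert np.isnan(stats.at["G", "cv"])


class TestRunTarget:
    def test_planted_mutation_recovered(self, small_cohort):
        ds = small_cohort
        out = run_target(
            "T01", ds.dependency, ds.mutation_binary, "mutation",
            "permutation_raw", bcfg=FAST_B, fcfg=FAST_F,
        )
        assert "M001" in out["feature_gene"].tolist()
        row = out[out["feature_gene"] == "M001"].iloc[0]
        assert row["pcc"] > 0
        assert row["n_samples"] == 160

    def test_null_target_mostly_empty(self, small_cohort):
        ds = small_cohort
        out = run_target(
            "T03", ds.dependency, ds.mutation_binary, "mutation",
            "permutation_raw", bcfg=FAST_B, fcfg=FAST_F,
        )
        assert len(out) <= 1  # rarely a spurious confirmation

    def test_self_column_survives_until_drop(self):
        rng = np.random.default_rng(0)
        n = 120
        dep = make_matrix(rng.normal(size=(n, 1)), [f"L{i}" for i in range(n)], ["G1"])
        feats = pd.DataFrame(
            {"G1": dep.data["G1"] * 1.0, "G2": rng.normal(size=n)}, index=dep.data.index
        )
        fm = OmicsMatrix(data=feats, kind="expression")
        out = run_target("G1", dep, fm, "expression", "gini",
                         bcfg=BorutaConfig(max_iter=15, importance_method="gini"),
                         fcfg=FAST_F)
        assert "G1" in out["feature_gene"].tolist()  # self-pair present pre-filter
        assert "G1" not in drop_self_pairs(out)["feature_gene"].tolist()

    def test_missing_target_errors(self, small_cohort):
        ds = small_cohort
        with pytest.raises(KeyError):
            run_target("NOPE", ds.dependency, ds.mutation_binary, "mutation",
                       "permutation_raw", bcfg=FAST_B, fcfg=FAST_F)


class TestRunCohort:
    def test_empty_target_list(self, small_cohort):
        ds = small_cohort
        pairs, stats = run_cohort([], ds.dependency, ds.mutation_binary,
                                  ds.expression, ["gini"])
        assert pairs.empty
        assert len(stats) == ds.dependency.shape[1]

    def test_method_bookkeeping(self, small_cohort):
        ds = small_cohort
        pairs, _ = run_cohort(
            ["T01"], ds.dependency, ds.mutation_binary, None,
            ["gini", "gini_corrected"],
            bcfg=BorutaConfig(max_iter=12), fcfg=ForestConfig(n_trees=25),
            master_seed=3,
        )
        if not pairs.empty:
            assert set(pairs["method"]) <= {"gini", "gini_corrected"}
            for _, g in pairs.groupby(["method", "feature_type"]):
                assert g["scaled_importance"].max() == pytest.approx(1.0)

    def test_deterministic(self, small_cohort):
        ds = small_cohort
        kwargs = dict(
            targets=["T01", "T02"], dep=ds.dependency, mut_matrix=ds.mutation_binary,
            expr_matrix=ds.expression, methods=["permutation_raw"],
            bcfg=FAST_B, fcfg=ForestConfig(n_trees=25), master_seed=9,
        )
        p1, s1 = run_cohort(**kwargs)
        p2, s2 = run_cohort(**kwargs)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_direction_filter_applied(self, small_cohort):
        ds = small_cohort
        pairs, _ = run_cohort(
            ["T01", "T02"], ds.dependency, ds.mutation_binary, ds.expression,
            ["permutation_raw"], bcfg=FAST_B, fcfg=ForestConfig(n_trees=25),
            master_seed=4,
        )
        mut = pairs[pairs["feature_type"] == "mutation"]
        expr = pairs[pairs["feature_type"] == "expression"]
        assert (mut["pcc"] > 0).all()
        assert (expr["pcc"] < 0).all()


def test_target_seed_stable_and_distinct():
    a = target_seed(1, "T01", "mutation", "gini")
    assert a == target_seed(1, "T01", "mutation", "gini")
    assert a != target_seed(1, "T01", "expression", "gini")
    assert a != target_seed(2, "T01", "mutation", "gini")


def test_prioritize_drops_essential_targets():
    p = pairs_df(pair_row("A", "x", importance=1.0), pair_row("B", "y", importance=2.0))
    p["scaled_importance"] = [0.2, 0.9]
    p["target_essential"] = [True, False]
    out = prioritize_pairs(p)
    assert out["target_gene"].tolist() == ["B"]
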