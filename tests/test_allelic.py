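"""The bi-allelic-position statistic and its downstream comparisons."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from xaquant import allelic
from xaquant.allelic import CallParams, call_biallelic, threshold_sweep
from xaquant.datasets import AlleleCountTable
from xaquant.synth_scrna import ScrnaSimConfig, simulate_allele_counts, simulate_expression

from conftest import random_allele_table, tiny_expression_dataset


def _one_cell_table(counts):
    rows = [
        ("c0", "X", (i + 1) * 10, "g0", ref, alt) for i, (ref, alt) in enumerate(counts)
    ]
    return AlleleCountTable(
        pd.DataFrame(
            rows, columns=["cell_id", "chrom", "pos", "gene", "ref_count", "alt_count"]
        )
    )


def brute_force_summary(table, params):
    """Record-by-record scan, independent of the vectorized implementation."""
    out = {}
    for _, row in table.records.iterrows():
        key = (row["cell_id"], row["chrom"])
        n_cov, n_bi = out.get(key, (0, 0))
        depth = row["ref_count"] + row["alt_count"]
        if depth >= params.min_total_reads:
            n_cov += 1
            if min(row["ref_count"], row["alt_count"]) / depth >= params.ratio_threshold - 1e-12:
                n_bi += 1
        out[key] = (n_cov, n_bi)
    return out


def test_worked_example_boundary_inclusive():
    # ratios 0.5, 0.05, 0.20: the 0.20 boundary counts as bi-allelic
    table = _one_cell_table([(10, 10), (19, 1), (8, 2)])
    params = CallParams(ratio_threshold=0.2, min_total_reads=5, min_positions=1)
    s = call_biallelic(table, params)
    assert len(s) == 1
    assert s.loc[0, "n_covered"] == 3
    assert s.loc[0, "n_biallelic"] == 2
    assert s.loc[0, "score"] == pytest.approx(2 / 3)
    # raising the threshold past the boundary drops the boundary position
    s2 = call_biallelic(table, dataclasses.replace(params, ratio_threshold=0.25))
    assert s2.loc[0, "n_biallelic"] == 1


def test_depth_filter_excludes_shallow_positions():
    table = _one_cell_table([(2, 2), (10, 10)])
    s = call_biallelic(table, CallParams(min_total_reads=5, min_positions=1))
    assert s.loc[0, "n_covered"] == 1 and s.loc[0, "n_biallelic"] == 1


def test_sparse_cells_flagged_missing_not_zero():
    table = _one_cell_table([(10, 10)])
    s = call_biallelic(table, CallParams(min_positions=5))
    assert not s.loc[0, "defined"]
    assert np.isnan(s.loc[0, "score"])
    assert s.loc[0, "n_covered"] == 1  # counts still reported


def test_empty_table_gives_empty_summary():
    empty = AlleleCountTable()
    assert len(call_biallelic(empty, CallParams())) == 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        CallParams(ratio_threshold=0.0)
    with pytest.raises(ValueError):
        CallParams(ratio_threshold=0.6)
    with pytest.raises(ValueError):
        CallParams(min_total_reads=0)


@pytest.mark.parametrize("seed", range(10))
def test_caller_matches_brute_force_scan(seed):
    rng = np.random.default_rng(seed)
    table = random_allele_table(rng)
    params = CallParams(
        ratio_threshold=float(rng.uniform(0.05, 0.5)),
        min_total_reads=int(rng.integers(1, 10)),
        min_positions=1,
    )
    s = call_biallelic(table, params).set_index(["cell_id", "chrom"])
    oracle = brute_force_summary(table, params)
    assert set(s.index) == set(oracle)
    for key, (n_cov, n_bi) in oracle.items():
        assert s.loc[key, "n_covered"] == n_cov
        assert s.loc[key, "n_biallelic"] == n_bi


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_threshold_sweep_monotone_and_coverage_constant(seed):
    rng = np.random.default_rng(seed)
    table = random_allele_table(rng, n_cells=2, n_pos=10)
    thresholds = [0.05, 0.2, 0.4, 0.5]
    sweep = threshold_sweep(table, thresholds, CallParams(min_positions=1))
    for _, grp in sweep.groupby(["cell_id", "chrom"]):
        grp = grp.sort_values("ratio_threshold")
        assert (np.diff(grp["n_biallelic"]) <= 0).all()
        assert grp["n_covered"].nunique() == 1


def test_sweep_error_calls_vanish_by_threshold_0p3():
    """Sequencing errors inflate low-threshold calls only."""
    base = ScrnaSimConfig(
        stages=("E4",),
        zga_stage="E4",
        n_embryos_per_stage=3,
        cells_per_embryo=10,
        sex_ratio=1.0,
        biallelic_fraction_by_stage={"E4": 0.0},
        autosomal_biallelic_fraction=0.0,
        n_positions_per_chrom={"X": 150},
        n_genes_per_chrom={"X": 15},
        lineage_onset_stage=None,
        coverage_mean=40.0,
        seed=3,
    )
    def total_calls(error_rate, thr):
        cfg = dataclasses.replace(base, error_rate=error_rate)
        table = simulate_allele_counts(simulate_expression(cfg), cfg)
        sweep = threshold_sweep(table, [thr], CallParams(min_positions=1))
        return sweep["n_biallelic"].sum()

    low = total_calls(0.05, 0.05)
    assert low > 20 * max(total_calls(0.0, 0.05), 1)
    assert total_calls(0.05, 0.3) < 0.02 * low  # excess essentially gone by 0.3


def test_normalization_by_depth_option():
    table = _one_cell_table([(10, 10), (19, 1), (8, 2)])
    s = call_biallelic(
        table, CallParams(min_positions=1, normalization="depth")
    )
    assert s.loc[0, "score"] == pytest.approx(2 / 50)


def test_group_comparison_requires_two_defined_scores():
    with pytest.raises(ValueError):
        allelic.compare_score_groups([0.1], [0.2, 0.3])


def test_stage_trend_perfectly_decreasing_scores():
    summary = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "chrom": ["X"] * 6,
            "n_covered": [10] * 6,
            "n_biallelic": [6, 5, 4, 3, 2, 1],
            "score": [0.6, 0.5, 0.4, 0.3, 0.2, 0.1],
            "defined": [True] * 6,
        }
    )
    stages = {f"c{i}": f"s{i}" for i in range(6)}
    with pytest.raises(ValueError):  # single-cell stages cannot be pair-tested
        allelic.stage_trend(summary, stages, [f"s{i}" for i in range(6)])
    # two cells per stage, strictly decreasing across stages
    stages = {f"c{i}": f"s{i // 2}" for i in range(6)}
    trend = allelic.stage_trend(summary, stages, ["s0", "s1", "s2"])
    # hand check: ranks of stage (1.5,1.5,3.5,3.5,5.5,5.5) vs score ranks
    # (6,5,4,3,2,1) -> Pearson on ranks = -0.956183
    assert trend["trend_spearman"] == pytest.approx(-0.956183, abs=1e-6)
    assert list(trend["per_stage"]["median"]) == pytest.approx([0.55, 0.35, 0.15])


def test_stage_trend_identical_distributions_give_p_one():
    summary = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(8)],
            "chrom": ["X"] * 8,
            "n_covered": [10] * 8,
            "n_biallelic": [2] * 8,
            "score": [0.2] * 8,
            "defined": [True] * 8,
        }
    )
    stages = {f"c{i}": f"s{i // 4}" for i in range(8)}
    trend = allelic.stage_trend(summary, stages, ["s0", "s1"])
    assert (trend["adjacent_tests"]["p_value"] == 1.0).all()


def test_stage_with_no_scores_is_skipped_with_warning():
    summary = pd.DataFrame(
        {
            "cell_id": ["c0", "c1", "c2", "c3"],
            "chrom": ["X"] * 4,
            "n_covered": [10] * 4,
            "n_biallelic": [1, 2, 3, 4],
            "score": [0.1, 0.2, 0.3, 0.4],
            "defined": [True] * 4,
        }
    )
    stages = {"c0": "s0", "c1": "s0", "c2": "s2", "c3": "s2"}
    with pytest.warns(UserWarning, match="s1"):
        trend = allelic.stage_trend(summary, stages, ["s0", "s1", "s2"])
    assert trend["skipped_stages"] == ["s1"]


def test_focal_status_strict_threshold():
    values = np.array([[1.0, 0.0, 2.0], [1.0, 0.5, 2.0], [1.0, 0.6, 2.0]])
    dataset = tiny_expression_dataset(values)
    status = allelic.classify_focal_status(dataset, "g1", expr_threshold=0.5)
    assert list(status) == ["negative", "negative", "positive"]
    status0 = allelic.classify_focal_status(dataset, "g1")
    assert list(status0) == ["negative", "positive", "positive"]
    with pytest.raises(KeyError, match="nosuch"):
        allelic.classify_focal_status(dataset, "nosuch")


def test_correlation_null_hand_oracle():
    # 5 cells; partners: g1 = perfect monotone copy, g2 anti, g3 shuffled
    values = np.array(
        [
            [1.0, 2.0, 10.0, 3.0],
            [2.0, 4.0, 8.0, 1.0],
            [3.0, 6.0, 6.0, 4.0],
            [4.0, 8.0, 4.0, 2.0],
            [5.0, 10.0, 2.0, 5.0],
        ]
    )
    dataset = tiny_expression_dataset(values)
    null = allelic.correlation_null(dataset, "g0", ["g1", "g2", "g3"], "g1")
    expected = {
        g: scipy.stats.spearmanr(values[:, 0], values[:, i]).statistic
        for g, i in [("g1", 1), ("g2", 2), ("g3", 3)]
    }
    for g, r in expected.items():
        assert null.r_values[g] == pytest.approx(r, abs=1e-12)
    assert null.focal_r == pytest.approx(1.0)
    assert null.focal_quantile == 1.0
    assert null.median_r == pytest.approx(np.median(list(expected.values())))


def test_correlation_null_excludes_constant_partners():
    values = np.array([[1.0, 2.0, 7.0], [2.0, 4.0, 7.0], [3.0, 6.0, 7.0]])
    dataset = tiny_expression_dataset(values)
    null = allelic.correlation_null(dataset, "g0", ["g1", "g2"], "g1")
    assert null.excluded_partners == ["g2"]
    assert "g2" not in null.r_values


def test_correlation_null_preconditions():
    values = np.arange(8.0).reshape(2, 4)
    dataset = tiny_expression_dataset(values)
    with pytest.raises(ValueError, match=">= 3 cells"):
        allelic.correlation_null(dataset, "g0", ["g1"], "g1")
    values = np.arange(12.0).reshape(3, 4)
    dataset = tiny_expression_dataset(values)
    with pytest.raises(ValueError, match="partner_set"):
        allelic.correlation_null(dataset, "g0", [], "g1")
    with pytest.raises(ValueError, match="focal"):
        allelic.correlation_null(dataset, "g0", ["g1"], "g2")


def test_gene_calls_pooling_and_uninformative_contract():
    rows = [
        # gene gA: two informative positions, one balanced -> biallelic
        ("c0", "X", 10, "gA", 5, 5),
        ("c1", "X", 10, "gA", 5, 5),
        ("c0", "X", 20, "gA", 10, 0),
        # gene gB: two informative, none balanced -> monoallelic
        ("c0", "X", 30, "gB", 10, 0),
        ("c0", "X", 40, "gB", 0, 10),
        # gene gC: one informative position only -> uninformative
        ("c0", "X", 50, "gC", 10, 0),
    ]
    table = AlleleCountTable(
        pd.DataFrame(
            rows, columns=["cell_id", "chrom", "pos", "gene", "ref_count", "alt_count"]
        )
    )
    calls = allelic.gene_allelic_calls(table, CallParams(), per_gene_min_positions=2)
    assert calls.loc["gA", "call"] == "biallelic"
    assert calls.loc["gB", "call"] == "monoallelic"
    assert calls.loc["gC", "call"] == "uninformative"

    comparison = allelic.compare_gene_calls(calls, calls)
    assert comparison["table"] == [[1, 1], [1, 1]]  # gC excluded
    assert comparison["p_value"] == 1.0

    empty = allelic.gene_allelic_calls(AlleleCountTable(), CallParams())
    with pytest.raises(ValueError, match="informative"):
        allelic.compare_gene_calls(calls, empty)


def test_assign_lineages_argmax_of_marker_panel():
    values = np.array([[1.0, 1.0, 9.0, 1.0], [1.0, 1.0, 1.0, 9.0]])
    dataset = tiny_expression_dataset(values)
    panel = {"TE": ["g2"], "EPI": ["g3"]}
    assert list(allelic.assign_lineages(dataset, panel)) == ["TE", "EPI"]
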