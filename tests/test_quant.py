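"""Ingestion, aggregation, fold changes, tests and correlation matrices."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from dvomics import quant
from dvomics.quant import ParseError, TableLayout


def _write_maxquant(tmp_path, rows, extra_cols=()):
    cols = ["Protein IDs"] + [
        f"LFQ intensity {g}_{b}_{t}"
        for g in ("WT", "D")
        for b in (1,)
        for t in (1, 2)
    ] + list(extra_cols)
    df = pd.DataFrame(rows, columns=cols)
    path = tmp_path / "proteinGroups.txt"
    df.to_csv(path, sep="\t", index=False)
    return path


def test_load_intensity_table_conventions(tmp_path):
    path = _write_maxquant(
        tmp_path,
        [
            ["P1", 1024.0, 0.0, 2048.0, 2048.0, "", ""],
            ["REV1", 100.0, 100.0, 100.0, 100.0, "+", ""],
            ["CON1", 100.0, 100.0, 100.0, 100.0, "", "+"],
        ],
        extra_cols=["Reverse", "Potential contaminant"],
    )
    m = quant.load_intensity_table(path)
    assert list(m.index) == ["P1"]  # decoys and contaminants dropped
    assert m.loc["P1", ("WT", 1, 1)] == 10.0  # log2(1024)
    assert np.isnan(m.loc["P1", ("WT", 1, 2)])  # zero -> missing


def test_load_rejects_unknown_genotype(tmp_path):
    df = pd.DataFrame({"Protein IDs": ["P1"], "LFQ intensity XX_1_1": [1.0]})
    path = tmp_path / "bad.txt"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(ParseError, match="XX_1_1"):
        quant.load_intensity_table(path)


def test_aggregate_means_counts_and_column_order_invariance():
    m = make_matrix({
        "P1": {("WT", 1, 1): 10.0, ("WT", 1, 2): 12.0, ("D", 1, 1): 9.5},
        "P2": {("D", 1, 1): 8.0},
    })
    agg = quant.aggregate_replicates(m)
    assert agg.loc["P1", ("mean", "WT")] == 11.0
    assert agg.loc["P1", ("n", "WT")] == 2
    assert agg.loc["P2", ("n", "WT")] == 0
    assert np.isnan(agg.loc["P2", ("mean", "WT")])
    assert agg.loc["P2", ("mean", "D")] == 8.0  # single value
    shuffled = m[m.columns[::-1]]
    pd.testing.assert_frame_equal(
        quant.aggregate_replicates(shuffled).sort_index(axis=1),
        agg.sort_index(axis=1),
    )


def test_fold_changes_and_status_flags():
    m = make_matrix({
        "P1": {("WT", 1, 1): 10.0, ("D", 1, 1): 12.0, ("L", 1, 1): 10.0},
        "P2": {("WT", 1, 1): 10.0},
        "P3": {("D", 1, 1): 10.0},
    })
    fc = quant.fold_changes(quant.aggregate_replicates(m))
    assert fc.fc.loc["P1", "D"] == 2.0
    assert fc.fc.loc["P1", "L"] == 0.0
    assert np.isnan(fc.fc.loc["P2", "D"])
    assert fc.status.loc["P2", "D"] == "undetected-in-mutant"
    assert fc.status.loc["P3", "D"] == "undetected-in-WT"


def test_pairwise_tests_bh_and_degenerate_groups():
    rng = np.random.default_rng(0)
    m = make_matrix({
        "sep": {("WT", 1, t): 0.0 + 1e-6 * rng.random() for t in (1, 2, 3)}
        | {("D", 1, t): 5.0 + 1e-6 * rng.random() for t in (1, 2, 3)},
        "same": {("WT", 1, t): 1.0 for t in (1, 2, 3)}
        | {("D", 1, t): 1.0 for t in (1, 2, 3)},
        "short": {("WT", 1, 1): 1.0, ("D", 1, 1): 2.0},
    })
    res = quant.pairwise_tests(m, [("WT", "D")])
    block = res["WT_vs_D"]
    assert block.loc["sep", "p"] < 1e-6
    assert block.loc["same", "p"] == 1.0 and block.loc["same", "flagged"]
    assert block.loc["short", "flagged"] and np.isnan(block.loc["short", "p"])


def test_benjamini_hochberg_hand_example():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
    assert np.allclose(adj, [0.03, 0.03, 0.03])


def test_anova_null_entity_q_near_one():
    rng = np.random.default_rng(1)
    values = {
        f"P{i}": {
            (g, b, t): 20.0 + rng.normal(0, 0.3)
            for g in ("WT", "D", "L")
            for b in (1,)
            for t in (1, 2, 3)
        }
        for i in range(50)
    }
    m = make_matrix(values)
    res = quant.anova_permutation_fdr(m, s0=0.1, n_perm=100, seed=3)
    assert res["q"].min() > 0.1  # nothing stands out among null entities
    # s0 -> infinity kills all significance
    res_inf = quant.anova_permutation_fdr(m, s0=1e9, n_perm=50, seed=3)
    assert not res_inf["significant"].any()
    assert np.allclose(res_inf["d"], 0.0, atol=1e-6)


def test_anova_detects_separated_entity_and_is_seed_stable():
    rng = np.random.default_rng(2)
    values = {}
    for i in range(30):
        shift = 5.0 if i == 0 else 0.0
        values[f"P{i}"] = {
            (g, 1, t): 20.0 + (shift if g == "D" and i == 0 else 0.0)
            + rng.normal(0, 0.2)
            for g in ("WT", "D", "L")
            for t in (1, 2, 3)
        }
    m = make_matrix(values)
    r1 = quant.anova_permutation_fdr(m, n_perm=100, seed=5)
    r2 = quant.anova_permutation_fdr(m, n_perm=100, seed=5)
    pd.testing.assert_frame_equal(r1, r2)
    assert r1.loc["P0", "q"] == r1["q"].min()
    assert r1.loc["P0", "significant"]
    # q monotone in the moderated statistic
    srt = r1.dropna().sort_values("d")
    assert (np.diff(srt["q"]) <= 1e-12).all()


def test_replicate_correlation_matrix_matches_bruteforce():
    rng = np.random.default_rng(4)
    values = {
        f"P{i}": {("WT", 1, t): rng.normal(20, 2) for t in (1, 2, 3)}
        for i in range(40)
    }
    m = make_matrix(values)
    m[("WT", 1, 4)] = -m[("WT", 1, 1)]  # anti-correlated synthetic replicate
    corr, order = quant.replicate_correlation_matrix(m)
    assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)
    assert corr.loc[("WT", 1, 1), ("WT", 1, 4)] == pytest.approx(-1.0)
    # brute force pairwise Pearson
    for a in m.columns:
        for b in m.columns:
            expected = np.corrcoef(m[a], m[b])[0, 1]
            assert corr.loc[a, b] == pytest.approx(expected)
    assert set(order) == set(m.columns)


def test_correlation_requires_complete_cases():
    m = make_matrix({"P1": {("WT", 1, 1): 1.0, ("WT", 1, 2): np.nan}})
    with pytest.raises(ValueError):
        quant.replicate_correlation_matrix(m)
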