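"""Thresholds, trichotomization, z-scores and DV cluster labelling."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from dvomics import clustering, quant
from dvomics.clustering import (
    COMPARISONS,
    ThresholdReport,
    TrichotomizedProfile,
)
from dvomics.quant import FoldChangeTable
from dvomics.simulate import ConfigurationError

PROTEOME_Q3 = {
    ("D", 1): 0.543, ("D", 2): 0.492, ("L", 1): 0.471,
    ("Vsp", 1): 0.463, ("Vsp", 2): 0.481, ("Vtl", 1): 0.565,
}
PHOSPHO_Q3 = {("D", 1): 0.405, ("L", 1): 0.366, ("Vsp", 1): 0.377, ("Vtl", 1): 0.259}


def test_threshold_is_mean_of_group_q3():
    report = ThresholdReport.from_q3(PROTEOME_Q3)
    assert report.threshold == pytest.approx(np.mean(list(PROTEOME_Q3.values())))


def test_fc_threshold_zero_for_identical_tech_reps():
    m = make_matrix({
        f"P{i}": {("D", 1, t): 20.0 + i for t in (1, 2, 3)} for i in range(5)
    })
    wt = pd.Series({f"P{i}": 19.0 for i in range(5)})
    report = clustering.fc_threshold(m, wt)
    assert report.threshold == 0.0
    assert set(report.q3) == {("D", 1)}


def test_fc_threshold_matches_manual_stdev_quartile():
    rng = np.random.default_rng(8)
    vals = rng.normal(20, 1, (30, 3))
    m = make_matrix({
        f"P{i}": {("D", 1, t + 1): vals[i, t] for t in range(3)}
        for i in range(30)
    })
    wt = pd.Series({f"P{i}": 20.0 for i in range(30)})
    report = clustering.fc_threshold(m, wt)
    expected = np.percentile(vals.std(axis=1, ddof=1), 75)
    assert report.q3[("D", 1)] == pytest.approx(expected)


def _fc_table(fcs, statuses=None):
    fc = pd.DataFrame(fcs, columns=COMPARISONS).rename_axis("entity")
    status = pd.DataFrame(
        statuses if statuses is not None else "detected",
        index=fc.index,
        columns=COMPARISONS,
    )
    return FoldChangeTable(fc=fc, status=status)


def test_trichotomize_thresholds_and_imputation():
    fc = _fc_table([[0.6, -0.2, 0.0, np.nan], [0.2, 0.1, 0.0, 0.0]])
    fc.status.loc[0, "Vsp"] = "undetected-in-mutant"
    fc.status.loc[1, :] = "undetected-in-WT"
    tri = clustering.trichotomize(fc, 0.5)
    assert list(tri.values.index) == [0]  # undetected-in-WT excluded
    assert tri.values.loc[0].tolist() == [1, 0, 0, -1]
    assert tri.provenance.loc[0, "Vsp"] == "imputed-undetected"
    with pytest.raises(ConfigurationError):
        clustering.trichotomize(fc, 0.0)


def test_trichotomize_odd_under_fc_negation():
    rng = np.random.default_rng(3)
    fcs = rng.normal(0, 1, (50, 4))
    t1 = clustering.trichotomize(_fc_table(fcs), 0.5).values
    t2 = clustering.trichotomize(_fc_table(-fcs), 0.5).values
    assert (t1.to_numpy() == -t2.to_numpy()).all()


def test_filter_profiles_rules():
    tri = clustering.trichotomize(
        _fc_table([[0, 0, 0, 0], [1, 1, 1, 1], [-1, -1, -1, -1], [1, 0, -1, 0]]),
        0.5,
    )
    # scale so the trichotomized values equal the raw ones
    tri = TrichotomizedProfile(
        values=pd.DataFrame(
            [[0, 0, 0, 0], [1, 1, 1, 1], [-1, -1, -1, -1], [1, 0, -1, 0]],
            columns=COMPARISONS,
        ),
        provenance=tri.provenance,
    )
    kept, tallies = clustering.filter_profiles(tri)
    assert tallies == {
        "unchanged": 1, "uniform_up": 1, "uniform_down": 1, "retained": 1,
    }
    assert kept.values.iloc[0].tolist() == [1, 0, -1, 0]


@pytest.mark.parametrize(
    "profile,expected",
    [
        ((1, 0, 0), (1.1547, -0.5774, -0.5774)),
        ((0, -1, -1), (1.1547, -0.5774, -0.5774)),
        ((1, -1, 0, 0), (1.2247, -1.2247, 0.0, 0.0)),
    ],
)
def test_row_zscore_worked_examples(profile, expected):
    assert np.allclose(clustering.row_zscore(profile), expected, atol=5e-5)


def test_row_zscore_mean_zero_unit_sd_and_constant_raises():
    rng = np.random.default_rng(5)
    z = clustering.row_zscore(rng.integers(-1, 2, (20, 4)).astype(float) + rng.random((20, 4)))
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=1, ddof=1), 1.0)
    with pytest.raises(ValueError):
        clustering.row_zscore([1, 1, 1, 1])


def test_zscores_equate_shifted_profiles():
    """(1,0,0,0) and (0,-1,-1,-1) express the same relative differences, so
    clustering must operate on z-scores, not raw signs."""
    z1 = clustering.row_zscore([1, 0, 0, 0])
    z2 = clustering.row_zscore([0, -1, -1, -1])
    assert np.allclose(z1, z2)


@pytest.mark.parametrize(
    "pattern,category,consistent",
    [
        ((-1, -1, 1, 1), "V", True),
        ((1, 1, -1, -1), "DL", True),
        ((-1, -1, 1, 0), "V", False),
        ((1, -1, -1, -1), "D", True),
        ((0, -1, 0, 0), "DV", True),
    ],
)
def test_regulation_category(pattern, category, consistent):
    assert clustering.regulation_category(pattern) == (category, consistent)


def test_regulation_category_ambiguous_raises():
    with pytest.raises(ValueError):
        clustering.regulation_category((1, 1, 1, 1))


def _profiles(rows):
    return TrichotomizedProfile(
        values=pd.DataFrame(rows, columns=COMPARISONS).rename_axis("entity"),
        provenance=pd.DataFrame("thresholded", index=range(len(rows)), columns=COMPARISONS),
    )


def test_identical_profiles_cocluster_and_row_order_invariance():
    rows = [[1, -1, -1, -1]] * 3 + [[-1, 1, -1, -1]] * 3 + [[0, 0, 1, 1]] * 3
    prof = _profiles(rows)
    out = clustering.hierarchical_cluster(prof, k=3)
    labels = out["cluster"].to_numpy()
    assert len(set(labels[:3])) == 1 and len(set(labels[3:6])) == 1
    shuffled = TrichotomizedProfile(
        values=prof.values.sample(frac=1, random_state=1),
        provenance=prof.provenance,
    )
    out2 = clustering.hierarchical_cluster(shuffled, k=3)
    joined = out.join(out2, rsuffix="_s")
    # same partition of entities regardless of row order
    for a in joined.index:
        for b in joined.index:
            same1 = joined.loc[a, "cluster"] == joined.loc[b, "cluster"]
            same2 = joined.loc[a, "cluster_s"] == joined.loc[b, "cluster_s"]
            assert same1 == same2


def test_exact_mode_duplicates_do_not_change_partition():
    rows = [[1, -1, -1, -1], [-1, 1, -1, -1], [0, 0, 1, 1]]
    out1 = clustering.hierarchical_cluster(_profiles(rows), k=3, exact=True)
    out2 = clustering.hierarchical_cluster(_profiles(rows + rows), k=3, exact=True)
    for i, row in enumerate(rows):
        assert out2["cluster"].iloc[i] == out2["cluster"].iloc[i + 3]
    assert out1["category"].tolist() == out2["category"].iloc[:3].tolist()


def test_k_larger_than_distinct_profiles_raises():
    with pytest.raises(ConfigurationError):
        clustering.hierarchical_cluster(_profiles([[1, 0, 0, 0]] * 5), k=3)


def test_ventral_inconsistent_cluster_flagged():
    rows = [[-1, -1, 1, 1]] * 4 + [[-1, -1, 1, 0]] * 4
    out = clustering.hierarchical_cluster(_profiles(rows), k=2)
    by_cluster = out.groupby("cluster").first()
    flags = set(zip(by_cluster["category"], by_cluster["consistent"]))
    assert ("V", True) in flags and ("V", False) in flags
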