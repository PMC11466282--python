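"""Variability-derived fold-change thresholds and trichotomized DV clustering.

The fold-change threshold is derived from technical-replicate variability: for
each biological replicate of each mutant genotype, the log2 FC of every
technical replicate against the wild-type mean is computed per entity, the
standard deviation of those FCs summarizes the entity's technical spread, and
the third quartile (Q3) of the per-entity spread distribution captures 75% of
the variability of that replicate group. The threshold is the mean of the Q3
values across groups.

Fold changes are then trichotomized to {-1, 0, +1} (direction of change only),
uninformative profiles removed, rows z-scored (sample standard deviation, so
profiles expressing the same relative differences such as (1,0,0) and
(0,-1,-1) coincide), and hierarchically clustered with average linkage on
Euclidean distance. Clusters are labelled with a regulation category: the set
of DV regions in which the cluster's consensus profile is maximal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .quant import FoldChangeTable
from .simulate import MUTANTS, ConfigurationError

COMPARISONS = list(MUTANTS)  # (D, L, Vtl, Vsp) vs WT


@dataclass
class ThresholdReport:
    """Per-replicate-group Q3 of FC standard deviations and their mean."""

    q3: dict  # (genotype, bio_rep) or label -> Q3 value
    threshold: float

    @classmethod
    def from_q3(cls, q3: dict) -> "ThresholdReport":
        return cls(q3=dict(q3), threshold=threshold_from_q3(q3.values()))


def threshold_from_q3(q3_values) -> float:
    """FC threshold = arithmetic mean of the per-group Q3 values."""
    values = list(q3_values)
    if not values:
        raise ConfigurationError("no Q3 values")
    return float(np.mean(values))


def fc_threshold(
    m: pd.DataFrame, wt_means: pd.Series, min_tech: int = 2
) -> ThresholdReport:
    """Derive the FC threshold from technical-replicate variability.

    For each (mutant genotype, biological replicate) group: per entity, the
    log2 FC of each technical replicate against the WT mean; the sample
    standard deviation across those FCs; and the Q3 (75th percentile, linear
    interpolation) of the resulting stdev distribution. The threshold is the
    mean of the group Q3 values. Entities need >= ``min_tech`` technical
    replicates with a value to contribute; groups with no such entity are
    skipped with a warning.
    """
    import warnings

    q3 = {}
    genotypes = [g for g in m.columns.get_level_values("genotype").unique() if g != "WT"]
    for g in genotypes:
        block = m[g]
        for bio in block.columns.get_level_values("bio_rep").unique():
            tech = block.xs(bio, axis=1, level="bio_rep")
            counts = tech.notna().sum(axis=1)
            usable = counts >= min_tech
            if not usable.any():
                warnings.warn(f"group ({g}, {bio}) has no entity with >= "
                              f"{min_tech} technical replicates; skipped")
                continue
            fcs = tech.sub(wt_means, axis=0)
            stdev = fcs[usable].std(axis=1, ddof=1).dropna()
            q3[(g, int(bio))] = float(np.percentile(stdev.to_numpy(), 75))
    if not q3:
        raise ConfigurationError("no usable replicate groups")
    return ThresholdReport(q3=q3, threshold=threshold_from_q3(q3.values()))


@dataclass
class TrichotomizedProfile:
    """Per-entity {-1, 0, +1} vector over the four mutant-vs-WT comparisons."""

    values: pd.DataFrame  # entity x comparison in {-1, 0, 1}
    provenance: pd.DataFrame  # "thresholded" or "imputed-undetected"


def trichotomize(fc: FoldChangeTable, threshold: float) -> TrichotomizedProfile:
    """Assign +1 / -1 / 0 per comparison from the FC and the threshold.

    +1 if FC > threshold, -1 if FC < -threshold, 0 otherwise. Entities
    undetected in a mutant are assigned -1 (they behave like regionally
    absent proteins) with provenance "imputed-undetected"; entities
    undetected in the wild type are excluded entirely.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    detected_wt = ~(fc.status == "undetected-in-WT").any(axis=1)
    fcv = fc.fc.loc[detected_wt, COMPARISONS]
    status = fc.status.loc[detected_wt, COMPARISONS]
    values = pd.DataFrame(0, index=fcv.index, columns=COMPARISONS, dtype=int)
    values[fcv > threshold] = 1
    values[fcv < -threshold] = -1
    imputed = status == "undetected-in-mutant"
    values[imputed] = -1
    provenance = pd.DataFrame(
        np.where(imputed, "imputed-undetected", "thresholded"),
        index=fcv.index,
        columns=COMPARISONS,
    )
    return TrichotomizedProfile(values=values, provenance=provenance)


def filter_profiles(
    profiles: TrichotomizedProfile,
) -> tuple[TrichotomizedProfile, dict]:
    """Remove all-zero (unchanged) and uniformly +1 / -1 profiles."""
    v = profiles.values
    all_zero = (v == 0).all(axis=1)
    all_up = (v == 1).all(axis=1)
    all_down = (v == -1).all(axis=1)
    keep = ~(all_zero | all_up | all_down)
    tallies = {
        "unchanged": int(all_zero.sum()),
        "uniform_up": int(all_up.sum()),
        "uniform_down": int(all_down.sum()),
        "retained": int(keep.sum()),
    }
    return (
        TrichotomizedProfile(values=v[keep], provenance=profiles.provenance[keep]),
        tallies,
    )


def row_zscore(values) -> np.ndarray:
    """Row z-scores with sample (n-1) standard deviation.

    Constant rows are a contract violation (they cannot occur after
    ``filter_profiles``) and raise.
    """
    x = np.asarray(values, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance row passed to row_zscore")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return z[0] if single else z


def regulation_category(pattern) -> tuple[str, bool]:
    """Regulation category and ventral-consistency of a consensus sign pattern.

    The category is the set of DV regions (D, L, V) whose component attains
    the pattern's strict maximum; the ventral axis counts if either
    ventralized genotype attains it. Consistent iff the Vtl and Vsp
    components agree. An all-equal pattern is ambiguous and raises.
    """
    p = tuple(int(v) for v in pattern)
    if len(p) != 4:
        raise ValueError("pattern must cover (D, L, Vtl, Vsp)")
    m = max(p)
    if min(p) == m:
        raise ValueError("ambiguous pattern: all components equal")
    axes = ""
    if p[0] == m:
        axes += "D"
    if p[1] == m:
        axes += "L"
    if p[2] == m or p[3] == m:
        axes += "V"
    return axes, p[2] == p[3]


def hierarchical_cluster(
    profiles: TrichotomizedProfile, k: int = 14, exact: bool = False
) -> pd.DataFrame:
    """Cluster filtered profiles and label clusters by regulation category.

    Rows are z-scored and clustered with average linkage on Euclidean
    distance, then the tree is cut into ``k`` flat clusters. With
    ``exact=True`` identical sign profiles are grouped directly instead (the
    profile alphabet is finite, so this is the idealized partition). Each
    cluster is labelled by its consensus sign pattern (sign of the
    component-wise mean): regulation category plus ventral-consistency flag.

    Rows are canonically sorted before linkage so the partition does not
    depend on input order.
    """
    v = profiles.values
    if exact:
        keys = v.apply(lambda r: tuple(r), axis=1)
        uniques = {key: i + 1 for i, key in enumerate(sorted(set(keys)))}
        labels = keys.map(uniques).to_numpy()
    else:
        uniq = v.drop_duplicates().sort_values(COMPARISONS)
        if k > len(uniq):
            raise ConfigurationError(
                f"k={k} exceeds the {len(uniq)} distinct profiles"
            )
        order = v.sort_values(COMPARISONS).index
        z = row_zscore(v.loc[order].to_numpy())
        link = hierarchy.linkage(z, method="average", metric="euclidean")
        flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=order).loc[v.index].to_numpy()

    out = pd.DataFrame({"cluster": labels}, index=v.index)
    categories, consistency = {}, {}
    for cluster, members in v.groupby(labels):
        consensus = np.sign(members.mean(axis=0)).astype(int)
        try:
            cat, cons = regulation_category(consensus)
        except ValueError:
            cat, cons = "ambiguous", False
        categories[cluster] = cat
        consistency[cluster] = cons
    out["category"] = out["cluster"].map(categories)
    out["consistent"] = out["cluster"].map(consistency)
    return out
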