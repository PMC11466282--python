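"""Intensity-table ingestion, replicate aggregation and significance testing.

The in-memory intensity matrix is a pandas DataFrame: rows are entities
(protein groups or phosphosites), columns a (genotype, bio_rep, tech_rep)
MultiIndex, values log2 intensities with NaN for undetected cells. Genotype
labels are WT, D (dorsalized), L (lateralized), Vtl and Vsp (the two
ventralized genotypes).

Significance testing follows the label-free proteomics convention: a one-way
ANOVA across genotypes with an s0-moderated statistic (a fudge factor added to
the pooled scale, damping the significance of tiny absolute differences) and a
permutation-estimated false discovery rate, plus FDR-corrected pairwise
unpaired t-tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .simulate import GENOTYPES, MUTANTS, ConfigurationError

SAMPLE_RE = re.compile(r"^(?P<genotype>[A-Za-z]+)_(?P<bio>\d+)_(?P<tech>\d+)$")


class ParseError(ValueError):
    pass


@dataclass
class TableLayout:
    """How to read a MaxQuant-style tab-separated intensity table."""

    intensity_prefix: str = "LFQ intensity "
    id_column: str = "Protein IDs"
    linear: bool = True  # apply log2 on load
    reverse_column: str = "Reverse"
    contaminant_column: str = "Potential contaminant"


def load_intensity_table(path: str, layout: TableLayout | None = None) -> pd.DataFrame:
    """Read a MaxQuant-style TSV into a log2 intensity matrix.

    Sample columns are ``<prefix><genotype>_<bio>_<tech>``. Zeros and blanks
    become missing; reverse-decoy and contaminant rows are dropped when the
    flag columns exist.
    """
    layout = layout or TableLayout()
    df = pd.read_csv(path, sep="\t", dtype={layout.id_column: str})
    for col in (layout.reverse_column, layout.contaminant_column):
        if col in df.columns:
            df = df[df[col].fillna("") != "+"]
    sample_cols, meta = [], []
    for col in df.columns:
        if not col.startswith(layout.intensity_prefix):
            continue
        token = col[len(layout.intensity_prefix):]
        m = SAMPLE_RE.match(token)
        if not m or m.group("genotype") not in GENOTYPES:
            raise ParseError(f"cannot parse sample column {col!r}: unknown genotype")
        sample_cols.append(col)
        meta.append((m.group("genotype"), int(m.group("bio")), int(m.group("tech"))))
    if not sample_cols:
        raise ParseError("no intensity columns found")
    values = df[sample_cols].to_numpy(dtype=float)
    values[values == 0.0] = np.nan  # MaxQuant zero = undetected
    if layout.linear:
        values = np.log2(values)
    out = pd.DataFrame(
        values,
        index=pd.Index(df[layout.id_column], name="entity"),
        columns=pd.MultiIndex.from_tuples(meta, names=["genotype", "bio_rep", "tech_rep"]),
    )
    if out.index.duplicated().any():
        raise ParseError("duplicate entity identifiers")
    return out


def aggregate_replicates(m: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype mean log2 intensity and detection count.

    Returns a DataFrame with MultiIndex columns (statistic, genotype) where
    statistic is ``mean`` (NaN when nothing detected) or ``n`` (replicates
    with a value).
    """
    means = m.T.groupby(level="genotype").mean().T
    counts = m.notna().T.groupby(level="genotype").sum().T
    out = pd.concat({"mean": means, "n": counts}, axis=1)
    out.columns.names = ["statistic", "genotype"]
    return out


def genotype_means(t: pd.DataFrame) -> pd.DataFrame:
    """The per-genotype mean block of an aggregated table."""
    return t["mean"]


def average_tech_reps(m: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to (genotype, bio_rep) means.

    Optional pre-processing for the ANOVA when technical replicates should
    not be treated as independent samples.
    """
    out = m.T.groupby(level=["genotype", "bio_rep"]).mean().T
    out.columns = pd.MultiIndex.from_tuples(
        [(g, b, 1) for g, b in out.columns],
        names=["genotype", "bio_rep", "tech_rep"],
    )
    return out


def fold_changes(t: pd.DataFrame, mutants: tuple = MUTANTS) -> "FoldChangeTable":
    """Mean log2 fold change of each mutant genotype vs WT, with status flags."""
    means = t["mean"]
    if "WT" not in means.columns:
        raise ConfigurationError("WT genotype missing from mean table")
    fc = pd.DataFrame(index=t.index, columns=list(mutants), dtype=float)
    status = pd.DataFrame("detected", index=t.index, columns=list(mutants))
    wt = means["WT"]
    for g in mutants:
        mg = means[g] if g in means.columns else pd.Series(np.nan, index=t.index)
        fc[g] = mg - wt
        status.loc[mg.isna() & wt.notna(), g] = "undetected-in-mutant"
        status.loc[wt.isna(), g] = "undetected-in-WT"
    return FoldChangeTable(fc=fc, status=status)


@dataclass
class FoldChangeTable:
    """Per-entity mean log2 FCs vs WT and detection status per comparison."""

    fc: pd.DataFrame  # entity x mutant genotype, NaN where undefined
    status: pd.DataFrame  # same shape: detected / undetected-in-mutant / undetected-in-WT


# --- ANOVA with permutation FDR ---------------------------------------------


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    groups, inverse = np.unique(labels, return_inverse=True)
    onehot = np.zeros((len(labels), len(groups)))
    onehot[np.arange(len(labels)), inverse] = 1.0
    return onehot, groups

def _moderated_stat(x: np.ndarray, onehot: np.ndarray, s0: float) -> np.ndarray:
    """s0-moderated one-way ANOVA statistic per row, NaN-aware.

    d = sqrt(MS_between) / (sqrt(MS_within) + s0); monotone in F at s0 = 0.
    Rows without >= 2 groups having >= 2 values get NaN.
    """
    present = np.isfinite(x)
    xf = np.where(present, x, 0.0)
    n_g = present @ onehot  # entities x groups
    sum_g = xf @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_g = sum_g / n_g
    ok_g = n_g >= 2
    n_tot = np.where(ok_g, n_g, 0.0).sum(axis=1)
    k = ok_g.sum(axis=1)
    grand = np.where(ok_g, sum_g, 0.0).sum(axis=1) / np.where(n_tot > 0, n_tot, np.nan)
    ss_between = np.nansum(
        np.where(ok_g, n_g * (mean_g - grand[:, None]) ** 2, 0.0), axis=1
    )
    # within-group sum of squares over usable groups
    sq_g = (xf**2) @ onehot
    ss_within_g = sq_g - n_g * np.where(np.isfinite(mean_g), mean_g, 0.0) ** 2
    ss_within = np.where(ok_g, ss_within_g, 0.0).sum(axis=1)
    df_b = k - 1.0
    df_w = n_tot - k
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ss_between / df_b
        msw = ss_within / df_w
        d = np.sqrt(np.maximum(msb, 0.0)) / (np.sqrt(np.maximum(msw, 0.0)) + s0)
    d[(k < 2) | (df_w < 1)] = np.nan
    return d


def anova_permutation_fdr(
    m: pd.DataFrame, s0: float = 0.1, n_perm: int = 500, seed: int = 0
) -> pd.DataFrame:
    """One-way ANOVA across genotypes with SAM-style permutation FDR.

    The moderated statistic adds ``s0`` to the pooled scale in the
    denominator. Genotype labels are shuffled jointly across all samples
    ``n_perm`` times; the q-value of an entity is the expected fraction of
    false positives among entities with a statistic at least as large,
    monotonized so that q is non-increasing in the statistic.

    Returns a DataFrame with columns F, d (moderated), q, significant
    (q < 0.1).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    labels = m.columns.get_level_values("genotype").to_numpy()
    onehot, _ = _group_onehot(labels)
    x = m.to_numpy(dtype=float)
    d_obs = _moderated_stat(x, onehot, s0)
    f_obs = _moderated_stat(x, onehot, 0.0) ** 2  # sqrt(F)-scale back to F

    rng = np.random.default_rng(seed)
    order = np.argsort(d_obs)  # NaNs sort last
    valid = np.isfinite(d_obs)
    n_valid = int(valid.sum())
    d_sorted = d_obs[order][:n_valid]

    exceed = np.zeros(n_valid)
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        d_perm = _moderated_stat(x[:, perm], onehot, s0)
        d_perm = d_perm[np.isfinite(d_perm)]
        # count permuted stats >= each observed stat (descending threshold)
        idx = np.searchsorted(np.sort(d_perm), d_sorted, side="left")
        exceed += len(d_perm) - idx
    mean_false = exceed / n_perm
    n_called = n_valid - np.arange(n_valid)  # observed stats >= threshold
    q_sorted = np.minimum(mean_false / n_called, 1.0)
    # q of an entity = min FDR over all thresholds that call it, i.e. its own
    # and every looser (smaller-d) threshold; the running min over the
    # ascending-d prefix also makes q non-increasing in the statistic
    q_sorted = np.minimum.accumulate(q_sorted)
    q = np.full(len(d_obs), np.nan)
    q[order[:n_valid]] = q_sorted

    return pd.DataFrame(
        {
            "F": f_obs,
            "d": d_obs,
            "q": q,
            "significant": q < 0.1,
        },
        index=m.index,
    )


def pairwise_tests(
    m: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Two-sided unpaired t-tests per genotype pair with BH adjustment.

    Returns a DataFrame with MultiIndex columns (pair, statistic) where
    statistic is t, p, p_adj or flagged. Entities with fewer than 2 values in
    a group, or zero variance in both groups, are flagged and reported
    non-significant (p = NaN or 1) rather than erroring mid-table.
    """
    results = {}
    for a, b in pairs:
        xa = m.xs(a, axis=1, level="genotype").to_numpy(dtype=float)
        xb = m.xs(b, axis=1, level="genotype").to_numpy(dtype=float)
        na = np.isfinite(xa).sum(axis=1)
        nb = np.isfinite(xb).sum(axis=1)
        usable = (na >= 2) & (nb >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(xa, xb, axis=1, nan_policy="omit")
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        zero_var = usable & ~np.isfinite(p)
        # identical constant groups: no evidence of difference
        same_mean = zero_var & (np.nanmean(xa, axis=1) == np.nanmean(xb, axis=1))
        p[same_mean] = 1.0
        p[~usable] = np.nan
        flagged = ~usable | zero_var
        p_adj = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        results[f"{a}_vs_{b}"] = pd.DataFrame(
            {"t": t, "p": p, "p_adj": p_adj, "flagged": flagged}, index=m.index
        )
    out = pd.concat(results, axis=1)
    out.columns.names = ["pair", "statistic"]
    return out


def replicate_correlation_matrix(
    m: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Pearson correlation between replicate columns, with a hierarchical
    ordering (average linkage, correlation distance).

    Only entities detected in every replicate of every genotype enter the
    matrix.
    """
    complete = m.dropna(axis=0, how="any")
    if complete.empty:
        raise ValueError("no entities detected in all replicates of all genotypes")
    corr = complete.corr(method="pearson")
    dist = squareform(1.0 - corr.to_numpy(), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    return corr, [corr.columns[i] for i in order]
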