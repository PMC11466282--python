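"""Spatial RNA-atlas matching: DV category assignment and protein comparison.

Genes are assigned to one of six DV categories (D, L, V, DL, DV, LV) by their
spatial Pearson correlation with reference expression profiles (dpp for
dorsal, the positionwise mean of sog and soxN for lateral, twist for ventral,
crb, net and neur for the two-domain categories). Within each category, only
genes in the top tail of the correlation distribution (strictly above the 95th
percentile by default) are kept as the high-confidence DV RNA reference sets.
Protein-cluster vs RNA-category agreement is scored perfect / partial /
mismatch by comparing the two region sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import REFERENCE_GENES, ConfigurationError

CATEGORY_ORDER = ["D", "L", "V", "DL", "DV", "LV"]  # fixed tie-break order
DOMAINS = {c: frozenset(c) for c in CATEGORY_ORDER}  # e.g. "DL" -> {D, L}


def reference_patterns(
    atlas: pd.DataFrame, ref_genes: dict[str, list] | None = None
) -> pd.DataFrame:
    """Six reference profiles (category x position) from designated genes.

    Multi-gene categories (lateral: sog and soxN) use the positionwise mean.
    """
    ref_genes = ref_genes or REFERENCE_GENES
    rows = {}
    for cat in CATEGORY_ORDER:
        genes = ref_genes[cat]
        missing = [g for g in genes if g not in atlas.index]
        if missing:
            raise KeyError(f"reference gene(s) missing from atlas: {missing}")
        profile = atlas.loc[genes].mean(axis=0)
        if profile.std() == 0:
            raise ValueError(f"constant reference profile for category {cat}")
        rows[cat] = profile
    return pd.DataFrame(rows).T.loc[CATEGORY_ORDER]


def assign_rna_category(atlas: pd.DataFrame, refs: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene the category of its best-correlated reference profile.

    Returns a DataFrame (gene x [category, r, tied, skipped]); constant gene
    profiles cannot be correlated and are flagged skipped. Argmax ties break
    by the fixed category order and are flagged.
    """
    x = atlas.to_numpy(dtype=float)
    r_refs = refs.loc[CATEGORY_ORDER].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = r_refs - r_refs.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    rs = np.sqrt((rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ rc.T) / np.outer(xs, rs)  # genes x categories
    skipped = xs == 0
    best = np.nanmax(np.where(skipped[:, None], -np.inf, corr), axis=1)
    is_best = corr == best[:, None]
    idx = np.argmax(is_best, axis=1)  # first max in fixed order
    tied = is_best.sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "category": [CATEGORY_ORDER[i] for i in idx],
            "r": best,
            "tied": tied,
            "skipped": skipped,
        },
        index=atlas.index,
    )
    out.loc[skipped, ["category"]] = None
    out.loc[skipped, "r"] = np.nan
    return out


def percentile_filter(
    assignments: pd.DataFrame, pct: float = 95.0
) -> dict[str, list]:
    """High-confidence DV RNA reference sets per category.

    Within each category, keep genes whose correlation strictly exceeds that
    category's ``pct`` percentile (linear interpolation) — the top tail with
    the strongest similarity to the reference pattern. Categories where no
    gene strictly exceeds the threshold come back empty.
    """
    if not 0 < pct < 100:
        raise ConfigurationError("pct must be in (0, 100)")
    ok = assignments[~assignments["skipped"].astype(bool)]
    sets = {}
    for cat in CATEGORY_ORDER:
        sub = ok[ok["category"] == cat]
        if sub.empty:
            sets[cat] = []
            continue
        thr = np.percentile(sub["r"].to_numpy(dtype=float), pct)
        sets[cat] = list(sub.index[sub["r"] > thr])
    return sets


def match_cluster_to_rna(protein_category: str, rna_category: str) -> str:
    """perfect / partial / mismatch between two DV regulation categories.

    Perfect if the region sets are equal, partial if they intersect without
    being equal, mismatch if disjoint.
    """
    a, b = DOMAINS[protein_category], DOMAINS[rna_category]
    if a == b:
        return "perfect"
    if a & b:
        return "partial"
    return "mismatch"
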