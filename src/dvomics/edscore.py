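"""Euclidean-distance (ED) score against the most extreme category behavior.

Each mutant-vs-WT fold-change distribution is rescaled to [0, 1] so that a
log2 FC of 0 maps to 0.5 and the dominant extreme (whichever of |max| or |min|
is larger) maps to 1 or 0:

    rescaled = (fc + M) / (2 M),  M = |max fc|  if |max| >= |min|  (eq i)
                                  M = |min fc|  otherwise           (eq ii)

Entities undetected in a mutant are imputed with the lower limit of that
comparison's rescaled distribution. Per regulation category, a reference
vector collects the observed extremes (max or min of the rescaled
distribution) of the (D, L, V) components; the ED score of an entity is the
Euclidean distance between its rescaled 3-vector and its category's reference
vector — low scores mark strongly differential entities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quant import FoldChangeTable

#: per category: +1 means the component takes max of the rescaled
#: distribution, -1 the min — D:(+,-,-), L:(-,+,-), V:(-,-,+), DL:(+,+,-),
#: DV:(+,-,+), LV:(-,+,+)
REFERENCE_SIGNS = {
    "D": (1, -1, -1),
    "L": (-1, 1, -1),
    "V": (-1, -1, 1),
    "DL": (1, 1, -1),
    "DV": (1, -1, 1),
    "LV": (-1, 1, 1),
}


@dataclass
class RescaledDistribution:
    """One comparison's rescaled FC distribution and its scaling."""

    scale: float  # M = dominant absolute extreme
    values: pd.Series  # rescaled values in [0, 1]
    lower: float  # minimum rescaled value (imputation value)
    upper: float


def rescale_fc(values: pd.Series) -> RescaledDistribution:
    """Rescale one comparison's log2 FC distribution to [0, 1].

    Uses eq (i) when the upper limit dominates in absolute value (ties
    included), eq (ii) otherwise; 0 always maps to 0.5.
    """
    v = values.dropna()
    if v.empty:
        raise ValueError("empty fold-change distribution")
    hi, lo = float(v.max()), float(v.min())
    m = abs(hi) if abs(hi) >= abs(lo) else abs(lo)
    if m == 0:
        raise ValueError("all fold changes are zero; scaling undefined")
    rescaled = (v + m) / (2 * m)
    return RescaledDistribution(
        scale=m,
        values=rescaled,
        lower=float(rescaled.min()),
        upper=float(rescaled.max()),
    )


def impute_rescaled(dist: RescaledDistribution) -> float:
    """Imputation value for an entity undetected in this comparison: the
    lower limit of the rescaled distribution."""
    return dist.lower


def rescaled_vectors(
    fc: FoldChangeTable, ventral: str = "Vtl"
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, RescaledDistribution]]:
    """Per-entity rescaled (D, L, V) vectors for one ventralized genotype.

    Entities undetected in the wild type have no FC and are excluded; entities
    undetected in a mutant get the imputed lower limit (flagged). Returns
    (vectors, imputed flags, distributions).
    """
    comparisons = ["D", "L", ventral]
    detected_wt = ~(fc.status[comparisons] == "undetected-in-WT").any(axis=1)
    sub_fc = fc.fc.loc[detected_wt, comparisons]
    sub_status = fc.status.loc[detected_wt, comparisons]
    dists = {c: rescale_fc(sub_fc[c]) for c in comparisons}
    vectors = pd.DataFrame(index=sub_fc.index, columns=comparisons, dtype=float)
    imputed = sub_status == "undetected-in-mutant"
    for c in comparisons:
        vectors[c] = dists[c].values.reindex(sub_fc.index)
        vectors.loc[imputed[c], c] = impute_rescaled(dists[c])
    return vectors, imputed, dists


def reference_vectors(
    dists: dict[str, RescaledDistribution], ventral: str = "Vtl"
) -> pd.DataFrame:
    """Six reference vectors (category x (D, L, V)) of observed extremes."""
    comparisons = ["D", "L", ventral]
    rows = {}
    for cat, signs in REFERENCE_SIGNS.items():
        rows[cat] = [
            dists[c].upper if s == 1 else dists[c].lower
            for c, s in zip(comparisons, signs)
        ]
    return pd.DataFrame(rows, index=comparisons).T


def ed_score(v, ref) -> float:
    """Euclidean distance between a rescaled FC vector and a reference."""
    return float(np.linalg.norm(np.asarray(v, dtype=float) - np.asarray(ref, dtype=float)))


def ed_scores(
    fc: FoldChangeTable, categories: pd.Series, ventral: str = "Vtl"
) -> pd.DataFrame:
    """ED score of every categorized entity against its category's reference.

    ``categories`` maps entity -> regulation category (D/L/V/DL/DV/LV);
    entities with other labels are skipped. Returns entity x [category,
    ed_score, n_imputed].
    """
    vectors, imputed, dists = rescaled_vectors(fc, ventral)
    refs = reference_vectors(dists, ventral)
    common = vectors.index.intersection(categories.index)
    cats = categories.loc[common]
    cats = cats[cats.isin(refs.index)]
    diff = vectors.loc[cats.index].to_numpy() - refs.loc[cats].to_numpy()
    scores = np.sqrt((diff**2).sum(axis=1))
    return pd.DataFrame(
        {
            "category": cats,
            "ed_score": scores,
            "n_imputed": imputed.loc[cats.index].sum(axis=1),
        },
        index=cats.index,
    )
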