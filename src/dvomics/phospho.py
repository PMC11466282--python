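"""Phosphosite / host-protein linkage and fold-change co-regulation classes.

Each phosphosite (id convention ``ProteinAccession_Residue_Position``, with
multiple host protein groups separated by ``;`` in the accession part) is
paired with its host protein's fold change (averaged when the site maps to
several protein groups). Per mutant-vs-WT comparison the pair is classified:

- correlation: both the host protein and the site exceed their thresholds
  with the same sign (corr-up / corr-down);
- anti-correlation: both exceed with opposite signs (labelled by the protein's
  direction);
- no correlation: the host is within its threshold but the site exceeds its
  own (nocorr-site-up / nocorr-site-down) — differential phosphorylation on a
  stable protein;
- unchanged: the site stays within its threshold.

Default thresholds are the variability-derived clustering thresholds, 0.5
log2 for proteins and 0.35 log2 for phosphosites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import FoldChangeTable
from .simulate import MUTANTS

CATEGORIES = (
    "corr-up",
    "corr-down",
    "anticorr-protein-up",
    "anticorr-protein-down",
    "nocorr-site-up",
    "nocorr-site-down",
    "unchanged",
)


def split_site_id(site_id: str) -> tuple[list, str, str]:
    """(host accessions, residue, position) from a site identifier."""
    acc, residue, position = site_id.rsplit("_", 2)
    return acc.split(";"), residue, position


def match_site_to_protein(
    sites: FoldChangeTable, proteins: FoldChangeTable
) -> pd.DataFrame:
    """Pair each phosphosite with its host protein fold changes.

    Host FCs are averaged when the site belongs to multiple protein groups.
    Sites with no proteome match are flagged unmatched (and excluded from
    classification downstream). Returns a long DataFrame: site, comparison,
    site_fc, host_fc, matched.
    """
    rows = []
    prot_fc = proteins.fc
    for site_id in sites.fc.index:
        hosts, _, _ = split_site_id(site_id)
        present = [h for h in hosts if h in prot_fc.index]
        for comp in sites.fc.columns:
            site_fc = sites.fc.at[site_id, comp]
            host_fc = float(prot_fc.loc[present, comp].mean()) if present else np.nan
            rows.append((site_id, comp, site_fc, host_fc, bool(present)))
    return pd.DataFrame(
        rows, columns=["site", "comparison", "site_fc", "host_fc", "matched"]
    )


def classify_pair(
    host_fc: float,
    site_fc: float,
    protein_threshold: float = 0.5,
    site_threshold: float = 0.35,
) -> str | None:
    """Co-regulation category of one (host FC, site FC) pair.

    Returns None when either FC is undefined (the pair is skipped for that
    comparison).
    """
    if not (np.isfinite(host_fc) and np.isfinite(site_fc)):
        return None
    host_reg = abs(host_fc) > protein_threshold
    site_reg = abs(site_fc) > site_threshold
    if not site_reg:
        return "unchanged"
    if host_reg:
        if np.sign(host_fc) == np.sign(site_fc):
            return "corr-up" if site_fc > 0 else "corr-down"
        return "anticorr-protein-up" if host_fc > 0 else "anticorr-protein-down"
    return "nocorr-site-up" if site_fc > 0 else "nocorr-site-down"


def classify_pairs(
    pairs: pd.DataFrame,
    protein_threshold: float = 0.5,
    site_threshold: float = 0.35,
) -> pd.DataFrame:
    """Vectorized ``classify_pair`` over a matched pair table."""
    out = pairs[pairs["matched"]].copy()
    out["category"] = [
        classify_pair(h, s, protein_threshold, site_threshold)
        for h, s in zip(out["host_fc"], out["site_fc"])
    ]
    return out.dropna(subset=["category"])


def tally_categories(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per category per mutant comparison.

    Fractions are reported over two denominators: all classified pairs and
    regulated-site pairs only (excluding "unchanged").
    """
    comparisons = list(classified["comparison"].unique()) or list(MUTANTS)
    rows = []
    for comp in comparisons:
        sub = classified[classified["comparison"] == comp]
        counts = sub["category"].value_counts()
        total = int(counts.sum())
        regulated = total - int(counts.get("unchanged", 0))
        for cat in CATEGORIES:
            n = int(counts.get(cat, 0))
            rows.append(
                {
                    "comparison": comp,
                    "category": cat,
                    "count": n,
                    "fraction_all": n / total if total else 0.0,
                    "fraction_regulated": (
                        n / regulated if regulated and cat != "unchanged" else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
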