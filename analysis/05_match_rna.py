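"""Assign atlas genes to DV categories by spatial correlation with the six
reference patterns, filter to the high-confidence RNA reference sets, and
score protein-cluster vs RNA-category agreement.

The atlas is generated with gene classes tied to the regulation categories of
a matched simulated proteome (gene g_i encodes protein P_i), emulating the
transcriptional origin of most regional protein differences; ubiquitous
proteins are excluded from the atlas comparison upstream.
"""

import argparse
from pathlib import Path

import pandas as pd

from dvomics import clustering, quant, rna
from dvomics.simulate import SimConfig, simulate_atlas, simulate_proteome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-entities", type=int, default=2000)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    cfg = SimConfig(n_entities=args.n_entities, seed=args.seed)
    m, truth = simulate_proteome(cfg)
    regulated = truth.category[truth.category != "ubiquitous"]
    gene_classes = pd.Series(
        regulated.to_numpy(),
        index=["g" + e[1:] for e in regulated.index],  # gene g_i <-> protein P_i
    )
    atlas, theta, atlas_truth = simulate_atlas(
        0, 72, seed=args.seed + 1, classes=gene_classes
    )
    refs = rna.reference_patterns(atlas)
    assigned = rna.assign_rna_category(atlas, refs)
    sets = rna.percentile_filter(assigned, pct=95.0)
    n_ref = {c: len(g) for c, g in sets.items()}
    print(f"DV RNA reference sets (top 5% per category): {n_ref} "
          f"-> {sum(n_ref.values())} genes total")
    pd.Series(
        {g: c for c, genes in sets.items() for g in genes}, name="category"
    ).rename_axis("gene").to_csv(results / "05_rna_reference_sets.tsv", sep="\t")

    fc = quant.fold_changes(quant.aggregate_replicates(m))
    kept, _ = clustering.filter_profiles(clustering.trichotomize(fc, 0.5))
    assign = clustering.hierarchical_cluster(kept, k=14)
    prot_cat = assign["category"][assign["category"].isin(rna.CATEGORY_ORDER)]

    rows = []
    for cat, genes in sets.items():
        for gene in genes:
            protein = "P" + gene[1:]
            if protein in prot_cat.index:
                rows.append({
                    "gene": gene,
                    "rna_category": cat,
                    "protein_category": prot_cat[protein],
                    "match": rna.match_cluster_to_rna(prot_cat[protein], cat),
                })
    matches = pd.DataFrame(rows)
    matches.to_csv(results / "05_rna_protein_match.tsv", sep="\t", index=False)
    if len(matches):
        print(f"RNA vs protein-cluster agreement ({len(matches)} reference genes "
              "with clustered proteins):")
        print(matches["match"].value_counts().to_string())


if __name__ == "__main__":
    main()
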