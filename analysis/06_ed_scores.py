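"""Rescale fold-change distributions to [0, 1], build per-category reference
vectors of the most extreme behaviors, and score every clustered entity's
Euclidean distance to its category's reference (low = strongly differential).
"""

import argparse
from pathlib import Path

from dvomics import clustering, edscore, quant, rna
from dvomics.simulate import SimConfig, simulate_proteome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-entities", type=int, default=2000)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    cfg = SimConfig(n_entities=args.n_entities, seed=args.seed)
    m, _ = simulate_proteome(cfg)
    fc = quant.fold_changes(quant.aggregate_replicates(m))
    kept, _ = clustering.filter_profiles(clustering.trichotomize(fc, 0.5))
    assign = clustering.hierarchical_cluster(kept, k=14)
    categories = assign["category"][assign["category"].isin(rna.CATEGORY_ORDER)]

    for ventral in ("Vtl", "Vsp"):
        _, _, dists = edscore.rescaled_vectors(fc, ventral)
        refs = edscore.reference_vectors(dists, ventral)
        print(f"{ventral} reference vectors:\n{refs.round(4).to_string()}")
        scores = edscore.ed_scores(fc, categories, ventral)
        scores.to_csv(results / f"06_ed_scores_{ventral}.tsv", sep="\t")
        per_cat = scores.groupby("category")["ed_score"].describe()[
            ["count", "mean", "min", "max"]
        ]
        print(f"{ventral} ED scores by category:\n{per_cat.round(3).to_string()}\n")


if __name__ == "__main__":
    main()
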