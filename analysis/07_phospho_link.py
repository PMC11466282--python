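"""Pair phosphosites with host-protein fold changes and tally the
co-regulation categories (correlation / anti-correlation / no correlation)
per mutant-vs-WT comparison.
"""

import argparse
from pathlib import Path

from dvomics import phospho, quant
from dvomics.simulate import SimConfig, simulate_phosphoproteome, simulate_proteome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-entities", type=int, default=2000)
    ap.add_argument("--n-sites", type=int, default=3000)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    cfg = SimConfig(n_entities=args.n_entities, n_sites=args.n_sites, seed=args.seed)
    m, truth = simulate_proteome(cfg)
    sites, _ = simulate_phosphoproteome(cfg, truth)
    prot_fc = quant.fold_changes(quant.aggregate_replicates(m))
    site_fc = quant.fold_changes(quant.aggregate_replicates(sites))

    pairs = phospho.match_site_to_protein(site_fc, prot_fc)
    n_unmatched = int((~pairs.groupby("site")["matched"].first()).sum())
    print(f"{pairs['site'].nunique()} sites; {n_unmatched} with no proteome match")

    classified = phospho.classify_pairs(pairs)
    tally = phospho.tally_categories(classified)
    tally.to_csv(results / "07_phospho_tally.tsv", sep="\t", index=False)
    nocorr = (
        tally[tally["category"].str.startswith("nocorr")]
        .groupby("comparison")["fraction_regulated"].sum()
    )
    print("fraction of regulated-site pairs with unchanged host (no correlation):")
    print((100 * nocorr).round(1).astype(str).add("%").to_string())


if __name__ == "__main__":
    main()
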