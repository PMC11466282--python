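"""Aggregate replicates, compute fold changes vs wild type, and run the
significance tests (s0-moderated permutation-FDR ANOVA and pairwise t-tests)
plus the replicate correlation matrix.
"""

import argparse
from pathlib import Path

import pandas as pd

from dvomics import quant
from dvomics.simulate import MUTANTS, SimConfig, simulate_proteome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-entities", type=int, default=2000)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    cfg = SimConfig(n_entities=args.n_entities, seed=args.seed)
    m, truth = simulate_proteome(cfg)
    agg = quant.aggregate_replicates(m)
    fc = quant.fold_changes(agg)
    fc.fc.to_csv(results / "02_fold_changes.tsv", sep="\t")

    anova = quant.anova_permutation_fdr(m, s0=0.1, n_perm=500, seed=args.seed)
    anova.to_csv(results / "02_anova.tsv", sep="\t")
    n_sig = int(anova["significant"].sum())
    print(f"ANOVA: {n_sig}/{len(anova)} entities at permutation q < 0.1")
    regulated = truth.category != "ubiquitous"
    tp = anova["significant"][regulated].mean()
    fp = anova["significant"][~regulated].mean()
    print(f"  among designed regional classes: {tp:.2%}; among nominally "
          f"ubiquitous: {fp:.2%}")
    print("  (nominally ubiquitous entities carry mild true regional modulation "
          "under the default generator, and shared biological-replicate noise "
          "makes the permutation test anticonservative — see docs/methods.md)")

    # calibration reference: an exchangeable null keeps discoveries near zero
    null_cfg = SimConfig(
        n_entities=500, seed=args.seed + 40,
        class_fractions={"ubiquitous": 1.0}, regional_sd=0.0, noise_sd_bio=0.0,
    )
    m_null, _ = simulate_proteome(null_cfg)
    anova_null = quant.anova_permutation_fdr(m_null, s0=0.1, n_perm=250,
                                             seed=args.seed)
    print(f"  exchangeable-null calibration: "
          f"{int(anova_null['significant'].sum())}/500 entities at q < 0.1")

    pairs = quant.pairwise_tests(m, [("WT", g) for g in MUTANTS])
    sig_counts = {
        p: int((pairs[p]["p_adj"] < 0.05).sum()) for p in pairs.columns.levels[0]
    }
    print(f"pairwise t-tests significant (BH<0.05): {sig_counts}")

    corr, order = quant.replicate_correlation_matrix(m)
    corr.loc[order, order].to_csv(results / "02_replicate_correlation.tsv", sep="\t")
    same = [corr.loc[a, b] for a in corr.columns for b in corr.columns
            if a != b and a[0] == b[0]]
    diff = [corr.loc[a, b] for a in corr.columns for b in corr.columns if a[0] != b[0]]
    print(f"replicate correlation: within-genotype mean {pd.Series(same).mean():.3f}, "
          f"between-genotype mean {pd.Series(diff).mean():.3f}")


if __name__ == "__main__":
    main()
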