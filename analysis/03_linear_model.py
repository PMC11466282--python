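"""Screen region proportions (a, b, c) with the linear mixing model, compute
per-entity deviations at the adopted proportions, and extract the extreme
deviators shared by both ventralized genotypes.
"""

import argparse
from pathlib import Path

import pandas as pd

from dvomics import linmodel, quant
from dvomics.simulate import SimConfig, simulate_proteome


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-entities", type=int, default=2000)
    ap.add_argument("--step", type=float, default=0.05)
    args = ap.parse_args()
    results = Path("results")
    results.mkdir(exist_ok=True)

    cfg = SimConfig(n_entities=args.n_entities, seed=args.seed)
    m, _ = simulate_proteome(cfg)
    means = quant.genotype_means(quant.aggregate_replicates(m))

    tables = {}
    for ventral in ("Vtl", "Vsp"):
        ranking = linmodel.proportion_screen(means, args.step, ventral)
        ranking.head(50).to_csv(
            results / f"03_proportion_screen_{ventral}.tsv", sep="\t", index=False
        )
        top = ranking.iloc[0]
        print(f"{ventral}: best combo (a,b,c)=({top.a}, {top.b}, {top.c}) "
              f"IQR={top.iqr:.4f} of {len(ranking)} combos")
        tables[ventral] = linmodel.deviation_table(means, (0.4, 0.4, 0.2), ventral)
        dev = tables[ventral].table["deviation"]
        print(f"  deviations at (0.4, 0.4, 0.2): median {dev.median():+.3f}, "
              f"IQR [{dev.quantile(.25):+.3f}, {dev.quantile(.75):+.3f}], n={len(dev)}")
        tables[ventral].table.to_csv(results / f"03_deviations_{ventral}.tsv", sep="\t")

    extreme = linmodel.extreme_deviators(tables, percentile=95.0)
    print(f"extreme deviators (>95th percentile |deviation| in both ventralized "
          f"genotypes): {len(extreme)}")
    pd.Series(sorted(extreme), name="entity").to_csv(
        results / "03_extreme_deviators.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
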