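"""Linear mixing model of the wild-type proteome.

The model assumes each mutant genotype represents one region of the DV axis,
so the wild-type abundance of a protein is the region-proportion weighted sum
of its abundance in the dorsalized (D), lateralized (L) and one ventralized
(V) mutant, computed on the linear intensity scale:

    twt = a*D + b*L + c*V

The deviation statistic is log2(twt / mwt) against the measured wild type; a
deviation of 0 means the mixture reproduces the measurement exactly. The
proportion screen enumerates (a, b, c) on a grid over [0, 1]^3 (no simplex
constraint by default) and ranks combinations by the interquartile range of
the deviation distribution: the best proportions give the narrowest spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ConfigurationError


@dataclass
class DeviationTable:
    """Per-entity theoretical vs measured wild-type comparison."""

    ventral: str  # which ventralized genotype contributed
    table: pd.DataFrame  # columns: twt, mwt, deviation (complete cases only)


def theoretical_wildtype(
    means: pd.DataFrame, combo: tuple[float, float, float], ventral: str = "Vtl"
) -> pd.Series:
    """Theoretical wild-type linear abundance a*D + b*L + c*V per entity.

    ``means`` holds per-genotype mean log2 intensities. Entities missing any
    of the three contributing genotypes are excluded (not zero-filled).
    """
    a, b, c = combo
    cols = means[["D", "L", ventral]].dropna()
    linear = np.exp2(cols.to_numpy())
    twt = a * linear[:, 0] + b * linear[:, 1] + c * linear[:, 2]
    return pd.Series(twt, index=cols.index, name="twt")


def deviation(twt, mwt):
    """log2(theoretical / measured) wild-type abundance; NaN if nonpositive."""
    twt = np.asarray(twt, dtype=float)
    mwt = np.asarray(mwt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where((twt > 0) & (mwt > 0), np.log2(twt / mwt), np.nan)
    return out if out.ndim else float(out)


def deviation_table(
    means: pd.DataFrame, combo: tuple[float, float, float], ventral: str = "Vtl"
) -> DeviationTable:
    """Deviations for all complete-case entities (detected in WT, D, L and
    the chosen ventral genotype)."""
    twt = theoretical_wildtype(means, combo, ventral)
    mwt = np.exp2(means.loc[twt.index, "WT"])
    table = pd.DataFrame({"twt": twt, "mwt": mwt})
    table["deviation"] = deviation(table["twt"].to_numpy(), table["mwt"].to_numpy())
    table = table.dropna()
    return DeviationTable(ventral=ventral, table=table)


def proportion_grid(step: float = 0.05) -> np.ndarray:
    """All (a, b, c) combinations on the grid over [0, 1]^3."""
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ConfigurationError("step must divide 1 evenly")
    axis = np.round(np.arange(n + 1) * step, 10)
    return np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T


def proportion_screen(
    means: pd.DataFrame,
    step: float = 0.05,
    ventral: str = "Vtl",
    simplex: bool = False,
) -> pd.DataFrame:
    """Rank all grid combinations of region proportions by deviation IQR.

    For every (a, b, c) on the grid the deviation distribution over
    complete-case entities is computed and summarized by its IQR. Rows are
    sorted ascending by IQR, with |median deviation| and grid order as
    documented tie-breaks (at zero noise, every scalar multiple of the true
    proportions also has IQR 0, but only the unscaled combination has median
    deviation 0). Exact IQR ties are flagged in the ``tied`` column.

    With ``simplex=True`` only combinations with a + b + c = 1 are screened.
    """
    cols = means[["D", "L", ventral, "WT"]].dropna()
    if cols.empty:
        raise ValueError("no complete-case entities for the screen")
    linear = np.exp2(cols.to_numpy())  # entities x (D, L, V, WT)
    grid = proportion_grid(step)
    if simplex:
        grid = grid[np.abs(grid.sum(axis=1) - 1.0) < 1e-9]
    # twt for every combo at once: combos x entities
    twt = grid @ linear[:, :3].T
    with np.errstate(divide="ignore"):
        dev = np.log2(twt) - np.log2(linear[:, 3])[None, :]
    dev[~np.isfinite(dev)] = np.nan  # twt = 0: deviation undefined
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN combos
        q1, med, q3 = np.nanpercentile(dev, [25, 50, 75], axis=1)
    iqr = q3 - q1
    out = pd.DataFrame(
        {"a": grid[:, 0], "b": grid[:, 1], "c": grid[:, 2], "iqr": iqr, "median": med}
    )
    out["abs_median"] = out["median"].abs()
    out = out.sort_values(
        ["iqr", "abs_median"], kind="stable"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["tied"] = out["iqr"].duplicated(keep=False)
    return out.drop(columns="abs_median")


def extreme_deviators(
    dev_tables: dict[str, DeviationTable],
    percentile: float = 95.0,
    site_to_host: pd.Series | None = None,
) -> set:
    """Entities whose |deviation| exceeds the per-genotype percentile of the
    |deviation| distribution in *both* ventralized genotypes.

    Phosphosites are collapsed to host proteins (via ``site_to_host``) and
    counted once. Percentiles use linear interpolation.
    """
    if not 0 < percentile < 100:
        raise ConfigurationError("percentile must be in (0, 100)")
    if set(dev_tables) != {"Vtl", "Vsp"}:
        raise ConfigurationError("deviation tables for both Vtl and Vsp required")
    per_genotype = []
    for dt in dev_tables.values():
        absdev = dt.table["deviation"].abs()
        thr = np.percentile(absdev.to_numpy(), percentile)
        per_genotype.append(set(absdev.index[absdev > thr]))
    extreme = per_genotype[0] & per_genotype[1]
    if site_to_host is not None:
        extreme = {site_to_host.get(e, e) for e in extreme}
    return extreme
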