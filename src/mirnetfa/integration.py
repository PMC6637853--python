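"""miRNA-mRNA integration at the module-eigengene level.

Within each group, every miRNA module eigengene is correlated with every
mRNA module eigengene; pairs with a negative Pearson correlation and a
nominal p < 0.10 are selected, reflecting the canonical repressive action of
miRNAs on their targets. Hub miRNAs of the implicated miRNA modules are then
taken forward and their pooled target sets tested for over-representation
against supplied gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError, GeneSetCollection, TargetMap
from .diffexpr import bh_adjust
from .wgcna import ModulePartition, top_hubs


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student-t transform."""
    if n < 4:
        raise DataError("need n >= 4 samples for the t transform")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def _permutation_pvalue(x: np.ndarray, y: np.ndarray, r_obs: float,
                        n_perm: int, rng: np.random.Generator) -> float:
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(rng.permutation(x), y)[0, 1]
        if abs(r) >= abs(r_obs):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def correlate_eigengenes(
    mirna_me: pd.DataFrame,
    mrna_me: pd.DataFrame,
    alpha: float = 0.10,
    method: str = "t",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """All miRNA-module x mRNA-module eigengene correlations with the
    negative-correlation / p < alpha selection flag.

    Both ME matrices are modules x samples over the identical sample set and
    order. ``method`` is "t" (Student-t transform) or "permutation".
    """
    if list(mirna_me.columns) != list(mrna_me.columns):
        raise DataError("sample mismatch between miRNA and mRNA eigengene matrices")
    n = mirna_me.shape[1]
    if n < 4:
        raise DataError("need >= 4 samples")
    rng = np.random.default_rng(seed)
    rows = []
    for mi in mirna_me.index:
        x = mirna_me.loc[mi].to_numpy(float)
        for mr in mrna_me.index:
            y = mrna_me.loc[mr].to_numpy(float)
            r = float(np.corrcoef(x, y)[0, 1])
            if method == "t":
                p = correlation_pvalue(r, n)
            elif method == "permutation":
                p = _permutation_pvalue(x, y, r, n_perm, rng)
            else:
                raise DataError(f"unknown method {method!r}")
            rows.append(
                {
                    "mrna_module": mr,
                    "mirna_module": mi,
                    "r": r,
                    "p": p,
                    "selected": bool(r < 0 and p < alpha),
                }
            )
    return pd.DataFrame(rows)


def apply_selection_rule(pair_table: pd.DataFrame, alpha: float = 0.10) -> pd.DataFrame:
    """Flag rows of a (r, p) module-pair table by the negative-correlation,
    p < alpha rule. Useful for re-filtering externally computed tables."""
    out = pair_table.copy()
    out["selected"] = (out["r"] < 0) & (out["p"] < alpha)
    return out


def select_hub_mirnas(
    pair_table: pd.DataFrame,
    partition: ModulePartition,
    k: int = 5,
    absolute: bool = False,
) -> dict[str, list[str]]:
    """Top-k membership miRNAs for every miRNA module in >= 1 selected pair."""
    selected_modules = sorted(set(pair_table.loc[pair_table["selected"], "mirna_module"]))
    return {
        m: top_hubs(partition, m, k, absolute)
        for m in selected_modules
        if m in partition.modules
    }


def ora(
    query: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set.

    Each annotated set is intersected with the universe before testing; the
    upper-tail p is P[X >= overlap] for X ~ Hypergeom(N=|universe|,
    K=|set & universe|, n=|query|), BH-adjusted across sets.
    """
    if not universe:
        raise DataError("empty universe")
    stray = query - universe
    if stray:
        raise DataError(f"query gene(s) outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe": N,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def hub_target_enrichment(
    hubs: dict[str, list[str]],
    targets: TargetMap,
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """ORA of each hub-miRNA module's pooled target genes (restricted to the
    expressed-gene universe)."""
    frames = []
    for module, mirnas in sorted(hubs.items()):
        query = targets.union(mirnas) & universe
        if not query:
            continue
        res = ora(query, sets, universe)
        res.insert(0, "mirna_module", module)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=["mirna_module", "set_name", "overlap", "set_size",
                     "query_size", "universe", "p", "padj"]
        )
    return pd.concat(frames, ignore_index=True)


def plot_me_correlations(pair_table: pd.DataFrame, ax=None):
    """Heatmap of miRNA-ME x mRNA-ME correlations with selected pairs marked."""
    from matplotlib import pyplot as plt

    grid = pair_table.pivot(index="mirna_module", columns="mrna_module", values="r")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * grid.shape[1], 1 + 0.6 * grid.shape[0]))
    im = ax.imshow(grid.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=90)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    sel = pair_table[pair_table["selected"]]
    for _, row in sel.iterrows():
        i = list(grid.index).index(row["mirna_module"])
        j = list(grid.columns).index(row["mrna_module"])
        ax.text(j, i, "*", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
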