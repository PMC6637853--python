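"""Signed weighted co-expression networks and module detection.

The network convention is signed: adjacency a_ij = ((1 + r_ij) / 2)^beta, so
anti-correlated features get near-zero connection strength. Topological
overlap is computed from the adjacency, 1 - TOM is clustered with
average-linkage hierarchical clustering, and the tree is cut at a fixed
height; clusters below the minimum size are left unassigned ("grey").
Modules whose eigengenes are closer than the merge height are merged
iteratively. This static cut + eigengene merge is a deliberate, documented
simplification of dynamic tree cutting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import DataError, ExpressionMatrix, UNASSIGNED


@dataclass(frozen=True)
class NetworkParams:
    """Tunables for signed network construction and module detection.

    beta : soft-threshold power of the signed adjacency (default 6).
    min_module_size : smallest cluster kept as a module (5 is the usual
        choice for miRNA, 30 for mRNA).
    merge_height : eigengene dissimilarity below which modules merge (0.25).
    cut_height : static tree-cut height on the 1 - TOM dendrogram. With a
        signed beta = 6 network, unrelated features sit near dissimilarity 1
        while co-expressed clusters close well below ~0.8, so the default
        0.75 separates modules and leaves unstructured features grey; the
        eigengene-merge step repairs any over-splitting.
    """

    beta: int = 6
    min_module_size: int = 30
    merge_height: float = 0.25
    cut_height: float = 0.75

    def __post_init__(self):
        if self.beta < 1:
            raise DataError("beta must be a positive integer")
        if self.min_module_size < 1:
            raise DataError("min_module_size must be >= 1")
        if not 0 < self.merge_height < 1:
            raise DataError("merge_height must be in (0,1)")
        if not 0 < self.cut_height < 1:
            raise DataError("cut_height must be in (0,1)")


MIRNA_DEFAULTS = NetworkParams(min_module_size=5)
MRNA_DEFAULTS = NetworkParams(min_module_size=30)


def _corr(values: np.ndarray) -> np.ndarray:
    r = np.corrcoef(values)
    return np.clip(r, -1.0, 1.0)


def signed_adjacency(expr: ExpressionMatrix | pd.DataFrame, beta: int = 6) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta, a_ii = 1."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 3:
        raise DataError("need >= 3 samples for correlation networks")
    arr = values.to_numpy(float)
    sd = arr.std(axis=1)
    zero_var = values.index[sd == 0]
    if len(zero_var):
        raise DataError(f"zero-variance feature(s): {list(map(str, zero_var))}")
    a = ((1.0 + _corr(arr)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour strength relative to the sparser node.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = adjacency.to_numpy(float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise DataError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise DataError("adjacency diagonal must be 1")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise DataError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=0) - 1.0
    shared = a @ a - 2.0 * a  # sum over u != i,j of a_iu * a_uj, off-diagonal
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):  # 0/0 on the diagonal of an empty graph
        tom = num / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Name modules module0, module1, ... in decreasing size; ties broken by
    first-occurring feature to keep the result order-stable."""
    out = pd.Series(UNASSIGNED, index=labels.index, dtype=object)
    clusters = {}
    for pos, (feat, lab) in enumerate(labels.items()):
        if lab == UNASSIGNED:
            continue
        clusters.setdefault(lab, []).append((pos, feat))
    ordered = sorted(clusters.items(), key=lambda kv: (-len(kv[1]), kv[1][0][0]))
    for new_id, (_, members) in enumerate(ordered):
        for _, feat in members:
            out[feat] = f"module{new_id}"
    return out


def detect_modules(tom_dissimilarity: pd.DataFrame, params: NetworkParams) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Returns a feature -> module label Series; clusters smaller than
    min_module_size become "grey". Labels are assigned in decreasing size
    order.
    """
    d = tom_dissimilarity.to_numpy(float)
    if d.shape[0] != d.shape[1]:
        raise DataError("dissimilarity must be square")
    if d.min() < -1e-12 or d.max() > 1 + 1e-9:
        raise DataError("dissimilarity entries must lie in [0, 1]")
    condensed = squareform(np.clip(d, 0, None), checks=False)
    tree = linkage(condensed, method="average")
    flat = fcluster(tree, t=params.cut_height, criterion="distance")
    labels = pd.Series(
        [f"c{c}" for c in flat], index=tom_dissimilarity.index, dtype=object
    )
    sizes = labels.value_counts()
    small = sizes[sizes < params.min_module_size].index
    labels[labels.isin(small)] = UNASSIGNED
    if (labels == UNASSIGNED).all():
        warnings.warn("all features unassigned (grey); empty partition", stacklevel=2)
    return _relabel_by_size(labels)


def _standardize(arr: np.ndarray) -> np.ndarray:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise DataError("zero-variance feature in module")
    return (arr - mean) / sd


def module_eigengene(expr: ExpressionMatrix | pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the standardized member profiles.

    Scaled to unit sample variance and sign-oriented so that the mean
    correlation of members with the eigengene is non-negative.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if len(members) == 0:
        raise DataError("empty module")
    if values.shape[1] < 2:
        raise DataError("eigengenes need >= 2 samples")
    x = _standardize(values.loc[list(members)].to_numpy(float))
    # first right singular vector = PC scores over samples
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    me = vt[0]
    sd = me.std(ddof=1)
    if sd == 0:
        raise DataError("degenerate eigengene (zero variance)")
    me = me / sd
    if np.mean([np.corrcoef(row, me)[0, 1] for row in x]) < 0:
        me = -me
    return pd.Series(me, index=values.columns, name="ME")


def module_membership(
    expr: ExpressionMatrix | pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every feature with every module eigengene.

    ``eigengenes`` is modules x samples; the result is features x modules.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if list(values.columns) != list(eigengenes.columns):
        raise DataError("sample mismatch between expression and eigengenes")
    x = values.to_numpy(float)
    e = eigengenes.to_numpy(float)
    xz = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
    ez = (e - e.mean(1, keepdims=True)) / e.std(1, ddof=1, keepdims=True)
    mm = xz @ ez.T / (x.shape[1] - 1)
    return pd.DataFrame(
        np.clip(mm, -1, 1), index=values.index, columns=eigengenes.index
    )


def _eigengene_matrix(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    modules = sorted(set(labels) - {UNASSIGNED})
    rows = {m: module_eigengene(values, list(labels.index[labels == m])) for m in modules}
    return pd.DataFrame(rows).T.set_axis(values.columns, axis=1)


def merge_modules(
    labels: pd.Series, expr: ExpressionMatrix | pd.DataFrame, merge_height: float = 0.25
) -> pd.Series:
    """Iteratively merge the closest module pair while their eigengene
    dissimilarity 1 - cor(ME_a, ME_b) is below merge_height."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = labels.copy()
    while True:
        modules = sorted(set(labels) - {UNASSIGNED})
        if len(modules) < 2:
            break
        me = _eigengene_matrix(values, labels)
        corr = np.corrcoef(me.to_numpy(float))
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        keep, absorb = modules[i], modules[j]
        labels[labels == absorb] = keep
    return _relabel_by_size(labels)


@dataclass
class ModulePartition:
    """Feature -> module labels with eigengenes and module membership."""

    module_of_feature: pd.Series
    eigengenes: pd.DataFrame  # modules x samples
    membership: pd.DataFrame  # features x modules
    params: NetworkParams

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, module: str) -> list[str]:
        return list(self.module_of_feature.index[self.module_of_feature == module])

    def sizes(self) -> pd.Series:
        return self.module_of_feature.value_counts()


def top_hubs(partition: ModulePartition, module: str, k: int = 5,
             absolute: bool = False) -> list[str]:
    """The k member features with the largest (signed, by default) module
    membership; ties broken by lexicographically smaller feature ID."""
    if module not in partition.modules:
        raise DataError(f"no such module {module!r}")
    members = partition.members(module)
    mm = partition.membership.loc[members, module]
    if absolute:
        mm = mm.abs()
    ranked = sorted(members, key=lambda f: (-mm[f], str(f)))
    return ranked[: min(k, len(ranked))]


@dataclass
class CoexpressionResults:
    """Fitted co-expression network: partition, eigengenes and diagnostics."""

    partition: ModulePartition
    tom: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        sizes = self.partition.sizes()
        modules = self.partition.modules
        rows = [
            {
                "module": m,
                "size": int(sizes.get(m, 0)),
                "mean_membership": float(
                    self.partition.membership.loc[self.partition.members(m), m].mean()
                ),
            }
            for m in modules
        ]
        rows.append(
            {
                "module": UNASSIGNED,
                "size": int(sizes.get(UNASSIGNED, 0)),
                "mean_membership": float("nan"),
            }
        )
        return pd.DataFrame(rows)

    def top_hubs(self, module: str, k: int = 5, absolute: bool = False) -> list[str]:
        return top_hubs(self.partition, module, k, absolute)

    def plot_dendrogram(self, ax=None):
        """Average-linkage dendrogram of 1 - TOM (requires the fit to have
        kept the TOM matrix)."""
        if self.tom is None:
            raise DataError("fit was run without keep_tom=True")
        from matplotlib import pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        d = 1.0 - self.tom.to_numpy(float)
        tree = linkage(squareform(np.clip(d, 0, None), checks=False), method="average")
        dendrogram(tree, ax=ax, no_labels=True, color_threshold=None)
        ax.set_ylabel("1 - TOM")
        return ax


class CoexpressionNetwork:
    """Signed co-expression network model for one group and feature kind.

    Examples
    --------
    >>> net = CoexpressionNetwork(expr_high, NetworkParams(min_module_size=5))
    >>> res = net.fit()
    >>> res.summary()
    """

    def __init__(self, expr: ExpressionMatrix, params: NetworkParams | None = None):
        self.expr = expr
        if params is None:
            params = MIRNA_DEFAULTS if expr.feature_kind == "miRNA" else MRNA_DEFAULTS
        self.params = params

    def fit(self, keep_tom: bool = False) -> CoexpressionResults:
        adj = signed_adjacency(self.expr, self.params.beta)
        tom = tom_similarity(adj)
        labels = detect_modules(1.0 - tom, self.params)
        if (labels != UNASSIGNED).any():
            labels = merge_modules(labels, self.expr, self.params.merge_height)
            me = _eigengene_matrix(self.expr.values, labels)
            mm = module_membership(self.expr, me)
        else:
            me = pd.DataFrame(columns=self.expr.sample_ids)
            mm = pd.DataFrame(index=self.expr.feature_ids)
        partition = ModulePartition(labels, me, mm, self.params)
        return CoexpressionResults(partition, tom if keep_tom else None)
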