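"""Partial-correlation-with-information-theory (PCIT) edge significance and
differential hubbing between two condition-specific networks.

For every unordered trio (x, y, z) the three first-order partial
correlations are computed, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

and averaged as signed ratios into a data-driven tolerance

    eps_xyz = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3,

where a ratio with zero direct correlation contributes 0. The edge (x, y)
is flagged non-significant in trio z when |r_xy| <= |eps * r_xz| and
|r_xy| <= |eps * r_yz|; an edge is significant iff no trio flags it. Trios
containing a degenerate pair (|r| = 1, partials undefined) are skipped and
counted. On top of PCIT significance the workflow keeps only edges with
|direct r| above a threshold (0.90 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DataError, ExpressionMatrix

_DEGENERATE_TOL = 1e-12


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def pcit_significance(r: np.ndarray) -> tuple[np.ndarray, int]:
    """PCIT significance flags for a correlation matrix.

    Returns (significant, skipped_trios): a boolean matrix with False
    diagonal, and the number of unordered trios skipped because a pair had
    |r| = 1 (undefined partials).
    """
    r = np.asarray(r, float)
    n = r.shape[0]
    if r.shape != (n, n) or not np.allclose(r, r.T, atol=1e-10):
        raise DataError("correlation matrix must be square and symmetric")
    if n < 3:
        raise DataError("PCIT needs at least 3 nodes")
    absr = np.abs(r)
    off = ~np.eye(n, dtype=bool)
    degenerate_pair = (absr >= 1.0 - _DEGENERATE_TOL) & off
    one_minus_r2 = np.clip(1.0 - r * r, 0.0, None)

    significant = off.copy()
    skipped_weighted = 0
    idx = np.arange(n)
    for z in range(n):
        rz = r[:, z]
        d = one_minus_r2[:, z]  # 1 - r_az^2
        with np.errstate(divide="ignore", invalid="ignore"):
            # partial of (x, y) given z, over direct r_xy
            pz = (r - np.outer(rz, rz)) / np.sqrt(np.outer(d, d))
            qz = _safe_ratio(np.nan_to_num(pz, nan=0.0, posinf=0.0, neginf=0.0), r)
            # s[a, b] = partial of (b, z) given a, over direct r_bz
            num = rz[None, :] - r * rz[:, None]
            den = np.sqrt(one_minus_r2 * d[:, None])
            s = _safe_ratio(
                _safe_ratio(num, den), np.broadcast_to(rz[None, :], r.shape).copy()
            )
        eps = (qz + s + s.T) / 3.0

        absrz = absr[:, z]
        flag = (absr <= np.abs(eps) * absrz[:, None]) & (absr <= np.abs(eps) * absrz[None, :])

        valid = off & (idx[:, None] != z) & (idx[None, :] != z)
        bad = degenerate_pair | degenerate_pair[:, z][:, None] | degenerate_pair[:, z][None, :]
        skipped_weighted += int((valid & bad)[np.triu_indices(n, 1)].sum())
        significant &= ~(flag & valid & ~bad)
    return significant, skipped_weighted // 3


@dataclass
class PcitNetwork:
    """Per-condition significant-edge network from PCIT.

    ``significant`` already includes the |direct r| > r_threshold filter
    when ``apply_r_threshold`` was on.
    """

    node_ids: list[str]
    direct_r: pd.DataFrame
    significant: pd.DataFrame
    r_threshold: float
    group: str | None = None
    skipped_trios: int = 0
    pcit_significant: pd.DataFrame | None = field(default=None, repr=False)

    def n_connections(self) -> pd.Series:
        return self.significant.sum(axis=1).astype(int)

    def edges(self) -> pd.DataFrame:
        sig = self.significant.to_numpy(bool)
        r = self.direct_r.to_numpy(float)
        iu = np.triu_indices(len(self.node_ids), 1)
        keep = sig[iu]
        return pd.DataFrame(
            {
                "node_a": np.array(self.node_ids)[iu[0][keep]],
                "node_b": np.array(self.node_ids)[iu[1][keep]],
                "r": r[iu][keep],
            }
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [self.group],
                "n_nodes": [len(self.node_ids)],
                "n_edges": [len(self.edges())],
                "r_threshold": [self.r_threshold],
                "skipped_trios": [self.skipped_trios],
            }
        )


class PcitAnalysis:
    """Model-style wrapper: PCIT edge significance for one expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Typically the combined miRNA + mRNA log2 matrix of one group.
    r_threshold : float
        Keep only significant edges with |direct r| above this (0.90).
    apply_r_threshold : bool
        Turn off to study raw PCIT significance.
    also_threshold_partials : bool
        Additionally require every defined first-order partial correlation
        of the edge to exceed the threshold in magnitude (a stricter reading
        of "direct and partial correlation greater than 0.90").
    max_nodes : int
        Guard against accidentally running the O(n^3) scan genome-wide.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        r_threshold: float = 0.90,
        apply_r_threshold: bool = True,
        also_threshold_partials: bool = False,
        group: str | None = None,
        max_nodes: int = 5000,
    ):
        if expr.n_features > max_nodes:
            raise DataError(
                f"{expr.n_features} nodes exceeds the {max_nodes}-node guard; "
                "raise max_nodes to force"
            )
        if expr.n_features < 3:
            raise DataError("PCIT needs at least 3 nodes")
        if expr.n_samples < 4:
            raise DataError("PCIT needs at least 4 samples")
        arr = expr.values.to_numpy(float)
        if (arr.std(axis=1) == 0).any():
            bad = expr.values.index[arr.std(axis=1) == 0]
            raise DataError(f"zero-variance node(s): {list(map(str, bad))}")
        self.expr = expr
        self.r_threshold = r_threshold
        self.apply_r_threshold = apply_r_threshold
        self.also_threshold_partials = also_threshold_partials
        self.group = group

    def fit(self) -> PcitNetwork:
        ids = self.expr.feature_ids
        r = np.clip(np.corrcoef(self.expr.values.to_numpy(float)), -1.0, 1.0)
        sig, skipped = pcit_significance(r)
        pcit_sig = sig.copy()
        if self.apply_r_threshold:
            sig = sig & (np.abs(r) > self.r_threshold)
        if self.also_threshold_partials:
            sig = self._partial_filter(r, sig)
        return PcitNetwork(
            node_ids=ids,
            direct_r=pd.DataFrame(r, index=ids, columns=ids),
            significant=pd.DataFrame(sig, index=ids, columns=ids),
            r_threshold=self.r_threshold,
            group=self.group,
            skipped_trios=skipped,
            pcit_significant=pd.DataFrame(pcit_sig, index=ids, columns=ids),
        )

    def _min_abs_partial(self, r: np.ndarray) -> np.ndarray:
        n = r.shape[0]
        one_minus_r2 = np.clip(1.0 - r * r, 0.0, None)
        min_abs = np.full_like(r, np.inf)
        idx = np.arange(n)
        for z in range(n):
            rz = r[:, z]
            d = one_minus_r2[:, z]
            with np.errstate(divide="ignore", invalid="ignore"):
                pz = (r - np.outer(rz, rz)) / np.sqrt(np.outer(d, d))
            valid = (idx[:, None] != z) & (idx[None, :] != z) & np.isfinite(pz)
            cur = np.where(valid, np.abs(pz), np.inf)
            min_abs = np.minimum(min_abs, cur)
        return min_abs

    def _partial_filter(self, r: np.ndarray, sig: np.ndarray) -> np.ndarray:
        min_abs = self._min_abs_partial(r)
        ok = np.isfinite(min_abs) & (min_abs > self.r_threshold)
        # edges with no valid trio at all (n == 3 degenerate cases) keep their flag
        ok |= ~np.isfinite(min_abs)
        return sig & ok


def differential_hubbing(net_high: PcitNetwork, net_low: PcitNetwork) -> pd.DataFrame:
    """Per-node difference in significant-connection counts, High minus Low,
    sorted ascending by dh (most negative first)."""
    if list(net_high.node_ids) != list(net_low.node_ids):
        raise DataError("node sets differ between the two networks")
    n_high = net_high.n_connections()
    n_low = net_low.n_connections()
    table = pd.DataFrame(
        {
            "node_id": net_high.node_ids,
            "n_high": n_high.to_numpy(),
            "n_low": n_low.to_numpy(),
            "dh": (n_high - n_low).to_numpy(),
        }
    )
    return table.sort_values(["dh", "node_id"]).reset_index(drop=True)


def top_differential_hubs(dh_table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k most negative and k most positive differentially hubbed nodes."""
    neg = dh_table.nsmallest(k, "dh").assign(extreme="negative")
    pos = dh_table.nlargest(k, "dh").sort_values("dh", ascending=False)
    pos = pos.assign(extreme="positive")
    return pd.concat([neg, pos], ignore_index=True)
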