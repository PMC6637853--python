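"""Regulatory impact factor (RIF1, RIF2) and phenotypic impact factor (PIF)
statistics contrasting High and Low condition groups.

With e_Hj, e_Lj the log2-scale target means and r^H_ij, r^L_ij the
within-group Pearson correlations of regulator i with target j:

    PIF_j  = (e_Hj + e_Lj) / 2 * (e_Hj - e_Lj)
    RIF1_i = (1/n_T) * sum_j PIF_j * (r^H_ij - r^L_ij)^2
    RIF2_i = (1/n_T) * sum_j [(e_Hj * r^H_ij)^2 - (e_Lj * r^L_ij)^2]

RIF1 rewards regulators whose wiring to impactful targets changes between
conditions; RIF2 emphasises expression-weighted correlation shifts. Raw
scores are z-standardized over the regulator list. PIF significance is a
two-sided normal tail on the z-scored PIF with BH adjustment — a reporting
convention, not a derived sampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DataError, ExpressionMatrix
from .diffexpr import bh_adjust


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError(f"z-standardization undefined for column {name!r} (sd = 0)")
    return (x - x.mean()) / sd


def pif(log2_high_means: pd.Series, log2_low_means: pd.Series) -> pd.DataFrame:
    """Phenotypic impact factor per feature, with normal-tail p and BH padj.

    A degenerate input (all PIF values equal, sd = 0) yields z = 0 and p = 1
    for every feature rather than an error.
    """
    if list(log2_high_means.index) != list(log2_low_means.index):
        raise DataError("feature lists of the two mean vectors differ")
    h = log2_high_means.to_numpy(float)
    low = log2_low_means.to_numpy(float)
    values = (h + low) / 2.0 * (h - low)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "feature_id": list(log2_high_means.index),
            "pif": values,
            "z": z,
            "p": p,
            "padj": bh_adjust(p),
        }
    )


def _group_corr(reg: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """Pearson correlations of every regulator row with every target row."""
    rz = (reg - reg.mean(1, keepdims=True))
    tz = (tgt - tgt.mean(1, keepdims=True))
    rsd = rz.std(1, ddof=1, keepdims=True)
    tsd = tz.std(1, ddof=1, keepdims=True)
    if (rsd == 0).any() or (tsd == 0).any():
        raise DataError("zero-variance feature in a group; drop it before scoring")
    c = (rz / rsd) @ (tz / tsd).T / (reg.shape[1] - 1)
    return np.clip(c, -1.0, 1.0)


def rif(
    expr_high: ExpressionMatrix,
    expr_low: ExpressionMatrix,
    targets: list[str],
    regulators: list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """RIF1/RIF2 z-scores and ranks for every candidate regulator.

    ``targets`` is typically the set of features carrying significant PCIT
    edges at the |r| > 0.90 filter; ``regulators`` defaults to all features
    (the full expressed list is tested as potential regulators). Both
    matrices must be on the log2 layer with identical feature sets.

    With ``standardize=False`` the z columns repeat the raw scores and no
    error is raised for constant raw scores; otherwise a zero spread across
    regulators is an error naming the offending column.
    """
    if expr_high.layer != "log2" or expr_low.layer != "log2":
        raise DataError("rif expects log2-layer matrices")
    if list(expr_high.values.index) != list(expr_low.values.index):
        raise DataError("feature sets of the two group matrices differ")
    if not targets:
        raise DataError("empty target set")
    if regulators is None:
        regulators = expr_high.feature_ids
    missing = [t for t in list(targets) + list(regulators)
               if t not in expr_high.values.index]
    if missing:
        raise DataError(f"unknown feature(s): {missing[:5]}")
    targets = list(targets)
    regulators = list(regulators)

    h = expr_high.values
    low = expr_low.values
    e_h = h.loc[targets].mean(axis=1).to_numpy(float)
    e_l = low.loc[targets].mean(axis=1).to_numpy(float)
    pif_t = (e_h + e_l) / 2.0 * (e_h - e_l)

    r_h = _group_corr(h.loc[regulators].to_numpy(float), h.loc[targets].to_numpy(float))
    r_l = _group_corr(low.loc[regulators].to_numpy(float), low.loc[targets].to_numpy(float))

    n_t = len(targets)
    rif1 = (pif_t[None, :] * (r_h - r_l) ** 2).sum(axis=1) / n_t
    rif2 = (((e_h[None, :] * r_h) ** 2) - ((e_l[None, :] * r_l) ** 2)).sum(axis=1) / n_t

    if standardize:
        rif1_z = _zscore(rif1, "rif1_z")
        rif2_z = _zscore(rif2, "rif2_z")
    else:
        rif1_z, rif2_z = rif1, rif2
    table = pd.DataFrame(
        {
            "feature_id": regulators,
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": rif1_z,
            "rif2_z": rif2_z,
        }
    )
    table["rank_rif1"] = table["rif1_z"].rank(ascending=False, method="min").astype(int)
    table["rank_rif2"] = table["rif2_z"].rank(ascending=False, method="min").astype(int)
    return table


@dataclass
class RegulatorImpactResults:
    """Fitted regulator scores with ranked views."""

    rif_table: pd.DataFrame
    pif_table: pd.DataFrame
    n_targets: int

    def top_rif(self, column: str = "rif1_z", k: int = 5, negative: bool = False
                ) -> pd.DataFrame:
        ordered = self.rif_table.sort_values(column, ascending=negative)
        return ordered.head(k).reset_index(drop=True)

    def top_pif(self, k: int = 10) -> pd.DataFrame:
        ordered = self.pif_table.reindex(
            self.pif_table["pif"].abs().sort_values(ascending=False).index
        )
        return ordered.head(k).reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_regulators": [len(self.rif_table)],
                "n_targets": [self.n_targets],
                "n_pif_significant": [(self.pif_table["padj"] < 0.05).sum()],
                "top_rif1": [self.top_rif("rif1_z", 1)["feature_id"].iloc[0]],
                "top_pif": [self.top_pif(1)["feature_id"].iloc[0]],
            }
        )

    def plot_pif(self, k: int = 10, ax=None):
        """Horizontal bar chart of the top-|PIF| features."""
        from matplotlib import pyplot as plt

        top = self.top_pif(k).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * k + 1))
        ax.barh(top["feature_id"], top["pif"])
        ax.set_xlabel("PIF")
        return ax


class RegulatorImpact:
    """Model-style wrapper for the RIF/PIF contrast of two groups.

    Parameters
    ----------
    expr_high, expr_low : ExpressionMatrix
        log2-layer matrices of the two groups over the same feature set.
    targets : list of str
        Features eligible as regulated targets (e.g. PCIT-connected nodes).
    regulators : list of str, optional
        Defaults to every feature.
    """

    def __init__(
        self,
        expr_high: ExpressionMatrix,
        expr_low: ExpressionMatrix,
        targets: list[str],
        regulators: list[str] | None = None,
    ):
        self.expr_high = expr_high
        self.expr_low = expr_low
        self.targets = list(targets)
        self.regulators = list(regulators) if regulators is not None else None

    def fit(self) -> RegulatorImpactResults:
        rif_table = rif(self.expr_high, self.expr_low, self.targets, self.regulators)
        pif_table = pif(
            self.expr_high.values.mean(axis=1), self.expr_low.values.mean(axis=1)
        )
        return RegulatorImpactResults(rif_table, pif_table, len(self.targets))
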