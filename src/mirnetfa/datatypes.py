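"""Shared domain containers for expression data, designs and annotation maps.

Expression tables are features x samples pandas DataFrames wrapped with a
``layer`` tag (counts / normalized / log2) so downstream stages can assert
they are operating on the scale they expect, and a ``feature_kind`` tag
(mRNA / miRNA) because module detection uses different minimum sizes for the
two transcript classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYERS = ("counts", "normalized", "log2")
FEATURE_KINDS = ("mRNA", "miRNA")
GROUPS = ("High", "Low")

#: label reserved for features not assigned to any module
UNASSIGNED = "grey"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples. All entries must be finite;
        the counts layer additionally requires non-negative values.
    layer : {"counts", "normalized", "log2"}
        Scale of the values.
    feature_kind : {"mRNA", "miRNA"}
        Transcript class of the rows.
    """

    values: pd.DataFrame
    layer: str
    feature_kind: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DataError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.feature_kind not in FEATURE_KINDS:
            raise DataError(
                f"unknown feature_kind {self.feature_kind!r}; expected one of {FEATURE_KINDS}"
            )
        if self.values.shape[0] == 0:
            raise DataError("no features")
        if self.values.shape[1] == 0:
            raise DataError("no samples")
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise DataError(f"duplicate feature ID(s): {sorted(set(map(str, dup)))}")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise DataError(f"duplicate sample ID(s): {sorted(set(map(str, dup)))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("non-numeric cell in expression matrix")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite value at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.layer == "counts" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataError(
                f"negative count at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise DataError(f"unknown sample ID(s): {missing}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.layer, self.feature_kind)

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise DataError(f"unknown feature ID(s): {missing}")
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], self.layer, self.feature_kind
        )

    def with_values(self, values: pd.DataFrame, layer: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, layer, self.feature_kind)


@dataclass
class GroupDesign:
    """Sample-to-group assignment with per-sample breeding values.

    ``table`` has one row per sample with columns ``sample_id``, ``group``
    (High/Low), ``phenotype`` (free label, e.g. OA or CLA), ``gebv`` and
    optionally ``mapped_reads``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "phenotype", "gebv")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"design missing column(s): {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise DataError(f"duplicate sample ID(s) in design: {sorted(set(dup))}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group label(s): {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if not (self.table["group"] == g).any():
                raise DataError(f"group {g!r} has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise DataError(f"unknown group {group!r}")
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def subset(self, sample_ids: list[str]) -> "GroupDesign":
        sub = self.table[self.table["sample_id"].isin(sample_ids)].reset_index(drop=True)
        return GroupDesign(sub)


@dataclass
class TargetMap:
    """miRNA -> set of target gene IDs."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if not genes:
                raise DataError(f"empty target set for miRNA {mirna!r}")

    def __getitem__(self, mirna: str) -> set[str]:
        return self.targets[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __len__(self) -> int:
        return len(self.targets)

    def union(self, mirnas) -> set[str]:
        """Union of the target sets of the given miRNAs (absent IDs ignored)."""
        out: set[str] = set()
        for m in mirnas:
            out |= self.targets.get(m, set())
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise DataError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)
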