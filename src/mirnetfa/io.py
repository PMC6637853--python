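"""Readers and writers for the pipeline's tab-separated exchange formats.

All files are UTF-8 TSV with "." as decimal point. Thousands separators are
rejected on input and never written, so a value like ``745,742`` must be
stored as ``745742``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DataError, ExpressionMatrix, GeneSetCollection, GroupDesign, TargetMap


def _strict_float(text: str, where: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise DataError(f"non-numeric cell {text!r} at {where}") from None


def read_expression(path, layer: str, feature_kind: str) -> ExpressionMatrix:
    """Read a features x samples TSV (first column feature IDs, header samples)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if raw.shape[0] == 0:
        raise DataError(f"{path}: no features")
    if raw.shape[1] < 2:
        raise DataError(f"{path}: malformed header — need a feature-ID column plus samples")
    features = raw.iloc[:, 0]
    data = raw.iloc[:, 1:]
    values = pd.DataFrame(
        [
            [_strict_float(v, f"feature {f!r}, column {c!r}") for c, v in row.items()]
            for f, (_, row) in zip(features, data.iterrows())
        ],
        index=list(features),
        columns=list(data.columns),
        dtype=float,
    )
    return ExpressionMatrix(values, layer=layer, feature_kind=feature_kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_design(path) -> GroupDesign:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[0] == 0:
        raise DataError(f"{path}: empty design")
    table = raw.copy()
    for col in ("gebv", "mapped_reads"):
        if col in table.columns:
            table[col] = [
                _strict_float(v, f"column {col!r}, row {i}") for i, v in enumerate(table[col])
            ]
    return GroupDesign(table)


def write_design(design: GroupDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_target_map(path) -> TargetMap:
    """Read a two-column TSV of (mirna_id, gene_id) pairs."""
    path = Path(path)
    targets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise DataError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            mirna, gene = fields
            targets.setdefault(mirna, set()).add(gene)
    if not targets:
        raise DataError(f"{path}: empty target map")
    return TargetMap(targets)


def write_target_map(target_map: TargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(target_map.targets):
            for gene in sorted(target_map.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, member genes)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line with <3 fields")
            name, desc, *genes = fields
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise DataError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = set(genes)
            descriptions[name] = desc
    if not sets:
        raise DataError(f"{path}: no gene sets")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def write_table(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with header, preserving row order."""
    if table.columns.duplicated().any():
        raise DataError("result table has duplicate column names")
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def group_median_summary(design: GroupDesign, column: str) -> dict[str, float]:
    """Per-group median of a numeric design column (gebv or mapped_reads).

    The median is the middle order statistic; for even n it is the mean of
    the two middle values.
    """
    if column not in design.table.columns:
        raise DataError(f"design has no column {column!r}")
    out: dict[str, float] = {}
    for group in ("High", "Low"):
        vals = design.table.loc[design.table["group"] == group, column].to_numpy(float)
        if vals.size == 0:
            raise DataError(f"empty group {group!r}")
        out[group] = float(np.median(vals))
    return out
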