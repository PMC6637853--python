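"""Bundled reference tables from a Nelore cattle skeletal-muscle fatty-acid study.

Two small worked-example tables ship with the package:

* the sample design for steers divergent in oleic acid (OA, 13 High / 15 Low)
  and conjugated linoleic acid (CLA, 15 / 15) content, with per-animal genomic
  estimated breeding values (GEBVs) and normalized mapped miRNA read counts;
* the Pearson correlations between miRNA and mRNA module eigengenes for the
  four group x phenotype networks, used to exercise the negative-correlation
  p < 0.10 module-pair selection rule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import GroupDesign


def _data_path(name: str):
    return resources.files("mirnetfa").joinpath("data", name)


def load_fatty_acid_design(phenotype: str | None = None) -> GroupDesign:
    """Load the cattle fatty-acid sample design.

    Parameters
    ----------
    phenotype : {"OA", "CLA"}, optional
        Restrict to one fatty-acid phenotype. Default: both.
    """
    with resources.as_file(_data_path("nelore_design.tsv")) as p:
        table = pd.read_csv(p, sep="\t")
    if phenotype is not None:
        if phenotype not in ("OA", "CLA"):
            raise ValueError(f"unknown phenotype {phenotype!r}; expected 'OA' or 'CLA'")
        table = table[table["phenotype"] == phenotype].reset_index(drop=True)
    return GroupDesign(table)


def load_me_correlation_table() -> pd.DataFrame:
    """Load the miRNA-ME vs mRNA-ME correlation table (columns: group,
    mrna_module, mirna_module, r, p)."""
    with resources.as_file(_data_path("me_correlations.tsv")) as p:
        return pd.read_csv(p, sep="\t")
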