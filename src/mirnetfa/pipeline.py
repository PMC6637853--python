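"""End-to-end orchestration: simulate (optional) -> normalize/DE -> per-group
co-expression modules -> eigengene integration -> PCIT -> differential
hubbing -> RIF/PIF -> enrichment, with a run manifest.

Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    DataError,
    ExpressionMatrix,
    GeneSetCollection,
    GroupDesign,
    TargetMap,
    UNASSIGNED,
)
from . import io as mio
from .diffexpr import GroupDifferentialExpression, log_transform, normalize, size_factors
from .integration import correlate_eigengenes, hub_target_enrichment, select_hub_mirnas
from .pcit import PcitAnalysis, differential_hubbing, top_differential_hubs
from .rif import RegulatorImpact
from .simulate import SyntheticConfig, config_to_dict, simulate
from .wgcna import CoexpressionNetwork, NetworkParams, module_eigengene


class StageError(RuntimeError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    Either ``synthetic`` is set (the generator produces the inputs) or the
    four input paths point at user files.
    """

    synthetic: SyntheticConfig | None = None
    mrna_counts: str | None = None
    mirna_counts: str | None = None
    design: str | None = None
    target_map: str | None = None
    gene_sets: str | None = None
    q: float = 0.1
    alpha_me: float = 0.10
    r_threshold: float = 0.90
    hub_k: int = 5
    pif_top: int = 10
    pseudocount: float = 1.0
    include_grey_me: bool = False
    mirna_params: NetworkParams = field(default_factory=lambda: NetworkParams(min_module_size=5))
    mrna_params: NetworkParams = field(default_factory=lambda: NetworkParams(min_module_size=30))
    seed: int = 0

    def validate(self) -> None:
        for thr, name, lo, hi in [
            (self.q, "q", 0, 1),
            (self.alpha_me, "alpha_me", 0, 1),
            (self.r_threshold, "r_threshold", 0, 1),
        ]:
            if not lo < thr < hi:
                raise DataError(f"{name} must be in ({lo}, {hi})")
        if self.synthetic is None:
            missing = [
                n for n in ("mrna_counts", "mirna_counts", "design")
                if getattr(self, n) is None
            ]
            if missing:
                raise DataError(f"no synthetic config and missing input path(s): {missing}")
            for n in ("mrna_counts", "mirna_counts", "design", "target_map", "gene_sets"):
                p = getattr(self, n)
                if p is not None and not Path(p).exists():
                    raise DataError(f"input path for {n} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("samples_per_group", "diff_module_ids", "shift_module_ids",
                        "regulator_ids", "loading_range"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        for key in ("mirna_params", "mrna_params"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = NetworkParams(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("synthetic", "mirna_params", "mrna_params")
        }
        out["synthetic"] = config_to_dict(self.synthetic) if self.synthetic else None
        out["mirna_params"] = self.mirna_params.__dict__
        out["mrna_params"] = self.mrna_params.__dict__
        return out


def _drop_zero_variance(expr: ExpressionMatrix) -> ExpressionMatrix:
    arr = expr.values.to_numpy(float)
    keep = arr.std(axis=1) > 0
    if keep.all():
        return expr
    return ExpressionMatrix(expr.values.loc[keep], expr.layer, expr.feature_kind)


def _log2_matrix(counts: ExpressionMatrix, pseudocount: float) -> ExpressionMatrix:
    return log_transform(normalize(counts, size_factors(counts)), pseudocount)


def combined_group_matrices(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    design: GroupDesign,
    pseudocount: float = 1.0,
) -> dict[str, ExpressionMatrix]:
    """Per-group combined (mRNA + miRNA) log2 matrices, as used by the PCIT
    and regulator-score stages. Each count matrix is normalized separately
    (its own size factors), log2-transformed, stacked, then split by group;
    features with zero variance in either group are dropped from both."""
    log2m = _log2_matrix(mrna, pseudocount)
    log2i = _log2_matrix(mirna, pseudocount)
    stacked = {
        g: pd.concat(
            [log2m.values[design.samples(g)], log2i.values[design.samples(g)]]
        )
        for g in ("High", "Low")
    }
    keep = [
        f
        for f in stacked["High"].index
        if stacked["High"].loc[f].std() > 0 and stacked["Low"].loc[f].std() > 0
    ]
    return {
        g: ExpressionMatrix(stacked[g].loc[keep], "log2", "mRNA") for g in stacked
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage and write result tables plus ``manifest.json``.

    Returns a dict with the in-memory result objects keyed by stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    written: list[Path] = []

    def emit(name: str, table: pd.DataFrame) -> None:
        path = outdir / name
        mio.write_table(table, path)
        written.append(path)

    # --- inputs -----------------------------------------------------------
    try:
        if config.synthetic is not None:
            mrna, mirna, design, truth = simulate(config.synthetic)
            mio.write_expression(mrna, outdir / "mrna_counts.tsv")
            mio.write_expression(mirna, outdir / "mirna_counts.tsv")
            mio.write_design(design, outdir / "design.tsv")
            (outdir / "truth.json").write_text(
                json.dumps(truth.to_json_dict(), indent=1, sort_keys=True)
            )
            written += [
                outdir / "mrna_counts.tsv",
                outdir / "mirna_counts.tsv",
                outdir / "design.tsv",
                outdir / "truth.json",
            ]
            target_map = truth.mirna_targets
            gene_sets = GeneSetCollection(
                {
                    m: set(truth.module_members(m)) & set(mrna.feature_ids)
                    for m in sorted(set(truth.module_of_feature.values()))
                    if m != UNASSIGNED
                    and set(truth.module_members(m)) & set(mrna.feature_ids)
                }
            )
            results["truth"] = truth
        else:
            mrna = mio.read_expression(config.mrna_counts, "counts", "mRNA")
            mirna = mio.read_expression(config.mirna_counts, "counts", "miRNA")
            design = mio.read_design(config.design)
            target_map = (
                mio.read_target_map(config.target_map) if config.target_map else None
            )
            gene_sets = mio.read_gmt(config.gene_sets) if config.gene_sets else None
    except DataError as err:
        raise StageError("inputs", str(err)) from err

    results["design"] = design

    # --- normalization and differential expression ------------------------
    try:
        de_results = {
            kind: GroupDifferentialExpression(
                mat, design, config.q, config.pseudocount
            ).fit()
            for kind, mat in (("miRNA", mirna), ("mRNA", mrna))
        }
        for kind, res in de_results.items():
            emit(f"de_{kind.lower()}.tsv", res.table)
        log2 = {
            "mRNA": _log2_matrix(mrna, config.pseudocount),
            "miRNA": _log2_matrix(mirna, config.pseudocount),
        }
    except DataError as err:
        raise StageError("normalization_de", str(err)) from err
    results["de"] = de_results

    # --- per-group, per-kind co-expression modules ------------------------
    coexp: dict[tuple[str, str], object] = {}
    try:
        for group in ("High", "Low"):
            samples = design.samples(group)
            for kind, params in (("mRNA", config.mrna_params), ("miRNA", config.mirna_params)):
                expr = _drop_zero_variance(log2[kind].subset_samples(samples))
                res = CoexpressionNetwork(expr, params).fit()
                coexp[(group, kind)] = res
                tag = f"{group.lower()}_{kind.lower()}"
                labels = res.partition.module_of_feature.rename("module").rename_axis(
                    "feature_id"
                )
                emit(f"modules_{tag}.tsv", labels.reset_index())
                me = res.partition.eigengenes.rename_axis("module")
                emit(f"eigengenes_{tag}.tsv", me.reset_index())
                mm = res.partition.membership.rename_axis("feature_id")
                emit(f"membership_{tag}.tsv", mm.reset_index())
    except DataError as err:
        raise StageError("coexpression", str(err)) from err
    results["coexpression"] = coexp

    # --- eigengene integration, hubs, enrichment --------------------------
    universe = set(mrna.feature_ids)
    try:
        pair_frames, hubs_all, enrich_frames = [], [], []
        for group in ("High", "Low"):
            mirna_res = coexp[(group, "miRNA")]
            mrna_res = coexp[(group, "mRNA")]
            mirna_me = mirna_res.partition.eigengenes
            mrna_me = mrna_res.partition.eigengenes.copy()
            if config.include_grey_me:
                samples = design.samples(group)
                grey = [
                    f
                    for f, m in mrna_res.partition.module_of_feature.items()
                    if m == UNASSIGNED
                ]
                if len(grey) >= 2:
                    expr = _drop_zero_variance(log2["mRNA"].subset_samples(samples))
                    grey = [g for g in grey if g in expr.values.index]
                    mrna_me.loc[UNASSIGNED] = module_eigengene(expr, grey)
            if mirna_me.empty or mrna_me.empty:
                continue
            pairs = correlate_eigengenes(mirna_me, mrna_me, config.alpha_me)
            pairs.insert(0, "group", group)
            pair_frames.append(pairs)
            hubs = select_hub_mirnas(pairs, mirna_res.partition, config.hub_k)
            for module, members in hubs.items():
                for rank, mid in enumerate(members, start=1):
                    hubs_all.append(
                        {"group": group, "mirna_module": module, "rank": rank,
                         "mirna_id": mid}
                    )
            if target_map is not None and gene_sets is not None and hubs:
                enr = hub_target_enrichment(hubs, target_map, gene_sets, universe)
                if len(enr):
                    enr.insert(0, "group", group)
                    enrich_frames.append(enr)
        pair_table = (
            pd.concat(pair_frames, ignore_index=True)
            if pair_frames
            else pd.DataFrame(
                columns=["group", "mrna_module", "mirna_module", "r", "p", "selected"]
            )
        )
        emit("me_pairs.tsv", pair_table)
        hub_table = pd.DataFrame(
            hubs_all, columns=["group", "mirna_module", "rank", "mirna_id"]
        )
        emit("hub_mirnas.tsv", hub_table)
        enrich_table = (
            pd.concat(enrich_frames, ignore_index=True)
            if enrich_frames
            else pd.DataFrame(
                columns=["group", "mirna_module", "set_name", "overlap", "set_size",
                         "query_size", "universe", "p", "padj"]
            )
        )
        emit("enrichment.tsv", enrich_table)
    except DataError as err:
        raise StageError("integration", str(err)) from err
    results["me_pairs"] = pair_table
    results["hubs"] = hub_table
    results["enrichment"] = enrich_table

    # --- PCIT, differential hubbing ---------------------------------------
    try:
        nets = {}
        combined = combined_group_matrices(mrna, mirna, design, config.pseudocount)
        for group in ("High", "Low"):
            net = PcitAnalysis(combined[group], config.r_threshold, group=group).fit()
            nets[group] = net
            emit(f"pcit_edges_{group.lower()}.tsv", net.edges())
        dh = differential_hubbing(nets["High"], nets["Low"])
        emit("differential_hubbing.tsv", dh)
        emit("differential_hubbing_top.tsv", top_differential_hubs(dh, 5))
    except DataError as err:
        raise StageError("pcit", str(err)) from err
    results["pcit"] = nets
    results["dh"] = dh

    # --- RIF / PIF --------------------------------------------------------
    try:
        connected = sorted(
            set(nets["High"].n_connections()[lambda s: s > 0].index)
            | set(nets["Low"].n_connections()[lambda s: s > 0].index)
        )
        if not connected:
            results["regulators"] = None
            reg_tables_written = False
        else:
            reg = RegulatorImpact(combined["High"], combined["Low"], connected).fit()
            emit("rif.tsv", reg.rif_table)
            emit("pif.tsv", reg.pif_table)
            emit("pif_top.tsv", reg.top_pif(config.pif_top))
            results["regulators"] = reg
            reg_tables_written = True
    except DataError as err:
        raise StageError("regulator_scores", str(err)) from err

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "mirnetfa",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "regulator_tables": reg_tables_written,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
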