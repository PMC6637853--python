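"""Synthetic two-group miRNA + mRNA count generator with planted network truth.

The latent model mirrors the structure the downstream analyses assume:

* mRNA modules: each sample s carries one factor value f_m(s) ~ N(0, sigma_m)
  per module m; a member gene's log-signal is loading_i * f_m(s) plus
  feature-level Gaussian noise. A configurable fraction of genes is left as
  unstructured background ("grey").
* group-specific modules (``diff_module_ids``): the factor is drawn only in
  the High group (with mean ``diff_mean``) and is identically zero in the Low
  group, planting edges that exist in exactly one condition.
* planted differential expression (``shift_module_ids``): members of these
  modules get a fixed +``shift_log2`` log2-scale offset in the High group,
  leaving their co-expression structure untouched.
* miRNA repression: each miRNA is assigned a target module and receives
  -repression_strength * c_i * f_m(s) plus noise, i.e. it is negatively
  correlated with the module it represses. One designated miRNA per module
  (the "primary repressor") has multiplier c_i = 1; the rest draw weaker
  multipliers, so hub recovery is a real test.
* designated regulators: extra mRNA features that track one module's factor
  in the High group only and are matched-variance noise in the Low group,
  planting a node whose connectivity differs strongly between conditions.

Counts are negative-binomial (variance mu + dispersion * mu^2) around
library-size-scaled softmax abundances, via the Gamma-Poisson mixture.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import DataError, ExpressionMatrix, GroupDesign, TargetMap

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings. Defaults emulate a two-group cattle muscle design
    (13 High vs 15 Low samples) at desk scale."""

    n_mrna: int = 300
    n_mirna: int = 30
    n_modules: int = 6
    samples_per_group: tuple[int, int] = (13, 15)
    module_signal_sd: float = 1.0
    noise_sd: float = 0.1
    mirna_noise_sd: float = 0.4
    repression_strength: float = 0.8
    repression_multiplier_range: tuple[float, float] = (0.7, 0.95)
    diff_module_ids: tuple[int, ...] = ()
    diff_mean: float = 1.0
    shift_module_ids: tuple[int, ...] = (0,)
    shift_log2: float = 2.0
    regulator_ids: tuple[str, ...] = ("reg1",)
    regulator_target_module: int = 0
    grey_frac: float = 0.1
    loading_range: tuple[float, float] = (0.9, 1.0)
    nb_dispersion: float = 0.005
    library_size_mean: float = 750_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 2:
            raise DataError("n_modules must be >= 2")
        if min(self.samples_per_group) < 4:
            raise DataError("samples_per_group must each be >= 4")
        if self.repression_strength < 0:
            raise DataError("repression_strength must be >= 0")
        if not 0 <= self.grey_frac < 1:
            raise DataError("grey_frac must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise DataError("nb_dispersion must be >= 0")
        if any(m < 0 or m >= self.n_modules for m in self.diff_module_ids):
            raise DataError("diff_module_ids out of range")
        if any(m < 0 or m >= self.n_modules for m in self.shift_module_ids):
            raise DataError("shift_module_ids out of range")
        if not 0 <= self.regulator_target_module < self.n_modules:
            raise DataError("regulator_target_module out of range")
        if self.n_mrna < self.n_modules:
            raise DataError("n_mrna must be >= n_modules")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the simulated matrices."""

    module_of_feature: dict[str, str]
    mirna_targets: TargetMap
    differential_edges: set[tuple[str, str]]
    regulator_ids: tuple[str, ...]
    repressor_of_module: dict[str, str] = field(default_factory=dict)
    shifted_features: set[str] = field(default_factory=set)

    def module_members(self, module: str) -> list[str]:
        return sorted(f for f, m in self.module_of_feature.items() if m == module)

    def to_json_dict(self) -> dict:
        return {
            "module_of_feature": self.module_of_feature,
            "mirna_targets": {m: sorted(g) for m, g in self.mirna_targets.targets.items()},
            "differential_edges": sorted(map(list, self.differential_edges)),
            "regulator_ids": list(self.regulator_ids),
            "repressor_of_module": self.repressor_of_module,
            "shifted_features": sorted(self.shifted_features),
        }


def _orthogonalize_rows(block: np.ndarray, sd: float) -> np.ndarray:
    """Gram-Schmidt on centered rows; each output row has zero sample
    correlation with every earlier row and standard deviation ``sd``."""
    out = block.astype(float).copy()
    n = out.shape[1]
    for i in range(out.shape[0]):
        row = out[i] - out[i].mean()
        for j in range(i):
            prev = out[j] - out[j].mean()
            denom = prev @ prev
            if denom > 0:
                row = row - (row @ prev) / denom * prev
        rsd = row.std()
        if rsd > 0:
            row = row * (sd / rsd)
        out[i] = row
    return out


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate(config: SyntheticConfig):
    """Draw one dataset.

    Returns
    -------
    (mrna, mirna, design, truth)
        Two counts-layer :class:`ExpressionMatrix` objects, the
        :class:`GroupDesign`, and the :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_high, n_low = config.samples_per_group
    n_samples = n_high + n_low
    high_ids = [f"H{i + 1:02d}" for i in range(n_high)]
    low_ids = [f"L{i + 1:02d}" for i in range(n_low)]
    sample_ids = high_ids + low_ids
    in_high = np.array([True] * n_high + [False] * n_low)

    # module factors: n_modules x n_samples, empirically decorrelated within
    # each group so chance factor-factor correlation cannot mimic planted
    # differential wiring at this sample size
    factors = rng.normal(0.0, config.module_signal_sd, size=(config.n_modules, n_samples))
    for mask in (in_high, ~in_high):
        factors[:, mask] = _orthogonalize_rows(
            factors[:, mask], config.module_signal_sd
        )
    for m in config.diff_module_ids:
        factors[m, in_high] = factors[m, in_high] + config.diff_mean
        factors[m, ~in_high] = 0.0

    # mRNA module assignment: contiguous blocks, tail fraction left grey
    n_grey = int(round(config.grey_frac * config.n_mrna))
    n_structured = config.n_mrna - n_grey
    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_mrna)]
    module_of: dict[str, str] = {}
    module_index = np.full(config.n_mrna, -1)
    for i in range(n_structured):
        m = i * config.n_modules // n_structured
        module_index[i] = m
        module_of[gene_ids[i]] = f"module{m}"
    for i in range(n_structured, config.n_mrna):
        module_of[gene_ids[i]] = "grey"

    loadings = rng.uniform(*config.loading_range, size=config.n_mrna)
    log_signal = np.zeros((config.n_mrna, n_samples))
    for i in range(config.n_mrna):
        m = module_index[i]
        if m >= 0:
            log_signal[i] = loadings[i] * factors[m]
    log_signal += rng.normal(0.0, config.noise_sd, size=log_signal.shape)

    shifted: set[str] = set()
    ln2 = np.log(2.0)
    for m in config.shift_module_ids:
        rows = np.where(module_index == m)[0]
        log_signal[np.ix_(rows, np.where(in_high)[0])] += config.shift_log2 * ln2
        shifted.update(gene_ids[i] for i in rows)

    # designated regulators: extra mRNA features, High-group trackers
    reg_rows = []
    m_reg = config.regulator_target_module
    sd_match = np.sqrt(config.module_signal_sd**2 + config.noise_sd**2)
    low_idx = np.where(~in_high)[0]
    for _ in config.regulator_ids:
        row = np.empty(n_samples)
        row[in_high] = factors[m_reg, in_high] + rng.normal(0, config.noise_sd, n_high)
        # Low-group profile: noise decorrelated from every Low-group factor
        low = rng.normal(0.0, sd_match, n_low)
        stacked = np.vstack([factors[:, low_idx], low])
        row[~in_high] = _orthogonalize_rows(stacked, sd_match)[-1]
        reg_rows.append(row)
    for rid in config.regulator_ids:
        module_of[rid] = "grey"

    mrna_ids = gene_ids + list(config.regulator_ids)
    mrna_signal = (
        np.vstack([log_signal] + [r[None, :] for r in reg_rows]) if reg_rows else log_signal
    )

    # miRNAs: round-robin target module, one full-strength repressor per module
    mirna_ids = [f"mir{i + 1:03d}" for i in range(config.n_mirna)]
    mirna_module = np.array([i % config.n_modules for i in range(config.n_mirna)])
    multipliers = rng.uniform(*config.repression_multiplier_range, size=config.n_mirna)
    repressor_of_module: dict[str, str] = {}
    for m in range(config.n_modules):
        assigned = np.where(mirna_module == m)[0]
        if assigned.size:
            multipliers[assigned[0]] = 1.0
            repressor_of_module[f"module{m}"] = mirna_ids[assigned[0]]
    mirna_signal = np.zeros((config.n_mirna, n_samples))
    for i in range(config.n_mirna):
        mirna_signal[i] = (
            -config.repression_strength * multipliers[i] * factors[mirna_module[i]]
        )
    mirna_signal += rng.normal(0.0, config.mirna_noise_sd, size=mirna_signal.shape)
    for i, mid in enumerate(mirna_ids):
        module_of[mid] = f"module{mirna_module[i]}"

    targets = {
        mid: {g for g, mod in zip(gene_ids, module_index) if mod == mirna_module[i]}
        for i, mid in enumerate(mirna_ids)
    }
    mirna_targets = TargetMap({m: g for m, g in targets.items() if g})

    # counts: feature baseline + signal -> softmax abundance -> NB counts
    def draw_counts(ids, signal):
        base = rng.normal(0.0, 1.2, size=len(ids))
        intensity = np.exp(base[:, None] + signal)
        props = intensity / intensity.sum(axis=0, keepdims=True)
        lib = np.exp(rng.normal(np.log(config.library_size_mean), 0.2, size=n_samples))
        mu = props * lib[None, :]
        return _nb_counts(rng, mu, config.nb_dispersion).astype(float)

    mrna_counts = draw_counts(mrna_ids, mrna_signal)
    mirna_counts = draw_counts(mirna_ids, mirna_signal)

    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_counts, index=mrna_ids, columns=sample_ids), "counts", "mRNA"
    )
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_counts, index=mirna_ids, columns=sample_ids), "counts", "miRNA"
    )

    gebv = np.concatenate(
        [rng.normal(2.5, 0.8, size=n_high), rng.normal(-4.0, 2.0, size=n_low)]
    )
    design = GroupDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": ["High"] * n_high + ["Low"] * n_low,
                "phenotype": "synthetic",
                "gebv": np.round(gebv, 3),
                "mapped_reads": mirna_counts.sum(axis=0),
            }
        )
    )

    # differential edges: pairs inside High-only modules + regulator wiring
    diff_edges: set[tuple[str, str]] = set()
    for m in config.diff_module_ids:
        members = [gene_ids[i] for i in np.where(module_index == m)[0]]
        diff_edges.update(
            tuple(sorted((a, b))) for k, a in enumerate(members) for b in members[k + 1 :]
        )
    reg_targets = [gene_ids[i] for i in np.where(module_index == m_reg)[0]]
    for rid in config.regulator_ids:
        diff_edges.update(tuple(sorted((rid, t))) for t in reg_targets)

    truth = SyntheticTruth(
        module_of_feature=module_of,
        mirna_targets=mirna_targets,
        differential_edges=diff_edges,
        regulator_ids=tuple(config.regulator_ids),
        repressor_of_module=repressor_of_module,
        shifted_features=shifted,
    )
    return mrna, mirna, design, truth


def _validate_seq(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise DataError(f"invalid character(s) {sorted(bad)} in sequence {name!r}")
    return s


def seed_match_targets(mirna_seqs, utr_seqs) -> TargetMap:
    """Toy seed-match target prediction for building synthetic target maps.

    A gene is a target of a miRNA iff the reverse complement of miRNA
    positions 2-8 (the 7-mer seed) occurs in the gene's UTR sequence.
    Accepts a single miRNA sequence (keyed ``"mirna"``) or a mapping
    ``mirna_id -> sequence``; sequences may use U or T.
    """
    if isinstance(mirna_seqs, str):
        mirna_seqs = {"mirna": mirna_seqs}
    utrs = {g: _validate_seq(s, g) for g, s in utr_seqs.items()}
    out: dict[str, set[str]] = {}
    for mid, seq in mirna_seqs.items():
        s = _validate_seq(seq, mid)
        if len(s) < 8:
            raise DataError(f"miRNA {mid!r} shorter than 8 nt")
        seed = s[1:8]
        site = "".join(_RC[c] for c in reversed(seed))
        hits = {g for g, u in utrs.items() if site in u}
        if hits:
            out[mid] = hits
    return TargetMap(out) if out else TargetMap({})


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
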