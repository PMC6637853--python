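# Methods

This note records the statistical model behind each stage, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Differential expression

Counts are normalized by median-of-ratios size factors: for sample *j*,
`s_j` is the median over reference features (those with strictly positive
counts in every sample) of `c_ij / geomean_i`. Factors are used as-is, with
no re-centering. The median of an even number of ratios is the arithmetic
mean of the two middle values; implementations that interpolate in log
space differ by ~0.1% in that case, which is why the cross-check against an
independent implementation uses an odd reference count.

The two-group test is Welch's *t* on `log2(normalized + 1)` with
Benjamini–Hochberg control at *q* = 0.1. This is a deliberate substitute
for a negative-binomial Wald test: at 13–15 samples per group the Welch
statistic is well calibrated on log counts, has a closed form that unit
tests can pin down, and keeps the package free of iterative GLM fitting.
The consequences are (a) slightly conservative behaviour for very low
counts, where the NB likelihood is more powerful, and (b) no dispersion
shrinkage, independent filtering or outlier handling. A feature constant in
both groups gets *p* = 1 when the means agree and *p* = 0 otherwise.

The log2 fold change is always mean(High) − mean(Low); positive means
higher in the High group. Published tables in this field sometimes orient
fold changes the other way around per contrast (a reported positive value
described as "up in Low"); this package fixes one convention instead.

The Table-1-style design summary deserves a note: the bundled study design
prints a summary row labelled "Mean" whose values equal the per-group
*medians* (e.g. the 13 High-OA GEBVs average ≈2.54 but the printed value is
2.16, their median). `group_median_summary` therefore reports medians and
this discrepancy is documented rather than guessed away.

## Signed co-expression networks

Adjacency is `((1 + r)/2)^β` with Pearson *r* and β = 6, so anti-correlated
features get near-zero connection strength (signed convention).
Topological overlap is

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with `k_i = Σ_{u≠i} a_iu`, `TOM_ii = 1`. Features are clustered by
average-linkage on 1 − TOM.

Module detection uses a **static cut plus eigengene merge** instead of
dynamic tree cutting: the tree is cut at a fixed height, clusters below the
minimum size (30 mRNA / 5 miRNA) become "grey" (unassigned), and modules
whose eigengene dissimilarity `1 − cor(ME_a, ME_b)` is below 0.25 are merged
iteratively (closest pair first, MEs recomputed after each merge). This is
the package's principal simplification of the reference methodology; the
minimum sizes and the 0.25 merge height are the field-standard values.

The cut height defaults to 0.75. In a signed β = 6 network, uncorrelated
features have adjacency 2⁻⁶ and pairwise TOM dissimilarity near 1, and
average-linkage joins *unrelated* clusters at heights ≈0.95–0.98, while
genuinely co-expressed clusters close below ≈0.8. A cut in between separates
modules and leaves unstructured features unassigned; 0.75 was fixed after
inspecting dendrogram height distributions on simulated data and is
deliberately below the between-cluster band so that background features fall
out as grey rather than being absorbed (the merge step repairs any
over-splitting the lower cut causes).

The module eigengene is the first right singular vector of the
per-feature-standardized member matrix, scaled to unit sample variance and
oriented so the mean member–ME correlation is non-negative. Module
membership MM is the Pearson correlation of each feature with each ME. Hub
features are the top-k *signed* MM values (ties broken by feature ID); an
absolute-MM ranking is available by flag, since either reading of "greatest
membership" is defensible. Modules are named `module0, module1, …` in
decreasing size order; decorative colour names are not reproduced.

Unassigned ("grey") features are excluded from hub selection and merging.
Whether a grey pseudo-module should take part in eigengene integration is
genuinely ambiguous in practice; the pipeline exposes `include_grey_me`
(default off) to compute a grey ME and include it.

## miRNA–mRNA integration

Within each group, every miRNA-module ME is correlated with every
mRNA-module ME; a pair is selected when *r* < 0 and the two-sided *p* from
the Student transform `t = r √((n−2)/(1−r²))` is below 0.10. Only negative
correlations are eligible because the canonical effect of a miRNA on its
targets is repression. A permutation option replaces the *t* transform for
small or non-normal samples. Hub miRNAs are taken from miRNA modules in at
least one selected pair; their pooled target genes, intersected with the
expressed-gene universe, are tested per gene set by the hypergeometric
upper tail with BH adjustment across sets.

## PCIT and differential hubbing

For every unordered node trio the three first-order partial correlations
are computed and averaged as signed ratios into the tolerance ε; edge
(x, y) is flagged in trio z when `|r_xy| ≤ |ε r_xz|` **and**
`|r_xy| ≤ |ε r_yz|`; an edge is significant iff no trio flags it.
Conventions fixed by the internal brute-force oracle: ratios with zero
direct correlation contribute 0 to ε; comparisons are ≤; trios containing a
|r| = 1 pair are skipped and counted. On top of PCIT significance the
workflow keeps only edges with |direct r| > 0.90; whether the partial
correlations themselves must also exceed the threshold is ambiguous in the
source methodology, so that stricter reading is available as
`also_threshold_partials` (default off).

Differential hubbing is `dh = n_High − n_Low` significant connections per
node; negative dh means more connections in the Low group. The
implementation is O(n³) in nodes and refuses more than 5 000 nodes unless
forced — genome-wide runs belong on a cluster, and the desk-scale surface
is where correctness is provable.

## RIF1 / RIF2 / PIF

Targets are the features carrying at least one significant filtered PCIT
edge in either group; every expressed feature is a candidate regulator. On
log2 means `e`:

    PIF_j  = ½ (e_Hj + e_Lj)(e_Hj − e_Lj)
    RIF1_i = (1/n_T) Σ_j PIF_j (r^H_ij − r^L_ij)²
    RIF2_i = (1/n_T) Σ_j [(e_Hj r^H_ij)² − (e_Lj r^L_ij)²]

The sums run over all targets including, when a regulator is itself a
target, the self pair — its RIF1 contribution is exactly zero and its RIF2
contribution is the feature's own expression contrast, so no exclusion mask
is applied. Both scores are z-standardized over the regulator list (sample
sd); a zero spread is an error naming the column, and `standardize=False`
exposes the raw scores. Note that swapping the group labels negates both
raw scores: the squared correlation difference in RIF1 is symmetric, but
its PIF weight changes sign with the contrast.

PIF "significance" is a reporting convention, not a sampling distribution:
the PIF vector is z-scored, given two-sided normal-tail *p* values and BH
adjustment. It ranks features by how extreme their abundance-weighted
expression contrast is relative to the transcriptome; the top-10 |PIF|
table mirrors the field's reporting habit.

## Synthetic data generator

Per sample, each module *m* carries a latent factor; member gene *i* has
log-signal `loading_i · f_m(s)` plus N(0, noise_sd) noise, miRNAs assigned
to module *m* get `−repression_strength · c_i · f_m(s)` plus their own
(larger) noise, and counts are negative-binomial (variance μ + φμ²) around
library-size-scaled softmax abundances. All randomness flows from one seed;
identical configs are bit-identical.

Design choices that matter:

* **Within-group factor orthogonalization.** Module factors are
  Gram-Schmidt decorrelated within each group. At 13–15 samples the chance
  correlation between two independent factors has sd ≈ 0.28, which is
  enough for a whole bystander module to mimic planted differential wiring;
  orthogonalizing makes the planted regulator the only systematic
  cross-module differential signal. Real data has no such guarantee — see
  the limitations below.
* **Correlation placement relative to the 0.90 filter.** mRNA defaults
  (noise_sd 0.1, loadings U(0.85–1.0) scaled by a unit-variance factor,
  dispersion 0.005) put within-module correlations near 0.95, safely above
  the workflow's |r| > 0.90 edge filter, because planted edges must survive
  the specified filter to constitute ground truth. miRNAs get
  mirna_noise_sd 0.4 and repression multipliers U(0.7–0.95), putting
  repression correlations near −0.8: strong enough for eigengene selection
  at *p* < 0.10 with n = 13 but below the edge filter, so miRNA–target
  blocks do not dominate differential hubbing. One designated full-strength
  (c = 1) repressor per module makes hub recovery a real ranking test.
* **Planted signals.** One module (default `module0`) is shifted +2 log2
  units (4-fold) in the High group — a planted DE signal whose stable sign
  also anchors the RIF1 weights. The designated regulator tracks that
  module's factor in the High group and is matched-variance noise,
  decorrelated from all factors, in the Low group. Optional
  `diff_module_ids` plant modules whose factor exists in only one group
  (differential co-expression blocks). Group sizes default to (13, 15),
  mirroring the motivating study design.

What the generator does **not** emulate: transcriptome-scale feature counts
(hundreds, not ~17 000, so multiple-testing burdens and PCIT trio counts are
orders of magnitude smaller); unbalanced module sizes and hierarchically
nested modules; correlated module factors (real pathways co-vary);
batch/library artefacts beyond a log-normal library-size spread;
sequence-driven targeting (the truth target map is the planted module
membership; a toy 7-mer seed-match utility exists only to build synthetic
maps). Passing recovery tests therefore demonstrates that the chain of
estimators is implemented correctly and is sensitive at realistic n, not
that real tissue data will yield equally clean rankings.

## Numerical conventions

* Pearson correlations are clipped to [−1, 1]; eigengene SVD signs are
  fixed by the mean-membership rule; MM ties in hub ranking break by
  lexicographic feature ID.
* BH adjustment is the standard step-up; the adjusted values are compared
  against *q* rather than re-running the procedure.
* PCIT ratio conventions as above; the vectorized implementation is pinned
  to a literal triple-loop oracle in the tests.
* Degenerate inputs fail fast with the offending feature/sample named:
  zero-variance features in correlation stages, empty groups, missing
  samples, non-finite values.
* Problem sizes used by the test suite and the acceptance script (300 mRNA
  / 30 miRNA / 5–6 modules, 5-seed recovery experiments, 100-seed DE power
  at 120 genes, 30-seed PCIT null at 40 nodes) were chosen so the planted
  effects are identifiable at the study's sample sizes while each
  experiment completes in seconds.

## Known limitations

* The DE stage is a Welch contrast, not an NB GLM; exact statistics from
  count-model tools will differ, especially at low counts.
* The static cut is not dynamic tree cutting; deeply nested module
  structure will be resolved differently.
* PIF p-values are a labelling convention (see above).
* PCIT is exact but cubic; genome-wide inputs need external infrastructure.
* The RIF formulas follow the original published statistics; variants exist
  in the literature and each is isolated behind a single function so
  alternates can be swapped.
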