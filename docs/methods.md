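# Methods

This note documents the models, parameter choices and numerical
conventions behind `lncnet`, and what the synthetic validation does and
does not establish.

## Study design and data model

The pipeline targets a small two-group bulk transcriptome study: 11 tumor
vs 5 normal samples, each gene quantified as a non-negative FPKM-like
abundance, genes labelled mRNA or lncRNA. All statistics operate
post-quantification; read simulation, alignment and transcript assembly
are out of scope.

Expression is modelled log-normally: log₂ abundances are Normal around a
per-gene baseline μ_g ~ Uniform[2, 8] (log₂ FPKM), with residual SD
`noise_sd` (default 0.3 log₂ units). A negative-binomial count model would
be appropriate for raw reads, but the pipeline's inputs are normalized
abundances, for which the log-normal is the standard working
approximation. The distribution choice is ours; nothing downstream depends
on it beyond approximate log-scale normality.

## Differential expression

* Fold change: FC = (mean_T + c)/(mean_N + c) with pseudocount c = 0.25
  inside both means, so genes unexpressed in one group remain computable
  (observed |log₂FC| ≈ 14 in real studies implies near-zero denominators).
* Test: two-sided Welch *t* on log₂(x + c). The original two-step
  assembly/testing stack is replaced deliberately: Welch on log₂ values
  reproduces the *filtering logic* without a transcript-assembly
  dependency, and is exact under the generator's log-normal model. Zero
  pooled variance with equal means gives p = 1; with unequal means, the
  smallest positive double.
* Multiplicity: Benjamini–Hochberg step-up, computed per biotype (lncRNAs
  and mRNAs are reported as separate populations; a pooled mode exists).
* Significance: FC > 2 or FC < 0.5, p < 0.05, FDR < 0.1, all strict
  inequalities. A gene at FC = 2.0 exactly is not significant.
* Heatmap ordering: UPGMA (average linkage) on 1 − Pearson distance over
  the significant genes (and over samples), hand-implemented so the
  tie-break is deterministic: tied merges are resolved toward the
  lexicographically smallest combined member-id tuple, and a merged
  cluster's leaf order puts the cluster holding the smaller id first.
  Constant rows get the maximal distance 2 with a logged warning.

## Positional classification

The six-way taxonomy is operationalized by precedence (the first matching
rule wins, making the label independent of coding-gene iteration order):

1. exonic sense — ≥ 1 bp overlap between a lncRNA exon and a same-strand
   coding exon;
2. intronic sense — lncRNA span contained in a same-strand coding span
   with no exonic overlap;
3. / 4. the antisense twins of 1–2;
5. bidirectional — no overlap with any coding span and lncRNA TSS within
   `promoter_window` (default 1000 bp, boundary inclusive) of an
   opposite-strand coding TSS;
6. intergenic — otherwise.

Classification is at gene level (multi-isoform genes collapse to the union
of exons). Coordinates are 0-based half-open internally; GTF input (1-based
inclusive) is converted on read via pyranges, and a write/read round-trip
preserves models and labels exactly. Chromosome names are normalized to
the `chr`-prefixed dialect. A lncRNA on a chromosome with no indexed
coding gene is intergenic by definition (logged).

## Co-expression networks

Correlations are computed on log₂(x + c) across the tumor cohort by
default (the biologically relevant covariation; configurable to all
samples). The edge rule is |r| ≥ cut with the sign kept as an attribute —
both positively and negatively correlated pairs are linked. Two regimes:
general network |r| ≥ 0.90 with no p cut; seeded sub-networks |r| ≥ 0.80
and p < 0.001 (raw, matching the field's convention; BH-adjusted mode
available). The published convention is ambiguous between ≥ and >; we use
≥ for the correlation cut and strict < for p. p-values use the exact-null
t transform on n − 2 df. Nodes are exactly the endpoints of retained
edges; constant-expression genes are dropped before correlation with a
logged count. Degree ties in hub ranking break lexicographically.

## Pathway enrichment and the act network

Fisher's exact test, one-sided (greater), on the 2×2 table built against a
universe of all detected coding genes — the standard expressed-background
choice, configurable. Significance keeps −log₁₀(p) strictly above 1.3
(p < 10^−1.3 ≈ 0.0501), unadjusted, again matching the convention the
pipeline reproduces. The activation z-score
z = (n_consistent − n_inconsistent)/√n over a set's significant DE members
with annotated expected directions (|z| ≥ 2 calls activated/suppressed) is
an explicit, open stand-in for proprietary causal-analytics scores and is
labelled as such in the output metadata. The pathway-act network joins two
of the top-k (default 20) most significant sets when they share strictly
more than `min_shared` (default 5) DE genes.

## qPCR quantification

Replicate wells (three by default) are averaged arithmetically per
(sample, gene); ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean
normal-group ΔCt, i.e. the calibrator is the normal group's geometric-mean
expression — the normal group's geometric-mean relative expression is 1 by
construction. A per-sample calibrator mode exists. Group comparison uses
Welch's t by default (11 vs 5 is unbalanced); the pooled-variance Student
variant is a flag. Relative expression is invariant to any constant Ct
shift, and the reference gene self-quantifies to 1 in every sample.

## Synthetic generator

* **DE planting**: the leading gene ids of each biotype carry the up then
  down shifts (|log₂FC| default 4, applied on the log₂ scale before
  noise), so the realized group log₂-mean difference equals the planted
  value exactly at zero noise.
* **Correlation planting**: planted edges form star modules (hub lncRNA
  with mRNA satellites, or hub mRNA with lncRNA satellites; non-star
  components are rejected). The hub carries a latent factor ẑ constructed
  orthonormally *in sample* over the tumor cohort; each satellite is
  ρ₀ ẑ + √(1−ρ₀²) ε̂ with ε̂ residualized against ẑ, so at zero noise the
  realized tumor-cohort sample correlation equals the target exactly (to
  machine precision). With noise the loading is attenuation-compensated,
  ρ₀ = ρ(1 + noise_sd²/signal_sd²) capped at |1|, so the expected realized
  correlation sits at the target. `signal_sd` (default 2.0 log₂ units) is
  the between-sample biological spread of co-regulated modules — a typical
  magnitude for strongly co-varying transcripts, and large enough that the
  compensated loading stays below 1 at the default noise level.
* **Annotation**: each lncRNA occupies an isolated 100-kb locus with a
  partner coding gene positioned to realize its category unambiguously;
  category counts come from the configured proportions by largest
  remainder and are assigned to gene ids through a seeded permutation so
  the DE subset is not confounded with category. The classifier recovers
  the recorded labels exactly, every seed — a construction round-trip, not
  a statistical claim.
* **Pathways**: pairwise shared-DE counts are realized by dedicated
  disjoint gene blocks (exact by construction); backgrounds cycle through
  the non-DE pool. Expected member directions default to full agreement
  with the planted direction.
* **qPCR**: reference gene at Ct ≈ 18, targets at Ct ≈ 24 in normals and
  24 − log₂(FC) in tumors, well noise Normal(0, 0.1 cycles).
* Seeds are mandatory; each generator draws from its own stream derived
  from the config seed, so generators are independently reproducible.

What the generator does **not** emulate: read-level sampling noise,
isoform structure beyond exons, batch effects, mean–variance coupling,
library-size artifacts, or correlated null genes. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to real-data pathologies.

## Problem sizes and numerical conventions

Validation cohorts use 200–1000 genes — far below genome scale, chosen as
desk-scale recovery experiments; every statistic involved is scale-free.
The Monte-Carlo studies use 50 seeded cohorts for DE recovery, 10 for edge
recovery, 20 for null edge rates and 100 for null DE rates. Other
conventions: −log₁₀ of an FDR of exactly 0 is capped at 320 in plot
tables; BH q-values are clipped to [0, 1]; Fisher p-values come from the
hypergeometric survival function (cross-checked against exhaustive
enumeration in the tests); correlation matrices are clipped to [−1, 1]
before the t transform.

## Known limitations

* The Welch substitution means p-values are not comparable to
  assembly-based differential tests on real data, only the filtering
  semantics are.
* The activation z-score is a sign-consistency statistic; it does not use
  causal edge directions and will not reproduce proprietary scores.
* The bidirectional category depends on an arbitrary (if conventional)
  1-kb promoter window; published analyses rarely state theirs.
* Star-only correlation modules cannot express arbitrary correlation
  structures (e.g. chained or dense modules).
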