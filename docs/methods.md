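# Methods

## Data model

The pipeline operates on an FPKM-scale expression matrix (genes × samples)
with a sample sheet assigning every sample to a (stage, replicate) pair.
Stage labels carry a total order — the time axis — and every stage needs at
least two replicates so that a within-stage noise distribution exists.
Functional categories are Mapman-style bins: dot-separated integer codes
("2.1.3") naming a hierarchy. Roll-up is on by default: a gene assigned to
a sub-bin is a member of every ancestor bin, which is what makes top-level
aggregates such as "major CHO metabolism" testable at all. A gene may
belong to several bins. Genes absent from the mapping are retained for
differential-expression calling and excluded from enrichment universes
under the default `universe = annotated` mode.

## Differential-expression calling

For a contrast (test stage t, reference stage r), stage means are
arithmetic means of replicate FPKM after adding a pseudo-count k = 0.5 to
every value. The pseudo-count guarantees finite statistics for
zero-expression genes; it is exposed in `PipelineConfig.pseudocount`.

Signal per gene: M = log₂(x̄_t / x̄_r) and D = |x̄_t − x̄_r|. Noise: for
each stage of the contrast, every unordered pair of replicates yields one
(|M*|, D*) point per gene, all pooled (2·C(3,2)·G = 6G points for the
default design). The probability of differential expression is the
fraction of noise points strictly dominated by the gene's signal
(m* < |M| and d* < D). Ties count against the gene, so a perfectly flat
gene has probability exactly 0; the probability is monotone in |M| and D.
No kernel smoothing is applied to the noise cloud — the downstream
analysis only consumes threshold behaviour, and the empirical cloud keeps
the estimator simple and exactly reproducible.

A gene is called *up* when 2^M ≥ 2 and probability ≥ 0.8, *down* when
2^(−M) ≥ 2 and probability ≥ 0.8, otherwise *ns*; both thresholds are
inclusive and configurable. This caller is deliberately NOISeq-*like*
rather than a reimplementation of any specific tool: it has no length-bias
correction, no count normalisation and no biological-replicate mode.
Externally produced calls can be passed to `run_pipeline(de_calls=...)`
(or `germclock run --de-calls calls.tsv`) to decouple the enrichment
science from caller fidelity.

## Directional enrichment

Per (rolled-up bin, contrast, direction): the universe has N genes, K of
them in the bin; n genes are differentially expressed in that direction;
k of those are in the bin. Both directions share the same universe. Bins
with K < 5 (configurable) are skipped.

The two-tailed p-value uses minimum-likelihood summation, the convention
of Fisher's exact test: p = Σ P(X = j) over all j in the support with
P(j) ≤ P(k)·(1 + 1e−7). Point probabilities are integer weights
C(K,j)·C(N−K,n−j), and the inclusion rule is evaluated as the exact
integer inequality 10⁷·c_j ≤ (10⁷+1)·c_k, so ties are resolved without
floating-point ambiguity and the result agrees with an
exhaustive-enumeration oracle to machine precision (verified for every
valid table with N ≤ 40). A tail-doubling dialect (`twosided: double`,
clipped to 1) is available for users matching other software.

The signed Z-value is Z = sign(k − nK/N) · Φ⁻¹(1 − p/2), zero when k
equals its expectation, capped at |Z| = 8 (also the value returned if p
underflows to 0). This conversion makes the two significance conventions
coincide exactly: |Z| ≥ 1.96 ⇔ p ≤ 2Φ(−1.96) ≈ 0.0499958, i.e. the
familiar 1.96 ↔ 0.05 rule up to the two-tailed conversion. No
multiple-testing correction is applied by default, matching the raw-Z
threshold convention of category-enrichment heat maps; users wanting FDR
control can apply it downstream on the emitted p column.

## Pathway activity, concordance and the timetable

ΣZ = Z_up − Z_down per (bin, contrast). Classification: ΣZ ≥ 1.96
significantly active, 0 < ΣZ < 1.96 active, −1.96 < ΣZ ≤ 0 inactive,
ΣZ ≤ −1.96 significantly inactive. The boundary is treated as significant
(≥), uniformly. When one direction has no enrichment cell its Z is taken
as 0 — the continuous limit of n = 0 ⇒ p = 1 ⇒ Z = 0. Relabelling every
DE call up↔down negates every ΣZ exactly and swaps the significant
statuses (an invariant the test suite enforces bit-for-bit).

Two contrast systems are built from the stage order: fixed
(s_i vs. s_0 for i ≥ 1) and continuous (s_i vs. s_{i−1}); their first
contrasts coincide. Concordance pairs, per bin and non-baseline stage,
x = ΣZ_fixed with y = ΣZ_continuous. A point is *green* when
|x| < 1.96 and |y| < 1.96; otherwise it is *blue* when strictly inside
quadrant I or III (x·y > 0) and *red* otherwise (including axis points).
Significance at exactly 1.96 counts as significant; the green class is the
strict complement. Bins present in only one system are excluded with a
warning.

The timetable is computed on the fixed system (activity trajectories are
conventionally plotted against the baseline): onset = first significantly
active stage, peak = global argmax of ΣZ (first stage on ties),
offset = first stage after onset with ΣZ ≤ 0. The offset rule is
"loss of activity" rather than "loss of significance" because a pathway
can stay positive-but-not-significant long after its burst; the
alternative rule is available as `offset_rule: nonsignificant`. The global
ordering sorts by onset stage index, then peak stage index, then bincode;
bins never significantly active have no onset and sort last.

## Stage-specific genes

A gene is expressed at a stage when at least 2 of its replicates reach
FPKM ≥ 1 (both configurable; FPKM ≥ 1 is the conventional presence
threshold for FPKM-scale data). The Venn partition assigns a gene to a
stage iff it is expressed at exactly that one stage; all other genes fall
into a shared/unexpressed complement. Raising the threshold shrinks each
gene's expressed-stage set monotonically. An alternative mode
(`specific_mode: de`) derives presence from fixed-system DE status
instead; in that mode the baseline stage has no self-contrast and
therefore cannot own specific genes. Stage-specific genes are joined to
their rolled-up bins; unannotated genes are kept with an empty bin list.

## Synthetic data

The generator emulates the target study design: 6 stages (0, 0.75, 6, 24,
48, 144 h) × 3 replicates, 2000 genes, 20 top-level categories of 60 genes
each (every category split into two sub-bins to exercise roll-up), the
remaining genes unannotated. Baseline means are log-normal (ln-mean 2.0,
ln-σ 1.5 — median ≈ 7 FPKM with a long right tail, a typical bulk FPKM
profile); replicate noise is multiplicative, 2^N(0, 0.25) — i.e. σ = 0.25
on the log₂ scale, a mid-range value for bulk RNA-seq biological
replicates. The seed is split into deterministic substreams (baseline,
responder selection, one per stage), so runs are exactly reproducible and
stages are independently perturbed.

A planted schedule marks categories as up- or down-regulated over a set of
active stages: each responding gene's stage mean is baseline ×
2^(direction · effect_size · weight), with an optional per-stage weight
profile (default 1) that lets a category ramp or decay. The truth table
records every (responder, active stage) with its planted direction and
effective log₂ fold change.

Canonical schedules:

- `canonical_schedule` (effect 2, responder fraction 0.6): CHO
  metabolism (bin 2) up from 0.75 h, decaying after 24 h (weights 1, 1,
  0.8, 0.5); lipid metabolism (bin 11) up 6–48 h (weights 1, 1, 0.8);
  protein metabolism (bin 29) up 6–48 h with a ramp (weights 0.3, 1, 1)
  whose 6 h effect (log₂FC 0.6) sits below the fold-change detection
  threshold, so protein's detected onset trails lipid's. All other
  categories are null. Schedule onsets satisfy
  onset(CHO) < onset(lipid) ≤ onset(protein), and the recovered timetable
  order is CHO → lipid → protein.
- `monotone_schedule`: effect weights grow by 0.75 per active stage
  (log₂FC 1.5 per stage-over-stage step), so expression changes in the
  same direction at every active stage and both contrast systems see
  concordant signals; includes one down-regulated category (bin 27) to
  populate quadrant III.
- `null_schedule`: nothing planted; used for calibration.

What the generator does **not** emulate: count-level sampling noise
(values are FPKM, so noise is log-normal rather than negative binomial),
library-size or gene-length biases, correlated co-expression within
pathways, and outlier replicates. Passing tests therefore demonstrate the
pipeline's statistical machinery and its behaviour under the declared
noise model, not the caller's performance on raw sequencing data.

## Numerical choices and degenerate inputs

- Exact integer combinatorics for hypergeometric point weights; p is
  formed by one float division at the end (error ≲ 1e−15).
- Z cap at 8 (p ≈ 1.2e−15, the edge of double-precision two-tailed
  resolution); underflowed p = 0 returns ±cap.
- K = N (category is the whole universe) forces k = n and p = 1; n = 0
  gives p = 1, Z = 0.
- Argmax ties in the timetable resolve to the earliest stage; ranking
  ties resolve by bincode, so output order never depends on input order.
- Result TSVs are stably sorted on all key columns and floats printed with
  a fixed format, making identical runs byte-identical.

## Problem sizes

Tests and the acceptance script run the default design (2000 genes,
6 × 3 samples) or smaller; the exact-test oracle sweep covers all ~1.4e5
valid tables with N ≤ 40. These sizes exercise every code path while
keeping a full run in tens of seconds; the pipeline itself is vectorised
(chunked dominance counting, cached combinatorial weights) and handles
transcriptome-scale matrices (tens of thousands of genes) without
modification.

## Known limitations

- The DE caller is a simplified nonparametric construction; it is not a
  drop-in replacement for NOISeq and makes no claim of matching its
  probabilities. Use external calls where caller fidelity matters.
- The inverse-normal Z conversion is a declared convention; other
  enrichment tools may transform p to Z differently, which shifts Z values
  but not the significance decisions at the 1.96/0.05 boundary.
- With fewer than two replicates per stage the probability model is
  undefined; the pipeline refuses rather than degrades.
- The concordance blue/red classification is only meaningful for bins
  tested in both contrast systems at the same stage.
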