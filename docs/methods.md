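# Methods

This note records the models, conventions and numerical choices behind
`rnai_nto`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Off-target scanning

A dsRNA trigger is processed into siRNAs from both strands, so a
transcript's off-target exposure is summarized as its longest contiguous
exact match against the trigger sequence (sense) and its reverse
complement (antisense); the per-gene value is the maximum of the two.
`N` bases never match anything: any candidate window containing `N` is
excluded, so assembly gaps cannot inflate match lengths.

The scanner binary-searches the match length, testing a candidate length
L by intersecting the L-mer sets of transcript and trigger.  Because a
common substring of length L implies one of length L−1, feasibility is
monotone and the search is exact.  Correctness is anchored to an
independent quadratic dynamic-programming longest-common-substring
oracle (`synthetic_data.longest_common_substring_dp`), not to the search
strategy; the test suite checks equality on hundreds of random
instances, and every reported occurrence is re-verified as an exact
string match.

**Report binning.** Genes are binned by their per-gene maximum
(exclusive bins 7–14 plus ≥15), so bin totals partition the genes with a
reportable match.  A cumulative (≥k) reading of the published table
would also be monotone-consistent; the exclusive reading was chosen
because it makes the totals a partition and the row conservation law
(up + down + unchanged = total) exact.  Genes absent from the DE table
(filtered upstream for low counts) count as unchanged and their number
is logged, since the table's universe is the transcriptome, not the
tested subset.

**Percent formatting.** Percentages are 100·n/total rounded half-up to
two decimals, computed in exact decimal arithmetic.  Two render styles
exist: the default always prints two decimals ("0.00%"); a legacy style
drops the decimals for integer-valued percentages ("0%", "100%"),
matching the mixed style of the published match-length table.  An empty
bin renders its percentages as an en-dash.

**Match vs fold change.** The association between match length and
expression response is the Spearman rank correlation between the
per-gene maximum and |log₂FC| over genes with a reportable match.  When
either vector is constant the coefficient is undefined by ties and is
reported as 0 with an explicit flag.  Scatter classes use inclusive
boundaries (red: |log₂FC| ≥ 1 and FDR ≤ 0.05; blue: |log₂FC| ≥ 1 and
FDR > 0.05; gray: |log₂FC| < 1).

## Differential expression

The DE stage is a deliberately small two-group negative-binomial Wald
test, certified by planted-truth recovery and type-I-error simulation
rather than by parity with any external engine:

1. size factors by median-of-ratios over genes positive in all samples;
2. gene-wise dispersion α by method of moments pooled across the two
   groups, floored at 1e-8, then shrunk 50/50 toward a fitted trend
   α(μ) = a₀ + a₁/μ (least squares over informative genes);
3. log₂FC = log₂((μ_t + 0.5)/(μ_c + 0.5)) of normalized group means; the
   0.5 pseudo-count keeps fold changes finite for zero-count groups;
4. delta-method standard error
   Var(μ̂_g) = μ_g·E[1/s]/n_g + α·μ_g²/n_g propagated through the log,
   two-sided normal (Wald) p-value, Benjamini–Hochberg FDR.

There is no LFC shrinkage, Cook's filtering or independent filtering.
Degenerate genes (all-zero, or identical normalized means) are reported
as log₂FC = 0, p = 1.  Under the null (α = 0.1, 3 vs 3, 2000 genes) the
measured type-I error at p < 0.05 is ≈ 0.07; with 10% of genes planted
at |log₂FC| = 2 and α = 0.05 at 1M reads/sample, recall is ≈ 0.98 with
empirical FDR < 0.01 (both recomputed by `scripts/acceptance.py`).

**DEG thresholds.** A gene is a significant DEG iff |log₂FC| > 1 and
FDR < 0.05 with *strict* inequalities (the Methods-style convention);
an `inclusive` boundary switch (≥ / ≤, the figure-legend convention) is
provided because the two conventions differ only on measure-zero
boundary cases.  Genes failing significance but with |log₂FC| ≥ 1 are
classed `fold_only`; the rest `unchanged`.

qPCR relative expression uses 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control.

## Homologs and pathway proximity

Homologs of the trigger's source gene are found by affine-gap local
alignment (Gotoh DP, numba-compiled) with BLASTN-like scoring: match +2,
mismatch −3, a gap of length k costs 5 + 2k; `N` scores as a mismatch
even against `N`.  Significance uses the ungapped Karlin–Altschul
formula E = K·m·n·exp(−λS) with K = 0.41, λ = 0.625 and n the total
transcriptome length; the contract is the E < 1e-10 threshold, not the
engine.  Both transcript strands are searched and one best hit per
transcript is kept.  Ties between equal-scoring alignments resolve to
the lowest (query_start, subject_start).  Planted homologs at 90%
identity to a 403 bp trigger score far above threshold; 1 kb random
transcripts essentially never reach it (0 hits in 50 seeded nulls).

"Pathways that interact" is operationalized as shared-gene overlap
(≥ 1 common gene by default, parameterizable), since the pipeline
ingests flat GMT sets without relation graphs.  Level-1 pathways contain
at least one seed gene (the homolog hits plus any caller-supplied ids);
level-(k+1) pathways are unassigned pathways overlapping a level-k
pathway; assignment is breadth-first, deterministic, and order-invariant.
A gene's level is the minimum over its assigned pathways, counted once;
seed genes are excluded from the per-level counts because they are the
cause of the classification, not its effect.

## Enrichment

Over-representation per gene set is the upper-tail hypergeometric
probability P(X ≥ k) for X ~ Hypergeometric(N, K, n), including the
observed k (the standard convention).  Sets are intersected with the
universe first; sets smaller than 3 genes are skipped and logged; BH
correction is applied across tested sets.  The universe defaults to the
tested genes (the DE table), overridable to the full transcriptome —
both conventions are common and the choice shifts absolute p-values but
not the planted-signal ranking the tests certify.

## Transcriptomic entropy

Per sample, H = −Σ pᵢ log₂ pᵢ over size-factor-normalized relative
abundances of raw counts (0·log 0 ≡ 0); 2^H is the effective gene
count.  Base 2 is the default and a natural-log option exists; the
group comparison — a two-sided Student's t-test of per-sample entropies,
two groups, ≥ 2 replicates — is invariant to the base and to per-sample
depth scaling, which is the property that carries the homeostasis
conclusion.  Identical groups are degenerate and reported as t = 0,
p = 1 with a zero-variance flag.  Length (FPKM-style) normalization is
intentionally not applied; the abundance unit cancels in the comparison.

## Synthetic data

The generator emulates the study conditions: a 403 bp trigger, two
groups of 3 replicates, log-normal baseline expression scaled to a
target depth (default 1M reads/sample), NB counts at dispersion 0.05,
~1% DEGs at |log₂FC| = 2, and a ~30 000-gene transcriptome as the
default scale (tests and the acceptance script use smaller gene counts,
chosen so the full suite runs in minutes at desk cost; all rates are
scale-free).

Planted contiguous matches copy trigger-strand substrings into random
transcript positions.  Chance matches are then removed by
verify-and-repair: every transcript window matching a trigger 7-mer
(either strand, outside the planted region) has one base resampled at a
random position within the window, iterating until clean — a fixed
mutation position can cycle when every variant of a window is itself a
trigger k-mer, so the position is randomized.  The final sequence is
verified by the DP oracle: planted genes must match at exactly their
planted length and all other non-homolog genes below 7 bp, else the
generator errors rather than emitting wrong truth.  Pathway collections
are built with disjoint member pools plus one bridge gene per configured
overlap edge, and are self-validated: the pipeline's own breadth-first
assignment must reproduce the configured level of every pathway before
the collection is emitted.  One integer seed fixes all artifacts
byte-for-byte.

What passing these tests shows: the implementation recovers known truth
under its own generative model.  What it does not show: robustness to
real-data features the generator omits — isoform redundancy, shared
domains between unrelated genes, GC- and length-dependent coverage
bias, outlier replicates, or annotation errors in real pathway
databases.

## Pipeline conventions

All tables are TSV with a header, UTF-8, '.' decimal separator; floats
are written with `%.10g` so reruns are byte-identical.  Counts must be
non-negative integers (estimated counts are rounded upstream by the
caller).  Separate datasets (e.g. two life stages) are separate
invocations with no cross-stage sharing.  The run log records versions,
seed, thresholds, per-stage timings and the count of genes excluded at
each filter so report denominators are auditable.  CLI exit codes:
0 ok, 1 input error, 2 internal error.

## Known limitations

- The NB test is a stand-in: no dispersion MAP with gamma-family GLM, no
  LFC shrinkage, no outlier handling; it is slightly anticonservative at
  n = 3 (type-I ≈ 0.07 at nominal 0.05).
- The E-value uses ungapped Karlin–Altschul constants with gapped
  alignments, as fixed engine constants; absolute E-values are
  approximate, the threshold behavior is what is certified.
- Pathway "interaction" by shared genes cannot distinguish regulatory
  direction or relation type.
- Mismatch-tolerant (seed-region) siRNA scoring and thermodynamics are
  out of scope; matching is exact-contiguous only.
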