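# Methods

## Activity model

The model treats a miRNA's predicted target set as a gene set and asks
whether that set is skewed toward one end of the expression change vector —
all genes ordered by decreasing case-minus-comparator differential
statistic.  The test statistic is a weighted Kolmogorov–Smirnov running sum:
walking the vector from rank 1 to N, add √((N−m)/m) at each of the m target
genes and subtract √(m/(N−m)) at each non-target.  The weights make the sum
end exactly at zero, so the extremum D (the value of largest magnitude along
the walk) measures pure positional skew and is invariant to the magnitudes
of the underlying statistics — only ranks matter.  The reported activity
score is AS = −D, fixing the sign convention "positive = activated":
repressed targets sit at the bottom of the vector, drive the running sum to
a negative extremum, and thus a positive AS.

Two numerical choices make the statistic fully deterministic: when the
largest magnitude is attained at several ranks (e.g. a symmetric ±x pair),
the extremum at the smallest rank is taken; and ties in the change statistic
itself are broken by ascending gene identifier when the vector is built.
Degenerate inputs are rejected or skipped explicitly: a miRNA with no target
on the vector is skipped with a logged warning, a target set covering every
gene is an error, and a gene with zero variance in both conditions receives
statistic 0.

The skew statistic could equally be formulated as a rank-sum; the KS-style
running sum was fixed as the package default because its extremum form is
directly checkable against a plain-walk oracle and degrades gracefully when
only part of a target set responds.  Binding-score weighting is deliberately
not applied; when scores are present an optional top-quantile filter
(`affinity_quantile`, default off) can restrict scoring to the
highest-affinity targets instead, which keeps the statistic itself
unweighted and auditable.

## Permutation inference

The null distribution comes from K (default 1000) permutations of the gene
labels of the expression matrix.  Permuting labels leaves every per-gene
statistic unchanged and only reassigns which gene carries which value, so
rebuilding the change vector under a permutation is implemented as a column
permutation of the target-membership indicator over ranks.  One shared
permutation per iteration is used for all miRNAs, preserving the
across-miRNA correlation induced by overlapping target sets.

The per-miRNA empirical p-value is the pseudocounted two-sided exceedance
p = (1 + #{k: |NS(x,k)| ≥ |AS(x)|}) / (K + 1).  This definition (including
the pseudocount and the two-sidedness on |·|) is the package's own — the
deregulation thresholds it feeds are conventional, but a p-value
construction had to be fixed, and the pseudocount keeps p > 0 and the null
calibration exact.  Its resolution floor is 1/(K+1); with the default
p ≤ 0.005 call threshold, K must be at least 200 for any call to be
possible, which is why the fitter warns below K = 100.

The FDR at an observed score AS* ≥ 0 is
[#{(x,k): NS ≥ 0 ∧ NS ≥ AS*}/#{(x,k): NS ≥ 0}] ÷
[#{x: AS ≥ 0 ∧ AS ≥ AS*}/#{x: AS ≥ 0}], mirrored with ≤ for AS* < 0,
capped at 1; a ratio with an empty side is reported as FDR 1 with a warning
(conservative).  This estimator is validated against a brute-force
enumeration of all (x, k) pairs.

Deregulation calls: activated = {AS > 0 ∧ p ≤ p_thr ∧ FDR ≤ fdr_thr},
silenced analogously.  Defaults p_thr = 0.005, fdr_thr = 0.01; validation-
style analyses conventionally relax to fdr_thr = 0.05.

## Preprocessing

*Virtual-reference scaling* (`dasl_normalize`): each sample is multiplied by
(mean of per-sample means)/(its own mean), the normalization used for
bead-array FFPE profiles; it is idempotent and equalises per-sample means.
*Batch adjustment* (`batch_adjust`): per gene, each batch is shifted to the
across-batch mean of batch means and rescaled to the pooled SD, defined as
the square root of the unweighted mean of within-batch variances (ddof 1);
zero-variance gene/batch cells are shifted only.  This transparent
location/scale matching is the package's own stand-in for published
batch-correction methods whose internals are not reproducible here; it is
isolated behind a single function so an empirical-Bayes alternative can be
swapped in without touching anything downstream.  The change statistic is
the Welch t (robust to the strongly unequal group sizes of tumor-vs-normal
compendia); a log-ratio alternative is selectable and the choice is recorded
in the vector metadata.

## Set logic and supporting statistics

Overlap significance between deregulated lists is the one-sided
hypergeometric (Fisher exact) upper tail.  The overlap universe is always
the set of miRNAs actually scored in both analyses (m ≥ 1 target on both
vectors) and is carried on every profile — published overlap p-values
without a stated universe cannot be compared directly, so the universe is
made explicit everywhere here.  Subtype-specific miRNAs are those
deregulated in one condition and, in the same direction, in no other
profile.  Pathway-"switching" miRNAs are activated(pathway-active) ∩
silenced(pathway-inactive).  Pathway-activation probabilities are consumed,
not computed; the activation cutoff is 0.8, inclusive (a stated *minimum*
probability).  Transcript-level comparisons between pathway groups use the
one-tailed Welch t-test with Welch–Satterthwaite degrees of freedom, default
direction "down-regulated in pathway-active" (the repression hypothesis for
miRNA-processing transcripts); constant equal groups return p = 0.5 by
convention with a warning.

Hierarchical clustering is UPGMA (unweighted average linkage over item
pairs) on 1 − Pearson correlation, implemented directly so the documented
tie-break — always merge the pair with the smallest (left, right) cluster
ids among minimum-distance pairs — is guaranteed; correlation distance is
not metric, so non-decreasing merge heights are not guaranteed and a
violation is logged rather than fatal.  Dendrograms export as Newick with
ultrametric half-height branch lengths.

## Enrichment

The EASE score is the one-sided Fisher exact enrichment p recomputed after
reducing the hit∩theme count by one (floored at zero), which exactly
nullifies single-gene support; "global FDR" is Benjamini–Hochberg across all
themes of one analysis.  The default enrichment universe is the expression
matrix's gene complement (the predicted-target union is an alternative the
caller can pass explicitly).

## Small-RNA procedure

Reads are truncated to their leading 21 bases — the mature-miRNA length; for
36-cycle reads the trailing 15 bases run into 3′ adaptor, so it is the
*leading* window that is retained.  Each trimmed read is aligned against
every substring of every precursor in four classes: exact, one substitution,
one base deleted in the read, one base inserted in the read.  Exact mappings
suppress all one-difference mappings for that read; otherwise all
one-difference mappings are reported.  A read contributes one count to every
miRNA it best-maps to (multi-mapping is counted per miRNA and said so in the
report; no fractional allocation rule is imposed).  A miRNA is flagged as a
potential single-base alteration when, in *every* sample/replicate, its
support is at least `min_reads` (default 10) with zero exact-class reads.
Flags are "potential" only: excluding other genomic origins for the variant
reads would need a genome index and is out of scope, and the report says so.
QC reports per-sample mean Phred quality and the implied base-call accuracy
100·(1 − 10^(−Q/10)).

## Synthetic data

The expression generator emulates a two-condition log-scale microarray
compendium: gene intensities ~ Normal(8, σ²) with σ = 1 by default, 2000
genes, 100 miRNAs with 50-gene target sets drawn independently without
replacement (sets may overlap between miRNAs, as real prediction sets do;
the mean pairwise Jaccard overlap is recorded in the ground truth), 20 case
and 20 comparator samples.  A planted activated miRNA has its targets
shifted by −δ·σ in the case samples (repression modelled as an additive
shift on the log scale), a silenced one by +δ·σ; δ = 1.5 by default.
Optional per-batch additive offsets exercise the batch adjustment.  A switch
program splits the case samples into pathway-active and pathway-inactive
halves with the program's targets repressed in the former and de-repressed
in the latter, together with matching synthetic activation probabilities
(active ~ U(0.85, 0.99), others ~ U(0.05, 0.5)).

The read generator emits leading-21-base precursor windows; an altered miRNA
emits only reads carrying its planted edit (deletion/substitution/insertion
inside the window), so downstream it must show ≥ n reads at ≤ 1 difference
and zero exact.  Qualities are discretised Normal(mean_q, 2) clipped to
[2, 41], Phred+33.

What the generator does *not* emulate — probe-level artefacts, FFPE RNA
degradation, heavy-tailed intensity noise, realistic miRNA sequence
composition, correlated target co-regulation beyond set overlap — bounds
what green tests mean: they demonstrate correctness and calibration of the
statistics under the stated model, not robustness to every property of real
cohort data.

## Validation experiments and problem sizes

`miract.validation` pairs every fast statistic with an independent reference
implementation (explicit-loop FDR enumeration, plain-walk activity score,
integer-arithmetic hypergeometric tail sums, definitional single-edit
enumeration for the mapper, re-averaging agglomeration for UPGMA) and runs
seeded experiments at the defaults above: null calibration over 20 seeds at
K = 200 (fraction of p ≤ 0.005 within 3 binomial SDs; per-seed KS uniformity
at α = 0.01 in ≥ 18/20 seeds), planted recovery over 10 seeds at K = 1000
(≥ 90% recovery, direction accuracy 100%, on average ≤ 1 false positive per
run), and exact switch-program recovery in ≥ 9/10 seeds.  The false-positive
bound is assessed as a per-run mean because single p ≤ 0.005 exceedances
among 80 null miRNAs are expected by chance (≈ 0.4 per run at K = 1000) and
the occasional run with two is consistent with a calibrated method.  These
sizes keep a full validation pass to roughly two minutes on one CPU while
leaving every Monte-Carlo margin comfortably wide.

## Known limitations

- The activity score ignores binding-affinity weights and miRNA family
  structure; family members with near-identical target sets will score
  near-identically rather than being collapsed.
- The FDR estimator pools all miRNAs' nulls, so a few very strong true
  effects deflate the FDR of moderate scores on the same sign side.
- Batch adjustment matches first and second moments only.
- The mapper is substring-based against precursors and does not consult a
  genome; multi-mapping inflation is possible for paralogous precursors.
- Alteration flags depend on the read simulator's or sequencer's edit
  staying inside the retained 21-base window.
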