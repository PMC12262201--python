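# Methods

This note documents the statistical model and numerical choices behind
`lrapa`, the assumptions they rest on, and what the synthetic-data validation
does and does not establish.

## Data model

The unit of observation is a read's 3'-terminal aligned genomic base,
attributed to a gene by an upstream assignment step (IsoQuant or equivalent;
only primary alignments, uniquely assigned reads). The 3' end is taken on the
*gene's* strand — the last aligned base for `+` genes, the first for `-`
genes — because cDNA reads may align antisense while the gene assignment
fixes transcription orientation. Soft-clipped bases (adapter, poly(A) tail)
are excluded. All coordinates are 0-based half-open internally; GTF (1-based
inclusive) and BED (0-based half-open) are converted at the I/O boundary.

Reads whose 3' ends fall outside the annotated gene span are retained: they
may define novel downstream PASs.

## PAS calling

Pooled across all samples and conditions (a shared catalog is required for
any cross-condition comparison), a gene's 3'-end multiset is clustered by
greedy maximum-depth selection: the unassigned coordinate with the most reads
becomes a peak and absorbs every unassigned coordinate within `window` nt
(default 20); repeat until all ends are assigned. Depth ties break toward the
transcription-proximal coordinate, making the procedure deterministic and
strand-mirror symmetric. Each cluster's usage is its depth divided by the
gene's pooled read count; clusters below `min_overall_pau` (default 0.01)
are removed together with their reads, and retained usages are *not*
renormalized — they remain fractions of all pooled gene reads.

Classification of a peak against a reference PAS set is strand-specific:
distance 0 (and, when the reference carries a gene label, the same host
gene) is a *match*; within 20 nt is *proximity* (signed transcription-wise
distance recorded); otherwise *novel*. Genomic context is assigned with
priority 3'UTR exon > CDS exon > intron > downstream > other, against the
union of annotated intervals. The 3'UTR is derived from annotated UTR
intervals lying transcription-wise 3' of the gene's 3'-most stop codon, so
no pre-existing 3'UTR annotation is required beyond CDS/stop features.

**Internal priming.** A PAS is flagged when either 10-nt flank immediately
5' or 3' of the peak (peak base excluded, sense strand) contains more than
6 adenosines — total, not consecutive; the boundary is strict (a 6-A flank
passes). Flagged PASs stay in the catalog; they are excluded from PAS-level
testing by default and kept in gene-level testing unless the caller opts
out, since in cDNA libraries internally primed reads still carry gene-level
information but corrupt site-level usage.

## PAU and usage change

`PAU(i,s) = counts(i,s) / total(gene,s)` over retained PASs, undefined when
`total(gene,s) < min_gene_reads` (default 10; the motif analyses use the
stricter per-sample >20-read preset for site grouping). Reads are assigned
to the nearest retained peak within the calling window, exact-distance ties
to the proximal PAS. Delta-PAU between conditions is the difference of
per-sample PAU means over eligible samples (replicate variability stays
visible), not of pooled counts.

## Gene-level test (signed KS)

Let F_a, F_b be empirical CDFs of transcription-oriented 3'-end positions
pooled per condition (minus-strand coordinates negated so larger always
means more distal), restricted by default to reads attributable to retained
PASs, with at least `min_reads` (10) per condition and at least two retained
PASs. The APA change is the value of F_a − F_b at the argmax of |F_a − F_b|
over the pooled support, argmax ties broken at the most proximal position —
this keeps the statistic exactly antisymmetric under condition swap even
when the two one-sided suprema tie. Positive values mean condition b is
stochastically more distal (3'UTR lengthening).

**P-values under ties.** 3'-end data are heavily tied, and the classical
Kolmogorov asymptotic (which assumes a continuous underlying distribution)
is then conservative: in null calibrations it yielded empirical type-I
around 0.02 at nominal 0.05. The implemented null is the asymptotic
distribution of the statistic under ties: sqrt(n_eff)·(F_a − F_b) converges
to a Brownian bridge evaluated at the pooled-CDF points h_i, so the p-value
is P(max_i |B(h_i)| ≥ z) with z the observed statistic scaled by Stephens'
finite-sample argument (sqrt(n_eff) + 0.12 + 0.11/sqrt(n_eff)). The maximum
is computed by the bridge's Markov recursion over a 121-point barrier grid
with exact Gaussian cell masses (stable even when step variances are far
below the grid spacing); the classical Kolmogorov survival function — an
upper bound, being the supremum over the whole path — is used directly when
it is below 1e-9 or when the support exceeds 200 distinct positions (the
continuous limit). Calibration on all-null fixtures: empirical type-I
0.042–0.054 across seeds at nominal 0.05.

Pooling across replicates follows from the test's design goal of supporting
unreplicated designs; replicate-aware gene-level alternatives are out of
scope. Benjamini–Hochberg correction is applied across tested genes;
direction calls need q < alpha (0.05) and |APA change| > tau (0.1).

## PAS-level test (NB-GLM LRT)

For each testable PAS (gene has ≥2 PASs, not internal-priming-flagged, ≥2
replicates per condition), the stacked (this PAS, rest of gene) counts are
modeled as negative binomial with log link: null design = per-sample effects
+ a column (this-vs-rest) effect; alternative adds condition×column. Twice
the log-likelihood ratio is referred to χ²(1). This preserves the structure
of differential exon usage testing — the interaction asks whether *usage*,
not expression, changes — at desk scale; the full joint-model machinery with
Cox–Reid shrinkage of the original differential-exon-usage method is
deliberately not reproduced, and cross-package binary compatibility is a
non-goal.

**Dispersion.** Per PAS, a method-of-moments estimate on the null mean
structure conditional on sample totals: within each condition the usage
proportion is pooled, fitted means are total·p and total·(1−p), and alpha
solves the df-corrected moment equation; the floor is 1e-8. Estimating
dispersion marginally would count library-size variation that the GLM's
sample effects absorb, and in calibration runs drove the test's type-I to
zero. Raw estimates are shrunk toward a trend alpha(mu) = a0 + a1/mu fitted
across all PASs (weighted average, default 0.5 raw / 0.5 trend; median
fallback for degenerate fits). Calibration: empirical type-I 0.048–0.052 on
null fixtures.

Usage fold change is the ratio of per-condition mean PAU with a
0.5/gene-total pseudo-usage guard against zeros; significance needs |FC|
beyond 1.5 and q < 0.05 (both configurable). The fold-change scale is usage,
not normalized counts — surfaced as a parameter choice.

## Sequence features

Windows are transcription-oriented RNA (T→U), position 0 = the cleavage/peak
base, so AAUAAA appears at negative (upstream) positions on both strands.
Composition profiles exclude N bases column-wise; motif incidence counts all
(including overlapping) match starts per position, and window aggregates use
any-match semantics. Plot smoothing is a centered moving average (window 5).
Enriched-site groups use fraction-scale delta-PAU with threshold 0.1 (the
percent-scale formulation ">10" is the same rule times 100) and a depth
criterion of >20 reads in every sample.

## Synthetic data: what it emulates and what it does not

The generator produces a random-background genome carrying two-exon genes on
both strands (one intron, a long last exon), each with 2–5 true PASs at
least 60 nt apart (so the 20-nt calling window cannot merge them), AAUAAA
planted 15–30 nt upstream of every true site, per-condition usage vectors on
the simplex with a floor keeping every site above the 1% PAU cutoff, and
optional A-rich decoy sites whose upstream flank carries ≥7 A while all true
sites are rejection-sampled to ≤6 A per flank. Reads per gene-sample are
NB(depth_mean, dispersion 0.1) — a realistic level of library-size noise —
allocated multinomially by the condition's usage vector, with cleavage
jitter a discretized normal (default sd 2 nt) truncated at ±15 nt so
clusters stay inside the calling window; effect genes move `delta_pau`
(default 0.3) of usage between the proximal and distal PAS. Default study
conditions for validation: 3 replicates per condition, ~200 reads per gene
and condition for recovery runs, 500 genes for null calibration.

Passing tests on these fixtures establish correctness of the algorithms and
calibration of the tests *under the generative model*: multinomial usage
given totals, symmetric unimodal cleavage jitter, no alignment error, no
expression change between conditions, no transcript-level ambiguity, and a
neutral base composition outside planted motifs. Real data violate several
of these (notably extra-multinomial usage variability, which the dispersion
estimator is there to absorb, and 3'-end softclipping artifacts); the
fixtures therefore validate the machinery, not biological effect sizes.
A "hard mode" with 25-nt jitter exists for exploring mis-clustering but is
not part of the validated conditions.

## Degenerate inputs and tie-breaks (summary)

- Empty 3'-end multiset → empty cluster list; gene absent from annotation →
  skipped with a warning.
- Depth ties in clustering → transcription-proximal peak; read-assignment
  distance ties → proximal PAS; KS argmax ties → most proximal position.
- Either condition empty or below `min_reads` → gene untested; <2 retained
  PASs → untested; unreplicated design → PAS-level test refuses with a
  pointer to the gene-level KS.
- Constant counts → dispersion floored at 1e-8; all-zero PAS rows skipped.
- Zero-variance inputs to correlations → value reported absent.
- Windows overhanging chromosome ends: clipped (flank fetch, internal
  priming evaluated on available bases) or dropped/N-padded per policy
  (motif windows, default dropped).

## Known limitations

- Two-condition designs only; no covariates.
- Greedy clustering is order-deterministic but not model-based; overlapping
  PASs closer than the window merge by construction.
- The tie-aware KS null is asymptotic; at very low depth (tens of reads) it
  inherits the usual small-sample coarseness of rank tests.
- The PAS-level test conditions on the shared catalog; uncertainty in peak
  positions is not propagated.
- Reference-PAS orientation follows the BED strand-wise 3'-position
  convention; differently lifted references must be converted first.
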