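# Methods

`slmkit` re-implements, as a tested library, the windowed methylome and TE
expression computations used to characterise DNA methylation reprogramming
in the male germline of *Brassica rapa*: identification of sex-cell
hypermethylated loci (SLM-like vs canonical SLH-like), sliding-window CHH
DMR calling for RdDM targets, end-anchored methylation metaprofiles, and
LTR-TE activity/clustering analysis. This note records the models, the
parameters that matter, and the choices made where the procedure was
genuinely open.

## The locus-calling model

The caller compares fractional methylation between the average of the male
sex cell types (meiocyte, microspore, pollen) and a somatic reference
(leaf), per sequence context (CG, CHG, CHH; H ∈ {A,C,T}).

1. **Windowing.** Counts are pooled into non-overlapping 50-bp windows per
   context. A window's fraction is Σmeth/Σtotal (coverage-weighted), never
   a mean of per-cytosine fractions: pooling is the standard reading of
   "average methylation per interval" and is stable at low coverage.
2. **Screening.** With diff_X = mean over sex cell types of the window
   fraction in context X minus the somatic fraction, a window is a
   candidate iff diff_CG > 0, diff_CHG > 0, diff_CHH > 0 and
   diff_CG + diff_CHG + diff_CHH > 0.2. The sex average is the unweighted
   mean of per-cell-type fractions. All inequalities are strict; windows
   in which any group lacks coverage in any context are excluded rather
   than imputed (all three differences must be computable).
3. **Merging.** Candidates within 100 bp (inclusive, end-to-start in
   0-based half-open coordinates) merge greedily left to right; merged
   loci shorter than 100 bp are dropped. A single 50-bp window can
   therefore never become a locus on its own.
4. **Testing.** Per locus, a two-sided Fisher's exact test compares total
   methylation — counts pooled over all three contexts and all sex cell
   types — against the somatic counts; loci with p ≥ 0.001 are dropped.
   "Total methylation" is read as all-context pooling; the test is
   two-sided (sidedness is enforced separately by the next step).
5. **Consistency.** Every sex cell type individually must be strictly more
   methylated than the somatic reference over the locus; a sex group with
   zero coverage cannot assert "higher" and fails.
6. **Classification.** Somatic CHH and CHG methylation over the locus act
   as an RdDM-activity indicator: CHH < 0.05 **and** CHG < 0.1 → SLM-like
   (de novo sex-lineage target); otherwise canonical SLH-like (already an
   RdDM target in soma). Boundary values and uncomputable somatic
   fractions fall to the SLH side.

Replicates are pooled (counts summed) before testing; the per-group
consistency check runs on the pooled per-cell-type counts.

## The DMR caller

RdDM-target loci are defined operationally as CHH DMRs lost in an
RdDM-mutant (rdr2-like) versus wild-type comparison. Effective sites are
cytosines of the context covered by ≥ 5 reads in **both** conditions.
50-bp windows (50-bp step; a smaller step produces overlapping windows,
deduplicated to the lowest-q window per overlapping run) with ≥ 10
effective cytosines are tested by the same two-sided Fisher's exact test
on pooled counts; Benjamini–Hochberg q-values are computed over the
retained windows. A window is a DMR iff q < 0.005 and the percent
methylation difference exceeds 10 points. The per-window test is Fisher +
BH rather than a logistic-regression/SLIM pipeline: it is deterministic,
dependency-free and exactly oracle-testable, and the thresholds are
unchanged. Homologous-interval transfer consumes a pre-computed mapping
table (best mapping by e-value, then identity, then length; offset lift
scaled when source and target lengths differ); the homology search itself
is upstream of this package.

The Fisher test is an authored vectorised hypergeometric enumeration
(`stats.fisher_exact_two_sided`): the two-sided p sums all table
probabilities not exceeding the observed probability, with a 1e-7
relative tolerance so analytic ties (symmetric tables) land on the
include side despite floating-point noise. Tests verify agreement with
`scipy.stats.fisher_exact` on random tables and with an exact-rational
enumeration on every table with row margins ≤ 30 (max |Δp| < 1e-12).

## Profiles

End-anchored metaprofiles align features at the biological 5′ or 3′ end
(coordinates flipped for minus-strand features) and pool counts into
100-bp bins spanning ±span (default 3 kb). To keep short features from
skewing the inside of the profile, a feature contributes to the inside
bin covering distances [d, d + bin) only when it fully spans that bin
(length ≥ d + bin); the per-bin contributing-feature count is reported.
TE-style profiles rescale the body to equal-occupancy bins (a cytosine at
relative position r lands in bin ⌊r·body_bins⌋, so features shorter than
the bin count contribute proportionally rather than being dropped) with
fixed-width flank bins (default 200 bp of flank in 50-bp bins). The
"substantial methylation" mask used for windowed box plots keeps
intervals with ≥ 4 covered cytosines of the context per group — an
interpretation; the threshold is configurable.

Coordinates are 1-based in CX files (as on disk) and 0-based half-open in
all BED-style interfaces and internal arithmetic. Strand-symmetric CG
collapsing is not performed; windows pool counts regardless of strand.
Replicate merging sums counts per position and requires context
agreement; no minimum replicate correlation is enforced (the windowed
Pearson matrix is reported, not gated).

## TE expression

TPM_i = 10⁶ · (c_i/l_i) / Σ_j (c_j/l_j) per sample after removing an
exclusion set (e.g. rRNA); effective length is the annotated feature
length (no fragment-length model). A TE is *active* if TPM > 10 in at
least one cell type, *inactive* if TPM < 0.001 in all, otherwise
*intermediate* (excluded from both downstream sets; both bounds strict).
Active TEs are clustered by k-means (k = 4, fixed seed, n_init = 10) on
per-feature z-scores of TPM across samples — z-scores, not raw TPM,
because raw-TPM k-means is dominated by magnitude while the clusters are
described by expression *pattern* (the heat-map scale in such analyses is
a z-score). Cluster numbers are a pure function of the fitted centroids:
clusters are renumbered by the cell type at which each centroid peaks
(meiocyte → 1, microspore → 2, leaf → 3, pollen → 4 when present, ties
broken by peak height), so reruns with the same seed reproduce identical
labelled output. The active-vs-inactive length comparison uses a
two-sided Wilcoxon rank-sum test (the specific test behind "significantly
shorter" is an interpretation).

## Annotation and integration

Distances between loci and features are unstranded gaps between closest
interval edges; "within 500 bp" is inclusive at exactly 500, and a locus
near both a gene and a TE counts in both per-kind summaries (the gene and
TE proximity pies are independent). Differential-expression direction is
applied here, on an externally fitted table: up iff p < 0.05 and
log₂FC ≥ 1, down iff p < 0.05 and log₂FC ≤ −1 (fold-change bound
inclusive, p bound strict). The fraction of locus-targeted genes
differentially expressed in ≥ 1 contrast is reported with its denominator
stated explicitly.

## The synthetic-data generator

The generator emulates the study design — two WGBS replicates of each of
leaf, meiocyte, microspore and pollen, plus a wild-type/mutant somatic
pair — at desk scale, with planted, recorded ground truth:

- **Genome**: by default two 300-kb chromosomes at 36% GC; 80 genes
  (1–3 kb) and 120 TEs (80% shorter than 2 kb, the rest 2–8 kb; Gypsy
  0.50 / Copia 0.35 / other 0.15) packed without overlap with ≥ 300-bp
  gaps. Sixty percent of planted SLM/SLH loci are placed 50–400 bp from
  a gene, mirroring the gene-targeting preference of sexual-lineage loci;
  the rest are intergenic.
- **Methylome**: contexts assigned strand-specifically from the reference
  trinucleotide (end cytosines lacking the needed downstream bases are
  omitted; the reader also drops Bismark-style `Unknown` rows). Depth is
  Poisson(20) per cytosine per replicate (a single overdispersion knob
  switches to gamma-Poisson); methylated counts are Binomial(depth, p)
  with p set by compartment × context (TE body 0.80/0.50/0.08, gene body
  0.20/0.03/0.01, 200-bp TE flank 0.30/0.20/0.08, intergenic
  0.10/0.05/0.02 for CG/CHG/CHH) — levels chosen once as plant-typical
  (high TE-body CG/CHG, low gene-body non-CG, modest flank CHH).
- **Planted loci** (150–350 bp, non-overlapping, ≥ 300 bp apart): SLM loci
  add +0.3 to all three contexts in sex cell types only; SLH loci
  additionally raise the somatic baseline to CHG 0.20 / CHH 0.15 in all
  cell types, so they pass the hypermethylation screen but must fail the
  low-somatic-RdDM classification; DMR loci sit at CHH 0.25 in the
  wild-type condition and 0.02 in the mutant.
- **Expression**: counts are gamma-Poisson (dispersion 10) around
  per-cluster mean-TPM profiles (peak cell type 100 TPM, off-peak 1);
  inactive TEs have zero expression; genes get a lognormal baseline
  around 50 TPM shared across cell types. Roughly 40% of TEs are made
  active — far above the few-percent rate of a real TE complement, but
  necessary for a clusterable population at 120 TEs — sampled with an
  8-fold preference for short (< 2 kb) elements, split
  meiocyte-dominated (50/16/14/20%) across four peak profiles.
- Every output file draws from its own RNG stream seeded by (master seed,
  file tag), so adding samples never perturbs existing ones; identical
  configurations reproduce byte-identical files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (bisulfite conversion
failure, mapping bias, PCR duplicates), spatial autocorrelation of
methylation beyond the compartment structure, partial or heterogeneous
effect sizes, CG-site depletion/clustering of real sequence, overlapping
or nested annotation, and biological replicate variance beyond sampling
noise. Recovery at precision/recall ≥ 0.9 therefore demonstrates
correctness of the procedure's logic under its stated assumptions, not
sensitivity on real, subtler methylomes.

## Numerical choices and degenerate inputs

- Window fractions with zero pooled coverage are NaN and flagged, never
  silently zero; such windows are excluded from screening.
- Fisher tables with a zero margin have a single-point support and get
  p = 1 by convention.
- Degenerate z-score rows (zero spread) are set to zero with a warning.
- Merging gap and proximity comparisons are inclusive at the printed
  bound; all screening/classification inequalities are strict exactly as
  printed, so boundary values fall to the conservative side.
- BH q-values come from statsmodels and are oracle-tested for the
  step-up identity, q ≥ p, and monotonicity.

## Problem sizes

Defaults are desk-scale by design: the 600-kb two-chromosome genome with
depth-20 methylomes makes the full pipeline (simulate → ingest → call →
profile → cluster → integrate) run in well under a minute, while leaving
≥ 10 candidate windows per planted locus and hundreds of active TEs'
worth of statistical resolution. The headline counts of the motivating
study (hundreds of loci on a ~350-Mb genome) are not reproducible at this
scale and are not targets; the recoverable quantities are the planted
ones.

## Known limitations

- The sliding-step (< window) DMR scan is an extension; only the tiling
  configuration matches the described procedure exactly.
- Null calibration of the locus caller is a sanity bound, not an exact
  size claim: screening precedes testing, so the Fisher p-values of
  surviving candidates are selected, not uniform.
- Homolog transfer lifts through the single best mapping; split or
  rearranged homologies are not modelled.
- `interval_quantify` checks chromosome bounds only when sizes are
  provided; BED inputs of unknown provenance are otherwise trusted.
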