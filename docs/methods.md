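# Methods

## Scope and model

`epiconcord` implements a two-condition (control vs treated) integrative
epigenomics analysis: broad-domain differential enrichment calling for
three histone H3K9 marks, positional attribution of differential islands
to genes, a fold-change + p-value differential expression filter on an
already-normalised log2 intensity matrix, relative qPCR quantification
(ΔΔCt) for validation, and gene-level integration (Venn overlaps,
mark × expression concordance classes, hypergeometric over-representation).
Everything upstream of these stages — read trimming, alignment, array
normalisation — is out of scope: the pipeline consumes fragment intervals
and normalised intensities.

## Island caller

The caller follows the window/island paradigm used for broad histone
domains.

* **Windowing.** Non-overlapping windows of `window_size_bp` (default
  200 bp, the conventional nucleosome-scale window for broad-mark
  callers). Each fragment contributes exactly once, to the window holding
  its midpoint `floor((start+end)/2)`; this makes counts conserved and the
  boundary convention oracle-checkable.
* **Eligibility.** Background is homogeneous Poisson with
  λ = library_size · W / effective_genome_length. The effective genome
  length is the plain sum of chromosome sizes — the synthetic genomes are
  fully mappable, so no mappability correction is applied. A window with
  count k is eligible iff P(X ≥ k) < `window_p` (default 0.01). At λ = 1
  this admits counts ≥ 5 (upper tail 0.00366).
* **Clustering.** Maximal runs of eligible windows, merging runs separated
  by ≤ `gap_windows` (default 3) ineligible windows; the island's count is
  the window-sum over its whole span, gaps included.
* **Differential test.** Islands are called in each condition separately
  and the two sets are merged (interval union) into one candidate
  universe. Each candidate's treated/control counts are compared with a
  two-sided exact binomial test with success probability
  N_t/(N_t + N_c), BH-corrected across candidates; islands with
  q < `fdr` (default 0.01) are emitted, direction by the normalised rate
  ratio. Judging both directions on one merged candidate set makes the
  increased and decreased sets disjoint by construction — the
  direction-conflict audit downstream can therefore only fire when two
  *distinct* opposite-direction islands hit the same gene.

Degenerate cases: an empty candidate set is an empty result, not an error;
a candidate with equal normalised rates is never emitted with a direction;
an empty track is rejected before fitting (λ = 0 has no background model).

## Positional rules

Coordinates are 0-based half-open everywhere; BED files are read and
written natively and the gene table is a minimal TSV in the same
convention (a deliberate choice over GTF — it avoids 1-based/half-open
dialect mistakes at the cost of a conversion step for external
annotations). The TSS of a '+' gene is `start`; of a '−' gene `end − 1`
(the last covered base), keeping the half-open convention symmetric under
strand reflection, a property the tests assert exactly.

Per mark (defaults, overridable per rule):

* **H3K9ac** — window ±1000 bp around the TSS, *minus* the gene body.
  The two clauses are read as a set subtraction: that is the only reading
  under which both constrain the region.
* **H3K9me1** — the gene body exactly.
* **H3K9me3** — the union of a −2000/+200 bp TSS window and the gene
  body. The intersection reading was rejected as it leaves an almost
  empty admissible region (only the +0..+200 sliver), inconsistent with
  this mark producing abundant gene-associated domains.

An island is attributed to a gene when its total overlap with the gene's
target region is ≥ `min_overlap_bp` (default 1 bp; no overlap fraction is
standard for this kind of rule). One island may hit several genes; all
hits are recorded with provenance. Assignment uses an interval tree per
mark and chromosome; tests compare it against an all-pairs per-base
membership oracle.

## Expression filter

Per probe, one-way ANOVA across the two groups on log2 values; with two
groups F = t² for the pooled-variance t statistic, and p comes from
F(1, n₁+n₂−2). Degenerate probes follow documented conventions: zero
within-group variance with zero between-group difference → p = 1; with a
nonzero difference → p = 0. A probe passes when unadjusted p < α (default
0.05) and |log2FC| ≥ log2(FC_min) (default 1.5, inclusive). The inclusive
boundary is implemented with a 1e-12 slack on the log2 scale so a fold of
exactly 1.5 is not lost to rounding of the group means. p-values are
deliberately unadjusted — that is the filter this pipeline models — and
multiple-testing correction of the DE stage is an explicit non-goal.
Probes map many-to-one onto genes; gene sets are deduplicated after
filtering, so gene-level counts are ≤ probe-level counts.

## qPCR quantification

Per replicate, ΔCt = Ct(target) − mean(Ct of the endogenous controls);
the combination rule across the two controls (a β-actin-like and an
18S-like gene) is the arithmetic mean of their Ct — the simplest symmetric
choice — and the control list is configurable. ΔΔCt = mean ΔCt(treated) −
mean ΔCt(control); fold = 2^(−ΔΔCt). ΔΔCt is invariant to adding a
constant to every Ct of a replicate; the tests assert this exactly.
Validation correlates gene-level array log2FC (mean over probes) with
log2 of the qPCR fold (Pearson and Spearman).

## Over-representation

Hypergeometric upper tail P(X ≥ k) for an overlap of k between the query
and a term set, drawing |query| from the universe; terms are intersected
with the universe before testing and BH-corrected jointly. The default
universe is all genes in the annotation, not the union of the collections
— the reproducible choice when the true assay background is unknown — and
it is configurable.

## Synthetic data generator

The generator emulates the study conditions end to end with explicit
ground truth:

* **Genome.** One 2-Mb chromosome, 100 non-overlapping genes of 2–10 kb
  with uniform random placement and strand. Placement draws the inter-gene
  free space uniformly, which guarantees disjointness; infeasible packing
  is an explicit error.
* **Fragments.** Intervals, not reads — nothing downstream needs bases.
  Background is homogeneous Poisson at 0.005 fragments/bp per condition
  (≈10,000 fragments per 2-Mb track, desk-scale in seconds), fragment
  lengths uniform in 200–500 bp, matching sonication fragment sizes in
  ChIP protocols. For each mark, 10 genes per direction receive a planted
  2-kb region whose in-region rate in the enriched condition is
  `enrichment_fold` (default 5) times background — extra fragments go to
  the treated track for increased regions and to the control track for
  decreased ones, so fold 1 makes the conditions exactly exchangeable.
  The planted region is anchored on the widest interval of the gene's
  admissible positional region (so attribution under the mark's rule is
  guaranteed) but may, like a real broad domain, spill beyond it; genes
  whose geometry cannot host the class (chromosome edges) are skipped and
  another gene is drawn, with an explicit failure if the annotation runs
  out.
* **Expression.** Per-probe baselines uniform in log2 6–12, Gaussian noise
  sd 0.25 log2 units, biological triplicates per condition; 20% of genes
  carry a second probe, exercising the many-probes-per-gene dedup.
  Differential genes (default 40) are shifted by |log2FC| = 2 in the
  treated group. Concordance is planted explicitly, not emergent: 75% of
  each mark's planted genes are made differentially expressed in the
  matching direction (increased → up, decreased → down), the remainder of
  the DE budget is filled with unplanted genes (direction up, mirroring a
  predominantly activating treatment). The explicit list is what makes
  end-to-end recovery assertable.
* **qPCR.** Ct = 30 − 1.0 · log2(expression) + N(0, 0.1), two
  endogenous-control genes with condition-invariant expected Ct, so a
  planted log2FC of +x yields ΔΔCt = −x and fold 2^x in the noise-free
  limit — the closed form the tests and acceptance script check.

What the generator does **not** emulate: mappability and GC structure,
duplicate reads, chromatin-input background, batch effects, probe
cross-hybridisation, isoforms. Passing tests therefore demonstrate the
pipeline's correctness and calibration under a well-specified null, not
robustness to those real-data artifacts.

All generators are deterministic: each stage draws from
`numpy.random.default_rng([seed, stage_tag])`, so a config + seed pair
reproduces every output byte-identically (the full `run` bundle is
asserted byte-identical in the tests).

## Problem sizes in the test suite and acceptance script

Oracle-equivalence checks run on ≥100 random instances with genomes
≤100 kb and ≤10³ intervals; calibration uses 10⁵ null windows, 50
exchangeable-condition seeds and ~1,200 null probes; parameter recovery
runs the full default conditions over 50 seeds (≈3,000 planted islands,
≈2,250 planted DE genes, 400 planted concordant genes). These sizes give
Monte-Carlo standard errors comfortably below the asserted margins while
keeping the whole suite in the tens of seconds.

## Known limitations

* The island caller has no chromatin-input correction or broad/narrow
  mode switch; it models exactly one background (homogeneous Poisson).
* Direction is binary; candidates with exactly equal normalised rates are
  dropped rather than reported as ambiguous.
* The DE stage supports exactly two groups.
* ORA treats gene sets as unordered; there is no rank-based enrichment.
* The pipeline joins every stage on `gene_id`; probe-set-level joins are
  not supported.
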