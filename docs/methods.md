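# Methods

This note documents the models, conventions, and design choices behind
dosagescope, and what the synthetic-data generator does and does not
emulate.

## The biological model

During fast growth, bacteria replicate faster than they divide by running
overlapping replication rounds. Loci close to the replication origin
(oriC) are then present in more copies than loci near the terminus (ter) —
up to ~8x in *E. coli* — and, all else equal, produce proportionally more
transcript. The package quantifies this *gene dosage* effect and separates
it from promoter regulation:

1. **Marker frequency analysis (MFA).** DNA coverage of an exponentially
   growing culture, normalized by a non-replicating (stationary) culture,
   falls log-linearly from oriC to ter along each replichore. Fitting one
   OLS line per replichore on log2 coverage ratios and intersecting the
   two lines yields oriC/ter position and copy-number estimates; the model
   is rescaled so the terminus has copy number 1 and can be evaluated at
   any locus.
2. **Fold-change decomposition.** A gene's expression fold change between
   two conditions is modelled multiplicatively, f_total = f_copy × f_reg,
   so the promoter component is f_reg = f_total / f_copy with f_copy taken
   from the fitted MFA model at the gene's midpoint.
3. **Spatial statistics.** Up/down-regulation bias, average fold change,
   and regulon membership are computed in sliding windows of a fixed
   number of genes (default 300, step 1 gene, circular) positioned at the
   mean coordinate of their members.
4. **Enrichment.** Over/under-representation of functional categories in a
   gene set is scored as z = (x − m)/s against the count distribution over
   1,000 same-size random gene sets.
5. **Constellation analysis.** For two species without annotated origins,
   candidate oriC positions are scanned on a grid over both chromosomes;
   the Pearson correlation of single-copy orthologs' normalized oriC
   distances is maximized over candidate pairs. The maximal correlation
   measures oriC-distance conservation; the arg-max superimposes the two
   origins (or, symmetrically, the two termini — the correlation level is
   the statistic of interest, so the optimum is not disambiguated).

## Conventions and parameters

* Coordinates are 0-based; intervals half-open. GFF3 input (1-based) is
  converted on read; a gene's location is the midpoint of its annotated
  interval, `(start-1 + end-1) // 2`.
* oriC proximity is `1 − d/(L/2)` with d the shortest arc to oriC,
  clamped to [0, 1]; normalization is by half the chromosome length even
  when the annotated ter is not the exact antipode.
* Replichore "right" is the arc oriC→ter in increasing coordinates; a
  position exactly at oriC is right, exactly at ter is left.
* MFA windows: 5 kb, sliding step window/5 by default (the windows
  overlap; the autocorrelation this induces does not bias the OLS fit but
  makes neighbouring profile points dependent). Windows with zero
  stationary coverage are dropped and counted. After the first fit,
  windows are re-assigned to replichores using the fitted axis and the fit
  repeats once, so auto-initialization (arg-max/arg-min of a smoothed
  profile) is self-consistent.
* A profile with |slope| below 1e-12 log2/bp on both arms (e.g. two
  stationary samples) is returned as a flagged flat model with ratio 1;
  parallel non-flat lines raise a degenerate-fit error.
* Expression normalization: counts / gene length, each sample scaled to a
  common total, then quantile normalization across all samples in one
  batch. The quantile step is a switch (default on): it is designed to
  harmonize *technical* distribution differences and will distort fold
  changes whenever the conditions differ globally in truth — which is
  exactly the planted situation in the synthetic data — so all
  planted-truth recovery analyses in the tests and the acceptance script
  run with `quantile=False`. On real data with technical batch variation
  the default applies.
* Window fold changes use the arithmetic mean of linear ratios (directly
  comparable to a linear copy-number difference curve); a geometric-mean
  variant is available.
* Frequency-bias correction: library-size normalization makes fold
  changes relative (enriching oriC-proximal transcripts depletes relative
  abundance everywhere else). Assuming the true average fold change is 1
  where the copy-number difference curve crosses 1, a log2-linear
  regression of the *per-gene* fold changes per replichore is evaluated at
  that locus and all fold changes are divided by the (geometric mean)
  ordinate. Regressing per-gene values rather than window means matters:
  the window mean of an exponential-in-position curve is not log-linear in
  the window position (Jensen gap), while the per-gene log2 fold change is
  exactly linear per replichore in the generative model, making the
  correction exact on noiseless data.
* Dominance and copy share are computed on log2 magnitudes
  (share = |log2 f_copy| / (|log2 f_copy| + |log2 f_reg|)), which weighs a
  2-fold and a 0.5-fold effect equally and stays well defined when the two
  factors act in opposite directions; ties classify as promoter so the
  copy class is never inflated. A linear-proportion alternative would not
  be symmetric under f → 1/f.
* Both printed one-fourth criteria are reported side by side:
  share ≥ 0.25, and |log2 f_copy| ≥ 0.25·|log2 f_reg|.
* Stringency subsets default to copy-share thresholds (0.5, 0.65, 0.8);
  the thresholds are a documented choice and configurable.
* Enrichment uses the population standard deviation (no Bessel
  correction; with 1,000 random sets the difference is negligible).
  Unannotated genes stay in the sampling universe by default
  (`annotated_only` restricts). s = 0 with x ≠ m reports ±inf with a
  degenerate flag rather than silently dropping the category.
* select_up_genes: Welch two-sample t-test on log2 normalized values,
  raw p < 0.05, no multiple-testing correction by default (a
  Benjamini-Hochberg option exists). The test choice is a default, not a
  claim about the best DE method; dispersion-modelling frameworks are out
  of scope.
* Constellation grid: L/200 per chromosome by default (configurable).
  Distances are normalized by L/2 before correlating so chromosomes of
  different lengths are comparable. Arg-max ties resolve to the first
  maximum in row-major scan order. The degeneracy diagnostic is the mean
  correlation along the wrapped diagonal through the arg-max divided by
  r_max; ≥ 0.9 flags a conserved-gene-order ridge.
* Growth classes from 16S rRNA gene counts: ≤ 3 slow, ≥ 6 fast, 4-5
  excluded.

## The synthetic-data generator

Defaults encode the study conditions the analyses target: L = 4.6 Mb,
2,000 genes placed uniformly, oriC/ter ratio R = 4 (fast exponential
growth with overlapping replication; planted copy number R^(1 − d/(L/2))),
lognormal coverage noise of 0.1 log2 sd per 5 kb window and phase, baseline
depth 100x, biological triplicates with lognormal replicate noise of 0.1
log2 sd, per-gene baseline expression lognormal with 2.0 log2 sd, promoter
log2 fold changes with sd 1.0, and a dosage-dominant gene fraction of 0.4.

The dosage-dominant fraction is planted by *shrinking*, not removing,
promoter effects: dominant genes draw their promoter log2 fold change from
Normal(0, 0.1·sd) truncated to |lfc| < |log2 f_copy|, the rest from
Normal(0, sd) truncated to |lfc| > |log2 f_copy|. The truncation keeps the
stated marginals near the per-gene dominance boundary — so classification
is exercised on genuinely hard cases — while making the planted label
exact: on noiseless data the classified copy fraction equals the planted
fraction to the gene. A consequence worth knowing: under measurement
noise, near-boundary genes flip asymmetrically (the non-dominant tail
piles up just outside the boundary), which biases the classified fraction
upward by a few percent when dominant genes are rare (phi ≈ 0.2). This is
a property of the planted-near-boundary design, not of the classifier.

Ortholog pairs: each gene keeps its oriC distance in the second species
with probability p_c (replichore side re-randomized with probability 0.5,
the symmetric rearrangement mode) or moves to a uniform position; all
second-species coordinates are finally rotated by a configurable offset so
its true origin is unknown to the analysis.

What the generator does **not** emulate: read-level artifacts (GC bias,
mappability), the cell-age structure of copy numbers within a cycle,
transcription-replication conflicts, operon structure (genes are
independent), dispersion/count noise of real RNA-seq (noise is lognormal,
not negative-binomial), or real phylogenetic covariance between species.
Passing the recovery tests therefore shows the estimators are correct and
well calibrated under the stated generative model, not that real libraries
are free of these artifacts.

## Statistical limits worth knowing

* **Origin position from MFA.** The origin estimate is the intersection
  of two OLS lines; its standard error is ≈ sqrt(2)·(2σ/√n)/(|β_r|+|β_l|),
  with σ the per-window log2 ratio noise and β the arm slopes. At R = 1.5
  and σ ≈ 0.14 (noise 0.1 in both phases) over ~460 windows per arm this
  is ≈ 26 kb — shallow gradients simply do not pin the origin to window
  resolution, although the oriC/ter *ratio* is recovered to ~1% regardless.
  Noiseless recovery is exact.
* **Constellation offset.** The correlation surface has a nearly flat
  peak: one grid step (23 kb at L/200) changes normalized distances by
  ~0.01, i.e. Δr ≈ 5e-4, while the sampling noise of that difference at
  1,000 orthologs is ≈ 1e-3, so the arg-max wanders ±2 grid steps unless
  conservation is high (p_c ≳ 0.9). A finer grid does not help; more
  orthologs or stronger conservation do. The conservation *level* r_max —
  the quantity the comparative analyses use — is far more stable than the
  arg-max location.
* **Slope flattening.** After copy normalization the residual spatial
  slope is noise-floor-limited by promoter scatter (se ≈ 4e-8 log2/bp at
  2,000 genes), which is about 5% of the uncorrected slope; multi-seed
  medians are therefore the right readout for flattening checks.

## Problem sizes

The test suite and the acceptance script run everything at the sizes the
checks prescribe (full 4.6 Mb chromosome, 2,000 genes, 1,000 orthologs,
1,000-set randomizations), with seed counts chosen to keep the whole suite
in the low minutes on one CPU: 50 seeds per gradient ratio for MFA
recovery, 100 seeds per planted fraction for dominance recovery and
enrichment calibration, 20 seeds for constellation and migration
orderings, 10-20 for the slope-flattening median.
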