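# dosagescope

Replication-induced gene dosage analysis for bacterial transcriptomics.

During fast growth, bacteria initiate new replication rounds before the
previous ones finish, so genes near the replication origin (oriC) are
transiently present in more copies than genes near the terminus (ter) —
and produce proportionally more transcript. dosagescope is a toolkit for
researchers who want to quantify this effect in their own data: estimate
the chromosomal copy-number gradient from DNA sequencing coverage, split
each gene's expression fold change into a dosage part and a promoter part,
test which cellular functions are dosage-regulated, and measure how
strongly evolution conserves genes' distance to oriC across species.

## What it computes

**Marker frequency analysis (MFA).** Coverage of exponential-phase cells
normalized by stationary-phase cells, averaged in 5 kb sliding windows,
falls log-linearly from oriC to ter along each replichore. One OLS line is
fitted per replichore on the log2 ratios; the intersections of the two
lines give the oriC/ter positions and copy numbers, normalized so the
terminus has copy number 1. The fitted model evaluates the copy number
`c(x)` at any locus x.

**Fold-change decomposition.** With `f_total` a gene's expression fold
change between conditions and `f_copy = c_A(x)/c_B(x)` its copy-number
difference, the promoter component is

    f_reg = f_total / f_copy

Genes are classed as predominantly copy-number or promoter regulated by
comparing |log2 f_copy| with |log2 f_reg|, with the copy share
|log2 f_copy| / (|log2 f_copy| + |log2 f_reg|) measuring the split.

**Spatial statistics.** Up/down-regulation bias, average fold change
(with correction for the relative-frequency bias that library-size
normalization introduces), and regulon frequency in circular sliding
windows of 300 genes.

**Enrichment.** Functional-category z-scores, z = (x − m)/s, against
1,000 random same-size gene sets.

**Constellation analysis.** For two species with unknown origins, a grid
scan over candidate oriC pairs maximizes the Pearson correlation of
single-copy orthologs' normalized oriC distances; the correlation level
measures oriC-distance conservation, with a degeneracy flag for conserved
gene order. Species are grouped into slow/fast growers by 16S rRNA gene
count (≤ 3 vs ≥ 6).

A synthetic-data module generates coverage tracks, count tables, genomes,
and ortholog pairs with planted ground truth (gradient ratio, promoter
factors, dominance labels, rearrangement breakpoints, origin offsets), so
every stage is testable at desk scale. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import numpy as np, pandas as pd
import dosagescope as ds
from dosagescope import mfa, spatial
from dosagescope.decomposition import decompose_table

cfg = ds.SimulationConfig(seed=1)               # 4.6 Mb, 2000 genes, R = 4
chrom, genes = ds.simulate_genome(cfg)
cov_exp, cov_stat = ds.simulate_coverage(cfg, chrom)

profile = ds.compute_mfa_profile(cov_exp, cov_stat, window=5000, step=1000)
model = ds.fit_copy_number_model(profile, chrom)
print(f"oriC/ter copy ratio: {model.ratio:.3f}")

counts, truth = ds.simulate_expression(cfg, chrom, genes)
expr = spatial.normalize_expression(counts, quantile=False)
fold = spatial.gene_fold_changes(expr, "EXP", "STAT")

flat = ds.CopyNumberModel(model.length, model.oriC_est, model.ter_est,
                          0.0, 0.0, (0, 0), (0, 0), flat=True)
zero = mfa.zero_difference_locus(model, flat)
curve = spatial.fold_change_curve(fold, genes, chrom, window=300)
curve, c = spatial.frequency_bias_correct(curve, fold, genes, chrom, zero)

mids = pd.Series({g.gene_id: g.midpoint for g in genes})
f_copy = pd.Series(2.0 ** np.asarray(model.log2_copy_at(mids.to_numpy())),
                   index=mids.index)
table = decompose_table(fold.f_total / c, f_copy)
frac = (table["dominance"] == "copy").mean()
print(f"predominantly copy-number regulated: {100 * frac:.1f}% of genes")
```

prints

```
oriC/ter copy ratio: 4.042
predominantly copy-number regulated: 42.6% of genes
```

The fitted gradient recovers the planted oriC/ter ratio of 4 to ~1%, and
the classified copy-dominant fraction tracks the planted 40%: expression
fold changes between exponential and stationary phase are dominated by
gene dosage for a large minority of genes under these conditions.

## Command line

The `dosagescope` CLI wraps the library: `simulate`, `mfa`, `spatial`,
`decompose`, `enrich`, `constellation`, `migrate`, `classes`, and `run`
(full pipeline from one YAML config, with a manifest recording parameters,
seeds and output checksums). Exit codes: 0 ok, 2 validation error,
3 runtime error.

```sh
dosagescope simulate --seed 3 --outdir out
dosagescope mfa out/coverage_exp.bedgraph out/coverage_stat.bedgraph
```

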