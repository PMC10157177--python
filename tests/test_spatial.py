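"""Normalization, fold changes, and sliding-window spatial statistics."""

import numpy as np
import pandas as pd
import pytest

import dosagescope as ds
from dosagescope import mfa, spatial
from dosagescope.errors import InputError
from dosagescope.io import CountTable

from conftest import flat_model_like


def make_counts(values: dict, lengths):
    genes = [f"g{i}" for i in range(len(lengths))]
    return CountTable(pd.DataFrame(values, index=pd.Index(genes, name="gene_id")),
                      pd.Series(lengths, index=genes))


class TestNormalize:
    def test_length_normalization(self):
        counts = make_counts({"EXP_1": [10.0, 10.0]}, [100, 200])
        expr = spatial.normalize_expression(counts, quantile=False)
        v = expr.values["EXP_1"]
        assert v.iloc[0] == pytest.approx(2 * v.iloc[1])

    def test_library_scaling_common_sum(self):
        counts = make_counts({"EXP_1": [10.0, 30.0], "STAT_1": [1.0, 3.0]},
                             [100, 100])
        expr = spatial.normalize_expression(counts, quantile=False)
        sums = expr.values.sum(axis=0)
        assert np.allclose(sums, sums.iloc[0])

    def test_quantile_makes_sorted_columns_identical(self):
        rng = np.random.default_rng(0)
        counts = make_counts({"A_1": rng.lognormal(size=50),
                              "B_1": rng.lognormal(size=50)}, [100] * 50)
        expr = spatial.normalize_expression(counts, quantile=True)
        a = np.sort(expr.values["A_1"].to_numpy())
        b = np.sort(expr.values["B_1"].to_numpy())
        assert np.allclose(a, b)

    def test_permuted_samples_identical_after_quantile(self):
        vals = np.arange(1.0, 21.0)
        rng = np.random.default_rng(1)
        counts = make_counts({"A_1": vals, "B_1": rng.permutation(vals)},
                             [100] * 20)
        expr = spatial.normalize_expression(counts, quantile=True)
        assert np.allclose(np.sort(expr.values["A_1"]),
                           np.sort(expr.values["B_1"]))

    def test_zero_length_rejected(self):
        with pytest.raises(Exception):
            make_counts({"EXP_1": [1.0]}, [0])


class TestFoldChanges:
    def test_identical_conditions_unity(self):
        counts = make_counts({"EXP_1": [5.0, 7.0], "STAT_1": [5.0, 7.0]},
                             [100, 100])
        expr = spatial.normalize_expression(counts, quantile=False)
        fold = spatial.gene_fold_changes(expr, "EXP", "STAT")
        assert np.allclose(fold.f_total, 1.0)

    def test_zero_denominator_excluded(self):
        counts = make_counts({"EXP_1": [5.0, 7.0], "STAT_1": [5.0, 0.0]},
                             [100, 100])
        expr = spatial.normalize_expression(counts, quantile=False)
        fold = spatial.gene_fold_changes(expr, "EXP", "STAT")
        assert fold.excluded == ["g1"]
        assert "g1" not in fold.f_total.index

    def test_missing_condition(self):
        counts = make_counts({"EXP_1": [5.0]}, [100])
        expr = spatial.normalize_expression(counts, quantile=False)
        with pytest.raises(InputError):
            spatial.gene_fold_changes(expr, "EXP", "STAT")


def genes_on_circle(n, L, start=0):
    step = L // n
    return [ds.GeneRecord(f"g{i}", start + i * step, "+", 100)
            for i in range(n)]


class TestWindowCurves:
    def test_all_up_gives_plus_one(self):
        chrom = ds.CircularChromosome("c", 10_000)
        genes = genes_on_circle(20, 10_000)
        f = pd.Series(2.0, index=[g.gene_id for g in genes])
        fold = spatial.FoldChanges(f, [], "A", "B")
        curve = spatial.updown_bias_curve(fold, genes, chrom, window=5)
        assert np.allclose(curve.values, 1.0)

    def test_balanced_window_zero_and_units_ignored(self):
        chrom = ds.CircularChromosome("c", 10_000)
        genes = genes_on_circle(4, 10_000)
        f = pd.Series([2.0, 0.5, 1.0, 1.0],
                      index=[g.gene_id for g in genes])
        fold = spatial.FoldChanges(f, [], "A", "B")
        curve = spatial.updown_bias_curve(fold, genes, chrom, window=4)
        assert np.allclose(curve.values, 0.0)

    def test_bias_bounds_and_self_comparison(self, small_cfg):
        chrom, genes = ds.simulate_genome(small_cfg)
        ids = [g.gene_id for g in genes]
        fold = spatial.FoldChanges(pd.Series(1.0, index=ids), [], "A", "A")
        curve = spatial.updown_bias_curve(fold, genes, chrom, window=50)
        assert np.allclose(curve.values, 0.0)
        fc = spatial.fold_change_curve(fold, genes, chrom, window=50)
        assert np.allclose(fc.values, 1.0)

    def test_arithmetic_mean_convention(self):
        chrom = ds.CircularChromosome("c", 10_000)
        genes = genes_on_circle(2, 10_000)
        f = pd.Series([2.0, 0.5], index=[g.gene_id for g in genes])
        fold = spatial.FoldChanges(f, [], "A", "B")
        curve = spatial.fold_change_curve(fold, genes, chrom, window=2)
        assert np.allclose(curve.values, 1.25)
        geo = spatial.fold_change_curve(fold, genes, chrom, window=2,
                                        log_mean=True)
        assert np.allclose(geo.values, 1.0)

    def test_bias_positive_at_oric_negative_at_ter(self, noiseless_cfg):
        """A pure copy-number gradient biases expression up near oriC."""
        chrom, genes = ds.simulate_genome(noiseless_cfg)
        counts, truth = ds.simulate_expression(noiseless_cfg, chrom, genes)
        # promoter-free fold changes: just the copy numbers
        fold = spatial.FoldChanges(truth["f_copy"].rename("f_total"), [],
                                   "EXP", "STAT")
        curve = spatial.updown_bias_curve(fold, genes, chrom, window=50)
        prox = np.asarray(ds.ori_proximity(curve.locations.astype(int)
                                           % chrom.length, chrom))
        assert curve.values[np.argmax(prox)] > 0.9
        # f_copy > 1 almost everywhere except the exact ter: bias near ter
        # is small but non-negative by construction
        assert curve.values[np.argmin(prox)] >= 0

    def test_window_larger_than_gene_set(self):
        chrom = ds.CircularChromosome("c", 10_000)
        genes = genes_on_circle(4, 10_000)
        f = pd.Series(1.0, index=[g.gene_id for g in genes])
        with pytest.raises(InputError):
            spatial.updown_bias_curve(spatial.FoldChanges(f, [], "A", "B"),
                                      genes, chrom, window=10)


class TestRegulonFrequency:
    def test_full_and_empty_target(self, small_cfg):
        chrom, genes = ds.simulate_genome(small_cfg)
        ids = [g.gene_id for g in genes]
        full = spatial.regulon_window_frequency(ids, genes, chrom, window=50)
        assert np.allclose(full.values, 1.0)
        empty = spatial.regulon_window_frequency([], genes, chrom, window=50)
        assert np.allclose(empty.values, 0.0)

    def test_oric_clustered_target_peaks_at_oric(self, small_cfg):
        chrom, genes = ds.simulate_genome(small_cfg)
        target = [g.gene_id for g in genes
                  if ds.ori_proximity(g.midpoint, chrom) > 0.8]
        curve = spatial.regulon_window_frequency(target, genes, chrom,
                                                 window=50)
        prox = np.asarray(ds.ori_proximity(curve.locations.astype(int)
                                           % chrom.length, chrom))
        assert curve.values[np.argmax(prox)] > curve.values[np.argmin(prox)]


class TestFrequencyBiasCorrection:
    def test_pure_composition_bias_removed(self):
        """Fold changes of 0.5 everywhere with no copy difference -> 1."""
        chrom = ds.CircularChromosome("c", 100_000)
        genes = genes_on_circle(40, 100_000)
        ids = [g.gene_id for g in genes]
        fold = spatial.FoldChanges(pd.Series(0.5, index=ids), [], "A", "B")
        curve = spatial.fold_change_curve(fold, genes, chrom, window=10)
        zero = [mfa.ZeroDifferenceResult("right", 25_000.0, "everywhere"),
                mfa.ZeroDifferenceResult("left", 75_000.0, "everywhere")]
        corrected, c = spatial.frequency_bias_correct(curve, fold, genes,
                                                      chrom, zero)
        assert c == pytest.approx(0.5)
        assert np.allclose(corrected.values, 1.0)

    def test_already_anchored_curve_unchanged(self, noiseless_cfg,
                                              fitted_model):
        """If fold changes equal the copy difference, c = 1 exactly."""
        chrom, genes = ds.simulate_genome(noiseless_cfg)
        _, truth = ds.simulate_expression(noiseless_cfg, chrom, genes)
        fold = spatial.FoldChanges(truth["f_copy"].rename("f_total"), [],
                                   "EXP", "STAT")
        curve = spatial.fold_change_curve(fold, genes, chrom, window=50)
        zero = mfa.zero_difference_locus(fitted_model,
                                         flat_model_like(fitted_model))
        corrected, c = spatial.frequency_bias_correct(curve, fold, genes,
                                                      chrom, zero)
        assert c == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(corrected.values, curve.values)


class TestBreakpointExclusion:
    def make_curve(self):
        chrom = ds.CircularChromosome("c", 10_000)
        genes = genes_on_circle(20, 10_000)  # genes at 0, 500, ... 9500
        ids = [g.gene_id for g in genes]
        fold = spatial.FoldChanges(pd.Series(1.0, index=ids), [], "A", "B")
        return spatial.fold_change_curve(fold, genes, chrom, window=4)

    def test_no_breakpoints_identity(self):
        curve = self.make_curve()
        out = spatial.exclude_breakpoint_windows(curve, [])
        assert not out.excluded.any()

    def test_breakpoint_flags_spanning_windows(self):
        curve = self.make_curve()
        # windows span 4 genes = 1500 bp; breakpoint at 1250 sits strictly
        # inside windows starting at genes 0..2 (spans [0,1500],[500,2000],
        # [1000,2500]) but not [1500,3000]
        out = spatial.exclude_breakpoint_windows(curve, [1250])
        assert out.excluded.sum() == 3
        assert list(np.nonzero(out.excluded)[0]) == [0, 1, 2]

    def test_boundary_breakpoint_not_flagged(self):
        curve = self.make_curve()
        # exactly on a member coordinate: strictly-inside rule leaves the
        # adjacent windows whose span it delimits unflagged
        out = spatial.exclude_breakpoint_windows(curve, [1500])
        spans = [curve.span(i) for i in np.nonzero(out.excluded)[0]]
        assert all(first < 1500 < last for first, last in spans)


class TestCopyNormalize:
    def test_unit_difference_identity(self):
        counts = make_counts({"EXP_1": [4.0, 8.0], "STAT_1": [2.0, 2.0]},
                             [100, 100])
        expr = spatial.normalize_expression(counts, quantile=False)
        out = spatial.copy_normalize_expression(
            expr, pd.Series(1.0, index=expr.values.index))
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_normalizing_by_own_copy_curve_recovers_promoter_profile(
            self, noiseless_cfg):
        chrom, genes = ds.simulate_genome(noiseless_cfg)
        counts, truth = ds.simulate_expression(noiseless_cfg, chrom, genes)
        expr = spatial.normalize_expression(counts, quantile=False)
        out = spatial.copy_normalize_expression(expr, truth["f_copy"],
                                                conditions=("EXP",))
        fold = spatial.gene_fold_changes(out, "EXP", "STAT")
        # remaining fold change is the promoter factor times the (constant)
        # library-composition factor
        resid = fold.f_total / truth["f_reg"].reindex(fold.f_total.index)
        assert np.allclose(resid, resid.iloc[0])

    def test_slope_flattened_after_normalization(self):
        # promoter-free data: the whole gradient is dosage, so normalizing
        # by the planted copy curve must flatten the slope essentially to 0
        cfg = ds.SimulationConfig(L=500_000, n_genes=300, coverage_window=2500,
                                  coverage_noise_sd=0.0, replicate_noise_sd=0.0,
                                  promoter_log2fc_sd=0.0,
                                  fraction_dosage_dominant=1.0, seed=7)
        chrom, genes = ds.simulate_genome(cfg)
        counts, truth = ds.simulate_expression(cfg, chrom, genes)
        expr = spatial.normalize_expression(counts, quantile=False)
        f0 = spatial.gene_fold_changes(expr, "EXP", "STAT").f_total
        s0 = spatial.spatial_log2_slope(f0, genes, chrom)
        out = spatial.copy_normalize_expression(expr, truth["f_copy"])
        f1 = spatial.gene_fold_changes(out, "EXP", "STAT").f_total
        s1 = spatial.spatial_log2_slope(f1, genes, chrom)
        assert abs(s1) < 0.05 * abs(s0)


class TestSelectUpGenes:
    def test_identical_replicates_empty(self):
        counts = make_counts({"EXP_1": [5.0, 7.0], "EXP_2": [5.0, 7.0],
                              "STAT_1": [5.0, 7.0], "STAT_2": [5.0, 7.0]},
                             [100, 100])
        expr = spatial.normalize_expression(counts, quantile=False)
        up, _ = spatial.select_up_genes(expr, "EXP", "STAT")
        assert up == set()

    def test_alpha_zero_empty(self, small_cfg):
        chrom, genes = ds.simulate_genome(small_cfg)
        counts, _ = ds.simulate_expression(small_cfg, chrom, genes)
        expr = spatial.normalize_expression(counts, quantile=False)
        up, _ = spatial.select_up_genes(expr, "EXP", "STAT", alpha=0.0)
        assert up == set()

    def test_power_on_planted_eightfold_genes(self):
        """100 genes at 8-fold up, log2 noise 0.1, n=3: nearly all found."""
        rng = np.random.default_rng(5)
        n = 1000
        base = rng.lognormal(3, 1, size=n)
        up_mask = np.zeros(n, dtype=bool)
        up_mask[:100] = True
        factor = np.where(up_mask, 8.0, 1.0)
        cols = {}
        for r in range(1, 4):
            cols[f"EXP_{r}"] = base * factor * 2 ** rng.normal(0, 0.1, n)
            cols[f"STAT_{r}"] = base * 2 ** rng.normal(0, 0.1, n)
        counts = make_counts(cols, [100] * n)
        expr = spatial.normalize_expression(counts, quantile=False)
        up, pvals = spatial.select_up_genes(expr, "EXP", "STAT")
        planted = {f"g{i}" for i in range(100)}
        assert len(up & planted) >= 95

    def test_single_replicate_rejected(self):
        counts = make_counts({"EXP_1": [5.0], "STAT_1": [5.0]}, [100])
        expr = spatial.normalize_expression(counts, quantile=False)
        with pytest.raises(InputError):
            spatial.select_up_genes(expr, "EXP", "STAT")
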