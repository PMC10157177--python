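"""Cross-species geometry: migration, constellation, growth classes."""

import itertools

import numpy as np
import pytest

import dosagescope as ds
from dosagescope.comparative import (SpeciesGeometry, class_symmetry_summary,
                                     constellation_permutation_null,
                                     constellation_scan, count_16S,
                                     diagonal_ridge, growth_class,
                                     migration_variation,
                                     ori_distance_vector,
                                     select_family_representatives)
from dosagescope.errors import InputError
from dosagescope.io import OrthologTable, SpeciesMeta


class TestOriDistanceVector:
    def test_endpoints(self):
        chrom = ds.CircularChromosome("c", 1000, oriC=0)
        v = ori_distance_vector(np.array([100, 600]), 100, chrom)
        assert v[0] == 0.0
        assert v[1] == 1.0  # antipode of the candidate

    def test_rotation_invariance(self):
        chrom = ds.CircularChromosome("c", 1000)
        pos = np.array([10, 250, 600, 900])
        v1 = ori_distance_vector(pos, 100, chrom)
        v2 = ori_distance_vector((pos + 333) % 1000, (100 + 333) % 1000, chrom)
        assert np.allclose(v1, v2)


def simulated_pair(p_c, delta, n, seed, L=500_000):
    cfg = ds.SimulationConfig(L=L, n_genes=n, ortholog_conservation=p_c,
                              oriC_offset=delta, seed=seed)
    chrom, genes = ds.simulate_genome(cfg)
    chrom_b, genes_b, table, truth = ds.simulate_ortholog_pair(cfg, chrom,
                                                               genes)
    return (table, SpeciesGeometry.from_genes(chrom, genes),
            SpeciesGeometry.from_genes(chrom_b, genes_b), truth)


class TestConstellation:
    def test_perfect_conservation_r_is_one(self):
        table, ga, gb, _ = simulated_pair(1.0, 0, 500, seed=1)
        res = constellation_scan(table, ga, gb)
        assert res.r_max == pytest.approx(1.0, abs=1e-9)
        err = abs(res.best_b - res.best_a) % 500_000
        assert min(err, 500_000 - err) <= 500_000 // 200

    def test_matrix_bounds_and_argmax_consistency(self):
        table, ga, gb, _ = simulated_pair(0.7, 100_000, 300, seed=2)
        res = constellation_scan(table, ga, gb)
        finite = res.matrix[np.isfinite(res.matrix)]
        assert finite.min() >= -1 - 1e-12 and finite.max() <= 1 + 1e-12
        i = list(res.candidates_a).index(res.best_a)
        j = list(res.candidates_b).index(res.best_b)
        assert res.matrix[i, j] == res.r_max == np.nanmax(res.matrix)

    def test_identical_gene_order_degenerate(self):
        cfg = ds.SimulationConfig(L=500_000, n_genes=300, seed=3)
        chrom, genes = ds.simulate_genome(cfg)
        shift = 123_456
        genes_b = [ds.GeneRecord(g.gene_id + "_b",
                                 (g.midpoint + shift) % cfg.L, g.strand,
                                 g.length) for g in genes]
        chrom_b = ds.CircularChromosome("B", cfg.L, oriC=shift)
        table = OrthologTable("A", "B",
                              [(g.gene_id, g.gene_id + "_b") for g in genes])
        res = constellation_scan(table, SpeciesGeometry.from_genes(chrom, genes),
                                 SpeciesGeometry.from_genes(chrom_b, genes_b))
        assert res.degenerate
        assert res.ridge_score > 0.9

    def test_shuffled_pairing_not_degenerate(self):
        table, ga, gb, _ = simulated_pair(0.8, 50_000, 400, seed=4)
        res = constellation_scan(table, ga, gb)
        assert not res.degenerate

    def test_single_spike_matrix_low_ridge(self):
        m = np.full((20, 20), 0.1)
        m[7, 11] = 0.95
        score, flag = diagonal_ridge(m)
        assert score == pytest.approx((0.95 + 19 * 0.1) / 20 / 0.95, rel=1e-6)
        assert not flag

    def test_too_few_orthologs(self):
        table, ga, gb, _ = simulated_pair(1.0, 0, 10, seed=5)
        small = OrthologTable("A", "B", table.pairs[:2])
        with pytest.raises(InputError):
            constellation_scan(small, ga, gb)

    def test_null_r_max_small(self):
        table, ga, gb, _ = simulated_pair(0.0, 200_000, 1000, seed=6)
        res = constellation_scan(table, ga, gb)
        assert res.r_max < 0.2

    def test_permutation_null_reproducible(self):
        table, ga, gb, _ = simulated_pair(0.5, 0, 200, seed=7)
        n1 = constellation_permutation_null(table, ga, gb, n_shuffles=20,
                                            seed=1)
        n2 = constellation_permutation_null(table, ga, gb, n_shuffles=20,
                                            seed=1)
        assert np.array_equal(n1, n2)


class TestMigration:
    def geometry_with_jitter(self, ref, jitter, seed):
        """Positions whose oriC proximity is jittered by +-jitter."""
        rng = np.random.default_rng(seed)
        chrom = ref.chrom
        pos = {}
        for gid, p in ref.positions.items():
            d = ds.circular_distance(p, chrom.oriC, chrom)
            d2 = np.clip(d + rng.uniform(-jitter, jitter) * chrom.half_length,
                         0, chrom.half_length)
            pos[gid + "_x"] = int(chrom.oriC + d2) % chrom.length
        return SpeciesGeometry(chrom, pos), {g: g + "_x" for g in ref.positions}

    def test_identical_positions_zero(self):
        cfg = ds.SimulationConfig(L=100_000, n_genes=50, seed=8)
        chrom, genes = ds.simulate_genome(cfg)
        ref = SpeciesGeometry.from_genes(chrom, genes)
        other, mapping = self.geometry_with_jitter(ref, 0.0, seed=0)
        out = migration_variation({"all": list(ref.positions)}, ref,
                                  [other, other], [mapping, mapping])
        assert out[0].mean == pytest.approx(0.0, abs=1e-9)
        assert out[0].se == pytest.approx(0.0, abs=1e-9)

    def test_two_gene_closed_form_se(self):
        chrom = ds.CircularChromosome("c", 1000, oriC=0)
        ref = SpeciesGeometry(chrom, {"a": 0, "b": 0})
        # averaged differences 0.1 and 0.3 -> mean 0.2, SE 0.1
        other = SpeciesGeometry(chrom, {"a_x": 50, "b_x": 150})
        mapping = {"a": "a_x", "b": "b_x"}
        out = migration_variation({"s": ["a", "b"]}, ref, [other], [mapping])
        assert out[0].mean == pytest.approx(0.2)
        assert out[0].se == pytest.approx(0.1)

    def test_low_jitter_set_below_high_jitter_set(self):
        cfg = ds.SimulationConfig(L=500_000, n_genes=200, seed=9)
        chrom, genes = ds.simulate_genome(cfg)
        ref = SpeciesGeometry.from_genes(chrom, genes)
        ids = list(ref.positions)
        for seed in range(5):
            # copy set jittered +-0.02, promoter set +-0.2 in the same species
            low, _ = self.geometry_with_jitter(ref, 0.02, seed * 2 + 1)
            high, _ = self.geometry_with_jitter(ref, 0.2, seed * 2 + 2)
            mapping = {g: g + "_x" for g in ids}
            lowhigh = SpeciesGeometry(chrom, {
                **{g + "_x": low.positions[g + "_x"] for g in ids[:100]},
                **{g + "_x": high.positions[g + "_x"] for g in ids[100:]}})
            out = migration_variation({"copy": ids[:100],
                                       "promoter": ids[100:]},
                                      ref, [lowhigh, lowhigh],
                                      [mapping, mapping])
            means = {s.set_name: s.mean for s in out}
            assert means["copy"] < means["promoter"]

    def test_missing_ortholog_dropped(self):
        chrom = ds.CircularChromosome("c", 1000)
        ref = SpeciesGeometry(chrom, {"a": 10, "b": 20})
        other = SpeciesGeometry(chrom, {"a_x": 10})
        out = migration_variation({"s": ["a", "b"]}, ref, [other],
                                  [{"a": "a_x"}])
        assert out[0].n_genes == 1 and out[0].n_dropped == 1


class TestGrowthClass:
    @pytest.mark.parametrize("n,expected", [
        (0, "slow"), (3, "slow"), (4, "excluded"), (5, "excluded"),
        (6, "fast"), (12, "fast")])
    def test_thresholds_exact(self, n, expected):
        assert growth_class(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            growth_class(-1)


class TestCount16S:
    def test_counts_by_product_substring(self):
        feats = [{"product": "16S ribosomal RNA"}] * 7 + \
                [{"product": "23S ribosomal RNA"}, {"product": "5S rRNA"}]
        assert count_16S(feats) == 7

    def test_mixed_case_counted(self):
        assert count_16S([{"product": "16s ribosomal RNA"}]) == 1

    def test_no_16s(self):
        assert count_16S([{"product": "5S"}, {"product": "23S"}]) == 0


class TestFamilyRepresentatives:
    META = [SpeciesMeta(f"sp{i}", f"fam{i % 3}", "Gamma", 3, 1_000_000)
            for i in range(12)]

    def test_one_per_family_deterministic(self):
        reps = select_family_representatives(self.META, seed=4)
        assert len(reps) == 3
        assert {r.family for r in reps} == {"fam0", "fam1", "fam2"}
        assert reps == select_family_representatives(self.META, seed=4)

    def test_singleton_family(self):
        meta = [SpeciesMeta("only", "famX", "Gamma", 7, 1_000_000)]
        assert select_family_representatives(meta, seed=0)[0].species == "only"


class TestClassSymmetry:
    def build_group(self, p_c, n_species, seed0):
        pair_data = {}
        species = [f"sp{seed0}_{i}" for i in range(n_species)]
        for k, (s1, s2) in enumerate(itertools.combinations(species, 2)):
            table, ga, gb, _ = simulated_pair(p_c, 77_000 * (k + 1), 200,
                                              seed=seed0 + k)
            pair_data[(s1, s2)] = (table, ga, gb)
        return species, pair_data

    def test_pair_count(self):
        species, pair_data = self.build_group(0.8, 3, seed0=10)
        out = class_symmetry_summary({"G/fast": species}, pair_data)
        assert out[0].n_pairs == 3

    def test_fast_group_exceeds_slow_group(self):
        fast_sp, fast_data = self.build_group(0.9, 3, seed0=20)
        slow_sp, slow_data = self.build_group(0.4, 3, seed0=30)
        out = class_symmetry_summary(
            {"G/fast": fast_sp, "G/slow": slow_sp},
            {**fast_data, **slow_data})
        means = {o.group: o.mean_r_max for o in out}
        assert means["fast"] > means["slow"]

    def test_small_group_skipped(self):
        species, pair_data = self.build_group(0.8, 2, seed0=40)
        out = class_symmetry_summary({"G/fast": species[:1]}, pair_data)
        assert out == []
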