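"""Generator behaviour: determinism, geometry, and count-model expectations."""

import numpy as np
import pandas as pd
import pytest

import cisspread as cs
from cisspread.simulate import SizingError
from cisspread.windows import baseline_gain_correlation


def _one_gene_setup(n_variants, s, seed=0, length=10_000_000):
    """Hand-built single-gene truth for direct count-model checks."""
    genes = pd.DataFrame({
        "gene_id": ["g0"], "chrom": ["chrT"], "start": [0], "end": [length],
        "strand": ["+"], "midpoint": [length // 2],
        "distance_to_integration": [0], "s_true": [s],
    })
    rng = np.random.default_rng(seed)
    variants = pd.DataFrame({
        "gene_id": "g0", "chrom": "chrT", "pos": np.arange(1, n_variants + 1),
        "allele_a_id": "A", "allele_b_id": "G",
        "cis_allele": np.where(rng.random(n_variants) < 0.5, "a", "b"),
    })
    return genes, cs.GroundTruth(genes=genes, variants=variants)


def _cis_counts(counts, truth):
    cis_is_a = (truth.variants["cis_allele"] == "a").to_numpy()
    cis_exp = np.where(cis_is_a, counts["exp_a"], counts["exp_b"])
    tot_exp = (counts["exp_a"] + counts["exp_b"]).to_numpy()
    return cis_exp, tot_exp


class TestGenerateGenes:
    def test_zero_genes_gives_empty_tables(self):
        genes, variants = cs.generate_genes(cs.SimParams(n_genes=0))
        assert len(genes) == 0 and len(variants) == 0

    def test_deterministic_for_fixed_seed(self, small_params):
        g1, v1 = cs.generate_genes(small_params)
        g2, v2 = cs.generate_genes(small_params)
        pd.testing.assert_frame_equal(g1, g2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_genes_in_bounds_disjoint_sorted_with_variants(self, small_params):
        genes, variants = cs.generate_genes(small_params)
        assert (genes["start"] >= 0).all()
        assert (genes["end"] <= small_params.chrom_length).all()
        # brute-force pairwise overlap check
        ivs = list(zip(genes["start"], genes["end"]))
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                assert ivs[i][1] <= ivs[j][0] or ivs[j][1] <= ivs[i][0]
        assert (genes["start"].diff().dropna() > 0).all()
        assert set(variants["gene_id"]) == set(genes["gene_id"])
        # each variant inside its gene (1-based position)
        merged = variants.merge(genes, on="gene_id")
        assert ((merged["pos"] > merged["start"]) & (merged["pos"] <= merged["end"])).all()

    def test_chromosome_too_short_raises(self):
        with pytest.raises(SizingError):
            cs.generate_genes(cs.SimParams(chrom_length=10_000, n_genes=100,
                                           integration_pos=100, centromere_pos=5_000))

    def test_resistant_domain_genes_have_zero_truth(self, small_params):
        params = small_params.replace(resistant_domains=[(3_000_000, 4_000_000)])
        genes, variants = cs.generate_genes(params)
        truth = cs.make_ground_truth(params, genes, variants).genes
        inside = (truth["midpoint"] >= 3_000_000) & (truth["midpoint"] < 4_000_000)
        assert inside.any()
        assert (truth.loc[inside, "s_true"] == 0).all()
        assert (truth.loc[~inside, "s_true"] > 0).all()


class TestAllelicCounts:
    def test_no_silencing_gives_balanced_experimental_ratio(self):
        genes, truth = _one_gene_setup(5_000, s=0.0)
        counts = cs.simulate_allelic_counts(genes, truth, cs.SimParams(seed=2))
        cis, tot = _cis_counts(counts, truth)
        freq = cis.sum() / tot.sum()
        se = np.sqrt(0.25 / tot.sum())
        assert abs(freq - 0.5) < 3 * se

    def test_complete_silencing_removes_cis_allele(self):
        genes, truth = _one_gene_setup(500, s=1.0)
        counts = cs.simulate_allelic_counts(genes, truth, cs.SimParams(seed=3))
        cis, _ = _cis_counts(counts, truth)
        assert (cis == 0).all()

    def test_half_silencing_gives_one_third_cis_frequency(self):
        # closed form: expected cis frequency (1 - s) / (2 - s) = 1/3 at s = 0.5
        genes, truth = _one_gene_setup(10_000, s=0.5)
        counts = cs.simulate_allelic_counts(genes, truth, cs.SimParams(seed=4))
        cis, tot = _cis_counts(counts, truth)
        freq = cis.sum() / tot.sum()
        se = np.sqrt((1 / 3) * (2 / 3) / tot.sum())
        assert abs(freq - 1 / 3) < 3 * se

    def test_deterministic_counts(self, small_params):
        genes, variants = cs.generate_genes(small_params)
        truth = cs.make_ground_truth(small_params, genes, variants)
        c1 = cs.simulate_allelic_counts(genes, truth, small_params)
        c2 = cs.simulate_allelic_counts(genes, truth, small_params)
        pd.testing.assert_frame_equal(c1, c2)


class TestChipWindows:
    def test_zero_gain_zero_noise_equals_baseline(self, small_params):
        params = small_params.replace(gain_coefficient=0.0, noise_sd=0.0)
        chip = cs.simulate_chip_windows(params)
        np.testing.assert_array_equal(chip.k27me3_ctrl.values,
                                      chip.k27me3_exp.values)

    def test_noiseless_uniform_proximity_gain_is_rank_identical(self, small_params):
        # flat proximity weight isolates the gain ∝ baseline construction
        params = small_params.replace(noise_sd=0.0, chip_gain_halflife=np.inf)
        chip = cs.simulate_chip_windows(params)
        res = baseline_gain_correlation(chip.k27me3_ctrl, chip.k27me3_exp,
                                        (0, params.centromere_pos))
        assert res.estimate == pytest.approx(1.0)

    def test_default_regime_mirrors_preexisting_levels(self):
        params = cs.SimParams(seed=5)  # 500 windows of 100 kb over 50 Mb
        chip = cs.simulate_chip_windows(params)
        res = baseline_gain_correlation(chip.k27me3_ctrl, chip.k27me3_exp,
                                        (0, params.centromere_pos))
        assert res.estimate >= 0.8

    def test_active_mark_lost_where_silenced(self, small_params):
        params = small_params.replace(noise_sd=0.0)
        chip = cs.simulate_chip_windows(params)
        near = chip.window_silencing > 0.5
        ratio = chip.k27ac_exp.values / chip.k27ac_ctrl.values
        assert (ratio[near] < 1).all()
        far = chip.window_silencing < 1e-3
        assert np.allclose(ratio[far], 1.0, atol=1e-3)

    def test_wrong_baseline_length_rejected(self, small_params):
        params = small_params.replace(k27me3_baseline_profile=np.ones(3))
        with pytest.raises(ValueError, match="length"):
            cs.simulate_chip_windows(params)


class TestHic:
    def test_two_bin_chromosome(self):
        params = cs.SimParams(chrom_length=80_000, n_genes=0, integration_pos=10,
                              centromere_pos=40_000, seed=0)
        hic = cs.simulate_hic(params)
        assert hic.matrix.shape == (2, 2)
        assert hic.matrix[0, 1] == hic.matrix[1, 0]

    def test_symmetry(self, small_params):
        hic = cs.simulate_hic(small_params)
        np.testing.assert_array_equal(hic.matrix, hic.matrix.T)

    def test_noise_off_reproduces_power_law(self, small_params):
        params = small_params.replace(hic_noise=False, hic_decay_exponent=1.0)
        hic = cs.simulate_hic(params)
        row = hic.matrix[0]
        d = np.arange(len(row))
        np.testing.assert_allclose(row, row[0] / (1.0 + d))
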