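import numpy as np
import pytest

from pclmhap import (
    PCLMHaplotypeEstimator,
    SimulationSpec,
    fit_blocks,
    ligate,
    partition_ligation_fit,
    simulate_population,
)
from pclmhap.partition_ligation import BlockFit


def expand(block, n_snps):
    full = np.zeros(2**n_snps)
    full[block.haplotypes] = block.probs
    return full


class TestBlockPartitioning:
    @pytest.mark.parametrize(
        "n, size, expected",
        [(10, 5, [(0, 5), (5, 10)]), (11, 5, [(0, 5), (5, 10), (10, 11)]), (4, 2, [(0, 2), (2, 4)])],
    )
    def test_block_ranges(self, n, size, expected, four_hap_panel):
        _, g = four_hap_panel
        if n != 4:
            rng = np.random.default_rng(0)
            g = rng.integers(0, 3, size=(60, n))
        blocks = fit_blocks(g, block_size=size)
        assert [b.snp_range for b in blocks] == expected

    def test_blocks_keep_at_least_one_haplotype(self, four_hap_panel):
        _, g = four_hap_panel
        for b in fit_blocks(g, block_size=2, prune=0.01):
            assert b.haplotypes.size >= 1
            assert np.isclose(b.probs.sum(), 1.0)
            assert np.all(b.probs > 0)


class TestLigation:
    def test_candidate_count_is_cartesian_product(self):
        p = np.zeros(16)
        p[[0b0001, 0b1110]] = [0.5, 0.5]
        g = simulate_population(SimulationSpec(4, p, 200, seed=1))
        left = BlockFit((0, 2), np.array([0b00, 0b11]), np.array([0.5, 0.5]))
        right = BlockFit((2, 4), np.array([0b01, 0b10]), np.array([0.5, 0.5]))
        merged = ligate(left, right, g, prune=0.0)
        assert merged.haplotypes.size == 4  # 2 x 2 candidates, none pruned
        assert merged.snp_range == (0, 4)

    def test_incompatible_candidates_give_clear_error(self, four_hap_panel):
        _, g = four_hap_panel
        left = BlockFit((0, 2), np.array([0b00]), np.array([1.0]))
        right = BlockFit((2, 4), np.array([0b01]), np.array([1.0]))
        with pytest.raises(ValueError, match="incompatible"):
            ligate(left, right, g)

    def test_candidate_cap_enforced(self, four_hap_panel):
        _, g = four_hap_panel
        left = BlockFit((0, 2), np.arange(4), np.full(4, 0.25))
        right = BlockFit((2, 4), np.arange(4), np.full(4, 0.25))
        with pytest.raises(ValueError, match="cap"):
            ligate(left, right, g, candidate_cap=8)

    def test_nonadjacent_blocks_rejected(self, four_hap_panel):
        _, g = four_hap_panel
        left = BlockFit((0, 2), np.arange(4), np.full(4, 0.25))
        right = BlockFit((3, 4), np.arange(2), np.full(2, 0.5))
        with pytest.raises(ValueError, match="adjacent"):
            ligate(left, right, g)


class TestPipelineFidelity:
    def test_ligated_close_to_direct_fit(self, four_hap_panel):
        p_true, g = four_hap_panel
        direct = PCLMHaplotypeEstimator(lam=1e-3).fit(g)
        pl = partition_ligation_fit(g, block_size=2, lam=1e-3, prune=0.01)
        assert np.max(np.abs(expand(pl, 4) - direct.haplotype_probs_)) < 0.02

    def test_zero_prune_threshold_is_exact(self, four_hap_panel):
        _, g = four_hap_panel
        direct = PCLMHaplotypeEstimator(lam=1e-3).fit(g)
        pl = partition_ligation_fit(g, block_size=2, lam=1e-3, prune=0.0)
        assert np.max(np.abs(expand(pl, 4) - direct.haplotype_probs_)) < 1e-6

    def test_tree_ligation_agrees_with_sequential(self, four_hap_panel):
        _, g = four_hap_panel
        seq = partition_ligation_fit(g, block_size=1, lam=1e-3, prune=0.0)
        tree = partition_ligation_fit(g, block_size=1, lam=1e-3, prune=0.0, ligation="tree")
        assert np.max(np.abs(expand(seq, 4) - expand(tree, 4))) < 1e-6

    def test_scales_past_direct_cap(self):
        # a 6-SNP panel fitted in blocks of 3 recovers the dominant haplotypes
        p = np.zeros(64)
        p[[0b000000, 0b111111, 0b000111]] = [0.5, 0.3, 0.2]
        g = simulate_population(SimulationSpec(6, p, 500, seed=2))
        pl = partition_ligation_fit(g, block_size=3, lam=1e-3, prune=0.01)
        full = expand(pl, 6)
        assert np.isclose(full.sum(), 1.0)
        top = np.argsort(-full)[:3]
        assert set(top) == {0b000000, 0b111111, 0b000111}
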