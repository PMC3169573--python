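"""Partition-ligation: scaling haplotype estimation past the direct-fit cap.

Small contiguous blocks of markers are fitted directly, haplotypes with
small probability are pruned, and adjacent blocks are merged pairwise: the
candidate haplotypes of a merged block are the cartesian product of the kept
lists, a reduced penalized model is refitted over just those candidates
(restricted mating and composition matrices), started from the products of
the block probabilities, and pruned again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import scipy.sparse as sp

from .estimator import PCLMHaplotypeEstimator, _expected_allele_freqs
from .pclm_core import PCLMFit, PCLMProblem, fit_pclm
from .variants import DoseProbTable

logger = logging.getLogger(__name__)

DEFAULT_PRUNE = 0.01
DEFAULT_CANDIDATE_CAP = 4096


@dataclass
class BlockFit:
    """Fitted, pruned haplotype distribution on a contiguous marker range."""

    snp_range: tuple[int, int]            # half-open [start, stop)
    haplotypes: np.ndarray                # bit patterns, first SNP of range = MSB
    probs: np.ndarray                     # renormalized over kept haplotypes

    @property
    def n_snps(self) -> int:
        return self.snp_range[1] - self.snp_range[0]

    def labels(self) -> list[str]:
        w = self.n_snps
        return [format(int(h), f"0{w}b") for h in self.haplotypes]


def _as_table(data: Union[np.ndarray, DoseProbTable]) -> DoseProbTable:
    if isinstance(data, DoseProbTable):
        return data
    return DoseProbTable.from_crisp(np.asarray(data, dtype=float))


def _pruned(haplotypes: np.ndarray, probs: np.ndarray, threshold: float):
    keep = probs >= threshold
    if not keep.any():
        keep[np.argmax(probs)] = True
    h = haplotypes[keep]
    p = probs[keep]
    return h, p / p.sum()


def fit_blocks(
    data: Union[np.ndarray, DoseProbTable],
    block_size: int = 5,
    lam: Union[float, str] = 1e-3,
    prune: float = DEFAULT_PRUNE,
) -> list[BlockFit]:
    """Fit contiguous marker blocks left to right (last block may be smaller)."""
    table = _as_table(data)
    n = table.n_snps
    if block_size < 1:
        raise ValueError("block_size must be positive")
    blocks = []
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        sub = table.subset_snps(range(start, stop))
        est = PCLMHaplotypeEstimator(lam=lam).fit(sub)
        haps, probs = _pruned(
            np.arange(2 ** (stop - start)), est.haplotype_probs_, prune
        )
        blocks.append(BlockFit(snp_range=(start, stop), haplotypes=haps, probs=probs))
    return blocks


def _restricted_fit(
    candidates: np.ndarray,
    start_probs: np.ndarray,
    table: DoseProbTable,
    snp_range: tuple[int, int],
    lam: float,
) -> PCLMFit:
    """Penalized fit over a restricted candidate-haplotype set."""
    start, stop = snp_range
    n_cat = stop - start
    m = candidates.size
    shifts = np.arange(n_cat - 1, -1, -1)
    cand_bits = (candidates[:, None] >> shifts[None, :]) & 1      # (m, n_cat)

    # restricted mating matrix over ordered candidate pairs
    j = np.arange(m * m)
    a, b = j // m, j % m
    M_r = sp.coo_matrix(
        (np.ones(2 * m * m), (np.concatenate([j, j]), np.concatenate([a, b]))),
        shape=(m * m, m),
    ).tocsr()

    pair_doses = cand_bits[a] + cand_bits[b]                       # (m^2, n_cat)
    powers = 3 ** np.arange(n_cat - 1, -1, -1, dtype=np.int64)
    pair_gidx = pair_doses.astype(np.int64) @ powers

    # per-individual composite rows: probability of each pair's genotype
    probs = table.probs[:, start:stop, :]
    n_ind = probs.shape[0]
    vals = np.ones((n_ind, m * m))
    for s in range(n_cat):
        vals *= probs[:, s, pair_doses[:, s]]
    comp = sp.csr_matrix(vals)

    # restricted full genotype table (unique reachable genotypes)
    uniq, inv = np.unique(pair_gidx, return_inverse=True)
    C_r = sp.coo_matrix(
        (np.ones(m * m), (inv, j)), shape=(uniq.size, m * m)
    ).tocsr()

    full_counts = None
    if table.is_crisp():
        g = np.argmax(probs, axis=2).astype(np.int64)
        gidx = g @ powers
        pos = np.searchsorted(uniq, gidx)
        ok = (pos < uniq.size) & (uniq[np.clip(pos, 0, uniq.size - 1)] == gidx)
        if ok.all():
            full_counts = np.bincount(pos, minlength=uniq.size).astype(float)

    # penalty target: linkage-equilibrium prior restricted to the candidates
    freqs = np.clip(_expected_allele_freqs(table)[start:stop], 1e-6, 1 - 1e-6)
    log_le = cand_bits @ np.log(freqs) + (1 - cand_bits) @ np.log1p(-freqs)
    log_le -= np.log(np.exp(log_le - log_le.max()).sum()) + log_le.max()
    beta0 = log_le

    problem = PCLMProblem(
        mating=M_r,
        comp=comp,
        full_comp=C_r,
        response=np.ones(n_ind),
        n_total=n_ind,
        beta0=beta0,
        lam=lam,
        kind="fuzzy",
        full_counts=full_counts,
    )
    start_p = np.maximum(start_probs, 1e-12)
    start_p = start_p / start_p.sum()
    theta_init = np.concatenate([np.log(start_p), [0.0]])
    return fit_pclm(problem, theta_init=theta_init)


def ligate(
    left: BlockFit,
    right: BlockFit,
    data: Union[np.ndarray, DoseProbTable],
    lam: float = 1e-3,
    prune: float = DEFAULT_PRUNE,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
) -> BlockFit:
    """Merge two adjacent block fits by refitting over the cartesian product
    of their kept haplotypes."""
    if left.snp_range[1] != right.snp_range[0]:
        raise ValueError("blocks must cover adjacent marker ranges")
    n_cand = left.haplotypes.size * right.haplotypes.size
    if n_cand > candidate_cap:
        raise ValueError(
            f"{n_cand} candidate haplotypes exceed the cap of {candidate_cap}; "
            "raise the prune threshold or the cap"
        )
    n_right = right.n_snps
    candidates = (
        (left.haplotypes[:, None].astype(np.int64) << n_right)
        | right.haplotypes[None, :].astype(np.int64)
    ).ravel()
    start_probs = (left.probs[:, None] * right.probs[None, :]).ravel()
    order = np.argsort(candidates)
    candidates, start_probs = candidates[order], start_probs[order]

    table = _as_table(data)
    snp_range = (left.snp_range[0], right.snp_range[1])
    try:
        fit = _restricted_fit(candidates, start_probs, table, snp_range, lam)
    except FloatingPointError as exc:
        raise ValueError(
            "some observed genotypes are incompatible with every candidate "
            "haplotype pair; lower the prune threshold"
        ) from exc
    haps, probs = _pruned(candidates, fit.p_hat, prune)
    return BlockFit(snp_range=snp_range, haplotypes=haps, probs=probs)


def partition_ligation_fit(
    data: Union[np.ndarray, DoseProbTable],
    block_size: int = 5,
    lam: Union[float, str] = 1e-3,
    prune: float = DEFAULT_PRUNE,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
    ligation: str = "sequential",
) -> BlockFit:
    """Full partition-ligation pipeline over a marker panel.

    ``ligation="sequential"`` merges left to right; ``"tree"`` merges
    neighbors pairwise in rounds (balanced alternative).
    """
    blocks = fit_blocks(data, block_size=block_size, lam=lam, prune=prune)
    lam_l = 1e-3 if isinstance(lam, str) else float(lam)
    if ligation == "sequential":
        current = blocks[0]
        for nxt in blocks[1:]:
            current = ligate(current, nxt, data, lam=lam_l,
                             prune=prune, candidate_cap=candidate_cap)
        return current
    if ligation == "tree":
        level = blocks
        while len(level) > 1:
            merged = []
            for k in range(0, len(level) - 1, 2):
                merged.append(
                    ligate(level[k], level[k + 1], data, lam=lam_l,
                           prune=prune, candidate_cap=candidate_cap)
                )
            if len(level) % 2:
                merged.append(level[-1])
            level = merged
        return level[0]
    raise ValueError(f"unknown ligation order {ligation!r}")
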