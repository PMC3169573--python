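"""Problem builders for the three PCLM data flavors.

* aggregated: counts over all ``3**n`` genotype states (zeros included —
  unobserved genotypes carry information and must not be dropped);
* individual: one row of the composition matrix per crisp individual;
* fuzzy: per-individual probability distributions over genotype states,
  built as repeated Kronecker products of per-SNP dose-probability triples
  (the confusion matrix ``F``), composed with ``C``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .model_matrices import HaploSpace, genotype_indices, haplo_space
from .pclm_core import PCLMFit, PCLMProblem, fit_pclm

logger = logging.getLogger(__name__)

#: Dose-probability triple representing a completely missing call.
MISSING_TRIPLE = np.array([1 / 3, 1 / 3, 1 / 3])


@dataclass
class DoseProbTable:
    """Per-individual, per-SNP genotype-state probability triples.

    ``probs[i, s]`` is the probability distribution of individual ``i``'s
    allele dose (0, 1 or 2 copies of the coded allele) at SNP ``s``.  A crisp
    call is a degenerate triple with a single 1; a missing call is the
    uniform triple.  Triples are renormalized on construction.
    """

    probs: np.ndarray
    individual_ids: Optional[Sequence[str]] = None
    snp_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("probs must have shape (n_individuals, n_snps, 3)")
        if np.any(p < 0) or np.any(~np.isfinite(p)):
            raise ValueError("dose probabilities must be finite and nonnegative")
        totals = p.sum(axis=2)
        if np.any(totals <= 0):
            i, s = np.argwhere(totals <= 0)[0]
            raise ValueError(
                f"dose triple of individual {i}, SNP {s} sums to zero and "
                "cannot be normalized"
            )
        self.probs = p / totals[:, :, None]
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i}" for i in range(p.shape[0])]
        if self.snp_ids is None:
            self.snp_ids = [f"snp{s}" for s in range(p.shape[1])]

    @property
    def n_individuals(self) -> int:
        return self.probs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.probs.shape[1]

    def is_crisp(self, atol: float = 0.0) -> bool:
        return bool(np.all(self.probs.max(axis=2) >= 1.0 - atol))

    @classmethod
    def from_crisp(
        cls,
        genotypes: np.ndarray,
        individual_ids=None,
        snp_ids=None,
    ) -> "DoseProbTable":
        """Degenerate table from a crisp 0/1/2 genotype matrix.

        ``NaN`` entries (missing calls) become the uniform triple.
        """
        g = np.asarray(genotypes, dtype=float)
        if g.ndim != 2:
            raise ValueError("genotype matrix must be 2-D")
        missing = np.isnan(g)
        filled = np.where(missing, 0, g)
        if not np.isin(filled, (0, 1, 2)).all():
            raise ValueError("crisp genotype entries must be 0, 1, 2 or NaN")
        n, m = g.shape
        probs = np.zeros((n, m, 3))
        idx = filled.astype(int)
        ii, ss = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
        probs[ii, ss, idx] = 1.0
        probs[missing] = MISSING_TRIPLE
        return cls(probs, individual_ids, snp_ids)

    def subset_snps(self, snp_indices) -> "DoseProbTable":
        idx = list(snp_indices)
        return DoseProbTable(
            self.probs[:, idx, :],
            individual_ids=self.individual_ids,
            snp_ids=[self.snp_ids[s] for s in idx],
        )


def aggregate_genotypes(genotype_matrix: np.ndarray, space: HaploSpace | None = None) -> np.ndarray:
    """Count vector over all ``3**n`` genotype states, zeros included."""
    g = np.asarray(genotype_matrix)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
    n = g.shape[1]
    if space is not None and space.n_snps != n:
        raise ValueError("space does not match the number of SNPs")
    idx = genotype_indices(g)
    return np.bincount(idx, minlength=3**n).astype(float)


def individual_composition(genotype_matrix: np.ndarray, space: HaploSpace | None = None) -> sp.csr_matrix:
    """Per-individual composition matrix: row ``i`` is the ``C`` row of
    individual ``i``'s genotype (duplicates allowed)."""
    g = np.asarray(genotype_matrix)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
    if space is None:
        space = haplo_space(g.shape[1])
    idx = genotype_indices(g)
    return sp.csr_matrix(space.C, dtype=float)[idx, :]


def confusion_rows(dose_table: DoseProbTable) -> sp.csr_matrix:
    """Confusion matrix ``F`` (``N x 3**n``): each row is the Kronecker
    product of the individual's per-SNP dose triples, SNP 1 outermost.

    Crisp individuals give unit-vector rows; an individual with one missing
    SNP gives three equal nonzeros, with two missing SNPs nine, and so on.
    """
    probs = dose_table.probs
    n_ind, n_snps, _ = probs.shape
    rows, cols, vals = [], [], []
    n_dense = 0
    for i in range(n_ind):
        idx = np.zeros(1, dtype=np.int64)
        val = np.ones(1)
        for s in range(n_snps):
            triple = probs[i, s]
            nz = np.flatnonzero(triple)
            idx = (idx[:, None] * 3 + nz[None, :]).ravel()
            val = (val[:, None] * triple[nz][None, :]).ravel()
        if idx.size == 3**n_snps:
            n_dense += 1
        rows.append(np.full(idx.size, i))
        cols.append(idx)
        vals.append(val)
    if n_dense:
        logger.info("%d individuals have fully dense confusion rows", n_dense)
    F = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_ind, 3**n_snps),
    ).tocsr()
    return F


def build_aggregated_problem(
    counts: np.ndarray, beta0: np.ndarray, lam: float, space: HaploSpace | None = None
) -> PCLMProblem:
    """Problem over an aggregated genotype-count vector of length ``3**n``."""
    counts = np.asarray(counts, dtype=float)
    n = int(round(np.log(counts.size) / np.log(3)))
    if 3**n != counts.size:
        raise ValueError("counts length must be a power of 3")
    if space is None:
        space = haplo_space(n)
    n_total = counts.sum()
    if n_total <= 0:
        raise ValueError("counts are all zero; nothing to fit")
    return PCLMProblem(
        mating=space.M,
        comp=space.C,
        full_comp=space.C,
        response=counts,
        n_total=int(round(n_total)),
        beta0=beta0,
        lam=lam,
        kind="aggregated",
        space=space,
    )


def build_individual_problem(
    genotype_matrix: np.ndarray, beta0: np.ndarray, lam: float, space: HaploSpace | None = None
) -> PCLMProblem:
    """Problem over crisp individual genotypes (all-ones response)."""
    g = np.asarray(genotype_matrix)
    if space is None:
        space = haplo_space(g.shape[1])
    comp = individual_composition(g, space)
    counts = aggregate_genotypes(g, space)
    return PCLMProblem(
        mating=space.M,
        comp=comp,
        full_comp=space.C,
        response=np.ones(g.shape[0]),
        n_total=g.shape[0],
        beta0=beta0,
        lam=lam,
        kind="individual",
        full_counts=counts,
        space=space,
    )


def build_fuzzy_problem(
    dose_table: DoseProbTable, beta0: np.ndarray, lam: float, space: HaploSpace | None = None
) -> PCLMProblem:
    """Problem over fuzzy genotypes: composite matrix ``F @ C``."""
    if space is None:
        space = haplo_space(dose_table.n_snps)
    F = confusion_rows(dose_table)
    comp = F @ sp.csr_matrix(space.C, dtype=float)
    full_counts = None
    if dose_table.is_crisp():
        g = np.argmax(dose_table.probs, axis=2)
        full_counts = aggregate_genotypes(g, space)
    return PCLMProblem(
        mating=space.M,
        comp=comp,
        full_comp=space.C,
        response=np.ones(dose_table.n_individuals),
        n_total=dose_table.n_individuals,
        beta0=beta0,
        lam=lam,
        kind="fuzzy",
        full_counts=full_counts,
        space=space,
    )


def fit_fuzzy(dose_table: DoseProbTable, beta0: np.ndarray, lam: float, **fit_kwargs) -> PCLMFit:
    """Fit the fuzzy-genotype PCLM; thin wrapper over the core engine."""
    return fit_pclm(build_fuzzy_problem(dose_table, beta0, lam), **fit_kwargs)
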