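"""State spaces and sparse structure matrices for biallelic SNP haplotypes.

For ``n`` SNPs there are ``2**n`` haplotypes (binary allele vectors, one bit
per SNP), ``4**n`` ordered haplotype pairs (diplotypes) and ``3**n`` unphased
genotypes (per-SNP minor-allele doses 0/1/2).  Two sparse matrices tie these
spaces together:

* the *mating matrix* ``M`` (``4**n x 2**n``): under random mating the vector
  of diplotype probabilities is ``q = exp(M @ log(p))`` for haplotype
  probabilities ``p``;
* the *composition matrix* ``C`` (``3**n x 4**n``): a 0/1 matrix mapping each
  diplotype to the single genotype it produces, so genotype probabilities are
  ``pi = C @ q``.

Digit convention (shared by every module): SNP 1 is the most significant
digit, both in the binary haplotype encoding and in the ternary genotype
encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

#: Default hard cap on the number of SNPs handled by a direct fit.  The
#: scoring equations are formed explicitly, which becomes impractical beyond
#: roughly this size; longer panels go through partition-ligation.
MAX_SNPS = 12


def _check_n_snps(n_snps: int, max_snps: int = MAX_SNPS) -> int:
    n = int(n_snps)
    if n != n_snps or n < 1:
        raise ValueError(f"n_snps must be a positive integer, got {n_snps!r}")
    if n > max_snps:
        raise ValueError(
            f"n_snps={n} exceeds the direct-fit cap of {max_snps} SNPs; "
            "use partition-ligation for longer panels"
        )
    return n


def haplotype_matrix(n_snps: int, max_snps: int = MAX_SNPS) -> np.ndarray:
    """Binary haplotype matrix ``H`` of shape ``(2**n, n)``.

    Row ``h`` is the binary expansion of ``h`` with SNP 1 as the most
    significant bit, so ``H[5] == [1, 0, 1]`` for ``n = 3``.
    """
    n = _check_n_snps(n_snps, max_snps)
    codes = np.arange(2**n)
    shifts = np.arange(n - 1, -1, -1)
    return ((codes[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def mating_matrix(n_snps: int, max_snps: int = MAX_SNPS) -> sp.csr_matrix:
    """Sparse mating matrix ``M`` of shape ``(4**n, 2**n)``.

    Diplotype ``j`` is the ordered pair ``(k, l)`` with ``k = j // 2**n`` and
    ``l = j % 2**n``; row ``j`` holds a 1 in columns ``k`` and ``l`` (a single
    2 when ``k == l``), so every row sums to 2 and
    ``exp(M @ log(p))[j] == p[k] * p[l]``.
    """
    n = _check_n_snps(n_snps, max_snps)
    n_hap = 2**n
    j = np.arange(n_hap * n_hap)
    k = j // n_hap
    l = j % n_hap
    rows = np.concatenate([j, j])
    cols = np.concatenate([k, l])
    data = np.ones(rows.size, dtype=np.int64)
    # duplicate (j, k) entries for homozygous diplotypes sum to 2 in CSR
    return sp.coo_matrix((data, (rows, cols)), shape=(n_hap**2, n_hap)).tocsr()


def genotype_index(dose_vector) -> int:
    """Decimal value of a per-SNP dose vector read as a ternary number.

    SNP 1 is the most significant digit: ``[1, 2] -> 5``.  Entries must be
    crisp doses in {0, 1, 2}; uncertain or missing calls are handled by the
    dose-probability machinery, not here.
    """
    d = np.asarray(dose_vector)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("dose_vector must be a non-empty 1-D sequence")
    if not np.isin(d, (0, 1, 2)).all():
        raise ValueError(f"dose entries must be in {{0,1,2}}, got {dose_vector!r}")
    powers = 3 ** np.arange(d.size - 1, -1, -1)
    return int(d.astype(np.int64) @ powers)


def genotype_indices(genotypes: np.ndarray) -> np.ndarray:
    """Vectorized :func:`genotype_index` over the rows of an ``(N, n)`` matrix."""
    g = np.asarray(genotypes)
    if g.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
    bad = ~np.isin(g, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"genotype entry at individual {i}, SNP {j} is {g[i, j]!r}; "
            "crisp doses must be 0, 1 or 2"
        )
    powers = 3 ** np.arange(g.shape[1] - 1, -1, -1)
    return g.astype(np.int64) @ powers


def composition_matrix(n_snps: int, max_snps: int = MAX_SNPS) -> sp.csr_matrix:
    """Sparse 0/1 composition matrix ``C`` of shape ``(3**n, 4**n)``.

    Column ``j`` (diplotype ``(k, l)``) has its single 1 in the row indexed by
    the ternary value of the dose vector ``H[k] + H[l]``.
    """
    n = _check_n_snps(n_snps, max_snps)
    H = haplotype_matrix(n, max_snps)
    n_hap = 2**n
    j = np.arange(n_hap * n_hap)
    doses = H[j // n_hap] + H[j % n_hap]
    powers = 3 ** np.arange(n - 1, -1, -1)
    g = doses.astype(np.int64) @ powers
    data = np.ones(j.size, dtype=np.int8)
    return sp.coo_matrix((data, (g, j)), shape=(3**n, n_hap**2)).tocsr()


@dataclass(frozen=True)
class HaploSpace:
    """Combinatorial index space for ``n`` biallelic SNPs.

    Bundles the haplotype bit matrix ``H`` with the sparse mating (``M``) and
    composition (``C``) matrices.  Instances are cheap to share; use
    :func:`haplo_space` for a cached build.
    """

    n_snps: int
    H: np.ndarray = field(repr=False)
    M: sp.csr_matrix = field(repr=False)
    C: sp.csr_matrix = field(repr=False)

    @property
    def n_hap(self) -> int:
        return 2**self.n_snps

    @property
    def n_dip(self) -> int:
        return 4**self.n_snps

    @property
    def n_gen(self) -> int:
        return 3**self.n_snps

    def haplotype_labels(self) -> list[str]:
        """Bit-string labels, SNP 1 leftmost (e.g. ``'01011'``)."""
        return ["".join(str(b) for b in row) for row in self.H]

    @classmethod
    def build(cls, n_snps: int, max_snps: int = MAX_SNPS) -> "HaploSpace":
        n = _check_n_snps(n_snps, max_snps)
        return cls(
            n_snps=n,
            H=haplotype_matrix(n, max_snps),
            M=mating_matrix(n, max_snps),
            C=composition_matrix(n, max_snps),
        )


@lru_cache(maxsize=16)
def haplo_space(n_snps: int, max_snps: int = MAX_SNPS) -> HaploSpace:
    """Cached :class:`HaploSpace` for ``n_snps`` markers."""
    return HaploSpace.build(n_snps, max_snps)
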