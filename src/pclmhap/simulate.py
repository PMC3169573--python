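"""Synthetic random-mating populations drawn from a known haplotype pool.

Each individual is two independent haplotype draws from a specified
frequency vector; the crisp genotype is the per-SNP dose sum.  Fuzzification
schemes then emulate the uncertainty patterns of real marker systems:
completely missing calls, AFLP-style dominant scoring (band presence cannot
distinguish the heterozygote from one homozygote), and graded dosage noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .model_matrices import haplotype_matrix
from .variants import MISSING_TRIPLE, DoseProbTable


@dataclass(frozen=True)
class Missing:
    """Replace each call by the uniform triple with probability ``rate``."""

    rate: float = 0.1


@dataclass(frozen=True)
class AflpDominant:
    """Dominant-marker information loss.

    For each affected call (probability ``rate``, default all), the
    band-present genotypes are merged: with ``band_absent_allele = 0`` the
    dose-0 homozygote is scored crisply while doses 1 and 2 both yield the
    "not AA" triple ``(0, w, 1 - w)``.  ``band_absent_allele = 1`` flips the
    direction ("not BB": doses 0 and 1 merge).  ``band_absent_allele`` may be
    a per-SNP sequence.
    """

    rate: float = 1.0
    w: float = 0.5
    band_absent_allele: Union[int, Sequence[int]] = 0


@dataclass(frozen=True)
class DosageNoise:
    """Mix each crisp triple with the uniform: ``(1-c)*crisp + c*uniform``."""

    concentration: float = 0.2


FuzzScheme = Union[Missing, AflpDominant, DosageNoise, None]


@dataclass
class SimulationSpec:
    """Conditions for one synthetic population."""

    n_snps: int
    hap_freqs: np.ndarray
    n_individuals: int
    seed: int = 0
    fuzz_scheme: FuzzScheme = None

    def __post_init__(self) -> None:
        p = np.asarray(self.hap_freqs, dtype=float)
        if p.ndim != 1 or p.size != 2**self.n_snps:
            raise ValueError(f"hap_freqs must have length {2 ** self.n_snps}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("hap_freqs must be nonnegative and sum to 1")
        self.hap_freqs = p / p.sum()
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")


def simulate_population(spec: SimulationSpec) -> np.ndarray:
    """Crisp genotype matrix ``(N, n)`` from two haplotype draws per individual."""
    rng = np.random.default_rng(spec.seed)
    H = haplotype_matrix(spec.n_snps)
    draws = rng.choice(2**spec.n_snps, size=(spec.n_individuals, 2), p=spec.hap_freqs)
    return (H[draws[:, 0]] + H[draws[:, 1]]).astype(np.int64)


def fuzzify(genotypes: np.ndarray, scheme: FuzzScheme, seed: int = 0) -> DoseProbTable:
    """Apply a fuzzification scheme to a crisp genotype matrix.

    For every built-in scheme the true genotype keeps nonzero probability in
    its triple.  ``scheme=None`` returns the degenerate crisp table.
    """
    g = np.asarray(genotypes)
    if g.ndim != 2 or not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be an (N, n) matrix of 0/1/2 doses")
    table = DoseProbTable.from_crisp(g)
    probs = table.probs
    rng = np.random.default_rng(seed)

    if scheme is None:
        return table
    if isinstance(scheme, Missing):
        if not 0 <= scheme.rate <= 1:
            raise ValueError("missing rate must be in [0, 1]")
        mask = rng.random(g.shape) < scheme.rate
        probs[mask] = MISSING_TRIPLE
    elif isinstance(scheme, AflpDominant):
        if not 0 < scheme.w < 1:
            raise ValueError("AFLP weight w must be in (0, 1)")
        direction = np.broadcast_to(
            np.asarray(scheme.band_absent_allele, dtype=int), (g.shape[1],)
        )
        if not np.isin(direction, (0, 1)).all():
            raise ValueError("band_absent_allele entries must be 0 or 1")
        affected = rng.random(g.shape) < scheme.rate
        not_aa = np.array([0.0, scheme.w, 1.0 - scheme.w])   # dose in {1, 2}
        not_bb = np.array([scheme.w, 1.0 - scheme.w, 0.0])   # dose in {0, 1}
        for s in range(g.shape[1]):
            if direction[s] == 0:
                mask = affected[:, s] & (g[:, s] > 0)
                probs[mask, s] = not_aa
            else:
                mask = affected[:, s] & (g[:, s] < 2)
                probs[mask, s] = not_bb
    elif isinstance(scheme, DosageNoise):
        c = scheme.concentration
        if not 0 <= c <= 1:
            raise ValueError("concentration must be in [0, 1]")
        probs[:] = (1 - c) * probs + c * MISSING_TRIPLE
    else:
        raise ValueError(f"unknown fuzzification scheme {scheme!r}")
    return DoseProbTable(probs, table.individual_ids, table.snp_ids)


def simulate(spec: SimulationSpec):
    """Run a spec end to end.

    Returns the crisp genotype matrix when no fuzzification is requested,
    otherwise ``(genotypes, dose_table)``.  The fuzzification stream is
    seeded from ``spec.seed + 1`` so crisp draws are unchanged by the scheme.
    """
    g = simulate_population(spec)
    if spec.fuzz_scheme is None:
        return g
    return g, fuzzify(g, spec.fuzz_scheme, seed=spec.seed + 1)


def linkage_equilibrium_freqs(mafs) -> np.ndarray:
    """Haplotype frequencies under linkage equilibrium for given allele
    frequencies (SNP 1 leftmost)."""
    f = np.asarray(mafs, dtype=float)
    H = haplotype_matrix(f.size)
    return np.exp(H @ np.log(f) + (1 - H) @ np.log1p(-f))


def correlated_hap_freqs(
    n_snps: int,
    major_haplotypes: Optional[Sequence[int]] = None,
    major_weight: float = 0.6,
    maf: float = 0.3,
) -> np.ndarray:
    """A haplotype pool with moderate linkage disequilibrium.

    A few "major" haplotypes share ``major_weight`` of the mass with
    descending weights (creating LD blocks) on top of a linkage-equilibrium
    background at allele frequency ``maf``.  The weights are deliberately
    unequal so the construction produces disequilibrium even when the major
    set spans all haplotypes of a short panel.
    """
    n_hap = 2**n_snps
    if major_haplotypes is None:
        all_ones = n_hap - 1
        half = all_ones >> (n_snps // 2)          # e.g. 00111 for n=5
        major_haplotypes = list(dict.fromkeys([0, all_ones, half, all_ones ^ half]))
    k = len(major_haplotypes)
    weights = np.arange(k, 0, -1, dtype=float)
    weights *= major_weight / weights.sum()
    base = linkage_equilibrium_freqs(np.full(n_snps, maf))
    p = (1.0 - major_weight) * base
    for h, w in zip(major_haplotypes, weights):
        p[h] += w
    return p / p.sum()
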