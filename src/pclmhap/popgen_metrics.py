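"""Hardy-Weinberg checks and pairwise linkage disequilibrium.

HWE testing is haplotype estimation with a single SNP (no penalty needed);
pairwise LD comes from two-SNP penalized fits, which makes the measures
available for fuzzy marker data as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .estimator import PCLMHaplotypeEstimator
from .variants import DoseProbTable

logger = logging.getLogger(__name__)


class HWEResult(NamedTuple):
    p_allele: float
    chi2: float
    p_value: float


def hwe_check(counts) -> HWEResult:
    """One-SNP Hardy-Weinberg test from genotype counts ``(n0, n1, n2)``.

    The allele frequency is the gene-counting estimate
    ``f = (n1 + 2 n2) / 2N``; the statistic is the 1-df chi-square of the
    observed counts against ``N * ((1-f)^2, 2 f (1-f), f^2)``.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,) or np.any(c < 0) or c.sum() <= 0:
        raise ValueError("counts must be three nonnegative values with a positive sum")
    N = c.sum()
    f = (c[1] + 2 * c[2]) / (2 * N)
    if f <= 0 or f >= 1:
        warnings.warn("monomorphic SNP: HWE test is vacuous", RuntimeWarning, stacklevel=2)
        return HWEResult(float(f), 0.0, 1.0)
    expected = N * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
    stat = float(((c - expected) ** 2 / expected).sum())
    return HWEResult(float(f), stat, float(chi2_dist.sf(stat, df=1)))


@dataclass
class LDMatrix:
    """Pairwise D' and r2 over a marker panel (symmetric, unit diagonal)."""

    snp_ids: Sequence[str]
    d_prime: np.ndarray
    r2: np.ndarray

    def to_frame(self, measure: str = "r2") -> pd.DataFrame:
        m = {"r2": self.r2, "dprime": self.d_prime}[measure]
        return pd.DataFrame(m, index=list(self.snp_ids), columns=list(self.snp_ids))

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.snp_ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    dict(
                        snp_i=self.snp_ids[i],
                        snp_j=self.snp_ids[j],
                        d_prime=self.d_prime[i, j],
                        r2=self.r2[i, j],
                    )
                )
        return pd.DataFrame(rows)


def ld_from_hap_freqs(p: np.ndarray) -> tuple[float, float]:
    """D' and r2 from two-locus haplotype frequencies ``(p00, p01, p10, p11)``.

    ``p11`` is the haplotype carrying the coded allele at both loci.  Both
    measures are invariant to which allele is labeled minor.
    """
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    pA = p[2] + p[3]
    pB = p[1] + p[3]
    if min(pA, 1 - pA, pB, 1 - pB) <= 1e-12:
        warnings.warn("degenerate marginal allele frequency; LD set to 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 0.0
    D = p[3] - pA * pB
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r2 = D**2 / (pA * (1 - pA) * pB * (1 - pB))
    eps = 1e-12
    return float(np.clip(d_prime, 0.0, 1.0 + eps).clip(max=1.0)), float(
        np.clip(r2, 0.0, 1.0 + eps).clip(max=1.0)
    )


def pairwise_ld(
    data: Union[np.ndarray, DoseProbTable],
    lam: Union[float, str] = 1e-3,
    snp_ids: Optional[Sequence[str]] = None,
) -> LDMatrix:
    """Pairwise D'/r2 matrices from two-SNP penalized haplotype fits.

    ``lam`` is a fixed small penalty by default (the penalty plays a minor
    role for two markers); pass ``"aic"`` for a per-pair AIC search.
    """
    fuzzy = isinstance(data, DoseProbTable)
    n = data.n_snps if fuzzy else np.asarray(data).shape[1]
    if n < 2:
        raise ValueError("pairwise LD needs at least two markers")
    if snp_ids is None:
        snp_ids = list(data.snp_ids) if fuzzy else [f"snp{s}" for s in range(n)]

    d_prime = np.eye(n)
    r2 = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if fuzzy:
                sub = data.subset_snps([i, j])
            else:
                sub = np.asarray(data)[:, [i, j]]
            est = PCLMHaplotypeEstimator(lam=lam)
            try:
                est.fit(sub)
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("LD fit failed for pair (%s, %s): %s",
                               snp_ids[i], snp_ids[j], exc)
                d_prime[i, j] = d_prime[j, i] = np.nan
                r2[i, j] = r2[j, i] = np.nan
                continue
            dp, rr = ld_from_hap_freqs(est.haplotype_probs_)
            d_prime[i, j] = d_prime[j, i] = dp
            r2[i, j] = r2[j, i] = rr
    return LDMatrix(snp_ids=snp_ids, d_prime=d_prime, r2=r2)
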