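"""Gene-counting EM estimator of haplotype frequencies from crisp genotypes.

The classical two-step iteration: the E-step distributes each genotype's
count over its compatible diplotypes in proportion to the current diplotype
probabilities ``q_j = p_k * p_l``; the M-step sets ``p`` proportional to the
expected haplotype counts.  Unlike the penalized composite link model, EM
estimates can sit exactly on the boundary (zero probability), which is the
behavior the ridge penalty is designed to avoid — this module exists as an
independent reference and baseline, and deliberately leaves zeros at zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from .model_matrices import HaploSpace


def em_haplotype_freqs(
    counts,
    space: HaploSpace,
    tol: float = 1e-10,
    max_iter: int = 5000,
    start="uniform",
    return_trace: bool = False,
):
    """Maximum-likelihood haplotype frequencies by gene counting.

    Parameters
    ----------
    counts
        Genotype counts over all ``3**n`` states.
    start
        ``"uniform"`` or an explicit probability vector of length ``2**n``.
    return_trace
        If true, also return the per-iteration log-likelihood trace.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 1 or y.size != space.n_gen:
        raise ValueError(f"counts must have length {space.n_gen}")
    if np.any(y < 0) or y.sum() <= 0:
        raise ValueError("counts must be nonnegative and not all zero")
    N = y.sum()

    C = sp.csr_matrix(space.C, dtype=float)
    M = sp.csr_matrix(space.M, dtype=float)

    if isinstance(start, str) and start == "uniform":
        p = np.full(space.n_hap, 1.0 / space.n_hap)
    else:
        p = np.asarray(start, dtype=float)
        if p.size != space.n_hap or np.any(p < 0):
            raise ValueError("start must be a probability vector of length 2**n")
        p = p / p.sum()

    trace = []
    converged = False
    for _ in range(max_iter):
        logq = M @ np.log(np.maximum(p, 1e-300))
        q = np.exp(logq)
        pi = C @ q
        obs = y > 0
        trace.append(float(y[obs] @ np.log(np.maximum(pi[obs], 1e-300))))
        ratio = np.zeros_like(pi)
        ratio[obs] = y[obs] / np.maximum(pi[obs], 1e-300)
        w = q * (C.T @ ratio)          # expected diplotype counts
        p_new = (M.T @ w) / (2.0 * N)  # each diplotype carries two haplotypes
        p_new = np.maximum(p_new, 0.0)
        p_new /= p_new.sum()
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    if not converged:
        warnings.warn(
            f"gene-counting EM did not reach tol={tol} in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_trace:
        return p, np.asarray(trace)
    return p
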