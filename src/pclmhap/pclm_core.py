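"""Penalized composite link model (PCLM) fitting for haplotype probabilities.

The model: haplotype log-probabilities ``beta`` (length ``2**n``) map to
diplotype probabilities ``gamma = exp(M_aug @ theta)`` with
``theta = (beta, kappa)``, where ``kappa`` is a scalar normalization offset
whose design column is the constant 2 (each diplotype multiplies two
haplotype probabilities, each carrying ``exp(kappa)``).  A composition matrix
turns diplotype probabilities into the probabilities of the observation units
(genotype table rows, or individuals).

All three data flavors (aggregated genotype counts, individual crisp
genotypes, fuzzy genotypes) are fitted by maximizing the same penalized
objective

    J(theta) = sum_i y_i log( (A @ gamma)_i )  -  N * sum_j gamma_j
               -  (lam / 2) * || beta - beta0 ||^2,

where ``A`` is the composite matrix of the flavor.  For aggregated counts
this is the penalized Poisson log-likelihood of the classical composite link
model up to a constant; for the individual and fuzzy flavors the
``-N * sum(gamma)`` term is the Lagrange treatment of the constraint that
diplotype probabilities sum to one (the multiplier equals the sample size).
Either way the score equation of the unpenalized offset forces
``sum(gamma) == 1`` exactly at convergence, so ``exp(beta + kappa)`` is a
proper probability vector.

Optimization is Fisher-type scoring with ridge penalty and step-halving:
a proposed update is accepted only if it increases ``J``, otherwise the step
is halved (at most 30 times), which makes the accepted trace of ``J``
monotone by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2 as _chi2  # noqa: F401  (re-export convenience)

from .model_matrices import HaploSpace, haplotype_matrix

logger = logging.getLogger(__name__)

#: Bound on the linear predictor, to keep exp() finite.
LOG_SCALE_BOUND = 30.0

#: Default grid of log10(lambda) values for AIC search.
DEFAULT_GRID_LOG10 = np.round(np.arange(-2.0, 4.0 + 1e-9, 0.2), 10)

_PRIOR_EPS = 1e-6


def linkage_equilibrium_prior(allele_freqs) -> np.ndarray:
    """Log haplotype probabilities under linkage equilibrium.

    ``exp(beta0)[h]`` is the product over SNPs of the allele frequency
    ``f_s`` where haplotype ``h`` carries the coded allele and ``1 - f_s``
    where it does not; the result sums to one by construction.  Frequencies
    are clamped to ``[1e-6, 1 - 1e-6]``; a clamped (monomorphic) frequency
    triggers a degenerate-prior warning but the fit proceeds.
    """
    f = np.asarray(allele_freqs, dtype=float)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("allele_freqs must be a non-empty 1-D vector")
    if np.any(~np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    clamped = (f < _PRIOR_EPS) | (f > 1 - _PRIOR_EPS)
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} allele frequencies at 0 or 1 were clamped to "
            f"[{_PRIOR_EPS}, {1 - _PRIOR_EPS}]; the prior is degenerate there",
            RuntimeWarning,
            stacklevel=2,
        )
    f = np.clip(f, _PRIOR_EPS, 1 - _PRIOR_EPS)
    H = haplotype_matrix(f.size)
    beta0 = H @ np.log(f) + (1 - H) @ np.log1p(-f)
    return beta0


@dataclass
class PCLMProblem:
    """One PCLM fitting problem.

    ``comp`` maps diplotypes to observation units: the full composition
    matrix ``C`` (aggregated counts), the per-individual matrix ``C-breve``
    (crisp individuals) or ``F @ C`` (fuzzy individuals).  ``full_comp``
    always maps to the complete genotype table and is used for the effective
    dimension, standard errors and (when counts exist) the deviance.
    """

    mating: sp.spmatrix            # (n_dip, n_hap)
    comp: sp.spmatrix              # (n_obs, n_dip)
    full_comp: sp.spmatrix         # (n_gen_like, n_dip)
    response: np.ndarray           # counts (aggregated) or ones (individual/fuzzy)
    n_total: int                   # N, number of individuals
    beta0: np.ndarray              # log prior haplotype probabilities
    lam: float
    kind: str = "aggregated"       # aggregated | individual | fuzzy
    full_counts: Optional[np.ndarray] = None  # counts on full_comp rows, if crisp
    space: Optional[HaploSpace] = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)
        if self.kind not in ("aggregated", "individual", "fuzzy"):
            raise ValueError(f"unknown problem kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("penalty weight lam must be nonnegative")
        if np.any(self.response < 0):
            raise ValueError("response entries must be nonnegative")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        total = abs(np.exp(self.beta0).sum() - 1.0)
        if total > 1e-6:
            raise ValueError("exp(beta0) must sum to 1")
        if self.kind == "aggregated":
            if abs(self.response.sum() - self.n_total) > 1e-8:
                raise ValueError("aggregated counts must sum to n_total")
            if self.full_counts is None:
                self.full_counts = self.response

    @property
    def n_hap(self) -> int:
        return self.mating.shape[1]


@dataclass
class PCLMFit:
    """Fitted PCLM state."""

    beta: np.ndarray
    kappa: float
    p_hat: np.ndarray
    q_hat: np.ndarray
    mu: np.ndarray
    se_p: np.ndarray
    ed: float
    deviance: float
    aic: float
    loglik: float                   # penalized objective at convergence
    data_loglik: float              # sum_i y_i log pi_i (unpenalized)
    lam: float
    converged: bool
    n_iter: int
    n_halvings: int
    objective_trace: np.ndarray = field(repr=False, default=None)


def _augmented_mating(M: sp.spmatrix) -> sp.csr_matrix:
    offset_col = np.full((M.shape[0], 1), 2.0)
    return sp.hstack([sp.csr_matrix(M, dtype=float), sp.csr_matrix(offset_col)]).tocsr()


def _objective(theta, M_aug, comp, y, obs, n_total, lam, beta0):
    eta = M_aug @ theta
    gamma = np.exp(np.clip(eta, -LOG_SCALE_BOUND, LOG_SCALE_BOUND))
    u = comp @ gamma
    if np.any(u[obs] <= 0):
        return -np.inf, gamma, u
    beta = theta[:-1]
    val = (
        float(y[obs] @ np.log(u[obs]))
        - n_total * gamma.sum()
        - 0.5 * lam * float((beta - beta0) @ (beta - beta0))
    )
    return val, gamma, u


def fit_pclm(
    problem: PCLMProblem,
    theta_init: Optional[np.ndarray] = None,
    tol_beta: float = 1e-8,
    tol_obj: float = 1e-10,
    max_iter: int = 200,
    max_halvings: int = 30,
    se_method: str = "inverse",
) -> PCLMFit:
    """Fit a PCLM problem by penalized scoring with step-halving.

    Parameters
    ----------
    theta_init
        Optional start ``(beta, kappa)``; defaults to ``(beta0, 0)``, the
        linkage-equilibrium start recommended for this model.
    se_method
        ``"inverse"`` (plain inverse penalized information, default) or
        ``"sandwich"``.
    """
    M_aug = _augmented_mating(problem.mating)
    comp = sp.csr_matrix(problem.comp, dtype=float)
    full = sp.csr_matrix(problem.full_comp, dtype=float)
    y = problem.response
    obs = y > 0
    n_hap = problem.n_hap
    lam = float(problem.lam)
    if lam == 0.0:
        logger.warning(
            "fitting with lam=0: the unpenalized problem may be ill-conditioned; "
            "relying on iteration caps and minimum-norm steps"
        )
    beta0 = problem.beta0
    n_total = float(problem.n_total)

    theta = (
        np.concatenate([beta0, [0.0]])
        if theta_init is None
        else np.asarray(theta_init, dtype=float).copy()
    )
    pen_diag = np.concatenate([np.full(n_hap, lam), [0.0]])

    J, gamma, u = _objective(theta, M_aug, comp, y, obs, n_total, lam, beta0)
    if not np.isfinite(J):
        raise FloatingPointError("objective is -inf at the starting values")

    trace = [J]
    converged = False
    total_halvings = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ratio = np.zeros_like(y)
        ratio[obs] = y[obs] / u[obs]
        t = comp.T @ ratio
        grad = M_aug.T @ (gamma * (t - n_total))
        grad[:n_hap] -= lam * (theta[:n_hap] - beta0)

        # scoring matrix: expected information on the full genotype table.
        # For aggregated counts this is the usual Poisson scoring matrix; for
        # the individual/fuzzy flavors it is an upper bound on the curvature
        # (fuzzy observations carry less information than the full table),
        # which keeps steps conservative while the step-halving guard keeps
        # the accepted objective trace monotone.  The fixed point depends
        # only on the gradient.
        B_full = full @ sp.diags(gamma) @ M_aug
        pi_full = np.maximum(full @ gamma, 1e-300)
        S = n_total * (B_full.T @ sp.diags(1.0 / pi_full) @ B_full).toarray()
        A = S + np.diag(pen_diag)
        try:
            direction = np.linalg.solve(A, grad)
        except np.linalg.LinAlgError:
            direction = np.linalg.lstsq(A, grad, rcond=None)[0]
        if lam == 0.0 and not np.all(np.isfinite(direction)):
            direction = np.linalg.lstsq(A, grad, rcond=None)[0]

        step = 1.0
        halvings = 0
        while True:
            theta_new = theta + step * direction
            J_new, gamma_new, u_new = _objective(
                theta_new, M_aug, comp, y, obs, n_total, lam, beta0
            )
            if J_new >= J or halvings >= max_halvings:
                break
            step /= 2.0
            halvings += 1
        total_halvings += halvings

        if J_new < J:
            # even the fully halved step decreases the objective: stop here
            converged = abs(J_new - J) < tol_obj
            break

        delta_beta = np.max(np.abs(theta_new[:n_hap] - theta[:n_hap]))
        delta_obj = J_new - J
        theta, J, gamma, u = theta_new, J_new, gamma_new, u_new
        trace.append(J)
        if delta_beta < tol_beta or delta_obj < tol_obj:
            converged = True
            break

    if not converged:
        logger.warning(
            "PCLM fit did not converge in %d iterations (lam=%.3g)", n_iter, lam
        )

    beta = theta[:n_hap]
    kappa = float(theta[n_hap])
    if np.any(np.abs(beta) >= LOG_SCALE_BOUND - 1e-9):
        logger.warning("some log-scale parameters hit the +/-%.0f bound", LOG_SCALE_BOUND)

    p_raw = np.exp(np.clip(beta + kappa, -LOG_SCALE_BOUND, LOG_SCALE_BOUND))
    p_hat = p_raw / p_raw.sum()
    q_hat = gamma / gamma.sum()

    pi = u / gamma.sum()
    if problem.kind == "aggregated":
        mu = n_total * pi
    else:
        mu = pi

    info, pen = _penalized_information(problem, gamma, M_aug)
    ed = _effective_dimension_from_info(info, pen)
    se_p = _standard_errors_from_info(info, pen, p_hat, method=se_method)
    deviance = _deviance(problem, gamma, pi, y, obs)
    aic_val = deviance + 2.0 * ed
    data_loglik = float(y[obs] @ np.log(pi[obs]))

    return PCLMFit(
        beta=beta,
        kappa=kappa,
        p_hat=p_hat,
        q_hat=q_hat,
        mu=mu,
        se_p=se_p,
        ed=ed,
        deviance=deviance,
        aic=aic_val,
        loglik=J,
        data_loglik=data_loglik,
        lam=lam,
        converged=converged,
        n_iter=n_iter,
        n_halvings=total_halvings,
        objective_trace=np.asarray(trace),
    )


def _penalized_information(problem: PCLMProblem, gamma, M_aug):
    """Expected information on the full genotype table plus the penalty.

    For the individual/fuzzy flavors the diplotype probabilities are mapped
    back to the complete genotype table (``pi = C @ gamma``) before forming
    the information, so diagnostics are comparable across flavors.
    """
    full = sp.csr_matrix(problem.full_comp, dtype=float)
    pi = full @ gamma
    pi = np.maximum(pi, 1e-300)
    B = full @ sp.diags(gamma) @ M_aug
    info = float(problem.n_total) * (B.T @ sp.diags(1.0 / pi) @ B).toarray()
    n_hap = problem.n_hap
    pen = np.diag(np.concatenate([np.full(n_hap, problem.lam), [0.0]]))
    return info, pen


def _solve_or_pinv(A, B):
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        warnings.warn(
            "penalized information is singular; using a pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(A) @ B


def _effective_dimension_from_info(info, pen) -> float:
    hat = _solve_or_pinv(info + pen, info)
    # subtract the unpenalized normalization offset's degree of freedom so
    # that the reported dimension counts haplotype parameters only
    return float(max(np.trace(hat) - 1.0, 0.0))


def _standard_errors_from_info(info, pen, p_hat, method="inverse") -> np.ndarray:
    n_hap = p_hat.size
    inv = _solve_or_pinv(info + pen, np.eye(info.shape[0]))
    if method == "inverse":
        cov = inv
    elif method == "sandwich":
        cov = inv @ info @ inv
    else:
        raise ValueError(f"unknown se_method {method!r}")
    # delta method for the reported (normalized) probabilities:
    # log p_h - log sum(p) has gradient e_h - p w.r.t. beta and none w.r.t.
    # kappa, so var(log p_h) = cov_hh - 2 (cov p)_h + p' cov p.  The
    # centering removes the variance of the unpenalized translation
    # direction (beta + c, kappa - c), which leaves the output unchanged.
    cov_bb = cov[:n_hap, :n_hap]
    cp = cov_bb @ p_hat
    var_log_p = np.diag(cov_bb) - 2.0 * cp + float(p_hat @ cp)
    return p_hat * np.sqrt(np.clip(var_log_p, 0.0, None))


def _deviance(problem: PCLMProblem, gamma, pi_obs, y, obs) -> float:
    """Deviance on the full genotype table (crisp) or vs. the saturated
    individual likelihood (fuzzy)."""
    if problem.full_counts is not None:
        full = sp.csr_matrix(problem.full_comp, dtype=float)
        mu_full = problem.n_total * (full @ gamma) / gamma.sum()
        yf = np.asarray(problem.full_counts, dtype=float)
        pos = yf > 0
        dev = 2.0 * float(
            (yf[pos] * np.log(yf[pos] / mu_full[pos]) - (yf[pos] - mu_full[pos])).sum()
            + mu_full[~pos].sum()
        )
        return max(dev, 0.0)
    # fuzzy: saturated model assigns probability 1 to each observation
    return max(-2.0 * float(y[obs] @ np.log(pi_obs[obs])), 0.0)


def effective_dimension(fit: PCLMFit, problem: PCLMProblem) -> float:
    """Effective model dimension (hat-matrix trace) at the fitted state."""
    M_aug = _augmented_mating(problem.mating)
    gamma = np.exp(np.clip(M_aug @ np.concatenate([fit.beta, [fit.kappa]]),
                           -LOG_SCALE_BOUND, LOG_SCALE_BOUND))
    info, pen = _penalized_information(problem, gamma, M_aug)
    return _effective_dimension_from_info(info, pen)


def standard_errors(fit: PCLMFit, problem: PCLMProblem, method: str = "inverse") -> np.ndarray:
    """Standard errors of the haplotype probabilities (delta method)."""
    M_aug = _augmented_mating(problem.mating)
    gamma = np.exp(np.clip(M_aug @ np.concatenate([fit.beta, [fit.kappa]]),
                           -LOG_SCALE_BOUND, LOG_SCALE_BOUND))
    info, pen = _penalized_information(problem, gamma, M_aug)
    return _standard_errors_from_info(info, pen, fit.p_hat, method=method)


def aic(fit: PCLMFit) -> float:
    """Akaike information criterion, deviance + 2 * effective dimension."""
    return fit.deviance + 2.0 * fit.ed


def select_lambda(
    problem: PCLMProblem,
    grid_log10=None,
    warm_start: bool = True,
    **fit_kwargs,
):
    """Profile the penalty weight over a log10 grid and pick the AIC minimum.

    Fits are warm-started from the previous grid point (ascending lambda).
    Ties are broken toward the larger lambda, i.e. more shrinkage.

    Returns ``(lambda_star, profile, fits)`` where ``profile`` is a DataFrame
    with columns lambda, log10_lambda, aic, ed, deviance, converged.
    """
    grid = DEFAULT_GRID_LOG10 if grid_log10 is None else np.asarray(grid_log10, float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")

    rows = []
    fits = []
    theta = None
    for lg in grid:
        lam = 10.0**lg
        prob = PCLMProblem(
            mating=problem.mating,
            comp=problem.comp,
            full_comp=problem.full_comp,
            response=problem.response,
            n_total=problem.n_total,
            beta0=problem.beta0,
            lam=lam,
            kind=problem.kind,
            full_counts=problem.full_counts,
            space=problem.space,
        )
        try:
            fit = fit_pclm(prob, theta_init=theta if warm_start else None, **fit_kwargs)
        except FloatingPointError as exc:  # pragma: no cover - defensive
            warnings.warn(f"fit failed at log10(lambda)={lg}: {exc}", RuntimeWarning)
            continue
        fits.append((lam, fit))
        rows.append(
            dict(
                lam=lam,
                log10_lambda=lg,
                aic=fit.aic,
                ed=fit.ed,
                deviance=fit.deviance,
                converged=fit.converged,
            )
        )
        if warm_start:
            theta = np.concatenate([fit.beta, [fit.kappa]])
    if not rows:
        raise RuntimeError("every fit on the lambda grid failed")
    profile = pd.DataFrame(rows)
    aics = profile["aic"].to_numpy()
    best = len(aics) - 1 - int(np.argmin(aics[::-1]))  # ties -> larger lambda
    return float(profile["lam"].iloc[best]), profile, fits
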