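"""Scikit-learn-style front end for penalized composite link haplotype fits.

``PCLMHaplotypeEstimator`` accepts either a crisp genotype matrix (doses
0/1/2, ``NaN`` for missing) or a :class:`~pclmhap.variants.DoseProbTable`
of fuzzy calls, dispatches to the appropriate problem flavor, optionally
selects the penalty weight by AIC, and exposes the fitted haplotype
probabilities with standard errors.  It follows the usual estimator
conventions (``get_params``/``set_params``, fitted attributes with a
trailing underscore), so it composes with sklearn pipelines and ``clone``.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import pclm_core
from .model_matrices import MAX_SNPS, haplo_space
from .pclm_core import fit_pclm, linkage_equilibrium_prior, select_lambda
from .variants import (
    DoseProbTable,
    build_aggregated_problem,
    build_fuzzy_problem,
    build_individual_problem,
)

logger = logging.getLogger(__name__)


def _expected_allele_freqs(X) -> np.ndarray:
    """Per-SNP coded-allele frequency: mean expected dose / 2."""
    if isinstance(X, DoseProbTable):
        doses = X.probs @ np.array([0.0, 1.0, 2.0])
        return doses.mean(axis=0) / 2.0
    g = np.asarray(X, dtype=float)
    return np.nanmean(g, axis=0) / 2.0


class PCLMHaplotypeEstimator(BaseEstimator):
    """Haplotype frequency estimation by penalized composite link model.

    Parameters
    ----------
    lam : float or "aic", default "aic"
        Ridge penalty weight toward the prior; ``"aic"`` profiles
        ``grid_log10`` and keeps the AIC minimizer.
    grid_log10 : sequence of float, optional
        log10 penalty grid for AIC search (default -2 to 4 in steps of 0.2).
    prior : "linkage-equilibrium", "uniform" or array, default "linkage-equilibrium"
        Penalty target and starting point.  The default estimates per-SNP
        allele frequencies from the data and takes their product, i.e. no
        linkage disequilibrium a priori.  An explicit array gives prior
        haplotype probabilities (length ``2**n``).
    variant : "auto", "aggregated", "individual" or "fuzzy", default "auto"
        Problem flavor; ``"auto"`` aggregates crisp matrices and routes any
        uncertainty (NaN entries or a dose table) to the fuzzy path.
    multi_start : int, default 0
        Extra fits from random perturbations of the prior start, for
        local-maximum diagnostics; the best penalized objective wins.
    se_method : "inverse" or "sandwich", default "inverse"
        Variance approximation: plain inverse penalized information or the
        sandwich form.

    Attributes
    ----------
    haplotype_probs_ : ndarray of shape (2**n,)
        Estimated haplotype probabilities (sum to 1).
    haplotypes_ : list of str
        Bit-string labels, SNP 1 leftmost.
    se_ : ndarray
        Delta-method standard errors of the probabilities.
    lambda_ : float
        Penalty weight actually used.
    profile_ : DataFrame or None
        (lambda, AIC, ED, deviance) profile when ``lam="aic"``.
    aic_, ed_, deviance_, converged_, n_iter_ : fit diagnostics.
    """

    def __init__(
        self,
        lam="aic",
        grid_log10=None,
        prior="linkage-equilibrium",
        variant: str = "auto",
        max_snps: int = MAX_SNPS,
        tol: float = 1e-8,
        max_iter: int = 200,
        se_method: str = "inverse",
        multi_start: int = 0,
        random_state: Optional[int] = None,
    ):
        self.lam = lam
        self.grid_log10 = grid_log10
        self.prior = prior
        self.variant = variant
        self.max_snps = max_snps
        self.tol = tol
        self.max_iter = max_iter
        self.se_method = se_method
        self.multi_start = multi_start
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _resolve_variant(self, X) -> str:
        if self.variant != "auto":
            return self.variant
        if isinstance(X, DoseProbTable):
            return "fuzzy"
        g = np.asarray(X, dtype=float)
        if np.isnan(g).any():
            logger.info("missing genotype entries found; using the fuzzy path")
            return "fuzzy"
        return "aggregated"

    def _prior_beta0(self, X, n_snps: int) -> np.ndarray:
        if isinstance(self.prior, str):
            if self.prior in ("linkage-equilibrium", "le"):
                return linkage_equilibrium_prior(_expected_allele_freqs(X))
            if self.prior == "uniform":
                return np.full(2**n_snps, -n_snps * np.log(2.0))
            raise ValueError(f"unknown prior {self.prior!r}")
        p0 = np.asarray(self.prior, dtype=float)
        if p0.size != 2**n_snps or np.any(p0 <= 0):
            raise ValueError("explicit prior must be positive with length 2**n")
        return np.log(p0 / p0.sum())

    def _build_problem(self, X, variant: str, beta0, lam: float):
        if variant == "fuzzy":
            table = X if isinstance(X, DoseProbTable) else DoseProbTable.from_crisp(X)
            return build_fuzzy_problem(table, beta0, lam)
        g = np.asarray(X)
        space = haplo_space(g.shape[1], self.max_snps)
        if variant == "aggregated":
            from .variants import aggregate_genotypes

            return build_aggregated_problem(aggregate_genotypes(g, space), beta0, lam, space)
        if variant == "individual":
            return build_individual_problem(g, beta0, lam, space)
        raise ValueError(f"unknown variant {variant!r}")

    def _fit_one(self, problem, theta_init=None):
        kwargs = dict(
            tol_beta=self.tol,
            max_iter=self.max_iter,
            se_method=self.se_method,
        )
        fit = fit_pclm(problem, theta_init=theta_init, **kwargs)
        if self.multi_start:
            rng = np.random.default_rng(self.random_state)
            for _ in range(int(self.multi_start)):
                start = np.concatenate(
                    [problem.beta0 + rng.normal(scale=0.5, size=problem.n_hap), [0.0]]
                )
                alt = fit_pclm(problem, theta_init=start, **kwargs)
                if alt.loglik > fit.loglik + 1e-8:
                    logger.warning(
                        "multi-start found a higher penalized likelihood "
                        "(%.6g > %.6g): likelihood is multimodal",
                        alt.loglik,
                        fit.loglik,
                    )
                    fit = alt
        return fit

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Fit haplotype probabilities to genotype data ``X``."""
        if isinstance(X, DoseProbTable):
            n_snps = X.n_snps
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[0] < 1:
                raise ValueError("X must be a 2-D genotype matrix")
            n_snps = X.shape[1]
        space = haplo_space(n_snps, self.max_snps)
        variant = self._resolve_variant(X)
        beta0 = self._prior_beta0(X, n_snps)

        if isinstance(self.lam, str) and self.lam == "aic":
            problem = self._build_problem(X, variant, beta0, 1.0)
            lam_star, profile, fits = select_lambda(
                problem,
                grid_log10=self.grid_log10,
                tol_beta=self.tol,
                max_iter=self.max_iter,
                se_method=self.se_method,
            )
            self.profile_ = profile
            fit = dict(fits)[lam_star]
            lam = lam_star
        else:
            lam = float(self.lam)
            problem = self._build_problem(X, variant, beta0, lam)
            fit = self._fit_one(problem)
            self.profile_ = None

        self.space_ = space
        self.variant_ = variant
        self.n_snps_ = n_snps
        self.n_individuals_ = int(problem.n_total)
        self.prior_probs_ = np.exp(beta0)
        self.lambda_ = lam
        self.fit_result_ = fit
        self.problem_ = problem
        self.haplotypes_ = space.haplotype_labels()
        self.haplotype_probs_ = fit.p_hat
        self.diplotype_probs_ = fit.q_hat
        self.se_ = fit.se_p
        self.beta_ = fit.beta
        self.kappa_ = fit.kappa
        self.aic_ = fit.aic
        self.ed_ = fit.ed
        self.deviance_ = fit.deviance
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        return self

    def genotype_probs(self) -> np.ndarray:
        """Fitted probabilities of all ``3**n`` genotype states."""
        self._check_fitted()
        return np.asarray(self.space_.C @ self.diplotype_probs_).ravel()

    def score(self, X, y=None) -> float:
        """Mean log-probability of the genotypes in ``X`` under the fit."""
        self._check_fitted()
        table = X if isinstance(X, DoseProbTable) else DoseProbTable.from_crisp(X)
        from .variants import confusion_rows

        F = confusion_rows(table)
        pi = F @ self.genotype_probs()
        return float(np.mean(np.log(np.maximum(pi, 1e-300))))

    def _check_fitted(self) -> None:
        if not hasattr(self, "haplotype_probs_"):
            raise RuntimeError("estimator is not fitted yet; call fit first")


def estimate_haplotypes(X, lam="aic", **params) -> PCLMHaplotypeEstimator:
    """Functional wrapper: fit an estimator and return it."""
    return PCLMHaplotypeEstimator(lam=lam, **params).fit(X)


def fit_genotype_counts(counts, lam: float, prior_probs=None, **fit_kwargs) -> pclm_core.PCLMFit:
    """Fit directly from an aggregated genotype-count vector.

    ``prior_probs`` defaults to linkage equilibrium at the allele
    frequencies implied by the counts themselves.
    """
    counts = np.asarray(counts, dtype=float)
    n = int(round(np.log(counts.size) / np.log(3)))
    space = haplo_space(n)
    if prior_probs is None:
        freqs = _allele_freqs_from_counts(counts, n)
        beta0 = linkage_equilibrium_prior(freqs)
    else:
        p0 = np.asarray(prior_probs, dtype=float)
        beta0 = np.log(p0 / p0.sum())
    problem = build_aggregated_problem(counts, beta0, lam, space)
    return fit_pclm(problem, **fit_kwargs)


def _allele_freqs_from_counts(counts: np.ndarray, n_snps: int) -> np.ndarray:
    """Coded-allele frequencies from an aggregated genotype-count vector."""
    idx = np.arange(counts.size)
    freqs = np.empty(n_snps)
    N = counts.sum()
    for s in range(n_snps):
        dose = (idx // 3 ** (n_snps - 1 - s)) % 3
        freqs[s] = float(counts @ dose) / (2.0 * N)
    return freqs
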