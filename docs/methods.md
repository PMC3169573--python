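# Methods

## Model

For `n` biallelic SNPs the haplotype space has `2^n` elements, coded as
binary vectors with SNP 1 the most significant digit; ordered haplotype
pairs (diplotypes) number `4^n`, unphased genotypes `3^n` (ternary dose
vectors, same digit order).  Two sparse structure matrices carry the whole
model: the mating matrix `M` (`4^n × 2^n`, row sums 2) with
`q = exp(M β)` giving diplotype probabilities under random mating for
haplotype log-probabilities `β`, and the 0/1 composition matrix `C`
(`3^n × 4^n`, one 1 per column) with `π = C q` the genotype probabilities.
Assumptions inherited from this construction: random mating (diplotype
probability is the product of its haplotype probabilities), diploidy,
biallelic markers, and independence of individuals.

### One objective for three data flavors

All flavors maximize

    J(θ) = Σ_i y_i log( (A γ)_i ) − N Σ_j γ_j − (λ/2) ‖β − β₀‖²,

with `γ = exp(M_aug θ)`, `θ = (β, κ)`, and `M_aug = [M | 2]` — the extra
unpenalized column is the normalization offset `κ`; every diplotype
probability carries `e^{2κ}` because it multiplies two haplotype terms.

* aggregated counts: `A = C`, `y` the `3^n` genotype counts.  `J` is then
  the penalized Poisson log-likelihood of the counts with mean `N·Cγ`, up
  to a data-only constant.
* crisp individuals: `A = C̆` (one `C` row per individual), `y = 1`.  The
  `−N Σ γ` term is the Lagrange treatment of the constraint `Σγ = 1`; the
  multiplier equals the sample size, which makes the two flavors exactly
  equivalent on crisp data (verified to 1e−9 in the tests).
* fuzzy individuals: `A = F C`, where row `i` of the confusion matrix `F`
  is the Kronecker product (SNP 1 outermost) of that individual's per-SNP
  dose-probability triples.  A missing SNP is the uniform triple
  (1/3, 1/3, 1/3) — row normalization only rescales a constant per
  individual and cannot move the maximizer, and normalized rows keep the
  genotype-probability interpretation.  A dominant AFLP "not AA" call is
  (0, w, 1−w) with w = 1/2 by default; the within-class split is not
  identified by the data system itself, and a Hardy–Weinberg-weighted
  alternative can be supplied by building the triples explicitly.

The score equation of the unpenalized offset forces `Σγ = 1` exactly at
any stationary point, so `p = exp(β + κ)` is a probability vector; the
reported estimates are renormalized to sum to one exactly to guard
last-digit drift.

### Why the penalty

The unpenalized scoring equations are ill-conditioned for more than a few
SNPs, and maximum-likelihood (EM) estimates put exact zeros on haplotypes
the data happen not to demand, equating unobserved with impossible.  The
ridge toward the linkage-equilibrium distribution `exp(β₀)` (product of
estimated marginal allele frequencies, clamped to [1e−6, 1−1e−6]) fixes
both: estimates are strictly positive for any λ > 0 and shrink toward
"no LD" as λ grows.  The penalty acts on the log-probability scale because
β is the linear-predictor coefficient vector of the composite link model.

## Fitting algorithm

Fisher-type scoring with a step-halving guard:

1. gradient `g = M_augᵀ diag(γ)(Aᵀ(y/u) − N·1) − λ(β − β₀)` with `u = Aγ`;
2. scoring matrix `S + P` where `S = N · B_fᵀ diag(1/π_f) B_f` is the
   expected information mapped to the **full** genotype table
   (`B_f = C_f diag(γ) M_aug`, `π_f = C_f γ`) and `P = diag(λ…λ, 0)`.  For
   aggregated counts this is the standard Poisson scoring matrix; for the
   individual/fuzzy flavors it upper-bounds the true curvature (uncertain
   observations carry less information than the full table), which keeps
   steps conservative while changing nothing about the fixed point —
   convergence is determined by the gradient alone;
3. a proposed step is accepted only if it increases `J`, otherwise halved
   (at most 30 times), so the accepted objective trace is monotone by
   construction;
4. convergence when `max|Δβ| < 1e−8` or `ΔJ < 1e−10`; at most 200
   iterations; non-convergence is flagged on the returned fit, never
   raised.

The linear predictor is clipped at ±30 to keep `exp` finite (clips are
logged).  `λ = 0` is allowed but logged as a warning; singular systems fall
back to minimum-norm/pseudo-inverse solves with a warning.  The fit starts
from `θ = (β₀, 0)`; by default no multi-start search is performed — the
likelihood can be multimodal in principle, and the package's policy is to
start from linkage equilibrium and accept the result, with an optional
`multi_start=k` diagnostic that refits from random perturbations and
reports if a higher mode is found.

## Diagnostics

* **Effective dimension.**  `ED = trace[(QᵀW⁻¹Q + P)⁻¹ QᵀW⁻¹Q] − 1`
  evaluated on the full genotype table (`Q = N C_f diag(γ) M_aug`,
  `W = diag(N π_f)`), the hat-matrix trace familiar from generalized
  additive models.  The constant −1 removes the always-unpenalized
  offset's degree of freedom so that ED counts haplotype parameters: it
  runs from `2^n − 1` (no penalty; one dof lost to normalization) down to
  0 (estimates pinned to the prior).  The shift leaves every AIC
  comparison unchanged.  Individual and fuzzy fits are mapped back to the
  full table before this computation, so diagnostics are comparable across
  flavors.
* **AIC.**  `deviance + 2·ED`.  For crisp data the deviance is the Poisson
  deviance of the full genotype-count table; for truly fuzzy data it is
  `−2 Σ_i log π_i` against the saturated per-individual likelihood
  (`π_i = 1`), which makes the two definitions agree on crisp data and
  share the argmin with `−2·loglik + 2·ED` always.
* **λ selection.**  The profile runs over `log10 λ ∈ [−2, 4]` in steps of
  0.2 by default, warm-starting each fit from the previous solution (a
  cold-start equivalence test guards against path dependence).  Ties break
  toward more shrinkage.
* **Standard errors.**  Covariance of `θ̂` taken as the inverse penalized
  information `(QᵀW⁻¹Q + P)⁻¹` (a sandwich form is available via
  `se_method="sandwich"`).  The reported probabilities are normalized, so
  the delta method uses the gradient of `log(p_h/Σp)`:
  `var(log p̃_h) = (e_h − p)ᵀ Cov_ββ (e_h − p)`, and `se(p̃_h) = p̃_h ·
  sqrt(var(log p̃_h))`.  The centering is essential: it annihilates the
  unpenalized translation direction `(β + c, κ − c)`, which does not move
  the output.  With this convention the errors reproduce the multinomial
  `sqrt(p(1−p)/2N)` scale at small λ and vanish as λ → ∞.

## Hardy–Weinberg and LD

HWE testing is the one-SNP case: gene-counting allele frequency and a 1-df
chi-square against `N(p², 2pq, q²)`; monomorphic markers return p-value 1
with a warning (the asymptotic test only — no exact test).  Pairwise LD
fits every marker pair as a two-SNP model (fuzzy-aware when the input is a
dose table) and converts the four haplotype frequencies to
`D = p₁₁ − p_A p_B`, `D′ = |D|/D_max`, `r² = D²/(p_A(1−p_A)p_B(1−p_B))`;
D′ is reported as a magnitude in [0, 1], degenerate marginals give 0 with
a warning.  The default pairwise penalty is a fixed small `λ = 1e−3`
rather than a per-pair AIC search — with two markers the penalty plays a
minor role, and the fixed value keeps an `n²` scan cheap; `lam="aic"`
switches the search on.

## Partition-ligation

Panels beyond the direct cap (12 SNPs by default; the scoring system is
solved densely in `2^n + 1` parameters) are fitted in contiguous blocks
(default size 5), pruned at probability 0.01 (the kept set is renormalized
and never empty), and merged pairwise left to right (a balanced-tree order
is available).  Each merge refits the penalized model restricted to the
cartesian product of the kept haplotype lists: mating and composition
matrices are rebuilt over the candidate pairs only, the product of block
probabilities supplies the starting value, and the penalty target is the
linkage-equilibrium prior restricted to the candidates — not the product
start — so that an unpruned ligation reproduces the direct fit exactly
(verified to 1e−6).  If pruning leaves some observed genotype with no
compatible candidate pair, the likelihood is genuinely −∞ and the merge
aborts with advice to lower the threshold.

## Synthetic data

The simulator draws two independent haplotypes per individual from a
specified pool — exactly the random-mating model being fitted — and
derives crisp genotypes as dose sums.  Fuzzification schemes: `Missing`
(uniform triple at a given rate), `AflpDominant` (band-present genotypes
merged to (0, w, 1−w), direction configurable per SNP, default
band-absent = dose-0 homozygote), `DosageNoise` (mixing with the uniform).
A helper builds moderate-LD pools as a few unequally weighted major
haplotypes over a linkage-equilibrium background.  What this does **not**
emulate: recombination and coalescent genealogy, population structure or
non-random mating, genotyping error that removes the true genotype's
support, or real AFLP band-intensity distributions (the dominance scheme
is a stand-in for those).  Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
their violation.

Test and acceptance problem sizes were chosen to make sampling noise small
relative to the tolerances while keeping the default suite quick: e.g.
N = 500 for oracle comparisons, N = 2000 × 50 replicates for parameter
recovery, N = 120 at 5 SNPs for the AIC-profile shape, N = 300 × 20 paired
replicates for the fuzzy-vs-crisp contrast.

## Known limitations

* Diploid, biallelic markers only; the autotetraploid generalization is
  out of scope.
* Random mating is assumed; there is no inbreeding/assortative-mating
  component.
* The direct fit scales as `O(8^n)` memory for the structure matrices and
  `O((2^n)³)` per scoring solve; partition-ligation trades exactness for
  reach beyond ~12 SNPs.
* AIC-based λ selection targets predictive fit, not frequentist coverage;
  the reported standard errors shrink with λ and should be read as
  penalized-fit uncertainty, not unbiased sampling error.
* The likelihood can be multimodal for extreme data; the default policy
  (linkage-equilibrium start, accept the result) is deliberate, with
  multi-start as a diagnostic only.
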