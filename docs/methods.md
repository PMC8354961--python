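# Methods

## Data model and coding

Genotypes are doses of fully inbred (doubled-haploid) lines at biallelic
markers. Raw input (VCF via cyvcf2, or a plain dosage table) may contain
doses 0/1/2 and missing values; `finalize_coding` then (i) sets
heterozygous calls to missing — a DH line cannot be heterozygous, so a dose
of 1 is a genotyping artifact; (ii) imputes each missing entry to its
column's modal dose among {0, 2} (tie -> 0); (iii) flips columns whose
counted-allele frequency exceeds 0.5 so every column counts the minor
allele (an exact 0.5 tie keeps the input orientation — the kernels are
invariant to that choice). The result is deterministic and idempotent.
Mode imputation is a deliberate simplification: production pipelines
usually impute with a haplotype model, but a modal fill is reproducible
without phased reference data, and at the missingness levels the quality
filters leave behind the kernels are insensitive to the difference.

LD pruning follows the sliding-window variance-inflation-factor procedure
(window 50 SNPs, step 5, VIF threshold 2 by default): within a window of
still-retained markers the marker with the largest VIF = 1/(1 - r^2)
(r^2 from regressing it on the other retained markers in the window) is
removed greedily until all VIFs are at or below the threshold, then the
window shifts. Ties at the maximum remove the later marker. Constant
columns are excluded from the regressions and always retained. This is a
faithful greedy reimplementation of the usual tool-chain step, not a
byte-level match of any external program.

## Kernels

All three relationship matrices are VanRaden-normalized cross-products of
centered designs; each records its normalizer because the interaction
backsolve needs it.

* `Gamma_VR = (M - P)(M - P)' / (2 sum p_i(1 - p_i))`.
* `Gamma_ERR`: the categorical-epistasis design has, for every pair
  j <= k (self-pairs included), four indicator columns for the genotype
  combinations (00, 02, 20, 22); `m* = 2m(m+1)`. Column order is pinned
  (pairs j-major, combos in that fixed order) so selection ids are
  portable. Self-pair columns for the impossible combos 02/20 are
  constant-zero and provably inert — they keep their ids but contribute
  nothing.
* `Gamma_sERR`: the same construction over a selected column subset.

The full kernel is computed in closed form: each line activates exactly
one combination per pair, so the dummy cross-product between lines i and
i' equals the number of pairs on which they match, `S(S+1)/2` with `S`
the per-marker agreement count — one n x n matrix product in O(n^2 m).
Row means of the match matrix give `sum_c M*_ic p*_c` and its grand mean
gives `sum_c p*_c^2`, which yields the centered numerator and the
normalizer `m(m+1)/2 - sum_c p*_c^2` without touching any column. A
generic blockwise accumulation over pairs is kept alongside; both paths
agree with the brute-force dummy-matrix kernel to 1e-10 in the tests, and
results are independent of block size. Constant columns (p* in {0, 1})
add exact zeros to numerator and denominator, so skipping them is a pure
optimization. A selection covering all columns delegates to the full
kernel — the two are the same computation, which keeps the pi = 1
reduction bit-exact through the whole pipeline.

## Backsolving and selection

Given an ERRBLUP fit (mu, sigma2_g, sigma2_e) on the selection
environment's complete data, the n-vector
`w = (sigma2_g Gamma_ERR + sigma2_e I)^{-1}(y - 1 mu)` is formed once, and
every column effect is `t_i = (sigma2_g / D) (col_i - p*_i)' w`. For each
pair (j, k) the four combination sums collapse onto three m x m genotype
cross-products (`X'X`, `X'diag(w)X`, and column sums), so the full t-vector
streams out of two matrix products; self-pairs fall out of the same
algebra because x^2 = x for 0/1 alleles. Effect variances are
`sigma2_i = t_i^2 * 2 p*_i (1 - p*_i)` — the printed formula's matrix
notation is read per-column with scalar p*_i, matching the univariate
effect-variance convention; this is the only reading consistent with a
scalar score per column. Selection keeps `ceil(pi * m*)` columns with the
largest score (effect variance by default; absolute effect as an option,
kept because it is the historical criterion even though it performs
slightly worse), ties at the cutoff broken toward the lower column id.
Ceiling guarantees a non-empty model at any legal pi and makes kept sets
monotone in pi. Effect and score vectors are materialized in full (16 MB
per 2e6 columns at the default scale; a hard cap refuses panels beyond
~4e7 columns) — only the n x m* indicator matrix is never built. A
streaming top-K variant would extend the reach to very dense panels at
the cost of a less transparent selection contract.

## Mixed models

**Univariate REML** is exact for one kernel plus residual: after one
eigendecomposition `Gamma = U D U'`, the restricted likelihood profiles
down to one dimension in `delta = sigma2_e / sigma2_g`; a 65-point grid on
log10(delta) in [-8, 8] brackets the optimum and Brent refinement pins it
(xatol 1e-10). The GLS mean is recomputed at each delta. A constant
response returns both components at the zero boundary. Estimates are
invariant to kernel scaling (sigma2_g rescales, predictions unchanged),
which is tested. Prediction uses the inverse-free identity
`g_hat = sigma2_g Gamma[:, train] (sigma2_g Gamma_tt + sigma2_e I)^{-1}(y - 1 mu)`,
equivalent to the mixed-model equations but defined for singular kernels —
aggressively selected `Gamma_sERR` can be low-rank.

**Bivariate REML** estimates `H` (2x2 genetic covariance, `Var(g) = H (x)
Gamma`, environment-major stacking) and `R0` (2x2 residual covariance,
applied between the two records of a line; lines observed in one
environment get the marginal variance only) by EM-REML formulated in
observation space: per iteration, build `V = ZGZ' + R` over the observed
records, form the REML projection `P`, and update

    H  <- H  + H (Q - T) H / n,    Q_ab = v_a' Gamma v_b,  T_ab = tr(Z_a' P Z_b Gamma)
    R0 <- from E[e e' | y] = e_hat e_hat' + R - R P R  (element-wise averages)

with `v_a` the per-line accumulation of `Py` for environment a. Both
updates avoid `Gamma^{-1}` entirely. After every update H and R0 are
projected onto the PSD cone (eigenvalue floor 1e-10 of the trace), which
also keeps degenerate cases — e.g. one environment an exact copy of the
other — at the correlation boundary without crashing. Convergence is
declared at relative parameter change below 1e-6.

EM's convergence rate is governed by the missing-information fraction,
which is close to 1 here: with both environments phenotyped on largely the
same lines, genetic covariance (structured by Gamma) and residual
covariance (structured by I) are weakly separated, and parameter changes
per iteration are still ~1e-4 at iteration 50 on clean simulated data.
Within the protocol caps the convergence flag therefore almost never
fires, and the fixed-value fallback is the *normal* path, not an edge
case. This mirrors how the method behaves with production REML software —
the two-stage protocol exists precisely because per-fold estimation of
six covariance parameters is fragile. The per-fold last iterates stay
within a few percent of the full-data estimates (tested at <25% relative
deviation), so predictions are insensitive to which path was taken.

**Two-stage protocol** (`estimate_bivariate_with_fallback`): full-data EM
capped at 100 iterations keeps its last iterate regardless of convergence;
each fold re-estimates from environment-1 full data plus the fold's
training lines, warm-started at the full-data values and capped at 50;
non-convergent folds use the full-data values as fixed components, with a
per-fold flag.

Bivariate prediction solves the same equations with components fixed:
`g_hat_2 = H_21 Gamma[:, obs1] w_1 + H_22 Gamma[:, obs2] w_2` with
`w = V^{-1}(y - X mu)`, and masked phenotypes are `mu_2 + g_hat_2`. Where
an explicit inverse is unavoidable the Cholesky is jittered by
1e-10..1e-4 of the mean diagonal on failure. The dense mixed-model
equations with `G = H (x) Gamma` plus ridge serve as an independent test
oracle only.

## Cross-validation

`make_folds` draws, per replicate, a random partition into k folds whose
sizes differ by at most one; the design depends only on (line ids, k,
reps, seed), so all models evaluated under one seed share identical folds
and model contrasts are paired. Univariate variance components are
re-estimated per fold from the training lines; bivariate components follow
the two-stage protocol. sERRBLUP's selection across environments is
computed once per selection environment from that environment's full data
and reused across folds — the target environment's test phenotypes never
enter it; within-environment mode instead recomputes the selection from
each training fold, the only leakage-free reading of within-environment
selection. Undefined fold correlations (constant predictions, or folds
smaller than 3 lines) are excluded from the 25-value mean and counted,
rather than coerced to zero. Heritability for the accuracy ratio is
user-supplied; `h2="auto"` approximates it as
sigma2_g / (sigma2_g + sigma2_e) from a full-data univariate fit —
entry-mean heritability from plot-level replicates would need field-design
structure this package does not model.

## Synthetic data

`simulate_genotypes` draws inbred doses in {0, 2} with allele frequencies
uniform in a MAF range (default 0.05–0.5) and block-local LD: within each
of `n_blocks` blocks (default 100) a marker copies its left neighbor's
allele with probability `within_block_ld` (default 0.7), otherwise draws
fresh. This produces the local correlation structure that makes pruning
and tagging meaningful; it does not emulate coalescent LD decay, drift,
or population structure.

`simulate_multi_env_phenotypes` assigns effects per genotype combination
of sampled marker pairs — the exact parameterization the epistasis kernel
estimates, so selection has literal ground truth — plus optional additive
effects. Environments mix a shared and an environment-specific
standardized genetic value with weights (sqrt(rho_g), sqrt(1 - rho_g)),
giving pairwise genetic correlation rho_g (negative rho_g: two
environments only, by sign flip); residual noise is scaled to the target
h2 per environment (h2 = 1 means noise-free). Passing tests on these data
shows the machinery is correct and that the method's qualitative behavior
(selection helps epistatic traits, full epistasis alone does not beat
additive, bivariate borrowing helps at high rho_g) emerges as expected;
it does not certify performance on real panels, where LD, allele-frequency
spectra and genotype-by-environment structure are richer.

## Problem sizes and defaults

The shipped studies run at desk scale, chosen to finish in minutes on one
CPU while leaving the qualitative contrasts clearly resolved: univariate
comparisons at n = 400 lines, m = 1000 markers (m* ~ 2.0e6 columns);
univariate REML recovery at n = 500; bivariate recovery of zero genetic
correlation at n = 400 (sized so the Monte-Carlo spread of the correlation
estimate sits below the 0.15 acceptance bound); the bivariate-versus-
univariate CV contrast at n = 300, where the capped EM iterations dominate
runtime. Selection proportions follow the pi grid 0.05…1e-6 downward as
m* allows; the studies use pi = 0.01. Trait architectures default to
sparse (tens of causal loci/pairs), h2 0.6–0.7 and rho_g 0.7–0.8 —
representative of multi-environment DH maize trials of adjusted means.

## Known limitations

* Pairwise interactions only; no third-order terms.
* Two environments per bivariate model (multi-environment use goes through
  the joint-average environment, not a full multi-trait covariance).
* EM-REML is robust but slow to converge; iteration counts are not
  comparable to AI-REML-based software, and the convergence flag is
  conservative (see above).
* Mode imputation and the greedy VIF pruner are deterministic stand-ins
  for heavier external tools; both are documented and tested, neither is
  byte-compatible with those tools.
* The DH assumption is load-bearing: doses other than {0, 2} after
  finalization are rejected, and the four-combination encoding is only
  complete for fully homozygous material.
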