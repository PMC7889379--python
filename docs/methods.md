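# Methods

## Null model

For family *i* (n_i members, K traits) the stacked response y_i is laid out
trait-major: K contiguous blocks of n_i, block k holding trait k for all
members. Marginal moments follow a GLM with canonical links — identity for
Gaussian traits (unit variance function A = 1, scale ϕ estimated) and logit
for Bernoulli traits (A = μ(1−μ), ϕ ≡ 1). Because the links are canonical,
Δ_ik = ∂θ/∂η is the identity; it is carried explicitly anyway so the score
expressions keep their general form. Mixing Gaussian and Bernoulli traits
in one model is not supported (single `trait_kind`): the single-scale
Kronecker working covariance has no natural mixed-scale version, and the
methodology this package implements is defined per trait kind.

The working covariance V_i = A^{1/2} (R_K ⊗ R_n) A^{1/2} ϕ combines a
cross-trait correlation R_K and a within-family correlation R_n, each
independence / exchangeable / unstructured. Estimation alternates:

1. moments (μ, A, Pearson residuals) at the current α;
2. ϕ from the mean squared Pearson residual (continuous only; df-corrected
   by the number of regression parameters);
3. correlation parameters by moment estimators on standardized residuals —
   exchangeable: averages of within-family same-trait (ρ) or same-subject
   cross-trait (γ) cross-products; unstructured: positionwise averages,
   normalized to unit diagonal and eigenvalue-floored at 1e-6 to stay
   positive definite (unstructured R_n requires a constant family size,
   which trios satisfy);
4. one Fisher-scoring step on α, solving
   Σ_i D_i' V_i^{-1} D_i · δ = Σ_i D_i' V_i^{-1}(y_i − μ_i) with
   D_i = ∂μ/∂α.

Iteration stops when max|δ| < tol (default 1e-6, max 50 iterations);
non-convergence and logit separation (|η| > 30) are flagged on the result,
never silent. α starts from trait-wise independence GLM fits. Families are
grouped by n_i and all per-family linear algebra is batched within a group
(`numpy` stacked solves), which is what keeps a 300-family fit near 10 ms
and the replicated experiments tractable on one CPU.

The exchangeable update schedule is a design choice: any fixed-point
ordering meeting the convergence contract is acceptable, and this one
(correlations before each α step) converges in 4–12 iterations on the
simulated designs.

### Deliberate working misspecification

The phenotype generator sets Cor(ε_ijk, ε_ij'k') = 0.1 for different
subject *and* different trait, which a Kronecker form cannot represent
(it forces γ·ρ = 0.3·0.2 = 0.06). This is left as-is: GEE regression
estimates stay consistent under working-correlation misspecification, and
the retrospective test variance does not depend on V_i being correct.

## Retrospective region tests

Scores Z_lk = Σ_i g_il' Δ_ik A_ik S_ik with S_i = V̂_i^{-1}(y_i − μ̂_i).
Treating genotypes as random given phenotypes, the null covariance of the
weighted scores is assembled from the dosage variance 2 m_l (1 − m_l), the
dosage correlation H, the family relatedness Ω_i, and

- C_Ho = Σ_i (Σ_k Δ A S)' Ω_i (Σ_k Δ A S)  (scalar),
- C_He[k,k'] = Σ_i (Δ A S)_k' Ω_i (Δ A S)_{k'}  (K × K),

with the identity C_Ho = Σ_{k,k'} C_He[k,k'] asserted at run time.

Weight placement: the kernel statistics are sums of squared *weighted*
scores, κ = Σ w Z² = Σ (√w Z)², so the covariance matrix uses √(w_l w_l')
— the only reading under which the χ²-mixture representation of κ is
internally consistent. Heterogeneous weights default to w_lk = w_l.

Minor-allele handling: allele frequencies are estimated on founders by
default (children would double-count transmitted alleles); variants whose
frequency exceeds 1/2 are folded (dosage 2 − g) so m ∈ (0, 0.5]; variants
monomorphic in the frequency sample are dropped before any test. H is the
Pearson correlation of (folded) dosages over all individuals — it is a
genotype-score correlation, and relatedness is already carried by Ω.

Ω comes from the pedigree (standard kinship recursion, doubled; supports
inbreeding and missing parents) or, on request, from genomic data via the
centered-and-scaled dosage cross-product averaged over variants.

## Mixture-chi-square p-values

Kernel p-values are survival probabilities of Σ λ_l χ²_{1,l} at the
observed statistic, with λ the eigenvalues of the null score covariance
(symmetrized; eigenvalues below 1e-10 of the maximum dropped; negatives
beyond −1e-8 of the maximum are an upstream error). Evaluation:

- all λ equal (including a single λ): exact scaled chi-square survival.
  This special case is what makes the single-variant HoK ≡ BT identity
  exact to 1e-10 rather than to saddlepoint accuracy.
- otherwise: Kuonen's saddlepoint approximation — Barndorff-Nielsen r*
  form Φ̄(w + log(v/w)/w) on the CGF K(t) = −½Σ log(1 − 2λ_l t), with the
  saddlepoint bracketed and solved by Brent (K' is monotone increasing on
  (−∞, 1/(2λ_max))). The removable singularity at q = Σλ is crossed by
  linear interpolation over a ±2·10⁻⁴ relative bracket. If the root search
  fails the code falls back to Satterthwaite moment matching and flags the
  result.

Accuracy: against numerically exact inversion, the first-order saddlepoint
carries a relative error of roughly −3% to +5% for strongly unequal weights
(e.g. λ = 2, 1, 0.5) over p ∈ [10⁻⁴, 0.5], growing slowly further into the
tail. This is intrinsic to the first-order approximation for small
mixtures, not an implementation artifact (second-order corrections do not
help at K = 3 components; verified empirically), and it is irrelevant at
the calibration levels the experiments target. Exact characteristic-
function inversion is deliberately out of scope; the test suite pins the
saddlepoint to its measured accuracy band against an Imhof-quadrature
oracle. p-values are floored at 1e-300.

Cauchy omnibus: O = −½(tan(π(p_a − ½)) + tan(π(p_b − ½))), p = ½ −
arctan(O)/π; inputs are clipped to [1e-15, 1 − 1e-15] (tan overflow guard,
flagged when active).

## Synthetic data

The generator emulates a two-subpopulation sequencing study:

- **Haplotype pools** (stand-in for coalescent-simulated pools): shared
  sites, i.i.d. Bernoulli haplotypes, no LD. Pool-A site frequencies mix a
  log-uniform rare spectrum on (10⁻³, 0.03) (60% of sites) with a uniform
  common spectrum on (0.03, 0.5); pool-B frequencies are drifted on the
  logit scale with sd 0.45 (≈ Fst 0.05, a modest continental
  differentiation chosen a priori). 10,000 haplotypes per pool; sites
  monomorphic in the combined pool are redrawn.
- **Trios** by gene drop: two distinct pool haplotypes per parent, one
  transmitted haplotype from each parent to the child, no recombination
  within the short region.
- **Covariates**: intercept; Bernoulli(½); Gaussian with mean 0.5, unit
  variance, covariance 0.1 between family members.
- **Continuous traits**: y = Xα + Gβ + ε with α = (0.01, 0.1, 0.1) per
  trait and ε multivariate normal, unit variance, correlations 0.2
  (within trait, across members), 0.3 (same subject, cross trait), 0.1
  (cross subject, cross trait).
- **Binary traits**: logit P(y=1) = Xα + Gβ with α = (−1.4, 0.1, 0.1);
  the joint distribution is a dichotomized multivariate normal whose
  latent pairwise correlations are solved (vectorized bisection on a
  Gauss-Legendre bivariate-normal CDF) so the realized *binary*
  correlations hit the same 0.2/0.3/0.1 targets at each family's actual
  marginal prevalences; infeasible targets (Fréchet bounds) raise.
  Pairwise-matched latent matrices are eigenvalue-floored if jointly
  slightly non-PD.
- **Effects** under the alternative: a random 35% of variants with
  MAF < 0.03 (strict) get |β| = 0.095·|log10 m|, all positive or an 80/20
  positive/negative mix; heterogeneous scenarios zero the second trait's
  effects, homogeneous ones share them.

What this generator does **not** emulate: linkage disequilibrium,
realistic site-frequency spectra from demography, admixture within
families, ascertainment, genotyping error, missingness. A green
calibration test therefore establishes that the statistics are valid for
independent-site genotypes with two-population stratification and the
stated trait correlations — not that they are robust to LD or demographic
fine structure.

## Experiments

Desk-scale defaults: 300 families (170/130, preserving the 4:3 population
ratio of the full design), 2,000 replicates, nominal levels {0.05, 0.01};
the full-scale design (1,400 families, 50,000 replicates) is accepted by
the same config but is a cluster job. Pools are built once per experiment;
each replicate draws a random contiguous window of 30 sites (a "region"),
new trios, covariates and phenotypes from a counter-derived per-replicate
seed, so any replicate is reproducible in isolation. Replicate-level fit
failures are excluded and counted; an experiment with > 1% failures is
flagged. Both working structures and both weight choices are evaluated on
the same replicate data, which removes between-run Monte-Carlo noise from
their comparison.

Power orderings at desk scale are qualitative: heterogeneous effects favor
HeK over HoK, homogeneous effects the converse, Beta(1,25) weighting beats
unweighted whenever the causal set is rare — each asserted with a 2-SE
slack at 500–2,000 replicates.

## Known limitations

- Complete cases only; no missing-data handling.
- No sandwich covariance for α (only the null fit is needed downstream).
- The saddlepoint's few-percent relative error (above) makes extremely
  small kernel p-values approximate; burden and omnibus p-values are exact
  given their statistics.
- X-chromosome variants of the statistics are not implemented.
- One scale parameter ϕ across traits (standard joint-GEE practice).
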