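# Methods

## Model and hypothesis

One gene at a time, counts y₁,…,yₙ are modelled as negative binomial,
yᵢ ~ NB(μᵢ, φ) with E[yᵢ] = μᵢ and Var[yᵢ] = μᵢ + φμᵢ², log link, and an
optional library-size offset log(mᵢ/m̄) (m̄ = geometric mean, so the
offset vector sums to zero and doubling all library sizes changes
nothing). The p covariates act through random coefficients with mean zero
and variance τ²; the null hypothesis of no association is τ² = 0, tested
one-sided against τ² > 0 by the score statistic u_nb. The covariates enter
only through the kernel R = (1/p)XXᵀ, so p may exceed n and collinear
covariates are unproblematic — they simply add weight to the similarity
structure they share.

The statistic is computed in matrix form from weighted residuals
eᵢ = (yᵢ−μ̂ᵢ)/(1+φ̂μ̂ᵢ) and trace weights wᵢ = μ̂ᵢ(1+φ̂yᵢ)/(1+φ̂μ̂ᵢ)²:
u_nb = ½eᵀRe − ½Σᵢ Rᵢᵢwᵢ. The test suite verifies exact agreement with
the literal double-sum definition on hundreds of random instances, and the
decompositions Σsᵢ = Σcⱼ = u_nb hold by construction: sᵢ = ½eᵢ(Re)ᵢ −
½Rᵢᵢwᵢ, cⱼ = [(xⱼᵀe)² − Σᵢxᵢⱼ²wᵢ]/(2p). The overall ½ scaling is a
convention; any rescaling is shared by all permuted statistics and cannot
change a p-value.

## Null fit

The intercept-only fit maximises the likelihood in (α, φ). The score in α
is strictly decreasing, so safeguarded Newton finds the unique root for
any fixed φ; the profile likelihood is then maximised over log φ by
bounded scalar search on [10⁻⁸, 10⁴], seeded additionally from the
method-of-moments value max(0, (s²−ȳ)/ȳ²) in case the global bounded
search lands on the wrong local shoulder. Whenever the Poisson likelihood
(φ = 0) is at least as high as the best interior point, φ̂ is clamped to
the boundary 0 and the statistic reduces exactly to its Poisson form.
Stationarity Σ(yᵢ−μ̂ᵢ)/(1+φ̂μ̂ᵢ) = 0 is tested to |·| < 10⁻⁶·Σy. The
likelihood is evaluated with the Gamma-ratio term written as the exact
product Π_{t<y}(1+tφ), which is numerically continuous in φ at 0 (the
naive gammaln difference loses all precision at φ ≈ 10⁻¹²).

An all-zero gene has a divergent intercept MLE; it raises a typed
`DegenerateResponseError`, and the scan driver skips such genes (as well
as constant genes and empty windows) with a logged flag.

## Permutation inference

y and μ̂ are permuted jointly, R stays fixed, and α̂, φ̂ are not
re-estimated: the intercept-only MLE is permutation-invariant, so the
permuted statistic needs only a re-indexing of e and w (this makes a
k=10 000 test a few milliseconds at n = 60). Permutations are drawn
uniformly with replacement from the permutation group, within strata when
strata are given. The observed configuration counts as one of the k draws
and ties are counted with ≥, so p = (1 + #{uᵢ ≥ u_obs})/k ∈ [1/k, 1].

Early stopping brackets the final p-value after any prefix of the stream:
with c exceedances among b permutations, p ∈ [(1+c)/k, (1+c+k−1−b)/k].
The run stops once the bracket lies entirely on one side of the target
level and reports the conservative end, so the early-stopped decision can
never contradict the full run.

## Control variates

The crude estimator p̂ = (1/k)Σ1[uᵢ ≥ u₀] is unbiased but noisy at small
k. The control-variates estimator subtracts the crude estimate of a
correlated control statistic with a known reference value:
p̂_cv = p̂_u − p̂_q + p\*. The control is the Gaussian-response global
test: q = z̃ᵀRz̃ with z̃ the centered, unit-variance transform of y.
Because z̃ is centered, R can be doubly centered (A = HRH) without
changing q, and the first two moments of z̃ᵀAz̃ under uniform permutation
have closed forms in tr A, tr A², Σᵢ Aᵢᵢ², Σz̃ᵢ² and Σz̃ᵢ⁴ (derived by
enumerating the coincidence patterns of the four indices of E[q²]; the
test suite checks them against exhaustive enumeration over all 8!
permutations to 10⁻⁸). p\* is the upper tail of the moment-matched scaled
chi-square at q_obs. The residual bias of p̂_cv equals p\* minus the true
permutation tail of q; for this reason the crude estimator remains the
default and the raw (unclipped) CV estimate is retained alongside the
reported value, which is clipped into [1/k, 1]. If q is
permutation-invariant (R proportional to the all-ones matrix or the
identity), the control is degenerate and the crude estimator is used with
a warning.

## Multiple covariate sets

The joint statistic over sets X₁,…,X_s is Σ (u(Xⱼ) − Ê[u(Xⱼ)])/√V̂ar[u(Xⱼ)]
with moments estimated from the permuted statistics of one shared
permutation stream; cross-set correlation is ignored by design. The
observed draw is included in the moment estimates, consistent with the
p-value convention — this makes the joint test of a single set reproduce
the crude p-value of that set exactly (asserted in the tests). Every
permutation's joint statistic is standardised with the same global moment
estimates (no circular re-standardisation).

## Synthetic data generator

The generator emulates a local eQTL design: SNP dosages in {0,1,2}
obtained by thresholding block-equicorrelated latent Gaussians at
Hardy-Weinberg quantiles of a per-SNP minor-allele frequency drawn from a
range; a coefficient vector whose non-zero entries form one consecutive
run of length r with values s (probability 0.8) or 2s (probability 0.2);
means via the identity relation μ = Xβ; and counts yᵢ ~ NB(μᵢ, φ)
sampled as a gamma–Poisson mixture. Null data are produced by shuffling
the elements of μ before sampling, which preserves the marginal count
distribution exactly — any calibration failure would implicate the test,
not the generator. The identity link in the generator is kept
deliberately even though the test uses a log link; the mismatch is part
of the study design and shows the test detecting association rather than
a correctly specified model.

Default conditions: n = 50 samples, p = 20 SNPs in blocks of 5 with
within-block latent correlation ρ = 0.5, minor-allele frequencies in
(0.1, 0.4), r = 5 causal SNPs, effect size s = 1, dispersion φ = 0.5, 200
alternative and 200 null replicates with k = 200 permutations per test —
a full study runs in seconds to minutes on one core and is exactly
reproducible from (config, seed). The power study varies one factor at a
time with everything else held equal: the covariate matrix is drawn once
(at the largest sample size, truncated for smaller n) and the coefficient
run is shortened or lengthened in place rather than redrawn. The three
effect-size levels used in the monotonicity check (0.05, 0.1, 0.25) sit
on the steep part of the power curve so the AUC ordering is informative
rather than saturated. A zero-effect arm needs a positive baseline (an
additive constant in μ, default 5 there, otherwise off): with μ = Xβ ≡ 0
every count is zero and the test is undefined.

What the generator does **not** emulate: real linkage-disequilibrium
patterns from genotyped panels (blocks are exchangeable and
equicorrelated), library-size variation (offsets are exercised by direct
unit tests instead), gene–gene correlation, and shared dispersion across
genes. Passing simulation checks therefore demonstrate calibration and
power under idealised LD and single-gene sampling, not performance on any
particular cohort.

## Numerical and design choices

- Covariate columns are used as provided (no centering or scaling):
  standardisation changes R and is a modelling decision left to the user.
- Dosages are treated as plain quantitative covariates; matrices arrive
  as pre-converted TSV (no VCF parsing).
- Window selection uses 0-based half-open coordinates, closed left edge
  (a covariate exactly at start − w is included), and ignores strand;
  anchors: gene body or gene start.
- Per-gene seeds in the scan are sha256 hashes of (master seed, gene id),
  so results do not depend on the order of genes in the input.
- Benjamini–Hochberg correction across genes (and across individual
  covariates in the joint-versus-individual study).
- Convergence: profile-likelihood search tolerance 10⁻¹⁰ in log φ, Newton
  tolerance 10⁻¹³ in α; boundary clamp triggered when the interior
  optimum beats Poisson by less than 10⁻⁸ log-likelihood units.

## Limitations

- No asymptotic (permutation-free) null distribution of u_nb is provided;
  significance resolution is bounded by 1/k.
- The null model is intercept-only: confounders can be absorbed through
  strata, but not through covariate adjustment of the mean.
- Dispersion is estimated per gene; no information sharing across genes,
  so φ̂ is noisy at small n (recovery to ±0.1 needs thousands of
  samples; at n = 50 the permutation test remains calibrated regardless,
  since the same φ̂ is used for all permutations).
- The control-variates reference value p\* is a chi-square approximation;
  its bias is inherited by the CV estimator, which is why it is opt-in.
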