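# Methods

## The per-variant model

For each focal variant *k* the phenotype is modeled as
`y = μ + x_k β_k + m_k + g_k + ε`, where `m_k ~ N(0, ω² K_k)` is the
polygenic additive background over the other p−1 variants
(`K_k = X_{−k} X_{−k}ᵀ/(p−1)`), `g_k ~ N(0, σ² G_k)` aggregates every
pairwise interaction involving variant *k*
(`G_k = D_k K_k D_k`, `D_k = diag(x_k)`), and `ε ~ N(0, τ² I)`.  This is
the variance-component form of a per-pair interaction model in which
each interaction coefficient is an i.i.d. normal draw; σ² is the
*marginal epistatic effect* and H₀: σ² = 0 is the per-variant test.  The
normality assumption on effect sizes is a working prior: moment
estimators of variance components are known to remain approximately
unbiased under effect-size misspecification, which is also what our
partition-recovery tests exercise.

Genotypes are standardized column-wise with the *population* (divide-by-n)
standard deviation.  This is a deliberate convention: it makes
`x_kᵀ x_k = n` exactly, so the projection `M_k = I − b(bᵀb)⁻¹bᵀ`
(b = [1, x_k]) has the closed form `I − (11ᵀ + x_k x_kᵀ)/n`, and
`trace(XXᵀ/p) = n` exactly.  All kernel algebra in the fast scan relies
on these identities.

## Estimation

The projected model `y* = M_k y` has covariance
`ω² K_k* + σ² G_k* + τ² M_k`.  The method-of-moments solve
`S δ = q` with `S_ij = tr(Σ_i Σ_j)` and `q_i = y*ᵀ Σ_i y*` is identical
to Haseman–Elston cross-product regression (asserted against an
independent least-squares oracle in the tests) and to the quadratic-form
expression `δ_i = y*ᵀ H_i y*` with `H_i = Σ_j (S⁻¹)_ij Σ_j`.  We solve
the 3×3 system directly and form `H_i` only where a quadratic form in it
is required (estimator variances, exact-test weights).  Estimates are
*not* truncated at zero — the two-sided normal test requires signed
estimates.  Near-singular `S` (condition number > 1e12) falls back to a
pseudo-inverse and flags the record.

Estimator variances use the plug-in approximation
`V(δ_i) ≈ 2 (H_i y*)ᵀ V (H_i y*)`, `V = Σ_j δ̂_j Σ_j`.  Because point
estimates may be negative, `V` can be indefinite and a computed variance
can come out negative; reported variances are clamped at zero and
flagged (`clamped_variance`).  The clamp applies only to variances of
estimates, never to the estimates themselves.

## Hypothesis testing

* **Normal test**: `p = 2 Φ(−|σ̂²|/se)`.
* **Exact test**: under H₀, `σ̂² = y*ᵀ H y*` with `y* ~ N(0, A)`,
  `A = ω̂₀² K_k* + τ̂₀² M_k` fitted from the two-component null system;
  the statistic is a weighted mixture `Σ λ_i χ²₁` with λ the eigenvalues
  of `A^{1/2} H A^{1/2}`.  Two conventions for `H` exist in the
  literature around this construction; we use the `H` of the *tested*
  (σ²) component from the full three-component system — the unique
  choice for which `σ̂² = y*ᵀ H y*` holds identically — and expose the
  first-component alternative behind `davies_h="literal"` for
  comparison.  The null covariance `A` is refitted from the restricted
  (K*, M) system rather than reusing the alternative-model estimates,
  keeping the null distribution internally consistent.
* **Mixture tail**: Imhof's characteristic-function inversion, the same
  quantity the Davies algorithm computes.  The integrand decays only
  like u^(−1−m/2), so we integrate the head `[0, 5/max|λ|]` adaptively
  and the oscillatory tail as a Fourier integral (QUADPACK cycle
  summation at frequency |q|/2).  Absolute accuracy is ~1e−10 against
  chi-square closed forms; default requested accuracy 1e−9.  Weights
  with `|λ| ≤ 1e−8·max|λ|` are dropped (noise eigenvalues of the
  rank-(n−2) projection); the weight sum is asserted against
  `tr(A H)` on every call.  When the inversion underflows (p ≤ 0), a
  Kuonen (Lugannani–Rice) saddlepoint approximation is used
  (`method="saddlepoint"`), and if the saddle equation fails, a
  Satterthwaite scaled chi-square (`method="satterthwaite"`); both
  return strictly positive p-values.
* **Hybrid**: normal test by default; exact recomputation whenever
  `p_normal < 0.05` (configurable).  This matches the intended
  genome-wide use where only promising variants pay the O(n³) exact
  test.

An operating fact worth knowing: at moderate α (0.05) the exact and
normal tests reject substantially *different* variants — the null
mixture is right-skewed, so its 95th percentile sits below the
1.96·se normal cutoff while the reverse holds deep in the tail.  The
hybrid procedure therefore tracks the exact test closely at stringent
thresholds but not at α = 0.05; the type-I-error harness consequently
computes the exact p-value for every tested variant rather than
screening through the normal test.

## Computational structure

`grm` + rank-one downdate gives every leave-one-out `K_k` in O(n²)
(verified entrywise against from-scratch rebuilds).  The scan keeps
`Σ_1 = M K_k M` implicit as `a(P − (x wᵀ + w xᵀ)/n + (c/n²) x xᵀ)` with
`w = P x_k`, `c = x_kᵀ w`, so all moment-matrix entries except those
involving `Σ_2` reduce to closed forms in precomputed scalars; `Σ_2` is
materialized once per variant during a phenotype-independent
precomputation.  Per phenotype replicate each variant then costs O(n)
plus three P-matvecs.  For repeated exact testing against one panel
(`exact_cache=True`), each variant additionally caches the spectrum
`κ, Ṽ` of `Σ_1` restricted to an orthonormal basis of range(M_k) and
`W̃ = ṼᵀQᵀHQṼ`; the per-phenotype mixture weights are then the
eigenvalues of `diag(s) W̃ diag(s)` with `s = √(max(ω̂₀²κ + τ̂₀², 0))` —
one symmetric eigenvalue problem per (variant, phenotype) and nothing
else.  For one-off exact tests a Cholesky route
(`λ(A^{1/2}HA^{1/2}) = λ(Lᵀ H L)`, `B = ω̂₀²K_k + τ̂₀²I = LLᵀ`) avoids a
second eigendecomposition; all three routes agree to 1e−6 in tests.
Results are independent of variant processing order, and per-variant
numerical failures become record flags rather than scan aborts.

## Variance partition

`partition_pve` fits `y = g1 + g2 + ε` with covariances
`(K, K∘K, I)` after projecting out the intercept and, optionally, the
top genotype PCs (eigenvectors of the standardized genotype covariance;
default 10 when enabled).  The projected identity component is `M`
itself with `tr(M) = n − 1 − n_pcs`, and pPVE terms are
`δ̂_i·tr(Σ_i)` normalized to sum to one.  Negative terms are clamped at
zero before normalization (our convention — a proportionality statement
alone does not define behavior for negative moment estimates); the raw
signed shares are reported alongside (`pve`) and are what the
recovery studies average, since clamping would bias means.  If every
term is non-positive the pPVE is reported as NaN with an
`undefined_ppve` flag.

## Synthetic studies

`simulate_genotypes` draws counts ~ Binomial(2, f), f ~ U(0.05, 0.5) by
default — unlinked variants; real-panel linkage disequilibrium is *not*
emulated, so calibration/power results here speak to the independent-SNP
regime only.  Phenotype components (stratification `Zu` from top PCs,
additive `Xβ`, epistatic `Wα` over the full group1×group2 cross product
of standardized-genotype products, noise) are centered, *sequentially
orthogonalized, and rescaled so realized sample-variance shares equal
the design exactly* (ρH², (1−ρ)H², strat share, remainder).  We read
"scaled to ensure" a given heritability as exact realized scaling; the
orthogonalization is what makes the shares simultaneously exact, and it
gives downstream recovery tests analytic truth.  Interaction columns are
not re-standardized.  Per-SNP interaction PVE is (1−ρ)H²/p_group —
0.012 per hub under scenario I at ρ = 0.8 — reported in
`true_pve_per_snp`.

Null phenotypes use the same machinery with all causal mass additive
(`y = [Zu] + Xβ + ε`); the stratified variant assigns 10 % of variance
to the top 5 (or 10) genotype PCs of the simulated panel itself.

## Study problem sizes

The default test suite and the acceptance script run the studies at
sizes chosen to finish on a single CPU while keeping Monte-Carlo error
well inside the comparison bands:

* **Type-I error**: one synthetic panel at n = 1,000, p = 2,000
  (500 causal additive SNPs, narrow-sense h² = 0.6), 100 phenotype
  replicates, 30 variants tested per replicate with full exact p-values
  (3,000 draws per test; binomial s.e. of the mean size ≈ 0.005).
  Genotypes are fixed across replicates, matching the study design the
  table we compare against describes.
* **Power**: scenario II at full sample size n = 2,900 with p = 5,747
  variants, 3 replicates, evaluating only the 30 causal interacting
  variants per replicate; comparisons use 3 binomial s.e. bands at the
  pooled draw counts.  Full 100-replicate power curves are available
  through `power_study` but are multi-hour runs.
* **Partition recovery**: n = 500, p = 1,000; 1,000 epistatic-phenotype
  replicates for the mean epistatic-PVE estimate (per-replicate s.d. of
  the estimate is large — ≈ 0.7 — because with unlinked SNPs K∘K is
  close to a shifted identity and partially confounded with the noise
  component; the mean over 1,000 replicates carries MC s.e. ≈ 0.02),
  and 200 model-drawn replicates for (ω², σ², τ²) recovery within
  3 MC s.e.  The epistatic-PVE study uses the polygenic causal
  configuration (10/100/890, 1,000 interacting pairs).  This is a
  measured property, worth knowing when applying the partition: the
  Hadamard-squared kernel encodes *all-pairs* epistasis, and with
  unlinked genotypes a sparse interaction architecture (e.g. 100 pairs
  of the ~5·10⁵ possible) projects onto it only partially — the sparse
  configuration recovers a mean share of ≈ 0.03 where the truth is
  0.12, while the 1,000-pair configuration recovers ≈ 0.10–0.13
  (across-seed means 0.097–0.13 at MC s.e. 0.02–0.04).  On linked real
  panels each interaction is spread across many correlated pairs, which
  improves the projection even for sparse architectures.

## Numerical choices and degenerate inputs

* PSD checks accept eigenvalues ≥ −1e−8·max|λ|; worse signals a
  standardization bug and raises.
* Constant genotype columns are dropped at load (standardization would
  divide by zero); a fully filtered panel is an error, not an empty
  result.
* Missing genotype calls are mean-imputed before standardization by
  default (`drop-variant` is available); MAF floor defaults to 0.05.
* `se = 0` records: p = 1 when the estimate is also 0, else p = 0, with
  a `zero_se` flag.
* Ties in quantile normalization share their average-rank quantile;
  quantile points are rank/(n+1).
* Two-step filtering breaks ranking ties at the top-v boundary by
  variant index (stable sort).

## Known limitations

* No linkage-disequilibrium structure in the simulator; LD-induced
  estimation bias in variance components is documented for related
  estimators and would affect this one similarly.  This matters most
  for *power*: with unlinked SNPs the off-diagonal relatedness entries
  shrink like 1/sqrt(p), so the contrast between the epistatic kernel
  and the identity weakens as panels grow, and at n = 2,900 with a
  per-SNP interaction PVE of 0.012 the per-variant standard error is
  ~0.015–0.02 — the PVE estimates themselves are unbiased, but
  detection power is only ~5–10 %.  Linked real panels concentrate the
  relatedness spectrum and can reduce that standard error severalfold,
  so power measured here is a lower bound on what structured genotypes
  give; calibration (type-I error) results transfer, power magnitudes
  do not.
* The exact test refits the null per variant but ignores uncertainty in
  (ω̂₀², τ̂₀²); at small n this leaves the test slightly liberal.
* Case-control phenotypes, dosage input, higher-order interaction
  kernels, and multivariate traits are out of scope.
* `pairwise_scan` is a dense OLS loop — fine for filtered pair sets,
  not for genome-wide exhaustive scans beyond the 1e8-pair guard.
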