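# mapit — marginal epistasis testing for quantitative traits

Exhaustively testing every pair of SNPs for interaction is statistically
and computationally brutal: with *p* markers there are *p(p−1)/2* pairs,
each individual interaction effect is tiny, and the multiple-testing
burden is crushing.  `mapit` takes a different route.  For each variant
*k* in turn it estimates and tests the **marginal epistatic effect** —
the *combined* pairwise interaction between that variant and all other
variants — so only *p* tests are needed, and a variant can be flagged as
"involved in epistasis" without knowing its partners.

## Model

For standardized genotypes (each column mean 0, s.d. 1) the phenotype of
*n* individuals is modeled per focal variant *k* as a variance-component
(linear mixed) model

    y = μ + x_k β_k + m_k + g_k + ε
    m_k ~ N(0, ω² K_k)      K_k = X_{-k} X_{-k}ᵀ / (p−1)
    g_k ~ N(0, σ² G_k)      G_k = D_k K_k D_k,  D_k = diag(x_k)
    ε   ~ N(0, τ² I)

`m_k` is the polygenic additive background and `g_k` collects every
pairwise interaction involving variant *k*; the null hypothesis of no
marginal epistasis is **H₀: σ² = 0**.  After projecting out the
intercept and `x_k` (M_k = I − b(bᵀb)⁻¹bᵀ, b = [1, x_k]), the variance
components are estimated by a method-of-moments solve

    S δ = q,   S_ij = tr(Σ_i Σ_j),   q_i = y*ᵀ Σ_i y*,
    Σ = [M_k K_k M_k, M_k G_k M_k, M_k]

which is mathematically identical to Haseman–Elston cross-product
regression but closed-form.  Two tests are provided:

* **normal (z) test** on σ̂²/se(σ̂²) — O(n²) per variant, slightly
  anti-conservative in the extreme tail;
* **exact test**: under H₀, σ̂² = y*ᵀH y* is a weighted mixture of
  χ²₁ variables whose weights are the eigenvalues of
  A^{1/2} H A^{1/2}, A = ω̂₀²K_k* + τ̂₀²M_k fitted under the null; the
  tail probability is computed by characteristic-function inversion
  (Imhof/Davies), with Kuonen saddlepoint and Satterthwaite fallbacks.

The **hybrid** procedure (the default) uses the normal test and
recomputes p-values exactly whenever p_normal < 0.05.  The package also
ships a genome-wide **variance partition** (`partition_pve`) splitting
phenotypic variance into additive (K = XXᵀ/p), pairwise-epistatic
(K∘K, the Hadamard square), and noise components with pPVE reporting, a
simulation engine with exactly enforced variance shares, single-SNP and
exhaustive-pairwise OLS baselines, and a study harness (type-I error,
power, TPR–FPR curves, two-step interaction filtering).

## Worked example

Three "hub" variants interact with three partner variants; the hubs each
carry a true marginal epistatic PVE of 0.10 and the interactions jointly
explain 30 % of phenotypic variance:

```python
import numpy as np
from mapit import (SimulationDesign, simulate_genotypes,
                   simulate_epistatic, mapit_scan, partition_pve)

geno = simulate_genotypes(n=800, p=300, seed=3)
design = SimulationDesign(n=800, p=300, h2=0.6, rho=0.5,
                          groups=(3, 3, 30), seed=3)
study = simulate_epistatic(geno, design)
print(study.true_pve_per_snp)
# {'group1': 0.0999..., 'group2': 0.0999..., 'total_epistatic': 0.3}

g1 = study.causal_groups[0]
records = mapit_scan(geno, study.y, mode="hybrid", variants=list(g1) + [0, 1, 2])
for r in records:
    tag = "hub " if r.k in g1 else "null"
    print(f"snp{r.k:<3} ({tag}): sigma2_hat={r.sigma2_hat:+.4f}  p={r.p_final:<8.3g} ({r.method})")
# snp254 (hub ): sigma2_hat=+0.0901  p=0.000775 (davies)
# snp299 (hub ): sigma2_hat=+0.1313  p=5.26e-06 (davies)
# snp9   (hub ): sigma2_hat=+0.0945  p=8.36e-05 (davies)
# snp0   (null): sigma2_hat=+0.0026  p=0.88     (normal)
# snp1   (null): sigma2_hat=-0.0243  p=0.114    (normal)
# snp2   (null): sigma2_hat=+0.0183  p=0.493    (normal)

part = partition_pve(geno, study.y)
print(np.round(part.ppve, 3))   # additive / epistatic / noise shares
# [0.312 0.338 0.349]
```

Every hub's σ̂² lands near its true 0.10 with a genome-wide-credible
p-value, the non-causal variants stay null, and the partition's pPVE is
close to the generating (0.3, 0.3, 0.4) split.  At realistic GWAS
architectures the per-variant signal is far smaller (a per-SNP
interaction PVE of ~0.01), and detection needs thousands of samples —
the study harness (`type1_study`, `power_study`) quantifies exactly
that.

A command-line interface mirrors the library:

```sh
mapit simulate --n 500 --p 1000 --scenario I --seed 7 --out sim
mapit scan --bfile sim --pheno sim.pheno --test hybrid --out results
mapit partition --bfile sim --pheno sim.pheno --out part
mapit evaluate --study type1 --n 300 --p 400 --replicates 20 --out ev
```

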