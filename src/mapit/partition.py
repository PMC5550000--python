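"""Additive / pairwise-epistatic partition of phenotypic variance.

A two-variance-component linear mixed model
``y = g1 + g2 + eps`` with ``g1 ~ N(0, omega^2 K)`` (additive,
K = X X^T / p), ``g2 ~ N(0, sigma^2 K o K)`` (pairwise epistasis via the
Hadamard square of the relatedness matrix), and i.i.d. noise.  The fixed
effects (intercept and, optionally, top genotype principal components)
are removed by projection; the remaining components are estimated by the
same moment (Haseman-Elston-equivalent) solve used in the per-variant
scan.  Each component's contribution is summarized as a proportion of
phenotypic variance explained (pPVE), proportional to
delta_hat_i * trace(Sigma_i) and normalized to sum to one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .genotypes_io import GenotypeMatrix, Phenotype
from .kernels import grm, hadamard_square

__all__ = ["PartitionResult", "partition_pve", "pve_normalize"]


@dataclasses.dataclass
class PartitionResult:
    """Variance partition over (K, K o K, I)-type components.

    ``delta_hat`` = (omega^2, sigma^2, tau^2) estimates, ``se`` their
    approximate standard errors, ``pve`` the raw per-component variance
    shares delta_hat_i * trace(Sigma_i) / trace(M) (signed, may be
    negative), ``ppve`` the clamped-normalized proportions, and
    ``p_epistasis`` a two-sided normal-test p-value on sigma^2.
    """

    delta_hat: np.ndarray
    se: np.ndarray
    pve: np.ndarray
    ppve: np.ndarray
    p_epistasis: float
    n_pcs: int
    flags: tuple[str, ...] = ()


def pve_normalize(delta_hat, traces, clamp: bool = True) -> np.ndarray:
    """Normalize delta_hat_i * trace_i terms into proportions summing to 1.

    Negative terms are clamped at zero before normalization when
    ``clamp`` is set (default).  If every term is <= 0 the proportions
    are undefined and a NaN vector is returned.
    """
    terms = np.asarray(delta_hat, float) * np.asarray(traces, float)
    if clamp:
        terms = np.maximum(terms, 0.0)
    total = terms.sum()
    if total <= 0:
        return np.full(terms.shape, np.nan)
    return terms / total


def partition_pve(X, y, n_pcs: int = 0) -> PartitionResult:
    """Fit the three-component partition and report pPVE.

    When ``n_pcs`` > 0, the top principal components of the standardized
    genotype matrix are projected out of y, K, and K o K (together with
    the intercept) before fitting.
    """
    Xs = X.standardized if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y, float)
    n = Xs.shape[0]
    if yv.size != n:
        raise ValueError("genotype and phenotype sample counts differ")

    K = grm(Xs)
    K2 = hadamard_square(K)

    cols = [np.ones(n)]
    if n_pcs > 0:
        # PCs = leading eigenvectors of the genotype covariance X X^T
        _, _, vt = np.linalg.svd(Xs - Xs.mean(axis=0), full_matrices=False)
        scores = (Xs - Xs.mean(axis=0)) @ vt[:n_pcs].T
        cols.append(scores)
    B = np.column_stack(cols)
    Q, _ = np.linalg.qr(B)
    M = np.eye(n) - Q @ Q.T

    Sigma = (M @ K @ M, M @ K2 @ M, M)
    ystar = M @ yv
    S = np.empty((3, 3))
    for i in range(3):
        for j in range(i, 3):
            S[i, j] = S[j, i] = float(np.sum(Sigma[i] * Sigma[j]))
    q = np.array([float(ystar @ (Sig @ ystar)) for Sig in Sigma])

    flags: tuple[str, ...] = ()
    if np.linalg.cond(S) > 1e12:
        S_inv = np.linalg.pinv(S)
        flags = ("singular_S",)
    else:
        S_inv = np.linalg.inv(S)
    delta = S_inv @ q

    V = sum(d * Sig for d, Sig in zip(delta, Sigma))
    var = np.empty(3)
    for i in range(3):
        H = sum(S_inv[i, j] * Sigma[j] for j in range(3))
        h = H @ ystar
        var[i] = 2.0 * float(h @ (V @ h))
    if (var < 0).any():
        flags = flags + ("clamped_variance",)
        var = np.maximum(var, 0.0)
    se = np.sqrt(var)

    m = float(np.trace(M))
    traces = np.array([float(np.trace(Sig)) for Sig in Sigma])
    pve = delta * traces / m
    ppve = pve_normalize(delta, traces, clamp=True)
    if np.isnan(ppve).all():
        flags = flags + ("undefined_ppve",)

    if se[1] > 0:
        p_epi = 2.0 * stats.norm.sf(abs(delta[1]) / se[1])
    else:
        p_epi = 1.0 if delta[1] == 0 else 0.0
        flags = flags + ("zero_se",)
    return PartitionResult(delta_hat=delta, se=se, pve=pve, ppve=ppve,
                           p_epistasis=float(p_epi), n_pcs=n_pcs, flags=flags)
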