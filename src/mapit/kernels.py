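"""Per-variant covariance structures for the marginal epistasis model.

For a focal variant k with standardized genotype x_k, the model places
three covariance components on the phenotype: an additive polygenic
background with leave-one-out relatedness K_k = X_{-k} X_{-k}^T / (p-1),
a pairwise-interaction component with G_k = D_k K_k D_k (D_k = diag(x_k)),
and i.i.d. noise.  The intercept and the focal variant's own additive
effect are removed by the projection M_k = I - b (b^T b)^{-1} b^T with
b = [1_n, x_k], giving the projected component set
[K_k^* , G_k^* , M_k] = [M_k K_k M_k, M_k G_k M_k, M_k] that the moment
estimator consumes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = [
    "ComponentSet",
    "grm",
    "loo_grm",
    "epistatic_kernel",
    "projection",
    "hadamard_square",
    "build_component_set",
]

# eigenvalues below -PSD_RTOL * max|eig| signal a standardization bug
PSD_RTOL = 1e-8


@dataclasses.dataclass(frozen=True)
class ComponentSet:
    """Projected covariance matrices and phenotype for one focal variant.

    Sigma1 = M_k K_k M_k, Sigma2 = M_k G_k M_k, Sigma3 = M_k,
    y_star = M_k y.  ``df`` is trace(M_k) = n - rank(b), the residual
    degrees of freedom after projection.
    """

    k: int
    Sigma1: np.ndarray
    Sigma2: np.ndarray
    Sigma3: np.ndarray
    y_star: np.ndarray
    df: float

    @property
    def n(self) -> int:
        return self.y_star.size

    def components(self):
        return (self.Sigma1, self.Sigma2, self.Sigma3)


def grm(X: np.ndarray) -> np.ndarray:
    """Genetic relatedness matrix K = X X^T / p over standardized genotypes.

    With population-sd standardization each column satisfies x^T x = n, so
    trace(K) = n exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("need an n x p matrix with p >= 1")
    return X @ X.T / X.shape[1]


def loo_grm(K_full: np.ndarray, x_k: np.ndarray, p: int) -> np.ndarray:
    """Leave-one-out relatedness via a rank-one downdate.

    Given K_full = X X^T / p over all p variants (including k), returns
    (p * K_full - x_k x_k^T) / (p - 1), which equals the relatedness matrix
    rebuilt from scratch without column k.
    """
    if p < 2:
        raise ValueError("leave-one-out relatedness needs p >= 2")
    x = np.asarray(x_k, dtype=np.float64)
    return (p * K_full - np.outer(x, x)) / (p - 1)


def epistatic_kernel(K_k: np.ndarray, x_k: np.ndarray) -> np.ndarray:
    """Pairwise-interaction kernel G_k = D_k K_k D_k with D_k = diag(x_k)."""
    x = np.asarray(x_k, dtype=np.float64)
    if K_k.shape != (x.size, x.size):
        raise ValueError("K_k and x_k shapes do not match")
    return K_k * np.outer(x, x)


def hadamard_square(K: np.ndarray) -> np.ndarray:
    """Elementwise square K degree-2 interaction kernel (Schur product K o K)."""
    return K * K


def projection(x_k: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
    """Projection M removing the intercept, x_k, and optional covariates.

    Symmetric, idempotent, annihilates every column of b = [1, x_k, C];
    trace(M) = n - rank(b).  A rank-deficient b (x_k proportional to 1_n,
    or collinear covariates) is reduced to its column space with a warning.
    """
    x = np.asarray(x_k, dtype=np.float64)
    n = x.size
    cols = [np.ones(n), x]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    b = np.column_stack(cols)
    q, r = np.linalg.qr(b)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        warnings.warn("rank-deficient projection basis; reducing to independent columns")
        q = q[:, keep]
    return np.eye(n) - q @ q.T


def _check_psd(A: np.ndarray, name: str) -> None:
    eig = np.linalg.eigvalsh(A)
    lam_max = max(abs(eig[0]), abs(eig[-1]), 1e-300)
    if eig[0] < -PSD_RTOL * lam_max:
        raise ValueError(
            f"{name} is not positive semi-definite (min eig {eig[0]:.3e}); "
            "this usually signals a standardization bug"
        )


def build_component_set(X: np.ndarray, y: np.ndarray, k: int,
                        background: np.ndarray | None = None,
                        covariates: np.ndarray | None = None,
                        check: bool = False) -> ComponentSet:
    """Assemble the projected component set for focal variant k.

    ``background`` optionally restricts the variants forming the
    relatedness matrix (the focal variant is always excluded when
    present in the background; a background that does not contain k is
    used as-is).  ``check`` verifies positive semi-definiteness of the
    projected kernels.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if not 0 <= k < p:
        raise ValueError(f"variant index {k} out of range for p={p}")
    x = X[:, k]

    if background is None:
        bg = np.arange(p)
    else:
        bg = np.asarray(background)
    bg = bg[bg != k]
    if bg.size < 1:
        raise ValueError("background is empty after excluding the focal variant")
    Xb = X[:, bg]
    K_k = Xb @ Xb.T / bg.size
    G_k = epistatic_kernel(K_k, x)
    M = projection(x, covariates)
    Sigma1 = M @ K_k @ M
    Sigma2 = M @ G_k @ M
    if check:
        _check_psd(Sigma1, "projected additive kernel")
        _check_psd(Sigma2, "projected epistatic kernel")
    return ComponentSet(
        k=int(k),
        Sigma1=Sigma1,
        Sigma2=Sigma2,
        Sigma3=M,
        y_star=M @ y,
        df=float(np.trace(M)),
    )
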