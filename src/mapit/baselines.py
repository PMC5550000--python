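"""Comparator methods: single-SNP additive test and exhaustive pairwise scan.

The additive scan fits y ~ 1 + [covariates] + x_k per variant and reports
a two-sided t-test on the genotype coefficient.  The pairwise scan fits
y ~ 1 + [covariates] + x_i + x_j + x_i o x_j per pair and tests the
interaction coefficient.  Interaction terms are built from standardized
genotypes and not re-standardized.  Both use ordinary least squares with
the t reference (residual d.f. = n - #parameters), the convention of the
standard GWAS tools these baselines mirror.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np
from scipy import stats

from .genotypes_io import GenotypeMatrix, Phenotype

__all__ = ["PairTestRecord", "additive_scan", "pairwise_scan", "bonferroni"]

MAX_PAIRS = 10**8


@dataclasses.dataclass(frozen=True)
class PairTestRecord:
    """One pairwise-interaction test (i < j)."""

    i: int
    j: int
    alpha_hat: float
    p_value: float
    flags: tuple[str, ...] = ()


def _as_xy(X, y):
    Xs = X.standardized if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y, float)
    if Xs.shape[0] != yv.size:
        raise ValueError("genotype and phenotype sample counts differ")
    return Xs, yv


def _covariate_basis(n, covariates):
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        cols.append(C)
    B = np.column_stack(cols)
    Q, R = np.linalg.qr(B)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    if not keep.all():
        warnings.warn("dropping collinear covariate column(s)")
        Q = Q[:, keep]
    return Q


def additive_scan(X, y, covariates=None) -> np.ndarray:
    """Per-variant OLS p-values for the additive genotype effect.

    Vectorized across variants: y and each x_k are residualized against
    the intercept (and covariates); the marginal slope t-test then has
    n - 2 - c residual degrees of freedom.
    """
    Xs, yv = _as_xy(X, y)
    n, p = Xs.shape
    Q = _covariate_basis(n, covariates)
    c = Q.shape[1] - 1
    yr = yv - Q @ (Q.T @ yv)
    Xr = Xs - Q @ (Q.T @ Xs)
    xx = np.sum(Xr * Xr, axis=0)
    xy = Xr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xx > 0, xy / xx, 0.0)
    df = n - 2 - c
    rss = np.maximum(yr @ yr - np.where(xx > 0, xy**2 / xx, 0.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / np.where(xx > 0, xx, np.inf))
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[xx == 0] = 1.0
    return pvals


def _pair_ols(yv, cols, df):
    """OLS of y on the given design columns; returns (last coefficient,
    its p-value, collinear flag)."""
    D = np.column_stack(cols)
    G = D.T @ D
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return 0.0, 1.0, True
    if np.linalg.cond(G) > 1e10:
        return 0.0, 1.0, True
    coef = Ginv @ (D.T @ yv)
    resid = yv - D @ coef
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * Ginv[-1, -1])
    if se == 0:
        return float(coef[-1]), 1.0 if coef[-1] == 0 else 0.0, False
    t = coef[-1] / se
    return float(coef[-1]), float(2.0 * stats.t.sf(abs(t), df)), False


def pairwise_scan(X, y, pairs="all", covariates=None,
                  allow_large: bool = False) -> list[PairTestRecord]:
    """Exhaustive (or listed) pairwise interaction tests.

    ``pairs`` is either ``"all"`` or an iterable of (i, j) index pairs.
    Refuses more than 10^8 pairs unless ``allow_large`` is set.  A pair
    whose interaction column is collinear with the main effects gets
    p = 1 with a flag.
    """
    Xs, yv = _as_xy(X, y)
    n, p = Xs.shape
    if pairs == "all":
        pair_list = list(itertools.combinations(range(p), 2))
    else:
        pair_list = [(min(i, j), max(i, j)) for i, j in pairs]
    if len(pair_list) > MAX_PAIRS and not allow_large:
        raise ValueError(f"{len(pair_list)} pairs exceeds the guard of {MAX_PAIRS}")
    Q = _covariate_basis(n, covariates)
    ncov = Q.shape[1]
    df = n - ncov - 3
    records = []
    for i, j in pair_list:
        xi, xj = Xs[:, i], Xs[:, j]
        alpha, pv, collinear = _pair_ols(
            yv, [Q, xi[:, None], xj[:, None], (xi * xj)[:, None]], df)
        flags = ("collinear",) if collinear else ()
        records.append(PairTestRecord(i=i, j=j, alpha_hat=alpha, p_value=pv,
                                      flags=flags))
    return records


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("test count must be >= 1")
    return alpha / m
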