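"""Method-of-moments (MQS) variance-component estimation.

For a component set Sigma = [Sigma1, Sigma2, Sigma3] and projected
phenotype y*, the moment estimator solves S delta = q where
S[i, j] = trace(Sigma_i Sigma_j) and q[i] = y*^T Sigma_i y*.  The solve
is algebraically identical to the quadratic-form formulation
delta_i = y*^T H_i y* with H_i = sum_j (S^-1)[i, j] Sigma_j, and to
Haseman-Elston cross-product regression of vec(y* y*^T) on the
vectorized components.  Estimates are NOT truncated at zero: the
two-sided normal test downstream requires signed estimates.

Approximate estimator variances follow the plug-in formula
V(delta_i) ~= 2 (H_i y*)^T V (H_i y*) with
V = sum_j delta_j Sigma_j.  Because point estimates may be negative, V
can be indefinite and a computed variance can come out negative; reported
variances are clamped at zero and the fit is flagged.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kernels import ComponentSet

__all__ = ["MqsFit", "moment_matrix", "mqs_estimate", "mqs_variance"]

# condition number beyond which the moment system is treated as singular
COND_MAX = 1e12


@dataclasses.dataclass
class MqsFit:
    """MQS estimates for one focal variant.

    delta_hat = (omega^2, sigma^2, tau^2); var_hat holds the approximate
    estimator variances (filled by :func:`mqs_variance`); S and q are the
    moment matrix and moment vector; flags collects quality notes.
    """

    k: int
    delta_hat: np.ndarray
    S: np.ndarray
    q: np.ndarray
    var_hat: np.ndarray | None = None
    flags: tuple[str, ...] = ()


def moment_matrix(cs: ComponentSet) -> np.ndarray:
    """The 3 x 3 matrix S[i, j] = trace(Sigma_i Sigma_j).

    Traces of symmetric products are computed as elementwise-product sums.
    """
    comps = cs.components()
    S = np.empty((3, 3))
    for i in range(3):
        for j in range(i, 3):
            S[i, j] = S[j, i] = float(np.sum(comps[i] * comps[j]))
    return S


def _solve(S: np.ndarray, q: np.ndarray):
    flags = []
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > COND_MAX:
        flags.append("singular_S")
        delta = np.linalg.pinv(S) @ q
    else:
        delta = np.linalg.solve(S, q)
    return delta, tuple(flags)


def mqs_estimate(cs: ComponentSet) -> MqsFit:
    """Point estimates delta_hat = S^{-1} q for one component set."""
    S = moment_matrix(cs)
    y = cs.y_star
    q = np.array([float(y @ (Sig @ y)) for Sig in cs.components()])
    delta, flags = _solve(S, q)
    return MqsFit(k=cs.k, delta_hat=delta, S=S, q=q, flags=flags)


def h_matrix(cs: ComponentSet, S_inv: np.ndarray, i: int) -> np.ndarray:
    """H_i = sum_j (S^-1)[i, j] Sigma_j, the quadratic-form matrix with
    delta_i = y*^T H_i y*."""
    comps = cs.components()
    return sum(S_inv[i, j] * comps[j] for j in range(3))


def mqs_variance(cs: ComponentSet, fit: MqsFit) -> np.ndarray:
    """Plug-in approximate variances of the three estimates.

    Negative computed variances (possible when V is indefinite) are
    clamped at zero and the fit flagged ``clamped_variance``.
    """
    comps = cs.components()
    V = sum(d * Sig for d, Sig in zip(fit.delta_hat, comps))
    S_inv = np.linalg.pinv(fit.S) if "singular_S" in fit.flags else np.linalg.inv(fit.S)
    y = cs.y_star
    var = np.empty(3)
    for i in range(3):
        h = h_matrix(cs, S_inv, i) @ y
        var[i] = 2.0 * float(h @ (V @ h))
    if (var < 0).any():
        fit.flags = fit.flags + ("clamped_variance",)
        var = np.maximum(var, 0.0)
    fit.var_hat = var
    return var
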