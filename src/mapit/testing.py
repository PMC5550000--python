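"""Hypothesis testing for the marginal epistatic variance component.

The null hypothesis for each focal variant is H0: sigma^2 = 0, i.e. the
variant has no pairwise interaction with any other variant.  Two tests
are provided:

* a two-sided normal (z) test on sigma2_hat / se -- fast but
  anti-conservative in the extreme tail;
* an exact test based on the fact that under H0 the moment estimate
  sigma2_hat = y*^T H y* is distributed as a weighted mixture of 1-d.f.
  chi-squares, sum_i lambda_i chi^2_1i, with lambda_i the eigenvalues of
  A^{1/2} H A^{1/2} where A = omega0^2 K_k^* + tau0^2 M_k is the null
  covariance fitted by a two-component moment system.  The mixture tail
  is evaluated by Imhof's characteristic-function inversion (exact to a
  requested accuracy, the same quantity the Davies algorithm computes),
  with a Kuonen saddlepoint approximation and a Satterthwaite
  scaled-chi-square as fallbacks when the inversion underflows.

The hybrid procedure uses the normal test by default and recomputes the
p-value exactly whenever the normal p-value falls below a threshold
(default 0.05).

On the choice of H: the mixture applies to the statistic actually
computed, sigma2_hat = y*^T H_2 y*, where H_2 is the quadratic-form
matrix of the sigma^2 component from the full three-component system
(the identity delta_i = y*^T H_i y* pins the index).  ``davies_h="literal"``
instead uses the first component's H matrix for comparison.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import integrate, optimize, stats

from .genotypes_io import GenotypeMatrix, Phenotype
from .kernels import ComponentSet, build_component_set
from .mqs import MqsFit, h_matrix, mqs_estimate, mqs_variance

__all__ = [
    "TestRecord",
    "NullFit",
    "normal_test",
    "null_fit",
    "null_mixture_weights",
    "quadform_tail",
    "saddlepoint_tail",
    "satterthwaite_tail",
    "hybrid_test",
    "davies_test",
    "mapit_scan",
    "MapitScanner",
]

# relative truncation for noise eigenvalues of the rank-(n-2) projection
EIG_RTOL = 1e-8


@dataclasses.dataclass
class TestRecord:
    """Per-variant marginal epistasis test result."""

    k: int
    sigma2_hat: float
    se: float
    p_normal: float
    p_davies: float | None
    p_final: float
    method: str  # normal | davies | saddlepoint | satterthwaite
    flags: tuple[str, ...] = ()


@dataclasses.dataclass(frozen=True)
class NullFit:
    """Two-component moment fit (omega^2, tau^2) under H0: sigma^2 = 0."""

    omega0_sq: float
    tau0_sq: float


def normal_test(sigma2_hat: float, se: float) -> float:
    """Two-sided z-test p-value, p = 2 Phi(-|sigma2_hat / se|)."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        return 1.0 if sigma2_hat == 0 else 0.0
    return 2.0 * stats.norm.sf(abs(sigma2_hat) / se)


def null_fit(cs: ComponentSet) -> NullFit:
    """Fit (omega0^2, tau0^2) from the two-component system (K_k^*, M_k)."""
    S1, _, M = cs.components()
    y = cs.y_star
    tr1 = float(np.trace(S1))
    S0 = np.array([[float(np.sum(S1 * S1)), tr1], [tr1, cs.df]])
    q0 = np.array([float(y @ (S1 @ y)), float(y @ y)])
    if np.linalg.cond(S0) > 1e12:
        sol = np.linalg.pinv(S0) @ q0
    else:
        sol = np.linalg.solve(S0, q0)
    return NullFit(omega0_sq=float(sol[0]), tau0_sq=float(sol[1]))


def _mixture_weights(Sigma1, Sigma3, H, nf: NullFit):
    A = nf.omega0_sq * Sigma1 + nf.tau0_sq * Sigma3
    d, U = np.linalg.eigh(A)
    d = np.maximum(d, 0.0)  # clamp tiny negative eigenvalues for the sqrt
    keep = d > EIG_RTOL * max(d[-1], 1e-300)
    if not keep.any():
        return np.zeros(0)
    W = U[:, keep] * np.sqrt(d[keep])
    T = W.T @ (H @ W)
    lam = np.linalg.eigvalsh(T)
    lam_max = np.abs(lam).max(initial=0.0)
    lam = lam[np.abs(lam) > EIG_RTOL * max(lam_max, 1e-300)]
    # trace identity: sum of weights == trace(A H), asserted on every call
    tr_AH = float(np.sum(A * H))
    if lam.size and not np.isclose(lam.sum(), tr_AH,
                                   rtol=1e-6, atol=1e-8 * max(1.0, abs(tr_AH))):
        raise AssertionError("mixture weights violate the trace identity")
    return lam


def null_mixture_weights(cs: ComponentSet, nf: NullFit,
                         davies_h: str = "sigma2") -> np.ndarray:
    """Eigenvalues of A^{1/2} H A^{1/2} defining the null mixture.

    ``davies_h`` selects which component's quadratic-form matrix H is
    used: ``"sigma2"`` (default, the tested component) or ``"literal"``
    (the first component).
    """
    fit = mqs_estimate(cs)
    S_inv = np.linalg.pinv(fit.S)
    idx = {"sigma2": 1, "literal": 0}[davies_h]
    H = h_matrix(cs, S_inv, idx)
    return _mixture_weights(cs.Sigma1, cs.Sigma3, H, nf)


def quadform_tail(weights, q_obs: float, accuracy: float = 1e-9) -> float:
    """Pr(sum_i lambda_i chi^2_{1,i} > q_obs) by Imhof integration.

    Exact (to the requested absolute accuracy) characteristic-function
    inversion; supports negative weights.  May return a value <= 0 on
    numerical underflow in the extreme tail, in which case the caller
    should fall back to :func:`saddlepoint_tail`.
    """
    lam = np.asarray(weights, dtype=np.float64)
    lam = lam[lam != 0.0]
    if lam.size == 0:
        raise ValueError("need at least one nonzero mixture weight")

    # Imhof (1961): p = 1/2 + (1/pi) Int_0^inf sin(theta(u)) / (u rho(u)) du
    # with theta = (sum arctan(lam u) - q u)/2, rho = prod (1+lam^2 u^2)^(1/4).
    # The integrand decays only like u^(-1-m/2); integrating the head
    # directly and the tail as a Fourier integral (QUADPACK's cycle
    # summation, weight=cos/sin at frequency |q|/2) keeps the absolute
    # error near machine precision even for a single weight.
    scale = np.abs(lam).max()
    T = 5.0 / scale

    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def log_rho(u):
        return 0.25 * np.sum(np.log1p((lam * u) ** 2))

    def head(u):
        return np.sin(phi(u) - 0.5 * q_obs * u) * np.exp(-log_rho(u)) / u

    def g_sin(u):
        return np.sin(phi(u)) * np.exp(-log_rho(u)) / u

    def g_cos(u):
        return np.cos(phi(u)) * np.exp(-log_rho(u)) / u

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(head, 0.0, T, epsabs=accuracy,
                                epsrel=1e-10, limit=500)
        w = abs(q_obs) / 2.0
        if w > 0:
            t1, _ = integrate.quad(g_sin, T, np.inf, weight="cos", wvar=w, limit=500)
            t2, _ = integrate.quad(g_cos, T, np.inf, weight="sin", wvar=w, limit=500)
            val += t1 - np.sign(q_obs) * t2
        else:
            t1, _ = integrate.quad(g_sin, T, np.inf, epsabs=accuracy, limit=500)
            val += t1
    p = 0.5 + val / np.pi
    return min(p, 1.0)


def _cgf(lam, z):
    return -0.5 * np.sum(np.log1p(-2.0 * z * lam))


def saddlepoint_tail(weights, q_obs: float) -> float:
    """Kuonen's saddlepoint (Lugannani-Rice) tail approximation.

    Strictly positive even where the exact inversion underflows.  Falls
    back to Satterthwaite's scaled chi-square when the saddle equation
    cannot be solved (e.g. q_obs outside the support direction).
    """
    lam = np.asarray(weights, dtype=np.float64)
    lam = lam[lam != 0.0]
    if lam.size == 0:
        raise ValueError("need at least one nonzero mixture weight")
    lam_max, lam_min = lam.max(), lam.min()
    hi = 1.0 / (2.0 * lam_max) if lam_max > 0 else np.inf
    lo = 1.0 / (2.0 * lam_min) if lam_min < 0 else -np.inf

    mean = lam.sum()
    if abs(q_obs - mean) < 1e-12 * max(1.0, abs(mean)):
        return 0.5

    def kprime(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam))

    # K' is increasing on (lo, hi); bracket the saddle K'(z) = q_obs
    span = (hi if np.isfinite(hi) else 1.0) - (lo if np.isfinite(lo) else -1.0)
    a = lo + 1e-12 * span if np.isfinite(lo) else -1.0
    b = hi - 1e-12 * span if np.isfinite(hi) else 1.0
    if not np.isfinite(lo):
        while kprime(a) > q_obs:
            a *= 2.0
            if a < -1e12:
                return satterthwaite_tail(lam, q_obs)
    if not np.isfinite(hi):
        while kprime(b) < q_obs:
            b *= 2.0
            if b > 1e12:
                return satterthwaite_tail(lam, q_obs)
    try:
        zhat = optimize.brentq(lambda z: kprime(z) - q_obs, a, b, xtol=1e-14)
    except ValueError:
        return satterthwaite_tail(lam, q_obs)
    w = np.sign(zhat) * np.sqrt(max(2.0 * (zhat * q_obs - _cgf(lam, zhat)), 0.0))
    kpp = np.sum(2.0 * lam**2 / (1.0 - 2.0 * zhat * lam) ** 2)
    v = zhat * np.sqrt(kpp)
    if w == 0 or v == 0:
        return satterthwaite_tail(lam, q_obs)
    p = stats.norm.sf(w + np.log(v / w) / w)
    return float(min(max(p, 5e-324), 1.0))


def satterthwaite_tail(weights, q_obs: float) -> float:
    """Satterthwaite moment-matched scaled chi-square tail."""
    lam = np.asarray(weights, dtype=np.float64)
    s1, s2 = lam.sum(), np.sum(lam**2)
    if s2 == 0:
        return 1.0
    if s1 <= 0:
        # mixture mean non-positive: a positive q_obs is extreme by construction
        return 1.0 if q_obs <= s1 else 0.5
    g = s2 / s1
    h = s1**2 / s2
    return float(stats.chi2.sf(q_obs / g, h))


def _exact_pvalue(weights, q_obs, accuracy):
    """Imhof tail with saddlepoint/Satterthwaite fallbacks.

    Returns (p_davies_or_None, p_final, method, flags).
    """
    if weights.size == 0:
        return None, 1.0, "davies", ("degenerate_null",)
    try:
        p = quadform_tail(weights, q_obs, accuracy)
    except Exception:
        p = -1.0
    if p > 0:
        return p, p, "davies", ()
    try:
        p_sp = saddlepoint_tail(weights, q_obs)
        return None, p_sp, "saddlepoint", ("davies_underflow",)
    except Exception:
        p_sw = satterthwaite_tail(weights, q_obs)
        return None, p_sw, "satterthwaite", ("davies_underflow", "saddle_failed")


def davies_test(cs: ComponentSet, fit: MqsFit | None = None,
                davies_h: str = "sigma2", accuracy: float = 1e-9):
    """Exact mixture p-value for H0: sigma^2 = 0 on one component set."""
    if fit is None:
        fit = mqs_estimate(cs)
    nf = null_fit(cs)
    lam = null_mixture_weights(cs, nf, davies_h)
    return _exact_pvalue(lam, float(fit.delta_hat[1]), accuracy)


def hybrid_test(cs: ComponentSet, fit: MqsFit, threshold: float = 0.05,
                davies_h: str = "sigma2", accuracy: float = 1e-9) -> TestRecord:
    """Normal test by default; exact recomputation when p_normal < threshold."""
    if fit.var_hat is None:
        mqs_variance(cs, fit)
    sigma2 = float(fit.delta_hat[1])
    se = float(np.sqrt(fit.var_hat[1]))
    flags = fit.flags
    if se == 0:
        p_norm = 1.0 if sigma2 == 0 else 0.0
        flags = flags + ("zero_se",)
    else:
        p_norm = normal_test(sigma2, se)
    if p_norm >= threshold:
        return TestRecord(k=cs.k, sigma2_hat=sigma2, se=se, p_normal=p_norm,
                          p_davies=None, p_final=p_norm, method="normal",
                          flags=flags)
    p_dav, p_final, method, dflags = davies_test(cs, fit, davies_h, accuracy)
    return TestRecord(k=cs.k, sigma2_hat=sigma2, se=se, p_normal=p_norm,
                      p_davies=p_dav, p_final=p_final, method=method,
                      flags=flags + dflags)


# ---------------------------------------------------------------------------
# Fast per-variant scan
#
# The generic path above materializes three n x n matrices per variant.
# The scanner below exploits the algebraic structure instead: with
# standardized genotypes (column means 0, x^T x = n) the projection is
# M = I - (1 1^T + x x^T)/n, the projected additive kernel is an explicit
# rank-two correction of the precomputed background relatedness matrix P,
# and every moment-system entry reduces to a handful of matrix-vector
# products.  Per phenotype replicate each variant costs O(n) plus three
# P-matvecs; the O(n^3) eigendecomposition is only paid for variants that
# reach the exact test.  Agreement with the generic ComponentSet path is
# enforced by tests.
# ---------------------------------------------------------------------------


class MapitScanner:
    """Reusable scan state for one genotype panel.

    Precomputes all phenotype-independent quantities (background
    relatedness matrix, per-variant moment-matrix entries) so that many
    phenotypes can be scanned against the same panel cheaply.
    """

    def __init__(self, X: np.ndarray, variants=None, background=None,
                 exact_cache: bool = False, davies_h: str = "sigma2"):
        X = np.asarray(X, dtype=np.float64)
        self.X = X
        self.n, self.p = X.shape
        self.test_idx = np.arange(self.p) if variants is None else np.asarray(variants)
        self.bg = np.arange(self.p) if background is None else np.asarray(background)
        self._precompute()
        self._cache = None
        self._cache_h = davies_h
        if exact_cache:
            self._build_exact_cache(davies_h)

    def _precompute(self):
        X, n = self.X, self.n
        Xb = X[:, self.bg]
        p_bg = self.bg.size
        P = Xb @ Xb.T / p_bg
        self.P = P
        self.trP = float(np.trace(P))
        self.sumP2 = float(np.sum(P * P))
        bg_set = set(self.bg.tolist())

        m = self.test_idx.size
        self.W = P @ X[:, self.test_idx]          # n x m, columns w_k = P x_k
        self.a = np.empty(m)
        self.bcoef = np.empty(m)
        self.cc = np.empty(m)                     # c_k = x_k^T P x_k
        self.S_upper = np.empty((m, 3, 3))        # per-variant moment matrix

        ones = np.ones(n)
        for t, k in enumerate(self.test_idx):
            x = X[:, k]
            w = self.W[:, t]
            in_bg = k in bg_set
            if in_bg:
                if p_bg < 2:
                    raise ValueError("background of size < 2 including the focal variant")
                a = p_bg / (p_bg - 1)
                b = 1.0 / (p_bg - 1)
            else:
                a, b = 1.0, 0.0
            c = float(x @ w)
            self.a[t], self.bcoef[t], self.cc[t] = a, b, c

            # With K_k = a P - b x x^T and M x = 0, the x x^T part is
            # annihilated: Sigma1 = a (P - (x w^T + w x^T)/n + (c/n^2) x x^T),
            # kept implicit; b enters only through G_k below.
            ww = float(w @ w)
            trS1 = a * (self.trP - c / n)
            S11 = a * a * (self.sumP2 - 2.0 * ww / n + (c / n) ** 2)

            # Sigma2 = M G M with G = a (P o x x^T) - b z z^T, z = x o x
            z = x * x
            G = a * (P * np.outer(x, x)) - b * np.outer(z, z)
            gs = G @ ones
            gx = G @ x
            s1 = float(gs @ ones)
            sb = float(gs @ x)
            s3 = float(gx @ x)
            U = np.column_stack([ones, x])
            V1 = np.column_stack([gs, gx])
            A2 = np.array([[s1, sb], [sb, s3]])
            C = -V1 / n + (U @ A2) / (2.0 * n * n)
            Sigma2 = G + U @ C.T + C @ U.T
            trS2 = float(np.trace(Sigma2))
            S22 = float(np.sum(Sigma2 * Sigma2))
            S12 = a * float(np.sum(P * Sigma2))
            S = np.array([[S11, S12, trS1],
                          [S12, S22, trS2],
                          [trS1, trS2, float(n - 2)]])
            self.S_upper[t] = S

    # -- per-variant dense reconstruction (exact-test path) -----------------

    def _dense(self, t: int):
        n = self.n
        x = self.X[:, self.test_idx[t]]
        w = self.W[:, t]
        a, b, c = self.a[t], self.bcoef[t], self.cc[t]
        ones = np.ones(n)
        Sigma1 = a * (self.P - (np.outer(x, w) + np.outer(w, x)) / n
                      + (c / n**2) * np.outer(x, x))
        z = x * x
        G = a * (self.P * np.outer(x, x)) - b * np.outer(z, z)
        gs, gx = G @ ones, G @ x
        A2 = np.array([[float(gs @ ones), float(gs @ x)],
                       [float(gs @ x), float(gx @ x)]])
        U = np.column_stack([ones, x])
        C = -np.column_stack([gs, gx]) / n + (U @ A2) / (2.0 * n * n)
        Sigma2 = G + U @ C.T + C @ U.T
        M = np.eye(n) - (np.outer(ones, ones) + np.outer(x, x)) / n
        return Sigma1, Sigma2, M

    def _project(self, u, x):
        return u - (u.sum() / self.n) - x * float(x @ u) / self.n

    def _build_exact_cache(self, davies_h: str = "sigma2"):
        """Precompute per-variant spectral structure for repeated exact tests.

        In an orthonormal basis Q of range(M_k) the projection is the
        identity, so with Sigma1 = Q Vt diag(kappa) Vt^T Q^T the null
        covariance is A = Q Vt diag(omega0^2 kappa + tau0^2) Vt^T Q^T and
        the mixture weights reduce to the eigenvalues of
        diag(s) W diag(s), s = sqrt(max(omega0^2 kappa + tau0^2, 0)),
        W = Vt^T Q^T H Q Vt.  kappa and W depend only on the genotypes,
        so scanning many phenotypes against one panel costs a single
        symmetric eigenvalue problem per (variant, phenotype).
        """
        idx = {"sigma2": 1, "literal": 0}[davies_h]
        cache = []
        ones = np.ones(self.n)
        for t in range(self.test_idx.size):
            x = self.X[:, self.test_idx[t]]
            Sigma1, Sigma2, M = self._dense(t)
            S_inv = np.linalg.pinv(self.S_upper[t])
            H = S_inv[idx, 0] * Sigma1 + S_inv[idx, 1] * Sigma2 + S_inv[idx, 2] * M
            Qfull, _ = np.linalg.qr(np.column_stack([ones, x]), mode="complete")
            Q = Qfull[:, 2:]
            kappa, Vt = np.linalg.eigh(Q.T @ (Sigma1 @ Q))
            W = Vt.T @ (Q.T @ (H @ Q) @ Vt)
            cache.append((np.maximum(kappa, 0.0), W))
        self._cache = cache

    def _cached_weights(self, t: int, nf: NullFit):
        kappa, W = self._cache[t]
        s2 = np.maximum(nf.omega0_sq * kappa + nf.tau0_sq, 0.0)
        s = np.sqrt(s2)
        T = W * np.outer(s, s)
        lam = np.linalg.eigvalsh(T)
        lam_max = np.abs(lam).max(initial=0.0)
        lam = lam[np.abs(lam) > EIG_RTOL * max(lam_max, 1e-300)]
        tr = float(s2 @ np.diag(W))
        if lam.size and not np.isclose(lam.sum(), tr, rtol=1e-6,
                                       atol=1e-8 * max(1.0, abs(tr))):
            raise AssertionError("mixture weights violate the trace identity")
        return lam

    def _fast_weights(self, t: int, H: np.ndarray, nf: NullFit):
        """Null mixture weights via Cholesky instead of two eigh calls.

        The null covariance factors as A = M B M with
        B = omega0^2 K_k + tau0^2 I, and H satisfies H = M H M, so the
        nonzero eigenvalues of A^{1/2} H A^{1/2} equal those of
        L^T H L with B = L L^T.  Only valid when B is positive definite
        (omega0^2 >= 0); returns None otherwise so the caller can fall
        back to the eigendecomposition path with clamping.
        """
        if nf.omega0_sq < 0 or nf.tau0_sq <= 0:
            return None
        x = self.X[:, self.test_idx[t]]
        a, b = self.a[t], self.bcoef[t]
        B = (nf.omega0_sq * a) * self.P
        if b != 0.0:
            B -= (nf.omega0_sq * b) * np.outer(x, x)
        B[np.diag_indices_from(B)] += nf.tau0_sq
        try:
            L = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return None
        T = L.T @ (H @ L)
        lam = np.linalg.eigvalsh(T)
        lam_max = np.abs(lam).max(initial=0.0)
        lam = lam[np.abs(lam) > EIG_RTOL * max(lam_max, 1e-300)]
        tr_BH = float(np.sum(B * H))
        if lam.size and not np.isclose(lam.sum(), tr_BH, rtol=1e-6,
                                       atol=1e-8 * max(1.0, abs(tr_BH))):
            raise AssertionError("mixture weights violate the trace identity")
        return lam

    def scan(self, y: np.ndarray, mode: str = "hybrid", threshold: float = 0.05,
             davies_h: str = "sigma2", accuracy: float = 1e-9) -> list[TestRecord]:
        """Test every configured variant against one phenotype."""
        if mode not in ("normal", "davies", "hybrid"):
            raise ValueError(f"unknown mode {mode!r}")
        y = np.asarray(y, dtype=np.float64)
        n = self.n
        yc = y - y.mean()
        v = self.P @ yc
        yv = float(yc @ v)
        records = []
        for t, k in enumerate(self.test_idx):
            x = self.X[:, k]
            w = self.W[:, t]
            a, b, c = self.a[t], self.bcoef[t], self.cc[t]
            gamma = float(x @ yc) / n
            ystar = yc - gamma * x
            q3 = float(ystar @ ystar)
            q1 = a * (yv - 2.0 * gamma * float(w @ yc) + gamma * gamma * c)
            z = x * x
            txy = x * ystar
            Pt = self.P @ txy
            zy = float(z @ ystar)
            q2 = a * float(txy @ Pt) - b * zy * zy

            S = self.S_upper[t]
            q = np.array([q1, q2, q3])
            flags: tuple[str, ...] = ()
            if np.linalg.cond(S) > 1e12:
                S_inv = np.linalg.pinv(S)
                flags = ("singular_S",)
            else:
                S_inv = np.linalg.inv(S)
            delta = S_inv @ q
            sigma2 = float(delta[1])

            # variance of the sigma^2 estimate
            Pys = v - gamma * w
            S1y = a * (Pys - x * (float(w @ ystar) / n))
            Gy = a * (x * Pt) - b * z * zy
            S2y = self._project(Gy, x)
            r = S_inv[1]
            h = r[0] * S1y + r[1] * S2y + r[2] * ystar
            Ph = self.P @ h
            S1h = a * (Ph - x * (float(w @ h) / n))
            Gh = a * (x * (self.P @ (x * h))) - b * z * float(z @ h)
            S2h = self._project(Gh, x)
            var2 = 2.0 * (delta[0] * float(h @ S1h) + delta[1] * float(h @ S2h)
                          + delta[2] * float(h @ h))
            if var2 < 0:
                var2 = 0.0
                flags = flags + ("clamped_variance",)
            se = float(np.sqrt(var2))
            if se == 0:
                p_norm = 1.0 if sigma2 == 0 else 0.0
                flags = flags + ("zero_se",)
            else:
                p_norm = normal_test(sigma2, se)

            need_exact = mode == "davies" or (mode == "hybrid" and p_norm < threshold)
            if not need_exact:
                records.append(TestRecord(k=int(k), sigma2_hat=sigma2, se=se,
                                          p_normal=p_norm, p_davies=None,
                                          p_final=p_norm, method="normal",
                                          flags=flags))
                continue

            tr1 = S[0, 2]
            S0 = np.array([[S[0, 0], tr1], [tr1, float(n - 2)]])
            q0 = np.array([q1, q3])
            sol = (np.linalg.pinv(S0) @ q0 if np.linalg.cond(S0) > 1e12
                   else np.linalg.solve(S0, q0))
            nf = NullFit(omega0_sq=float(sol[0]), tau0_sq=float(sol[1]))
            if self._cache is not None and davies_h == self._cache_h:
                lam = self._cached_weights(t, nf)
            else:
                Sigma1, Sigma2, M = self._dense(t)
                idx = {"sigma2": 1, "literal": 0}[davies_h]
                H = (S_inv[idx, 0] * Sigma1 + S_inv[idx, 1] * Sigma2
                     + S_inv[idx, 2] * M)
                lam = self._fast_weights(t, H, nf)
                if lam is None:
                    lam = _mixture_weights(Sigma1, M, H, nf)
            p_dav, p_final, method, dflags = _exact_pvalue(lam, sigma2, accuracy)
            records.append(TestRecord(k=int(k), sigma2_hat=sigma2, se=se,
                                      p_normal=p_norm, p_davies=p_dav,
                                      p_final=p_final, method=method,
                                      flags=flags + dflags))
        return records


def mapit_scan(X, y, mode: str = "hybrid", background=None, covariates=None,
               variants=None, threshold: float = 0.05,
               davies_h: str = "sigma2", accuracy: float = 1e-9) -> list[TestRecord]:
    """Marginal epistasis scan: one TestRecord per tested variant.

    ``X`` may be a GenotypeMatrix or a standardized n x p array; ``y`` a
    Phenotype or n-vector.  ``background`` restricts the variants that
    form the relatedness matrices; ``variants`` restricts which variants
    are tested.  With ``covariates`` the projection removes them along
    with the intercept and the focal genotype (generic per-variant path).
    Results are independent of variant processing order; per-variant
    numerical failures are isolated into record flags.
    """
    Xs = X.standardized if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y, float)
    if Xs.shape[0] != yv.size:
        raise ValueError("genotype and phenotype sample counts differ")

    if covariates is not None:
        idx = np.arange(Xs.shape[1]) if variants is None else np.asarray(variants)
        records = []
        for k in idx:
            cs = build_component_set(Xs, yv, int(k), background=background,
                                     covariates=covariates)
            fit = mqs_estimate(cs)
            if mode == "normal":
                mqs_variance(cs, fit)
                sigma2 = float(fit.delta_hat[1])
                se = float(np.sqrt(fit.var_hat[1]))
                p = normal_test(sigma2, se) if se > 0 else (1.0 if sigma2 == 0 else 0.0)
                records.append(TestRecord(k=int(k), sigma2_hat=sigma2, se=se,
                                          p_normal=p, p_davies=None, p_final=p,
                                          method="normal", flags=fit.flags))
            else:
                eff_threshold = 1.1 if mode == "davies" else threshold
                records.append(hybrid_test(cs, fit, eff_threshold, davies_h, accuracy))
        return records

    scanner = MapitScanner(Xs, variants=variants, background=background)
    return scanner.scan(yv, mode=mode, threshold=threshold,
                        davies_h=davies_h, accuracy=accuracy)
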