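import numpy as np
import pytest
from scipy import stats

from mapit import (
    MapitScanner,
    build_component_set,
    hybrid_test,
    mapit_scan,
    mqs_estimate,
    normal_test,
    null_fit,
    null_mixture_weights,
    quadform_tail,
    saddlepoint_tail,
    satterthwaite_tail,
    simulate_genotypes,
)
from mapit.testing import davies_test


class TestNormalTest:
    @pytest.mark.parametrize("stat,se,expected", [
        (0.0, 1.0, 1.0),
        (1.959964, 1.0, 0.05),
        (-1.959964, 1.0, 0.05),
    ])
    def test_quantiles(self, stat, se, expected):
        assert np.isclose(normal_test(stat, se), expected, atol=1e-6)

    def test_zero_se_contract(self):
        assert normal_test(0.5, 0.0) == 0.0
        assert normal_test(0.0, 0.0) == 1.0


class TestQuadformTail:
    def test_chi2_closed_forms(self):
        assert abs(quadform_tail([1.0], 3.841459) - stats.chi2.sf(3.841459, 1)) < 1e-6
        assert abs(quadform_tail([1.0, 1.0], 5.991465) - stats.chi2.sf(5.991465, 2)) < 1e-6

    def test_monte_carlo_tail(self):
        w = np.array([0.6, 0.3, 0.1])
        rng = np.random.default_rng(3)
        draws = (w * rng.chisquare(1, size=(10**6, 3))).sum(axis=1)
        q95 = np.quantile(draws, 0.95)
        assert abs(quadform_tail(w, q95) - 0.05) < 1e-3

    def test_negative_weights_supported(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(-0.3, 1.0, size=25)
        draws = (w * rng.chisquare(1, size=(10**6, 25))).sum(axis=1)
        q = np.quantile(draws, 0.99)
        assert abs(quadform_tail(w, q) - 0.01) < 1e-3

    def test_monotone_in_q(self):
        w = [0.5, 0.3, 0.2]
        qs = np.linspace(-1, 8, 25)
        ps = [quadform_tail(w, q) for q in qs]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


class TestSaddlepointTail:
    def test_chi2_1_limit(self):
        # Lugannani-Rice is accurate to ~2e-3 at the chi-square-1 5% point
        assert abs(saddlepoint_tail([1.0], 3.841459) - 0.05) < 2e-3

    def test_agreement_with_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            w = rng.uniform(0.05, 1.0, size=rng.integers(3, 30))
            q = w.sum() + rng.uniform(1, 6) * np.sqrt(2 * (w**2).sum())
            exact = quadform_tail(w, q)
            if 1e-6 < exact < 0.1:
                assert abs(saddlepoint_tail(w, q) / exact - 1) < 0.10

    def test_positive_when_exact_underflows(self):
        w = np.ones(5) * 0.1
        p = saddlepoint_tail(w, 600.0)
        assert p > 0

    def test_satterthwaite_moment_match(self):
        w = [1.0, 1.0]
        assert abs(satterthwaite_tail(w, 5.991465) - 0.05) < 1e-6


def _null_cs(n=80, p=60, seed=0, k=3):
    panel = simulate_genotypes(n, p, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y = rng.standard_normal(n)
    return build_component_set(panel.standardized, y, k), panel, y


class TestNullFit:
    def test_zero_phenotype(self):
        import dataclasses

        cs, *_ = _null_cs()
        cs = dataclasses.replace(cs, y_star=np.zeros(cs.n))
        nf = null_fit(cs)
        assert nf.omega0_sq == 0.0 and nf.tau0_sq == 0.0

    def test_matches_restricted_system(self):
        cs, *_ = _null_cs()
        nf = null_fit(cs)
        S1, _, M = cs.components()
        y = cs.y_star
        S = np.array([[np.sum(S1 * S1), np.trace(S1)],
                      [np.trace(S1), np.trace(M)]])
        q = np.array([y @ S1 @ y, y @ y])
        sol = np.linalg.solve(S, q)
        assert np.allclose([nf.omega0_sq, nf.tau0_sq], sol, rtol=1e-10)

    def test_pure_noise_recovery(self):
        """Over replicates, omega0 ~ 0 and tau0 ~ Var(y) for unstructured noise."""
        import dataclasses

        cs0, panel, _ = _null_cs(n=120, p=80)
        rng = np.random.default_rng(9)
        oms, taus = [], []
        for _ in range(200):
            y = rng.standard_normal(panel.n)
            cs = dataclasses.replace(cs0, y_star=cs0.Sigma3 @ y)
            nf = null_fit(cs)
            oms.append(nf.omega0_sq)
            taus.append(nf.tau0_sq)
        assert abs(np.mean(oms)) < 3 * np.std(oms) / np.sqrt(200)
        assert abs(np.mean(taus) - 1.0) < 3 * np.std(taus) / np.sqrt(200) + 0.05


class TestMixtureWeights:
    def test_dense_oracle(self):
        cs, *_ = _null_cs(n=40, p=50)
        nf = null_fit(cs)
        lam = null_mixture_weights(cs, nf)
        # dense reconstruction of A^{1/2} H A^{1/2}
        fit = mqs_estimate(cs)
        S_inv = np.linalg.pinv(fit.S)
        H = sum(S_inv[1, j] * Sig for j, Sig in enumerate(cs.components()))
        A = nf.omega0_sq * cs.Sigma1 + nf.tau0_sq * cs.Sigma3
        w, U = np.linalg.eigh(A)
        root = U * np.sqrt(np.maximum(w, 0.0))
        dense = np.linalg.eigvalsh(root.T @ H @ root)
        dense = dense[np.abs(dense) > 1e-8 * np.abs(dense).max()]
        assert np.allclose(np.sort(lam), np.sort(dense), rtol=1e-6, atol=1e-10)

    def test_weights_sum_to_trace(self):
        cs, *_ = _null_cs(n=50, p=40, seed=2)
        nf = null_fit(cs)
        lam = null_mixture_weights(cs, nf)
        fit = mqs_estimate(cs)
        S_inv = np.linalg.pinv(fit.S)
        H = sum(S_inv[1, j] * Sig for j, Sig in enumerate(cs.components()))
        A = nf.omega0_sq * cs.Sigma1 + nf.tau0_sq * cs.Sigma3
        assert np.isclose(lam.sum(), np.sum(A * H), rtol=1e-6)


class TestHybridProcedure:
    def test_normal_branch_above_threshold(self):
        cs, *_ = _null_cs(seed=6)
        fit = mqs_estimate(cs)
        rec = hybrid_test(cs, fit, threshold=1e-12)
        assert rec.method == "normal"
        assert rec.p_final == rec.p_normal

    def test_exact_branch_below_threshold(self):
        cs, *_ = _null_cs(seed=6)
        fit = mqs_estimate(cs)
        rec = hybrid_test(cs, fit, threshold=1.0)
        assert rec.method in ("davies", "saddlepoint", "satterthwaite")
        assert rec.p_davies is None or rec.p_davies == rec.p_final

    def test_hybrid_equals_davies_when_triggered(self):
        panel = simulate_genotypes(70, 50, seed=8)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(70)
        hyb = mapit_scan(panel.standardized, y, mode="hybrid", threshold=0.5)
        dav = mapit_scan(panel.standardized, y, mode="davies")
        for h, d in zip(hyb, dav):
            if h.p_normal < 0.5:
                assert np.isclose(h.p_final, d.p_final, rtol=1e-8)


class TestScanConsistency:
    def test_fast_path_matches_component_set_path(self):
        from mapit.mqs import mqs_variance

        panel = simulate_genotypes(60, 45, seed=13)
        rng = np.random.default_rng(13)
        y = rng.standard_normal(60)
        recs = mapit_scan(panel.standardized, y, mode="davies")
        for k in (0, 11, 44):
            cs = build_component_set(panel.standardized, y, k)
            fit = mqs_estimate(cs)
            mqs_variance(cs, fit)
            ref = hybrid_test(cs, fit, threshold=1.1)
            assert np.isclose(recs[k].sigma2_hat, fit.delta_hat[1], rtol=1e-8)
            assert np.isclose(recs[k].se, np.sqrt(fit.var_hat[1]), rtol=1e-6)
            assert np.isclose(recs[k].p_final, ref.p_final, rtol=1e-6)

    def test_cached_exact_path_matches(self):
        panel = simulate_genotypes(50, 40, seed=14)
        rng = np.random.default_rng(14)
        y = rng.standard_normal(50)
        plain = MapitScanner(panel.standardized).scan(y, mode="davies")
        cached = MapitScanner(panel.standardized, exact_cache=True).scan(y, mode="davies")
        for a, b in zip(plain, cached):
            assert np.isclose(a.p_final, b.p_final, rtol=1e-6)

    def test_sample_permutation_equivariance(self):
        panel = simulate_genotypes(40, 30, seed=15)
        rng = np.random.default_rng(15)
        y = rng.standard_normal(40)
        perm = rng.permutation(40)
        r1 = mapit_scan(panel.standardized, y, mode="normal")
        r2 = mapit_scan(panel.standardized[perm], y[perm], mode="normal")
        p1 = np.array([r.p_final for r in r1])
        p2 = np.array([r.p_final for r in r2])
        assert np.allclose(p1, p2, rtol=1e-8)

    def test_variant_subset(self):
        panel = simulate_genotypes(40, 30, seed=16)
        rng = np.random.default_rng(16)
        y = rng.standard_normal(40)
        full = mapit_scan(panel.standardized, y, mode="normal")
        sub = mapit_scan(panel.standardized, y, mode="normal", variants=[3, 17])
        assert [r.k for r in sub] == [3, 17]
        assert np.isclose(sub[0].p_final, full[3].p_final)
        assert np.isclose(sub[1].p_final, full[17].p_final)

    def test_covariate_projection_removes_confounder(self):
        """A strong covariate effect is absorbed by the projection: the
        covariate-adjusted scan matches a scan of the unconfounded trait."""
        panel = simulate_genotypes(50, 30, seed=17)
        rng = np.random.default_rng(17)
        y = rng.standard_normal(50)
        covar = rng.standard_normal(50)
        rec_adj = mapit_scan(panel.standardized, y + 5 * covar,
                             covariates=covar[:, None], mode="normal", variants=[2])
        rec_clean = mapit_scan(panel.standardized, y,
                               covariates=covar[:, None], mode="normal", variants=[2])
        assert np.isclose(rec_adj[0].sigma2_hat, rec_clean[0].sigma2_hat, rtol=1e-8)

    def test_background_subset_scan(self):
        panel = simulate_genotypes(40, 30, seed=18)
        rng = np.random.default_rng(18)
        y = rng.standard_normal(40)
        bg = np.arange(15)
        rec = mapit_scan(panel.standardized, y, mode="normal",
                         background=bg, variants=[2, 20])
        from mapit.mqs import mqs_variance

        for r in rec:
            cs = build_component_set(panel.standardized, y, r.k, background=bg)
            fit = mqs_estimate(cs)
            mqs_variance(cs, fit)
            assert np.isclose(r.sigma2_hat, fit.delta_hat[1], rtol=1e-8)


class TestDaviesFallbacks:
    def test_davies_zero_triggers_saddlepoint(self):
        """An extreme observed statistic drives the inversion below zero and
        the record must fall back to a strictly positive p-value."""
        cs, *_ = _null_cs(n=60, p=50, seed=20)
        fit = mqs_estimate(cs)
        # inflate the statistic far into the tail
        fit.delta_hat = fit.delta_hat.copy()
        fit.delta_hat[1] = 1e4
        p_dav, p_final, method, flags = davies_test(cs, fit)
        assert p_final > 0
        if method != "davies":
            assert "davies_underflow" in flags
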