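"""EM multi-SNP fit: every update checked against independent numeric oracles."""

import numpy as np
import pytest
from scipy import integrate, linalg, optimize

from memlgwas import (MEMLConfig, a_matrix, e_step_polygenic, e_step_scales, fit_meml,
                      m_step, observed_log_posterior, snp_heritability)
from memlgwas.meml import MEMLError, MEMLState

from conftest import founder_pedigree, full_sib_pedigree, random_panel


def make_instance(seed, n, p, beta=None, sigma=1.0):
    """Small seeded instance on a two-family pedigree."""
    rng = np.random.default_rng(seed)
    n_fam = max(2, n // 8)
    ped = full_sib_pedigree(n_fam, -(-n // n_fam))
    A = a_matrix(ped).submatrix([f"i{k + 1}" for k in range(n)])
    panel = random_panel(rng, n, p)
    X = panel.genotypes
    if beta is None:
        beta = rng.normal(0, 0.5, p) * rng.integers(0, 2, p)
    y = 1.0 + X @ beta + rng.normal(0, sigma, n)
    return y, X, A, rng


def random_state(rng, n, p):
    return MEMLState(
        mu=float(rng.normal()), gamma=rng.normal(0, 0.4, p),
        tau2=np.ones(p), lambda2=rng.uniform(0.5, 4.0, p),
        sigma_g2=float(rng.uniform(0.3, 1.5)), sigma_e2=float(rng.uniform(0.3, 1.5)),
        g_hat=np.zeros(n))


class TestScaleExpectations:
    def gig_moments(self, gamma, lam2):
        """Quadrature oracle for the latent-scale conditional (GIG density)."""
        def dens(t):
            return t ** -0.5 * np.exp(-gamma**2 / (2 * t) - lam2 * t / 2)
        upper = 40.0 / lam2 + 10 * abs(gamma)
        z, _ = integrate.quad(dens, 0, upper, limit=200)
        m1, _ = integrate.quad(lambda t: t * dens(t), 0, upper, limit=200)
        mneg, _ = integrate.quad(lambda t: dens(t) / t, 0, upper, limit=200,
                                 points=[abs(gamma) ** 2 / 10 + 1e-12])
        return mneg / z, m1 / z

    @pytest.mark.parametrize("gamma,lam2", [
        (1.0, 4.0), (0.3, 1.0), (-0.7, 2.5), (2.0, 0.3), (0.05, 9.0)])
    def test_closed_forms_match_quadrature(self, gamma, lam2):
        e_inv, e_tau2 = e_step_scales(gamma, lam2)
        o_inv, o_tau2 = self.gig_moments(gamma, lam2)
        assert float(e_inv) == pytest.approx(o_inv, rel=1e-6)
        assert float(e_tau2) == pytest.approx(o_tau2, rel=1e-6)

    def test_stated_example(self):
        e_inv, _ = e_step_scales(1.0, 4.0)
        assert float(e_inv) == pytest.approx(2.0)

    def test_sign_symmetry(self):
        assert e_step_scales(0.8, 2.0) == e_step_scales(-0.8, 2.0)

    def test_large_gamma_limit(self):
        e_inv, _ = e_step_scales(1e9, 1.0)
        assert float(e_inv) < 1e-8

    def test_zero_gamma_guard(self):
        e_inv, _ = e_step_scales(0.0, 4.0)
        assert float(e_inv) == pytest.approx(2.0 / 1e-12)

    def test_nonpositive_lambda2_rejected(self):
        with pytest.raises(MEMLError):
            e_step_scales(1.0, 0.0)


class TestPolygenicEStep:
    def test_matches_dense_solve(self):
        """n = 8 instance vs direct dense linear algebra, 1e-10."""
        y, X, A, rng = make_instance(3, 8, 2)
        st = random_state(rng, 8, 2)
        g_hat, v_g = e_step_polygenic(st, y, X, A)
        V = st.sigma_g2 * A.values + st.sigma_e2 * np.eye(8)
        r = y - st.mu - X @ st.gamma
        g_oracle = st.sigma_g2 * A.values @ np.linalg.solve(V, r)
        v_oracle = (st.sigma_g2 * A.values
                    - st.sigma_g2 * A.values @ np.linalg.solve(V, st.sigma_g2 * A.values))
        assert np.allclose(g_hat, g_oracle, atol=1e-10)
        assert np.allclose(v_g, v_oracle, atol=1e-10)

    def test_zero_polygenic_variance(self):
        y, X, A, rng = make_instance(4, 8, 2)
        st = random_state(rng, 8, 2)
        st.sigma_g2 = 0.0
        g_hat, v_g = e_step_polygenic(st, y, X, A)
        assert np.all(g_hat == 0) and np.all(v_g == 0)

    def test_small_residual_variance_limit(self):
        y, X, A, rng = make_instance(5, 10, 2)
        A_id = a_matrix(founder_pedigree(10))
        A_id.id_order = A.id_order
        st = random_state(rng, 10, 2)
        st.sigma_e2 = 1e-12
        g_hat, _ = e_step_polygenic(st, y, X, A_id)
        r = y - st.mu - X @ st.gamma
        assert np.allclose(g_hat, r, atol=1e-6)


class TestMStepArgmaxOracle:
    """Each block update must equal the numeric argmax of its Q-function block."""

    def q_function(self, mu, gamma, lam2, sg2, se2, exps, y, X, A, cfg):
        n = y.size
        resid = y - mu - X @ gamma - exps["g_hat"]
        q = (-(n / 2) * np.log(se2)
             - (resid @ resid + exps["v_g_trace"]) / (2 * se2)
             - np.log(se2))
        if sg2 > 0:
            q += (-(n / 2) * np.log(sg2)
                  - (exps["g_ainv_quad"] + exps["v_g_ainv_trace"]) / (2 * sg2))
        q += np.sum(-0.5 * gamma**2 * exps["e_inv_tau2"])
        q += np.sum((1 + cfg.a) * np.log(lam2) - (cfg.b + exps["e_tau2"] / 2) * lam2)
        return q

    def expectations(self, st, y, X, A):
        g_hat, v_g = e_step_polygenic(st, y, X, A)
        a_inv = np.linalg.inv(A.values)
        e_inv_tau2, e_tau2 = e_step_scales(st.gamma, st.lambda2)
        return {"g_hat": g_hat, "v_g_trace": float(np.trace(v_g)),
                "v_g_ainv_trace": float(np.trace(a_inv @ v_g)),
                "g_ainv_quad": float(g_hat @ a_inv @ g_hat),
                "e_inv_tau2": e_inv_tau2, "e_tau2": e_tau2}

    def argmax_1d(self, f, x0):
        span = max(abs(x0), 1e-3)
        res = optimize.minimize_scalar(lambda t: -f(t),
                                       bounds=(x0 - 10 * span, x0 + 10 * span),
                                       method="bounded",
                                       options={"xatol": 1e-12})
        return res.x

    def argmax_pos(self, f, x0):
        res = optimize.minimize_scalar(lambda t: -f(np.exp(t)),
                                       bounds=(np.log(x0) - 8, np.log(x0) + 8),
                                       method="bounded", options={"xatol": 1e-13})
        return float(np.exp(res.x))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_blocks_match_numeric_argmax(self, seed):
        n, p = 12, 3
        y, X, A, rng = make_instance(seed, n, p)
        st = random_state(rng, n, p)
        cfg = MEMLConfig()
        exps = self.expectations(st, y, X, A)
        upd = m_step(st, exps, y, X, A, cfg)

        # mu: maximized first, with the old gamma
        mu_hat = self.argmax_1d(
            lambda m: self.q_function(m, st.gamma, st.lambda2, st.sigma_g2,
                                      st.sigma_e2, exps, y, X, A, cfg), upd["mu"])
        assert upd["mu"] == pytest.approx(mu_hat, rel=1e-6, abs=1e-8)

        # gamma: coordinate j maximized with the new mu, coordinates < j new
        gam = st.gamma.copy()
        for j in range(p):
            def qj(v, j=j):
                g = gam.copy()
                g[j] = v
                return self.q_function(upd["mu"], g, st.lambda2, st.sigma_g2,
                                       st.sigma_e2, exps, y, X, A, cfg)
            gj_hat = self.argmax_1d(qj, upd["gamma"][j])
            assert upd["gamma"][j] == pytest.approx(gj_hat, rel=1e-6, abs=1e-8)
            gam[j] = upd["gamma"][j]

        # lambda2 blocks (separable)
        for j in range(p):
            def ql(v, j=j):
                l2 = st.lambda2.copy()
                l2[j] = v
                return self.q_function(upd["mu"], upd["gamma"], l2, st.sigma_g2,
                                       st.sigma_e2, exps, y, X, A, cfg)
            assert upd["lambda2"][j] == pytest.approx(
                self.argmax_pos(ql, upd["lambda2"][j]), rel=1e-6)

        # variance blocks
        sg_hat = self.argmax_pos(
            lambda v: self.q_function(upd["mu"], upd["gamma"], upd["lambda2"], v,
                                      st.sigma_e2, exps, y, X, A, cfg), upd["sigma_g2"])
        assert upd["sigma_g2"] == pytest.approx(sg_hat, rel=1e-6)
        se_hat = self.argmax_pos(
            lambda v: self.q_function(upd["mu"], upd["gamma"], upd["lambda2"],
                                      upd["sigma_g2"], v, exps, y, X, A, cfg),
            upd["sigma_e2"])
        assert upd["sigma_e2"] == pytest.approx(se_hat, rel=1e-6)

    def test_lambda2_update_example(self):
        # a = b = 1e-6, E[tau2] = 2 -> (1 + 1e-6)/(1 + 1e-6) = 1
        n, p = 12, 3
        y, X, A, rng = make_instance(9, n, p)
        st = random_state(rng, n, p)
        cfg = MEMLConfig()
        exps = self.expectations(st, y, X, A)
        exps["e_tau2"] = np.full(p, 2.0)
        upd = m_step(st, exps, y, X, A, cfg)
        assert np.allclose(upd["lambda2"], 1.0, atol=1e-9)

    def test_unpenalized_sweep_equals_ols(self, rng):
        """E[1/tau2] = 0, orthonormal X, no polygenic part -> OLS solution."""
        n, p = 24, 4
        raw = rng.normal(size=(n, p))
        q_mat, _ = np.linalg.qr(raw - raw.mean(axis=0))
        beta = np.array([1.0, -2.0, 0.5, 0.0])
        y = q_mat @ beta + 0.1 * rng.normal(size=n)
        A = a_matrix(founder_pedigree(n))
        st = MEMLState(mu=0.0, gamma=np.zeros(p), tau2=np.ones(p),
                       lambda2=np.ones(p), sigma_g2=0.0, sigma_e2=1.0,
                       g_hat=np.zeros(n))
        exps = {"g_hat": np.zeros(n), "v_g_trace": 0.0, "v_g_ainv_trace": 0.0,
                "g_ainv_quad": 0.0, "e_inv_tau2": np.zeros(p),
                "e_tau2": np.ones(p)}
        upd = m_step(st, exps, y, q_mat, A, MEMLConfig(update_mu=False))
        ols = np.linalg.lstsq(q_mat, y - y @ np.zeros(n) if False else y, rcond=None)[0]
        assert np.allclose(upd["gamma"], ols, atol=1e-10)


class TestHeritability:
    from hypothesis import given, settings
    from hypothesis import strategies as hst

    @given(hst.floats(-5, 5), hst.floats(0, 1), hst.floats(0.01, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_sign_symmetry(self, gamma, p, vy):
        h2 = float(snp_heritability(gamma, p, vy))
        assert h2 >= 0.0
        assert h2 == pytest.approx(float(snp_heritability(-gamma, p, vy)))
        # the {1,0,-1} code variance is at most 1/2, at p = 1/2
        assert h2 <= 0.5 * gamma * gamma / vy + 1e-12

    @pytest.mark.parametrize("gamma,p,vy,expected", [
        (0.0, 0.5, 1.0, 0.0),
        (1.0, 1.0, 1.0, 0.0),       # monomorphic
        (1.0, 0.5, 4.0, 0.125),     # 2*0.25*1/4
    ])
    def test_formula(self, gamma, p, vy, expected):
        assert snp_heritability(gamma, p, vy) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(MEMLError):
            snp_heritability(1.0, 0.5, 0.0)
        with pytest.raises(MEMLError):
            snp_heritability(1.0, 1.5, 1.0)


class TestFitMEML:
    def test_pure_noise_fully_shrunk(self):
        """Null data: every effect collapses to (numerical) zero."""
        rng = np.random.default_rng(11)
        n, p = 200, 50
        ped = full_sib_pedigree(20, 10)
        A = a_matrix(ped).submatrix([f"i{k + 1}" for k in range(n)])
        panel = random_panel(rng, n, p)
        y = rng.normal(size=n)
        fit = fit_meml(y, None, A, MEMLConfig(), X=panel.genotypes)
        assert np.all(np.abs(fit.state.gamma) < 1e-4)
        assert np.all(fit.heritabilities < 1e-6)

    def test_single_qtl_recovery(self):
        """One 20%-variance QTL: mean recovered h2 within 0.05 over 20 seeds."""
        h2_hat = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, p = 500, 20
            ped = full_sib_pedigree(50, 10)
            A = a_matrix(ped).submatrix([f"i{k + 1}" for k in range(n)])
            panel = random_panel(rng, n, p)
            X = panel.genotypes
            beta = np.sqrt(0.2 / (2 * 0.5 * 0.5) / 0.8)  # h2 = 0.2 at p = 0.5
            y = 1.0 + X[:, 7] * beta + rng.normal(size=n)
            fit = fit_meml(y, None, A, MEMLConfig(max_iter=4000), X=X)
            assert np.argmax(fit.heritabilities) == 7
            h2_hat.append(fit.heritabilities[7])
        assert abs(np.mean(h2_hat) - 0.20) <= 0.05

    def test_infinite_tol_single_iteration(self):
        y, X, A, _ = make_instance(2, 16, 3)
        fit = fit_meml(y, None, A, MEMLConfig(tol=np.inf), X=X)
        assert fit.n_iterations == 1 and not fit.converged

    def test_scale_equivariance(self):
        """y -> c*y scales gamma by c and leaves h2 invariant."""
        beta = np.array([0.8, 0.0, -0.6, 0.0, 0.0, 0.0])
        y, X, A, _ = make_instance(6, 200, 6, beta=beta, sigma=0.5)
        cfg = MEMLConfig()
        f1 = fit_meml(y, None, A, cfg, X=X)
        c = 3.7
        f2 = fit_meml(c * y, None, A, cfg, X=X)
        nz = np.abs(f1.state.gamma) > 1e-8
        assert np.any(nz)
        # exact equivariance holds only in the a,b -> 0 limit (the hyperprior
        # fixes an absolute scale); deviations are O(a,b)
        assert np.allclose(f2.state.gamma[nz] / f1.state.gamma[nz], c, rtol=1e-4)
        assert np.allclose(f2.heritabilities, f1.heritabilities, atol=1e-5)

    def test_em_ascent_small_instances(self):
        """Observed-data log posterior non-decreasing on seeded small fits."""
        for seed in range(5):
            y, X, A, _ = make_instance(30 + seed, 16, 4)
            fit = fit_meml(y, None, A, MEMLConfig(max_iter=400), X=X)
            assert fit.objective_kind == "observed"
            assert np.all(np.diff(fit.objective_trace) >= -1e-8)

    def test_fixed_variance_map_matches_grid_oracle(self):
        """EM fixed point for gamma equals the marginal-posterior MAP (p = 2)."""
        rng = np.random.default_rng(77)
        n, p = 20, 2
        ped = full_sib_pedigree(4, 5)
        A = a_matrix(ped).submatrix([f"i{k + 1}" for k in range(n)])
        panel = random_panel(rng, n, p)
        X = panel.genotypes
        y = 1.0 + 1.5 * X[:, 0] - 1.2 * X[:, 1] + rng.normal(0, 0.3, n)
        cfg = MEMLConfig(update_mu=False, update_sigma_g2=False,
                         update_sigma_e2=False, max_iter=5000)
        fit = fit_meml(y - y.mean() + 1.0, None, A, cfg, X=X)
        st = fit.state

        def neg_post(g):
            return -observed_log_posterior(y - y.mean() + 1.0, X, A, st.mu,
                                           np.asarray(g), st.sigma_g2, st.sigma_e2,
                                           cfg.a, cfg.b)
        # 2-D grid + local refinement
        grid = np.linspace(-2.0, 2.0, 41)
        vals = [(neg_post([g1, g2]), g1, g2) for g1 in grid for g2 in grid]
        _, g1, g2 = min(vals)
        res = optimize.minimize(neg_post, [g1, g2], method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-12})
        assert np.allclose(st.gamma, res.x, atol=1e-4)

    def test_divergence_not_triggered_and_config_validation(self):
        with pytest.raises(MEMLError):
            MEMLConfig(a=0.0, b=0.0)
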