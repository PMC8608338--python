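import numpy as np
import pytest

from liureg import (
    DesignResponse,
    SimulationConfig,
    cell_seed,
    enumerate_factorial,
    estimate_d,
    fit_ols,
    generate_X,
    generate_beta,
    generate_y,
    liu_fit,
    run_cell,
    run_grid,
    spectral_decompose,
)
from liureg.simulation import CHUNK, DEFAULT_RULES


class TestGenerateX:
    def test_independent_columns_at_rho_zero(self, rng):
        corrs = []
        for _ in range(200):
            X = generate_X(1000, 4, 0.0, rng)
            c = np.corrcoef(X, rowvar=False)
            corrs.append(c[np.triu_indices(4, 1)])
        assert abs(np.mean(corrs)) < 0.01

    @pytest.mark.parametrize(
        "corr_mode,target", [("target_rho", 0.9), ("literal_rho_squared", 0.81)]
    )
    def test_population_pairwise_correlation(self, rng, corr_mode, target):
        X = generate_X(100_000, 4, 0.9, rng, corr_mode=corr_mode)
        c = np.corrcoef(X, rowvar=False)
        off = c[np.triu_indices(4, 1)]
        assert np.all(np.abs(off - target) < 0.005)

    def test_rho_out_of_range(self, rng):
        with pytest.raises(ValueError):
            generate_X(10, 2, 1.0, rng)


class TestGenerateBeta:
    def test_axis_aligned_spectrum(self):
        X = np.array([[3.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_allclose(generate_beta(X), [1.0, 0.0], atol=1e-12)

    def test_unit_norm_and_eigen_identity(self, rng):
        X = generate_X(50, 4, 0.95, rng)
        beta = generate_beta(X)
        G = X.T @ X
        lam_max = np.linalg.eigvalsh(G)[-1]
        assert np.linalg.norm(beta) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(G @ beta, lam_max * beta, atol=1e-8 * lam_max)

    def test_matches_unit_circle_grid_search(self, rng):
        X = generate_X(30, 2, 0.9, rng)
        G = X.T @ X
        theta = np.arange(0.0, np.pi, 1e-5)
        V = np.stack([np.cos(theta), np.sin(theta)])
        forms = np.einsum("it,ij,jt->t", V, G, V)
        v_star = V[:, np.argmax(forms)]
        beta = generate_beta(X)
        # same direction up to sign and grid resolution
        assert abs(abs(v_star @ beta) - 1.0) < 1e-8


class TestGenerateY:
    def test_noiseless_limit_recovers_beta(self, rng):
        X = generate_X(60, 3, 0.9, rng)
        beta = generate_beta(X)
        y = generate_y(X, beta, 1e-12, rng)
        fit = fit_ols(DesignResponse(X=X, y=y, intercept=False))
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-6)

    def test_deterministic_given_seed(self):
        X = generate_X(20, 2, 0.5, np.random.default_rng(3))
        beta = generate_beta(X)
        y1 = generate_y(X, beta, 1.0, np.random.default_rng(11))
        y2 = generate_y(X, beta, 1.0, np.random.default_rng(11))
        np.testing.assert_array_equal(y1, y2)

    def test_noise_moments(self, rng):
        X = generate_X(100_000, 2, 0.5, rng)
        beta = generate_beta(X)
        y = generate_y(X, beta, 1.5, rng)
        assert np.var(y - X @ beta) == pytest.approx(1.5**2, rel=0.02)

    def test_sigma_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            generate_y(np.ones((3, 1)), [1.0], 0.0, rng)


class TestRunCell:
    def test_matches_per_replication_loop_oracle(self):
        """The chunked engine must agree with a naive one-replication-at-a-time
        pipeline built from the public API, sharing only the random draws."""
        cfg = SimulationConfig(n=15, p=3, rho=0.9, sigma=1.0, M=64, seed=42)
        cell = run_cell(cfg)
        assert cell.retries == 0
        assert cfg.M <= CHUNK

        rng = np.random.default_rng(cfg.seed)
        z = rng.standard_normal((cfg.M, cfg.n, cfg.p + 1))
        eps = cfg.sigma * rng.standard_normal((cfg.M, cfg.n))
        a, b = np.sqrt(1 - cfg.rho), np.sqrt(cfg.rho)
        acc_se = {r: [] for r in DEFAULT_RULES}
        acc_ae = {r: [] for r in DEFAULT_RULES}
        for i in range(cfg.M):
            X = a * z[i, :, : cfg.p] + b * z[i, :, cfg.p :]
            beta = generate_beta(X)
            y = X @ beta + eps[i]
            data = DesignResponse(X=X, y=y, intercept=False)
            fit = fit_ols(data)
            spec = fit.spectral
            from liureg import ShrinkageInputs

            inp = ShrinkageInputs.from_fit(fit)
            for rule in DEFAULT_RULES:
                if rule == "OLS":
                    err = fit.beta_hat - beta
                else:
                    d = estimate_d(inp, rule).d
                    err = liu_fit(fit, spec, d).beta_liu - beta
                acc_se[rule].append(err @ err)
                acc_ae[rule].append(np.abs(err).sum())
        for rule in DEFAULT_RULES:
            assert cell.emse[rule] == pytest.approx(np.mean(acc_se[rule]), rel=1e-9)
            assert cell.emae[rule] == pytest.approx(np.mean(acc_ae[rule]), rel=1e-9)

    def test_bit_identical_reruns(self):
        cfg = SimulationConfig(n=25, p=4, rho=0.99, sigma=1.0, M=300, seed=5)
        c1, c2 = run_cell(cfg), run_cell(cfg)
        assert c1.emse == c2.emse and c1.emae == c2.emae and c1.mean_d == c2.mean_d

    def test_degenerate_noise_leaves_only_shrinkage_bias(self):
        # OLS recovers beta exactly; a shrinkage rule may still clip to d = 0,
        # whose only error is the deterministic bias 1/(lambda_max + 1) along
        # the principal direction -- bounded, but not zero
        cfg = SimulationConfig(n=20, p=3, rho=0.9, sigma=1e-12, M=50, seed=1)
        cell = run_cell(cfg)
        assert cell.emse["OLS"] < 1e-10
        assert cell.emae["OLS"] < 1e-6
        for rule in DEFAULT_RULES:
            assert cell.emse[rule] < 1e-3
            assert cell.emae[rule] < 0.05

    def test_ols_emse_agrees_with_analytic_oracle(self):
        cfg = SimulationConfig(n=40, p=4, rho=0.95, sigma=1.0, M=1500, seed=9)
        cell = run_cell(cfg)
        assert abs(cell.emse["OLS"] - cell.ols_emse_analytic) <= 3 * cell.emse_se["OLS"]

    def test_fixed_design_mode_matches_its_single_draw(self):
        cfg = SimulationConfig(
            n=30, p=3, rho=0.9, sigma=1.0, M=800, seed=13, redraw_X=False
        )
        cell = run_cell(cfg)
        # the analytic OLS MSE is constant across replications for a fixed X
        rng = np.random.default_rng(cfg.seed)
        z = rng.standard_normal((1, cfg.n, cfg.p + 1))
        X = np.sqrt(1 - cfg.rho) * z[0, :, : cfg.p] + np.sqrt(cfg.rho) * z[0, :, cfg.p :]
        lam = np.linalg.eigvalsh(X.T @ X)
        assert cell.ols_emse_analytic == pytest.approx(np.sum(1.0 / lam), rel=1e-10)
        assert abs(cell.emse["OLS"] - cell.ols_emse_analytic) <= 3 * cell.emse_se["OLS"]

    def test_liu_rules_beat_ols_under_severe_collinearity(self):
        for rho in (0.999, 0.9999):
            cfg = SimulationConfig(n=25, p=4, rho=rho, sigma=1.0, M=2000, seed=17)
            cell = run_cell(cfg)
            for rule in DEFAULT_RULES:
                if rule != "OLS":
                    assert cell.emse[rule] < cell.emse["OLS"]

    def test_analytic_oracle_monotone_in_sigma_and_rho(self):
        base = dict(n=30, p=4, M=200, seed=3)
        by_sigma = [
            run_cell(SimulationConfig(rho=0.9, sigma=s, **base)).ols_emse_analytic
            for s in (0.5, 1.0, 2.0)
        ]
        assert by_sigma[0] < by_sigma[1] < by_sigma[2]
        by_rho = [
            run_cell(SimulationConfig(rho=r, sigma=1.0, **base)).ols_emse_analytic
            for r in (0.9, 0.99, 0.999)
        ]
        assert by_rho[0] < by_rho[1] < by_rho[2]


class TestRunGrid:
    def test_single_cell_grid_equals_run_cell_with_derived_seed(self):
        cfg = SimulationConfig(n=20, p=3, rho=0.9, sigma=1.0, M=100, seed=0)
        table = run_grid([cfg], master_seed=7)
        from dataclasses import replace

        direct = run_cell(replace(cfg, seed=cell_seed(7, cfg)))
        assert table.cells[0].emse == direct.emse

    def test_shuffled_order_gives_identical_cells(self):
        cfgs = [
            SimulationConfig(n=20, p=3, rho=r, sigma=1.0, M=100) for r in (0.9, 0.99)
        ]
        t1 = run_grid(cfgs, master_seed=11)
        t2 = run_grid(cfgs[::-1], master_seed=11)
        assert t1.cells[0].emse == t2.cells[1].emse
        assert t1.cells[1].emse == t2.cells[0].emse

    def test_duplicate_cells_warn_but_run(self):
        cfg = SimulationConfig(n=20, p=3, rho=0.9, sigma=1.0, M=50)
        with pytest.warns(UserWarning, match="duplicate"):
            table = run_grid([cfg, cfg], master_seed=1)
        assert len(table.cells) == 2

    def test_long_and_wide_views(self):
        cfgs = [
            SimulationConfig(n=n, p=3, rho=r, sigma=1.0, M=50)
            for n in (20, 30)
            for r in (0.9, 0.99)
        ]
        table = run_grid(cfgs, master_seed=2)
        long = table.to_dataframe()
        assert set(long.columns) >= {
            "n", "p", "rho", "sigma", "M", "seed", "rule",
            "emse", "emse_se", "emae", "emae_se", "mean_d",
        }
        assert len(long) == 4 * len(DEFAULT_RULES)
        wide = table.to_wide("emse")
        assert wide.shape == (len(DEFAULT_RULES), 4)

    def test_factorial_enumeration_counts_the_full_product(self):
        cells = enumerate_factorial(
            n=(25, 50, 100, 200), p=(4, 8, 16, 32),
            rho=(0.90, 0.99, 0.999, 0.9999), sigma=(1.0,),
        )
        assert len(cells) == 64


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=4, p=4, rho=0.9, sigma=1.0),
            dict(n=25, p=4, rho=1.0, sigma=1.0),
            dict(n=25, p=4, rho=0.9, sigma=0.0),
            dict(n=25, p=4, rho=0.9, sigma=1.0, M=0),
            dict(n=25, p=4, rho=0.9, sigma=1.0, corr_mode="bogus"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
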