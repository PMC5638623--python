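"""Dispersion relation, critical point, phase diagrams, irregular scaling."""

import numpy as np
import pytest

import gridforge as gf
from conftest import FIG5_A


@pytest.fixture(scope="module")
def fig5_cfg():
    return gf.SpectrumConfig(a=FIG5_A)


class TestSpectrum:
    def test_peak_location_and_height(self, fig5_cfg):
        cp = gf.critical_point(fig5_cfg)
        assert cp.regime == "grid"
        assert round(cp.k_max) == 3
        assert cp.lambda_max == pytest.approx(1.0, rel=0.05)

    def test_tau_str(self, fig5_cfg):
        cp = gf.critical_point(fig5_cfg)
        assert gf.structure_time(cp.lambda_max, 2e-5) == pytest.approx(
            5e4, rel=0.05
        )

    def test_large_k_limit_is_minus_a(self, fig5_cfg):
        assert gf.eigenvalue_spectrum(fig5_cfg, 50.0) == pytest.approx(
            -fig5_cfg.a, abs=1e-6
        )

    def test_linear_scaling_in_rho_w_tot(self, fig5_cfg):
        k = 2.5
        base = gf.eigenvalue_spectrum(fig5_cfg, k) + fig5_cfg.a
        doubled = (
            gf.eigenvalue_spectrum(fig5_cfg.replace(rho=1800.0), k) + fig5_cfg.a
        )
        assert doubled == pytest.approx(2 * base)

    def test_discrete_eigenvalues_lie_on_curve(self, correlation_900, fig5_cfg):
        """Eigenvalues of the discrete regular-input matrix match lambda(k)
        at the torus frequencies (the red-dots-on-line property)."""
        ev = np.sort(np.linalg.eigvalsh(correlation_900.matrix))[::-1] - FIG5_A
        # the largest eigenvalues belong to the modes nearest k_max = 3
        for mode in [(3, 0), (2, 2), (3, 1)]:
            k = float(np.hypot(*mode))
            lam = gf.eigenvalue_spectrum(fig5_cfg, k)
            gap = np.abs(ev - lam).min()
            assert gap < 0.02 * max(abs(lam), 0.1)

    def test_raising_tau_l_shifts_k_max_to_two(self, fig5_cfg):
        cfg = fig5_cfg.replace(
            kernel=gf.AdaptationKernel(tau_s=0.1, tau_l=0.35, mu=1.06)
        )
        cp = gf.critical_point(cfg)
        assert round(cp.k_max) == 2


class TestCriticalPointEdgeCases:
    def test_no_pattern_regime(self, fig5_cfg):
        cp = gf.critical_point(fig5_cfg.replace(rho=100.0))
        assert cp.regime == "none"
        assert cp.lambda_max <= 0.0

    def test_place_regime_at_positive_kernel_integral(self, fig5_cfg):
        # mu < 1: net-excitatory kernel, spectrum peaks at k -> 0
        cfg = fig5_cfg.replace(
            kernel=gf.AdaptationKernel(tau_s=0.1, tau_l=0.16, mu=0.2),
            rho=2000.0,
        )
        cp = gf.critical_point(cfg)
        assert cp.regime == "place"
        assert cp.k_max == 0.0

    def test_peak_at_grid_edge_raises(self, fig5_cfg):
        cfg = fig5_cfg.replace(k_grid=np.arange(0.05, 1.0, 0.05))
        with pytest.raises(ValueError):
            gf.critical_point(cfg)


class TestSweep:
    def test_regimes_exhaustive_and_k_max_monotone_in_tau_l(self, fig5_cfg):
        res = gf.sweep(
            fig5_cfg,
            ("tau_l", np.linspace(0.12, 0.45, 8)),
            ("mu", np.array([1.06])),
        )
        assert set(np.unique(res["regime"])) <= {"grid", "place", "none",
                                                 "invalid"}
        ks = res["k_max"][0]
        grid_mask = res["regime"][0] == "grid"
        assert np.all(np.diff(ks[grid_mask]) < 0)  # larger tau_l, coarser grid

    def test_lambda_max_increases_with_tau_l(self, fig5_cfg):
        res = gf.sweep(
            fig5_cfg,
            ("tau_l", np.linspace(0.14, 0.40, 6)),
            ("mu", np.array([1.06])),
        )
        lam = res["lambda_max"][0]
        assert np.all(np.diff(lam) > 0)

    def test_default_kernel_sits_in_grid_region(self, fig5_cfg):
        res = gf.sweep(
            fig5_cfg,
            ("tau_l", np.array([0.16])),
            ("mu", np.array([1.06])),
        )
        assert res["regime"][0, 0] == "grid"

    def test_ahp_grids_need_slow_output_kernels(self):
        """k_max > 2 requires output time constants of order seconds; fast
        AHPs yield place-like or coarse patterns only."""
        cfg = gf.SpectrumConfig(
            rho=900.0,
            kernel=gf.AHPKernel(tau_in=0.005, tau_out=1.0, mu_out=1.0),
            a=0.0,
        )
        res = gf.sweep(
            cfg,
            ("tau_out", np.array([0.05, 0.2, 0.5, 1.0, 5.0, 8.0])),
            ("mu_out", np.array([1.0, 10.0, 50.0])),
        )
        k = np.nan_to_num(res["k_max"], nan=0.0)
        fast = res["tau_out"] < 1.0
        assert np.all(k[:, fast] < 2.0)
        assert np.any(k[:, ~fast] > 2.0)


class TestIrregularScale:
    def test_phi_limits(self):
        assert gf.phi_factor(10 ** 6).phi * 10 ** 6 == pytest.approx(4 / 3,
                                                                     rel=1e-5)
        with pytest.raises(ValueError):
            gf.phi_factor(1)

    def test_phi_monotone_decreasing(self):
        phis = [gf.phi_factor(m).phi for m in range(2, 31)]
        assert np.all(np.diff(phis) < 0)

    def test_phi_monte_carlo_agreement(self):
        """The closed form is a small-covariance approximation: accurate to
        a few percent for M >= 10, within 20% down to M = 2."""
        for M in (2, 3, 5, 10, 20, 30):
            mc = gf.phi_monte_carlo(M, n_draws=20000, rng=77)
            an = gf.phi_factor(M).phi
            tol = 0.25 if M < 5 else (0.15 if M < 10 else 0.05)
            assert abs(mc - an) <= tol * mc

    def test_phi_one_recovers_regular_spectrum(self):
        cfg = gf.SpectrumConfig(a=FIG5_A)
        k = np.array([1.0, 2.5, 3.0])
        lam_reg = gf.eigenvalue_spectrum(cfg, k)
        # Phi -> 1 corresponds to the single-field (regular) case
        lam_irr = gf.irregular_spectrum(cfg, 10, k)
        phi = gf.phi_factor(10).phi
        assert np.allclose(lam_irr + cfg.a, phi * (lam_reg + cfg.a))

    def test_irregular_argmax_independent_of_m(self):
        cfg = gf.SpectrumConfig(
            rho=3600.0,
            field_spec=gf.GaussianFieldSpec(sigma=0.0625, r_av=0.8, L=1.0),
            a=2.5,
        )
        ref = gf.critical_point(cfg).k_max
        for M in (2, 5, 10, 30):
            lam = gf.irregular_spectrum(cfg, M, cfg.k_grid)
            k_at_max = cfg.k_grid[int(np.argmax(lam))]
            assert k_at_max == pytest.approx(ref, abs=0.05)

    def test_discrete_irregular_eigenvalue_near_prediction(self, kernel):
        """Top eigenvalue of a sampled irregular correlation matrix lies
        within tens of percent of the Phi-scaled analytic maximum."""
        spec = gf.GaussianFieldSpec(sigma=0.0625, r_av=0.8, L=1.0)
        ens = gf.make_irregular_ensemble(2500, 10, spec, rng=3)
        model = gf.correlation_matrix(ens, kernel, 0.25, 1.0)
        top = np.linalg.eigvalsh(model.matrix)[-1] - 2.5
        cfg = gf.SpectrumConfig(rho=2500.0, field_spec=spec, a=2.5)
        lam = gf.irregular_spectrum(cfg, 10, cfg.k_grid).max()
        assert top == pytest.approx(lam, abs=0.6 * abs(lam) + 0.2)
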