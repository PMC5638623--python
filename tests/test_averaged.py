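"""Averaged dynamics: correlation models, a/b rates, normalization, Euler."""

import numpy as np
import pytest
from scipy.integrate import quad

import gridforge as gf
from gridforge import averaged
from conftest import FIG5_A, FIG5_B


class TestDeriveAB:
    def test_published_spiking_configuration(self, plasticity, kernel, neuron):
        ab = gf.derive_ab(plasticity, kernel, neuron, r_av=0.4)
        assert round(ab["a"], 1) == 1.1
        assert round(ab["b"], 2) == 0.49

    def test_overlap_closed_form_vs_quadrature(self, plasticity, kernel):
        closed = averaged.stdp_kernel_overlap(plasticity, kernel)
        oracle, _ = quad(
            lambda t: gf.stdp_window(plasticity, -t) * kernel.value(t),
            0.0, 5.0, limit=500,
        )
        assert closed == pytest.approx(oracle, abs=1e-8)

    def test_zero_window_integral(self, kernel, neuron):
        plast = gf.PlasticityParams(eta=1e-5, tau_w=0.05, w_tot=0.0,
                                    alpha=3.56, beta=-8.78)
        ab = gf.derive_ab(plast, kernel, neuron, r_av=0.4)
        assert ab["a"] == pytest.approx(0.4 * 3.56)
        assert ab["b"] == pytest.approx(0.4 * -8.78)


class TestCorrelationRadial:
    def test_mexican_hat_shape(self, field_spec, kernel):
        u = np.linspace(0.0, 0.4, 200)
        c = averaged.correlation_radial(field_spec, kernel, 0.25, 1.0, u)
        assert c[0] > 0  # attraction at short distances
        assert c.min() < 0  # repulsion at intermediate distances
        assert np.abs(c[-1]) < 0.02 * c[0]

    def test_linear_in_w_tot(self, field_spec, kernel):
        u = np.array([0.0, 0.1, 0.2])
        c1 = averaged.correlation_radial(field_spec, kernel, 0.25, 1.0, u)
        c0 = averaged.correlation_radial(field_spec, kernel, 0.25, 0.0, u)
        c2 = averaged.correlation_radial(field_spec, kernel, 0.25, 2.0, u)
        assert np.allclose(c0, 0.0)
        assert np.allclose(c2, 2 * c1)

    def test_hankel_inverse_consistency(self, field_spec, kernel):
        """Numerically Hankel-transforming C(u) recovers the analytic
        correlation spectrum (dispersion relation consistency)."""
        from scipy.special import j0

        cfg = gf.SpectrumConfig(rho=900.0, field_spec=field_spec, kernel=kernel)
        u = np.linspace(1e-6, 1.2, 6000)
        c = averaged.correlation_radial(field_spec, kernel, 0.25, 1.0, u)
        for k in (1.0, 2.0, 3.0, 4.0, 6.0):
            # 2D Fourier transform of the radial function at frequency k
            hank = np.trapezoid(2 * np.pi * u * c * j0(2 * np.pi * k * u), u)
            analytic = (gf.eigenvalue_spectrum(cfg, k) + cfg.a) / cfg.rho
            assert hank == pytest.approx(analytic, rel=2e-3, abs=1e-6)


class TestCorrelationMatrix:
    def test_regular_entries_match_radial_closed_form(self, field_spec, kernel):
        ens = gf.make_regular_ensemble(36, field_spec)
        mat = gf.correlation_matrix(ens, kernel, 0.25, 1.0).matrix
        c = ens.centers[:, 0, :]
        for i, j in [(0, 1), (0, 7), (3, 20), (5, 5)]:
            d = gf.trajectory.minimal_image(c[i] - c[j], 1.0)
            expected = averaged.correlation_radial(
                field_spec, kernel, 0.25, 1.0, float(np.hypot(*d))
            )
            assert mat[i, j] == pytest.approx(expected, rel=1e-2, abs=2e-4)

    def test_modes_agree_with_general_maps_construction(self, field_spec, kernel):
        ens = gf.make_regular_ensemble(16, field_spec)
        m1 = gf.correlation_matrix(ens, kernel, 0.25, 1.0).matrix
        m2 = gf.correlation_matrix(ens, kernel, 0.25, 1.0,
                                   method="maps", n_bins=100).matrix
        assert np.abs(m1 - m2).max() < 0.01 * np.abs(m1).max()

    def test_modes_agree_with_maps_for_irregular_inputs(self, field_spec, kernel):
        ens = gf.make_irregular_ensemble(9, 5, field_spec, rng=2)
        m1 = gf.correlation_matrix(ens, kernel, 0.25, 1.0).matrix
        m2 = gf.correlation_matrix(ens, kernel, 0.25, 1.0,
                                   method="maps", n_bins=100).matrix
        assert np.abs(m1 - m2).max() < 0.01 * np.abs(m1).max()

    def test_symmetry(self, field_spec, kernel):
        ens = gf.make_irregular_ensemble(12, 4, field_spec, rng=3)
        mat = gf.correlation_matrix(ens, kernel, 0.25, 1.0).matrix
        assert np.allclose(mat, mat.T)

    def test_mean_row_sum_identity(self, kernel):
        """For any ensemble normalized to r_av, N*C_av equals
        N W_tot r_av^2 (1 - mu) exactly (uniform-coverage identity)."""
        spec = gf.GaussianFieldSpec(sigma=0.0625, r_av=2.0, L=0.5)
        ens = gf.make_regular_ensemble(100, spec)
        mat = gf.correlation_matrix(ens, kernel, 0.25, 1.0).matrix
        assert 100 * mat.mean() == pytest.approx(
            100 * 1.0 * 2.0 ** 2 * (1 - 1.06), rel=1e-4
        )


class TestNormalization:
    def test_published_table_values(self, correlation_900):
        norm = gf.normalization_quantities(correlation_900, FIG5_A, FIG5_B, 2e-5)
        assert norm["tau_av"] == pytest.approx(5.13e3, rel=0.03)
        assert norm["w_av_inf"] == pytest.approx(0.05, rel=0.03)

    def test_uncorrelated_limit(self):
        c = np.zeros((10, 10))
        norm = gf.normalization_quantities(c, 2.0, 1.0, 1e-4)
        assert norm["w_av_inf"] == pytest.approx(0.5)
        assert norm["tau_av"] == pytest.approx(1.0 / (1e-4 * 2.0))

    def test_b_scaling(self, correlation_900):
        n1 = gf.normalization_quantities(correlation_900, FIG5_A, FIG5_B, 2e-5)
        n2 = gf.normalization_quantities(correlation_900, FIG5_A, 2 * FIG5_B, 2e-5)
        assert n2["w_av_inf"] == pytest.approx(2 * n1["w_av_inf"])
        assert n2["tau_av"] == pytest.approx(n1["tau_av"])

    def test_unstable_normalization_signalled(self):
        c = np.full((4, 4), 1.0)
        with pytest.raises(ValueError):
            gf.normalization_quantities(c, 1.0, 1.0, 1e-4)


class TestIntegrate:
    def test_scalar_linear_ode_limit(self):
        # C = 0: mean weight converges to b/a at rate eta*a
        params = gf.AveragedParams(a=2.0, b=1.0, eta=1e-4, dt=10.0)
        w0 = np.full(5, 0.1)
        t_end = 40000.0
        h = gf.integrate(np.zeros((5, 5)), params, w0,
                         t_end, checkpoints=[10000.0, t_end])
        tau = 1.0 / (1e-4 * 2.0)
        for t, w in zip(h.times, h.weights):
            pred = 0.5 + (0.1 - 0.5) * np.exp(-t / tau)
            assert w.mean() == pytest.approx(pred, rel=5e-3)

    def test_mean_weight_law_along_trajectory(self, correlation_900):
        """d w_av / dt = eta [(N C_av - a) w_av + b] while the clamp is
        inactive (interior weights)."""
        params = gf.AveragedParams(a=FIG5_A, b=FIG5_B, eta=2e-5, dt=50.0)
        w0 = np.full(900, 0.02)
        ck = np.array([0.0, 2000.0, 4000.0, 8000.0])
        h = gf.integrate(correlation_900, params, w0, 8000.0, checkpoints=ck)
        ncav = 900 * correlation_900.matrix.mean()
        tau = 1.0 / (2e-5 * (FIG5_A - ncav))
        w_inf = FIG5_B / (FIG5_A - ncav)
        for t, w in zip(h.times, h.weights):
            pred = w_inf + (0.02 - w_inf) * np.exp(-t / tau)
            assert w.mean() == pytest.approx(pred, rel=5e-3)

    def test_linear_regime_fourier_growth_matches_dispersion(
        self, correlation_900, regular_ensemble_900
    ):
        """With the clamp disabled, torus Fourier modes grow/decay as
        exp(eta lambda(k) t) with lambda from the analytic spectrum."""
        params = gf.AveragedParams(a=FIG5_A, b=FIG5_B, eta=2e-5, dt=50.0)
        rng = np.random.default_rng(11)
        w0 = rng.normal(5e-3, 1e-3, 900).clip(min=0)
        t_end = 4e4
        h = gf.integrate(correlation_900, params, w0,
                         t_end, checkpoints=[0.0, t_end], clamp=False)
        grid = regular_ensemble_900.centers[:, 0, :]
        cfg = gf.SpectrumConfig(a=FIG5_A)
        for n in [(1, 0), (2, 0), (2, 2), (3, 0), (4, 0)]:
            kvec = np.array(n, dtype=float)
            amps = [
                np.abs(np.sum(w * np.exp(-2j * np.pi * (grid @ kvec))))
                for w in h.weights
            ]
            rate = np.log(amps[1] / amps[0]) / (2e-5 * t_end)
            lam = gf.eigenvalue_spectrum(cfg, float(np.hypot(*kvec)))
            assert rate == pytest.approx(lam, abs=0.02)

    def test_divergence_guard(self):
        c = np.array([[10.0]])
        params = gf.AveragedParams(a=0.0, b=0.0, eta=1e-3, dt=10.0)
        with pytest.raises(RuntimeError):
            gf.integrate(c, params, np.array([1.0]), 1e6,
                         divergence_limit=100.0)

    def test_unstable_step_rejected(self):
        c = np.diag([1000.0] * 3)
        params = gf.AveragedParams(a=0.0, b=0.0, eta=1e-3, dt=10.0)
        with pytest.raises(ValueError):
            gf.integrate(c, params, np.ones(3), 100.0)

    def test_batched_matches_single(self, correlation_900):
        params = gf.AveragedParams(a=FIG5_A, b=FIG5_B, eta=2e-5, dt=50.0)
        rng = np.random.default_rng(0)
        w0 = rng.normal(5e-3, 1e-3, (2, 900)).clip(min=0)
        hb = gf.integrate(correlation_900, params, w0, 5e3)
        h0 = gf.integrate(correlation_900, params, w0[0], 5e3)
        assert np.allclose(hb.final[0], h0.final)
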