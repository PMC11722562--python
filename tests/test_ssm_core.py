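"""State-space core: discretization closed forms, scan equivalences."""

import numpy as np
import pytest
from scipy.linalg import expm

from multiphys.ssm_core import (
    DiscreteSSMParams,
    SSMParams,
    SelectiveParams,
    build_kernel,
    discretize,
    scan_convolutional,
    scan_recurrent,
    selective_scan,
)

from conftest import random_stable_params


class TestDiscretize:
    def test_scalar_closed_form(self):
        # A=-1, delta=ln2: exp(-ln2) = 1/2 and (-ln2)^-1 (1/2 - 1) ln2 = 1/2
        d = discretize(SSMParams(A=-1.0, B=1.0, C=1.0, delta=np.log(2)))
        assert d.A_bar == pytest.approx(0.5)
        assert d.B_bar == pytest.approx(0.5)
        assert d.C_bar == pytest.approx(1.0)

    def test_small_delta_first_order_limit(self, rng):
        A = rng.normal(size=(3, 3))
        p = SSMParams(A=A, B=rng.normal(size=(3, 1)), C=rng.normal(size=(1, 3)), delta=1e-6)
        d = discretize(p)
        assert np.allclose(d.A_bar, np.eye(3) + 1e-6 * A, atol=1e-9)

    def test_bbar_matches_quadrature_oracle(self, rng):
        # B_bar must equal (integral_0^delta exp(sA) ds) B; fine Riemann sum
        for _ in range(5):
            p = random_stable_params(rng, n_max=4)
            d = discretize(p)
            m = 10_000
            h = p.delta / m
            step = expm(h * p.A)
            panel = expm(0.5 * h * p.A)  # midpoint of the first panel
            acc = np.zeros_like(p.A)
            for _i in range(m):
                acc += panel
                panel = panel @ step
            oracle = (h * acc) @ p.B
            assert np.allclose(d.B_bar, oracle, rtol=1e-6, atol=1e-8)

    def test_c_passes_through_unchanged(self, rng):
        p = random_stable_params(rng)
        assert np.array_equal(discretize(p).C_bar, p.C)

    def test_series_branch_near_zero_A(self):
        p = SSMParams(A=np.zeros((2, 2)), B=np.ones((2, 1)), C=np.ones((1, 2)), delta=0.5)
        d = discretize(p)
        assert d.method == "series"
        # A -> 0 limit: B_bar -> delta * B
        assert np.allclose(d.B_bar, 0.5 * np.ones((2, 1)))

    def test_validation_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            SSMParams(A=np.eye(2), B=np.ones((2, 1)), C=np.ones((1, 2)), delta=-1.0)
        with pytest.raises(ValueError):
            SSMParams(A=np.full((2, 2), np.nan), B=np.ones((2, 1)), C=np.ones((1, 2)), delta=0.1)
        with pytest.raises(ValueError):
            SSMParams(A=np.eye(3), B=np.ones((2, 1)), C=np.ones((1, 3)), delta=0.1)


class TestScans:
    def test_scalar_recurrence_by_hand(self):
        d = DiscreteSSMParams(A_bar=0.5, B_bar=1.0, C_bar=2.0)
        assert np.allclose(scan_recurrent(d, [1.0, 1.0]), [2.0, 3.0])  # psi = 1, 1.5

    def test_zero_input_zero_output(self, rng):
        d = discretize(random_stable_params(rng))
        assert np.array_equal(scan_recurrent(d, np.zeros(17)), np.zeros(17))

    def test_impulse_response_equals_kernel(self, rng):
        for _ in range(5):
            d = discretize(random_stable_params(rng))
            L = 16
            imp = np.zeros(L)
            imp[0] = 1.0
            assert np.allclose(scan_recurrent(d, imp), build_kernel(d, L).k, atol=1e-6)

    def test_kernel_scalar_closed_form(self):
        d = DiscreteSSMParams(A_bar=0.5, B_bar=1.0, C_bar=2.0)
        assert np.allclose(build_kernel(d, 3).k, [2.0, 1.0, 0.5])

    def test_kernel_nilpotent_A(self):
        d = DiscreteSSMParams(A_bar=np.zeros((2, 2)), B_bar=np.ones((2, 1)), C_bar=np.ones((1, 2)))
        assert np.allclose(build_kernel(d, 5).k, [2.0, 0, 0, 0, 0])

    def test_conv_equals_recurrent_50_draws(self, rng):
        worst = 0.0
        for _ in range(50):
            d = discretize(random_stable_params(rng, n_max=8))
            L = int(rng.integers(4, 65))
            rho = rng.normal(size=L)
            rec = scan_recurrent(d, rho)
            conv = scan_convolutional(d, rho)
            worst = max(worst, np.abs(conv - rec).max() / max(np.abs(rec).max(), 1e-12))
        assert worst < 1e-5

    def test_linearity(self, rng):
        d = discretize(random_stable_params(rng))
        r1, r2 = rng.normal(size=20), rng.normal(size=20)
        lhs = scan_convolutional(d, 2.0 * r1 - 3.0 * r2)
        rhs = 2.0 * scan_convolutional(d, r1) - 3.0 * scan_convolutional(d, r2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_nan_input_reports_step(self):
        d = DiscreteSSMParams(A_bar=0.5, B_bar=1.0, C_bar=1.0)
        with pytest.raises(FloatingPointError, match="step 2"):
            scan_recurrent(d, [1.0, 1.0, np.nan, 1.0])


class TestStabilityAndZOH:
    def test_diagonal_stability(self, rng):
        # diagonal A in [-5, -0.1], delta in (0, 1] => A_bar entries in (0, 1)
        for _ in range(20):
            diag = rng.uniform(-5.0, -0.1, size=4)
            p = SSMParams(A=np.diag(diag), B=np.ones((4, 1)), C=np.ones((1, 4)),
                          delta=float(rng.uniform(1e-3, 1.0)))
            d = discretize(p)
            bars = np.diag(d.A_bar)
            assert np.all(bars > 0) and np.all(bars < 1)

    def test_stable_spectral_radius_below_one(self, rng):
        for _ in range(10):
            p = random_stable_params(rng)
            d = discretize(p)
            assert np.abs(np.linalg.eigvals(d.A_bar)).max() < 1.0

    def test_zoh_step_refinement_consistency(self, rng):
        # scanning n steps at delta ~ scanning 2n steps at delta/2 of the
        # zero-order-held input, to first order in delta
        p = random_stable_params(rng, n_max=3, delta_range=(0.01, 0.05))
        d1 = discretize(p)
        d2 = discretize(SSMParams(A=p.A, B=p.B, C=p.C, delta=p.delta / 2))
        rho = rng.normal(size=12)
        coarse = scan_recurrent(d1, rho)
        fine = scan_recurrent(d2, np.repeat(rho, 2))[1::2]
        assert np.abs(coarse - fine).max() < 10.0 * p.delta


class TestSelectiveScan:
    def _constant_sel(self, p: SSMParams, L: int) -> SelectiveParams:
        n = p.state_size
        return SelectiveParams(
            delta_t=np.full(L, p.delta),
            B_t=np.tile(p.B.reshape(n), (L, 1)),
            C_t=np.tile(p.C.reshape(n), (L, 1)),
            A=p.A,
        )

    def test_constant_params_reduce_to_lti(self, rng):
        p = random_stable_params(rng, n_max=4)
        d = discretize(p)
        x = rng.normal(size=(12, 3))
        out = selective_scan(x, self._constant_sel(p, 12))
        for c in range(3):
            assert np.allclose(out[:, c], scan_recurrent(d, x[:, c]), atol=1e-10)

    def test_zero_input_zero_output(self, rng):
        p = random_stable_params(rng)
        out = selective_scan(np.zeros((6, 2)), self._constant_sel(p, 6))
        assert np.array_equal(out, np.zeros((6, 2)))

    def test_matches_naive_loop_oracle(self, rng):
        # 8 tokens, 4 channels, genuinely time-varying parameters
        n, L, C = 3, 8, 4
        A = -np.diag(rng.uniform(0.5, 2.0, size=n)) + 0.1 * rng.normal(size=(n, n))
        A = A - (max(np.linalg.eigvals(A).real.max(), 0) + 0.2) * np.eye(n)
        sel = SelectiveParams(
            delta_t=rng.uniform(0.05, 0.3, size=L),
            B_t=rng.normal(size=(L, n)),
            C_t=rng.normal(size=(L, n)),
            A=A,
        )
        x = rng.normal(size=(L, C))
        out = selective_scan(x, sel)

        # independent step-by-step reference
        expected = np.zeros((L, C))
        for c in range(C):
            psi = np.zeros(n)
            for t in range(L):
                dt = sel.delta_t[t]
                A_bar = expm(dt * A)
                B_bar = np.linalg.solve(dt * A, A_bar - np.eye(n)) @ (dt * sel.B_t[t])
                psi = A_bar @ psi + B_bar * x[t, c]
                expected[t, c] = sel.C_t[t] @ psi
        assert np.allclose(out, expected, atol=1e-10)

    def test_rejects_nonpositive_delta(self, rng):
        with pytest.raises(ValueError):
            SelectiveParams(delta_t=np.array([0.1, 0.0]), B_t=np.ones((2, 2)),
                            C_t=np.ones((2, 2)), A=-np.eye(2))
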