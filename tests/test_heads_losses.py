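"""Gate blocks, task heads, negative-Pearson loss and the combined loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiphys._autodiff import Tensor
from multiphys.backbone import BackboneConfig
from multiphys.heads_losses import (
    GateBlock,
    GateOutput,
    LossConfig,
    MultiPhysModel,
    VitalsBundle,
    gate,
    neg_pearson,
    select,
    theta,
    total_loss,
)


def tiny_model(rng_seed=0):
    cfg = BackboneConfig(H=32, W=64, C_embed=4, N1=1, N2=1, N_mp=2, n_heads=2,
                         mlp_ratio=2, D_r=16, state_size=4)
    return MultiPhysModel(cfg, rng=rng_seed)


class TestGate:
    def test_zero_weights_give_half(self, rng):
        g = GateBlock(8, rng)
        for lin in (g.fc1, g.fc2):
            lin.weight.data[...] = 0
            lin.bias.data[...] = 0
        out = gate(g, rng.random((3, 8)), "HR")
        assert np.allclose(out.sigma, 0.5)

    def test_outputs_in_open_unit_interval(self, rng):
        g = GateBlock(16, rng)
        out = gate(g, 10 * rng.standard_normal((5, 16)), "SpO2")
        assert np.all(out.sigma > 0) and np.all(out.sigma < 1)

    def test_matches_straight_line_oracle(self, rng):
        g = GateBlock(6, rng)
        r = rng.standard_normal((2, 6))
        out = gate(g, r, "RR").sigma

        def ln(x, gamma, beta):
            mu = x.mean(-1, keepdims=True)
            sd = np.sqrt(((x - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
            return (x - mu) / sd * gamma + beta

        h = r @ g.fc1.weight.data + g.fc1.bias.data
        h = np.maximum(ln(h, g.ln1.gamma.data, g.ln1.beta.data), 0)
        h = h @ g.fc2.weight.data + g.fc2.bias.data
        h = ln(h, g.ln2.gamma.data, g.ln2.beta.data)
        expected = 1 / (1 + np.exp(-h))
        assert np.allclose(out, expected, atol=1e-10)

    def test_select_elementwise_product(self, rng):
        r = rng.standard_normal(8)
        sigma = rng.uniform(0.01, 0.99, size=8)
        g = GateOutput(sigma=sigma, task="HR")
        assert np.allclose(select(r, g).r_prime, sigma * r)
        assert np.allclose(select(np.zeros(8), g).r_prime, 0.0)

    def test_selected_magnitude_never_exceeds_input(self, rng):
        for _ in range(100):
            r = rng.standard_normal(8)
            g = GateOutput(sigma=rng.uniform(1e-6, 1 - 1e-6, size=8), task="RR")
            assert np.all(np.abs(select(r, g).r_prime) <= np.abs(r))

    def test_select_length_mismatch(self, rng):
        g = GateOutput(sigma=np.full(4, 0.5), task="HR")
        with pytest.raises(ValueError):
            select(np.zeros(5), g)


class TestHeads:
    def test_zero_weight_heads_predict_bias(self, rng):
        m = tiny_model()
        for head, bias in ((m.head_hr, 1.5), (m.head_spo2, -2.0), (m.head_rr, 0.25)):
            head.weight.data[...] = 0
            head.bias.data[...] = bias
        m.train()
        x = Tensor(rng.random((2, 32, 64, 3)))
        out = m(x)
        assert np.allclose(out.hr.data, 1.5)
        assert np.allclose(out.spo2.data, -2.0)
        assert np.allclose(out.rr.data, 0.25)

    def test_bundle_has_all_fields_with_shapes(self, rng):
        m = tiny_model().train()
        out = m(Tensor(rng.random((2, 32, 64, 3))))
        assert out.hr.shape == (2,) and out.spo2.shape == (2,) and out.rr.shape == (2,)
        assert out.bvp.shape == (2, 64)

    def test_bvp_length_configurable(self, rng):
        cfg = BackboneConfig(H=64, W=256, C_embed=4, N1=1, N2=1, N_mp=2, n_heads=2,
                             mlp_ratio=2, D_r=16, state_size=4)
        m = MultiPhysModel(cfg, bvp_len=256, rng=0).train()
        out = m(Tensor(np.random.default_rng(0).random((2, 64, 256, 3))))
        assert out.bvp.shape == (2, 256)


class TestNegPearson:
    def test_identical_sequences_score_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert neg_pearson(x, x) == pytest.approx(0.0)

    def test_anticorrelated_sequences_score_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert neg_pearson(-x, x) == pytest.approx(2.0)

    def test_affine_invariance_example(self):
        assert neg_pearson(np.array([1.0, 2, 1, 2]), np.array([0.0, 1, 0, 1])) == pytest.approx(0.0)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_property(self, a, b):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(32), rng.standard_normal(32)
        assert neg_pearson(a * x + b, y) == pytest.approx(neg_pearson(x, y), abs=1e-9)

    def test_constant_gold_raises(self):
        with pytest.raises(ValueError):
            neg_pearson(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0))

    def test_differentiable_path_matches_numpy(self, rng):
        p, g = rng.standard_normal((2, 20)), rng.standard_normal((2, 20))
        t = neg_pearson(Tensor(p), g)
        expected = np.mean([neg_pearson(p[i], g[i]) for i in range(2)])
        assert t.item() == pytest.approx(expected, abs=1e-12)


class TestTheta:
    def test_ramp_endpoints_and_midpoint(self):
        cfg = LossConfig(warmup_fraction=0.1)
        assert theta(0, 1000, cfg) == 0.0
        assert theta(50, 1000, cfg) == pytest.approx(0.5)
        assert theta(100, 1000, cfg) == 1.0
        assert theta(1000, 1000, cfg) == 1.0

    def test_monotone_nondecreasing(self):
        cfg = LossConfig(warmup_fraction=0.25)
        vals = [theta(s, 200, cfg) for s in range(0, 201, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            theta(0, 0, LossConfig())


class TestTotalLoss:
    def test_perfect_predictions_zero_loss(self, rng):
        bvp = rng.standard_normal(32)
        b = VitalsBundle(hr=72.0, spo2=98.0, rr=15.0, bvp=bvp)
        L, terms = total_loss(b, b, step=100, total=100, cfg=LossConfig())
        assert L == pytest.approx(0.0)
        assert terms["L_BVP"] == pytest.approx(0.0)

    def test_theta_zero_reduces_to_hr_term(self, rng):
        pred = VitalsBundle(hr=75.0, spo2=90.0, rr=20.0, bvp=rng.standard_normal(16))
        gold = VitalsBundle(hr=72.0, spo2=98.0, rr=15.0, bvp=rng.standard_normal(16))
        L, terms = total_loss(pred, gold, step=0, total=100, cfg=LossConfig())
        assert L == pytest.approx(terms["L_HR"]) == pytest.approx(3.0)

    def test_printed_arithmetic_case(self):
        # errors (2, 1, 1), theta=1, w=1e-4, no waveform term: 2 + 2e-4
        pred = VitalsBundle(hr=2.0, spo2=1.0, rr=1.0)
        gold = VitalsBundle(hr=0.0, spo2=0.0, rr=0.0)
        cfg = LossConfig(w1=1e-4, w2=1e-4, include_bvp=False)
        L, _ = total_loss(pred, gold, step=100, total=100, cfg=cfg)
        assert L == pytest.approx(2.0 + 2e-4, abs=1e-12)

    def test_total_at_least_hr_term(self, rng):
        for _ in range(10):
            pred = VitalsBundle(hr=float(rng.normal()), spo2=float(rng.normal()),
                                rr=float(rng.normal()), bvp=rng.standard_normal(16))
            gold = VitalsBundle(hr=float(rng.normal()), spo2=float(rng.normal()),
                                rr=float(rng.normal()), bvp=rng.standard_normal(16))
            step = int(rng.integers(0, 101))
            L, terms = total_loss(pred, gold, step=step, total=100, cfg=LossConfig(w1=1, w2=1, w3=1))
            assert L >= terms["L_HR"] - 1e-12
            assert all(v >= 0 for k, v in terms.items() if k.startswith("L_"))

    def test_gate_weight_gradient_matches_finite_difference(self, rng):
        """Backprop through gate -> select -> head -> loss vs central differences."""
        m = tiny_model().train()
        x = rng.random((2, 32, 64, 3))
        gold = VitalsBundle(hr=np.array([0.1, -0.2]), spo2=np.array([0.3, 0.0]),
                            rr=np.array([-0.1, 0.2]), bvp=rng.standard_normal((2, 64)))
        cfg = LossConfig(w1=1.0, w2=1.0, w3=1.0)

        def loss_value():
            L, _ = total_loss(m(Tensor(x)), gold, step=50, total=100, cfg=cfg)
            return L

        L = loss_value()
        m.zero_grad()
        L.backward()
        w = m.gate_hr.fc1.weight
        eps = 1e-6
        idx = (3, 5)
        analytic = w.grad[idx]
        orig = w.data[idx]
        w.data[idx] = orig + eps
        fp = loss_value().item()
        w.data[idx] = orig - eps
        fm = loss_value().item()
        w.data[idx] = orig
        numeric = (fp - fm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9)
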