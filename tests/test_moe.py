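"""Unit tests for the mixture-of-experts flow blocks."""

import numpy as np
import pytest

from conftest import numeric_logdet
from flowgen.autodiff import Tensor
from flowgen.maf import base_log_density
from flowgen.moe import (ActNormLayer, ContextMask, MoEConfig, MoECouplingLayer,
                         build_moefb, coupling_split)
from flowgen.train import _init_actnorms


def make_coupling(d, seed=0, randomize=0.0, **kwargs):
    kwargs.setdefault("n_experts", 2)
    kwargs.setdefault("n_heads", 2)
    kwargs.setdefault("embed_dim", 4)
    kwargs.setdefault("gate_hidden", 8)
    layer = MoECouplingLayer(d, rng=np.random.default_rng(seed), **kwargs)
    if randomize:
        r = np.random.default_rng(seed + 1)
        for p in layer.parameters():
            p.data = p.data + r.normal(0.0, randomize, p.data.shape)
    return layer


class TestContextMask:
    def test_vanishing_mask_limit_is_identity(self, rng):
        module = ContextMask(3, 8, rng=np.random.default_rng(0))
        module.b_m.data[:] = -40.0       # sigmoid -> 0, so m -> 0
        module.W_m.data[:] = 0.0
        x = rng.normal(size=(5, 3))
        assert np.allclose(module.apply(x), x, atol=1e-12)

    def test_forced_half_mask_hand_example(self):
        module = ContextMask(2, 4, rng=np.random.default_rng(0))
        module.W_m.data[:] = 0.0
        module.b_m.data[:] = 40.0        # sigmoid -> 1, so m -> 0.5
        out = module.apply(np.array([[1.0, 3.0]]))   # sample mean 2
        assert np.allclose(out, [[1.5, 2.5]], atol=1e-12)

    def test_mask_range_and_convexity(self, rng):
        module = ContextMask(6, 16, rng=np.random.default_rng(3))
        for p in module.parameters():
            p.data = p.data + rng.normal(0, 0.5, p.data.shape)
        x = rng.normal(size=(50, 6)) * 3
        m = module.mask_t(Tensor(x)).data
        assert np.all(m > 0) and np.all(m < 0.5)
        out = module.apply(x)
        xbar = x.mean(axis=1, keepdims=True)
        low = np.minimum(x, xbar) - 1e-12
        high = np.maximum(x, xbar) + 1e-12
        assert np.all(out >= low) and np.all(out <= high)


class TestActNorm:
    def test_identity_defaults(self, rng):
        layer = ActNormLayer(2)
        x = rng.normal(size=(4, 2))
        y, logdet = layer.forward(x)
        assert np.allclose(y, x) and np.allclose(logdet, 0.0)

    def test_hand_example_cancelling_logdet(self):
        layer = ActNormLayer(2)
        layer.s.data = np.array([2.0, 0.5])
        y, logdet = layer.forward(np.array([[1.0, 1.0]]))
        assert np.allclose(y, [[2.0, 0.5]])
        assert np.allclose(logdet, 0.0)      # log 2 + log 0.5
        assert np.allclose(layer.inverse(y), [[1.0, 1.0]])

    def test_data_dependent_init_standardizes_batch(self, rng):
        layer = ActNormLayer(5)
        batch = rng.normal(3.0, 2.5, size=(200, 5))
        layer.initialize_from(batch)
        y, _ = layer.forward(batch)
        assert np.abs(y.mean(axis=0)).max() < 1e-6
        assert np.abs(y.std(axis=0) - 1.0).max() < 1e-6

    def test_zero_scale_invalid(self):
        layer = ActNormLayer(2)
        layer.s.data = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            layer.forward(np.ones((1, 2)))

    def test_disabled_is_identity_with_no_params(self, rng):
        layer = ActNormLayer(3, enabled=False)
        x = rng.normal(size=(4, 3))
        y, logdet = layer.forward(x)
        assert np.allclose(y, x) and np.allclose(logdet, 0.0)
        assert layer.parameters() == []

    def test_random_roundtrip(self, rng):
        layer = ActNormLayer(6)
        layer.initialize_from(rng.normal(1.0, 3.0, size=(50, 6)))
        y = rng.normal(size=(30, 6))
        out, _ = layer.forward(layer.inverse(y))
        assert np.abs(out - y).max() < 1e-6


class TestCouplingSplit:
    def test_alternating_example(self):
        x_a, x_b = coupling_split(np.array([1.0, 2.0, 3.0, 4.0]),
                                  np.array([1.0, 0.0, 1.0, 0.0]))
        assert np.allclose(x_a, [1, 0, 3, 0])
        assert np.allclose(x_b, [0, 2, 0, 4])

    def test_all_ones_mask_and_partition(self, rng):
        x = rng.normal(size=(5, 4))
        x_a, x_b = coupling_split(x, np.ones(4))
        assert np.allclose(x_a, x) and np.allclose(x_b, 0.0)
        x_a, x_b = coupling_split(x, np.array([1.0, 0, 1, 0]))
        assert np.allclose(x_a + x_b, x)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            coupling_split(np.ones(4), np.ones(3))


class TestMoEAttention:
    def test_single_expert_ignores_gate(self, rng):
        layer = make_coupling(4, n_experts=1, randomize=0.3)
        x_a = Tensor(rng.normal(size=(6, 4)) * layer.M)
        agg = layer.moe_attention_t(x_a).data
        tokens = (x_a @ layer._select_a).reshape(6, len(layer.a_idx), 1) \
            @ layer.W_embed + layer.b_embed
        direct = layer._mha_t(tokens, layer.experts[0]).data
        assert np.allclose(agg, direct)

    def test_zero_preactivation_gate_is_uniform(self, rng):
        layer = make_coupling(4, n_experts=3)   # W_g, b_g zero-initialized
        g = layer.gate_weights(rng.normal(size=(5, 4)) * layer.M)
        assert np.allclose(g, 1.0 / 3.0)

    def test_gate_simplex_for_random_inputs(self, rng):
        layer = make_coupling(6, n_experts=4, randomize=0.5)
        g = layer.gate_weights(rng.normal(size=(20, 6)) * layer.M)
        assert np.all(g >= 0)
        assert np.allclose(g.sum(axis=1), 1.0)


class TestCouplingTransform:
    def test_zero_heads_identity(self, rng):
        layer = make_coupling(4)
        x = rng.normal(size=(5, 4))
        z, logdet = layer.forward(x)
        assert np.allclose(z, x) and np.allclose(logdet, 0.0)

    def test_forced_half_scale_logdet(self):
        layer = make_coupling(4)        # b-set is {1, 3}
        layer.b_s.data[:] = np.arctanh(0.5)
        z, logdet = layer.forward(np.zeros((1, 4)))
        assert np.allclose(logdet, [1.0])   # 0.5 on each of 2 coordinates
        assert np.allclose(layer.inverse(z), np.zeros((1, 4)))

    def test_a_set_passthrough_and_bounded_logdet(self, rng):
        layer = make_coupling(7, randomize=0.5)
        x = rng.normal(size=(20, 7)) * 3
        z, logdet = layer.forward(x)
        assert np.array_equal(z[:, layer.a_idx], x[:, layer.a_idx])
        assert np.all(np.abs(logdet) <= len(layer.b_idx))

    @pytest.mark.parametrize("d", [2, 5, 8])
    def test_logdet_matches_numeric_jacobian(self, d, rng):
        layer = make_coupling(d, seed=d, randomize=0.4)
        x = rng.normal(size=d)
        _, logdet = layer.forward(x[None, :])
        oracle = numeric_logdet(lambda v: layer.forward(v[None, :])[0][0], x)
        assert abs(logdet[0] - oracle) < 1e-4

    def test_roundtrip_100_random(self, rng):
        layer = make_coupling(6, randomize=0.4)
        z = rng.normal(size=(100, 6))
        z_back, _ = layer.forward(layer.inverse(z))
        assert np.abs(z_back - z).max() < 1e-5


class TestMoEModel:
    def test_dim_below_two_rejected(self):
        with pytest.raises(ValueError):
            build_moefb(1, MoEConfig(hidden_features=4))

    def test_identity_init_density_is_base_of_masked_input(self, rng):
        model = build_moefb(4, MoEConfig(hidden_features=8, seed=1))
        x = rng.normal(size=(10, 4))
        masked = model.context_mask.apply(x)
        assert np.allclose(model.log_prob(x), base_log_density(masked))

    def test_invertible_stack_roundtrip(self, rng):
        model = build_moefb(6, MoEConfig(n_blocks=2, hidden_features=16,
                                         embed_dim=4, n_heads=2, seed=5))
        r = np.random.default_rng(9)
        for p in model.parameters():
            p.data = p.data + r.normal(0, 0.1, p.data.shape)
        x = rng.normal(size=(40, 6))
        z = x.copy()
        for layer in model.layers:
            z, _ = layer.forward(z)
        back = z.copy()
        for layer in reversed(model.layers):
            back = layer.inverse(back)
        assert np.abs(back - x).max() < 1e-5

    def test_trainer_initializes_actnorms_sequentially(self, rng):
        model = build_moefb(4, MoEConfig(hidden_features=8, seed=2))
        batch = rng.normal(2.0, 3.0, size=(128, 4))
        _init_actnorms(model, batch)
        first = model.layers[0]
        assert first.initialized
        incoming = model.context_mask.apply(batch)
        y, _ = first.forward(incoming)
        assert np.abs(y.mean(axis=0)).max() < 1e-6
        assert np.abs(y.std(axis=0) - 1.0).max() < 1e-6

    def test_sampling_skips_context_mask(self):
        # identity-initialized invertible stack: samples are exactly the
        # base draws, untouched by the (non-identity) context mask
        model = build_moefb(4, MoEConfig(hidden_features=8, seed=3))
        s = model.sample(50, seed=11)
        base = np.random.default_rng(11).standard_normal((50, 4))
        assert np.allclose(s, base)
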