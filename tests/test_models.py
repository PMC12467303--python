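"""Denoiser networks: contracts, determinism, and an independent
hand-rolled oracle for the Transformer encoder arithmetic."""

import numpy as np
import pytest
from scipy.special import erf

from diffdecon.models import (DenoiserConfig, DiffFormer, DiffMLP,
                              MLPDenoiserConfig, set_conditioning_stats)


def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _layer_norm(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return gamma * (x - mu) / np.sqrt(var + eps) + beta


def _reference_forward(model: DiffFormer, xt, t, c):
    """Independent numpy re-implementation of the encoder forward pass."""
    cfg = model.config
    emb = model.embed
    c_std = (np.atleast_2d(c) - emb.cond_mean) / emb.cond_std
    toks = np.stack([
        np.atleast_2d(xt) @ emb.prop_embed.weight.data + emb.prop_embed.bias.data,
        (np.atleast_1d(t)[:, None] / cfg.T) @ emb.time_embed.weight.data
        + emb.time_embed.bias.data,
        c_std @ emb.bulk_embed.weight.data + emb.bulk_embed.bias.data,
    ], axis=1) + model.pos_embed.data

    h = toks
    d_head = cfg.d_model // cfg.n_heads
    for layer in model.layers:
        # pre-norm self-attention
        z = _layer_norm(h, layer.ln1.gamma.data, layer.ln1.beta.data)
        q = z @ layer.attn.q_proj.weight.data + layer.attn.q_proj.bias.data
        k = z @ layer.attn.k_proj.weight.data + layer.attn.k_proj.bias.data
        v = z @ layer.attn.v_proj.weight.data + layer.attn.v_proj.bias.data
        b, s, d = z.shape
        ctx = np.empty_like(q)
        for head in range(cfg.n_heads):
            sl = slice(head * d_head, (head + 1) * d_head)
            scores = q[..., sl] @ k[..., sl].swapaxes(-1, -2) / np.sqrt(d_head)
            w = np.exp(scores - scores.max(axis=-1, keepdims=True))
            w = w / w.sum(axis=-1, keepdims=True)
            ctx[..., sl] = w @ v[..., sl]
        h = h + ctx @ layer.attn.out_proj.weight.data + layer.attn.out_proj.bias.data
        # pre-norm feed-forward
        z = _layer_norm(h, layer.ln2.gamma.data, layer.ln2.beta.data)
        z = _gelu(z @ layer.ff1.weight.data + layer.ff1.bias.data)
        h = h + z @ layer.ff2.weight.data + layer.ff2.bias.data
    h = _layer_norm(h, model.final_ln.gamma.data, model.final_ln.beta.data)
    return h[:, 0, :] @ model.out_proj.weight.data + model.out_proj.bias.data


class TestDiffFormer:
    def test_matches_hand_rolled_encoder_oracle(self):
        """Micro-config forward equals an independent numpy computation."""
        model = DiffFormer(DenoiserConfig(K=3, G=7, d_model=4, n_heads=1,
                                          n_layers=1, d_ff=8, T=50), seed=5)
        model.eval()
        rng = np.random.default_rng(0)
        xt = rng.standard_normal((4, 3))
        t = rng.integers(1, 51, 4)
        c = rng.standard_normal((4, 7))
        set_conditioning_stats(model, c.mean(axis=0), c.std(axis=0) + 1e-8)
        assert np.allclose(model(xt, t, c).data,
                           _reference_forward(model, xt, t, c), atol=1e-6)

    def test_multihead_matches_oracle(self):
        model = DiffFormer(DenoiserConfig(K=4, G=10, d_model=8, n_heads=2,
                                          n_layers=2, d_ff=16, T=100), seed=6)
        model.eval()
        rng = np.random.default_rng(1)
        xt = rng.standard_normal((3, 4))
        t = rng.integers(1, 101, 3)
        c = rng.standard_normal((3, 10))
        assert np.allclose(model(xt, t, c).data,
                           _reference_forward(model, xt, t, c), atol=1e-6)

    def test_output_shape_and_eval_determinism(self):
        model = DiffFormer(DenoiserConfig(K=5, G=20, T=100), seed=2)
        model.eval()
        rng = np.random.default_rng(3)
        xt = rng.standard_normal((6, 5))
        t = rng.integers(1, 101, 6)
        c = rng.standard_normal((6, 20))
        out1 = model(xt, t, c).data
        out2 = model(xt, t, c).data
        assert out1.shape == (6, 5)
        assert np.array_equal(out1, out2)

    def test_dropout_active_only_in_training_mode(self):
        model = DiffFormer(DenoiserConfig(K=3, G=10, T=100), seed=4)
        rng = np.random.default_rng(5)
        xt = rng.standard_normal((4, 3))
        t = rng.integers(1, 101, 4)
        c = rng.standard_normal((4, 10))
        model.train()
        a = model(xt, t, c, np.random.default_rng(1)).data
        b = model(xt, t, c, np.random.default_rng(2)).data
        assert not np.allclose(a, b)          # stochastic under dropout
        model.eval()
        assert np.array_equal(model(xt, t, c).data, model(xt, t, c).data)

    def test_token_order_matters_with_positional_embeddings(self):
        """Swapping the positional embeddings of two tokens changes the
        output, i.e. position information is actually used."""
        model = DiffFormer(DenoiserConfig(K=3, G=10, T=100), seed=7)
        model.eval()
        rng = np.random.default_rng(8)
        xt = rng.standard_normal((2, 3))
        t = rng.integers(1, 101, 2)
        c = rng.standard_normal((2, 10))
        base = model(xt, t, c).data
        model.pos_embed.data = model.pos_embed.data[[1, 0, 2]]
        swapped = model(xt, t, c).data
        assert not np.allclose(base, swapped)

    def test_zero_inputs_with_zero_positions_yield_bias_tokens(self):
        model = DiffFormer(DenoiserConfig(K=3, G=10, T=100), seed=9)
        model.pos_embed.data[:] = 0.0
        toks = model.embed_tokens(np.zeros((1, 3)), np.array([0]),
                                  np.zeros((1, 10)))
        expected = np.stack([model.embed.prop_embed.bias.data,
                             model.embed.time_embed.bias.data,
                             model.embed.bulk_embed.bias.data])
        assert np.allclose(toks.data[0], expected)

    def test_parameter_count_of_published_config(self):
        """Default architecture (K=7 proportions, 5000-gene bulk): the count
        follows from the layer dimensions and must not drift silently."""
        K, G, d, ff, L = 7, 5000, 128, 256, 3
        expected = (
            (K * d + d) + (1 * d + d) + (G * d + d)   # modality embeddings
            + 3 * d                                    # positional embeddings
            + L * (2 * d + 4 * (d * d + d)             # ln1 + q,k,v,out
                   + 2 * d + (d * ff + ff) + (ff * d + d))  # ln2 + ff
            + 2 * d                                    # final layer norm
            + (d * K + K)                              # output projection
        )
        model = DiffFormer(DenoiserConfig(K=K, G=G), seed=0)
        assert model.n_parameters() == expected

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DenoiserConfig(K=1, G=10)
        with pytest.raises(ValueError):
            DenoiserConfig(K=3, G=10, d_model=10, n_heads=4)
        with pytest.raises(ValueError):
            DenoiserConfig(K=3, G=10, dropout=1.0)


class TestDiffMLP:
    def test_output_shape(self):
        model = DiffMLP(MLPDenoiserConfig(K=4, G=15, T=100), seed=0)
        model.eval()
        rng = np.random.default_rng(1)
        out = model(rng.standard_normal((5, 4)), rng.integers(1, 101, 5),
                    rng.standard_normal((5, 15)))
        assert out.data.shape == (5, 4)

    def test_linear_variant_is_affine_in_embeddings(self):
        """With no hidden layers the output is one affine map of the
        concatenated embeddings, so it is additive in the inputs."""
        model = DiffMLP(MLPDenoiserConfig(K=3, G=8, hidden=(), T=100), seed=1)
        model.eval()
        t = np.array([10])
        x1, x2 = np.ones((1, 3)), 2.0 * np.ones((1, 3))
        c = np.zeros((1, 8))
        o0 = model(np.zeros((1, 3)), t, c).data
        o1 = model(x1, t, c).data
        o2 = model(x2, t, c).data
        assert np.allclose(o2 - o0, 2.0 * (o1 - o0), atol=1e-10)

    def test_conditioning_sensitivity_of_trained_model(self, e2e):
        """Permuting bulk profiles across the trained DiffFormer's batch
        strictly increases validation noise-prediction loss, i.e. the model
        actually uses the bulk token."""
        from diffdecon.diffusion import forward_noise, noise_prediction_loss
        model = e2e["diffformer"]["model"]
        sched = e2e["schedule"]
        rng = np.random.default_rng(17)
        x0 = e2e["test_props"]
        c = e2e["test_bulk"]
        t = rng.integers(1, sched.T + 1, len(x0))
        eps = rng.standard_normal(x0.shape)
        xt = forward_noise(x0, t, eps, sched)
        matched = noise_prediction_loss(model, xt, t, c, eps).data
        perm = rng.permutation(len(x0))
        shuffled = noise_prediction_loss(model, xt, t, c[perm], eps).data
        assert shuffled > matched
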