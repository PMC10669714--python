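import numpy as np
import pytest

from confrna.autograd import Tensor, cross_entropy
from confrna.conf_model import (
    ConF,
    ConvLayerParams,
    ModelConfig,
    bilstm_encode,
    block,
    conv1d,
    downsample,
    forward,
    frontend,
    init_params,
    lstm_step,
    mlp_attention_fuse,
    _lstm_params,
)
from confrna.representation import build_vocab, tokenize, tokenize_dataset
from confrna.synthetic_data import easy_four_family_config, generate


def conv_oracle(x, w, b, dilation):
    """Triple-loop direct sum: out[t, j] = b_j + sum_u sum_i x[t + u*d - left, i] w[u, i, j]."""
    length, c_in = x.shape
    kernel, _, c_out = w.shape
    span = (kernel - 1) * dilation + 1
    left = (span - 1) // 2
    out = np.zeros((length, c_out))
    for t in range(length):
        for j in range(c_out):
            acc = b[j]
            for u in range(kernel):
                src = t + u * dilation - left
                if 0 <= src < length:
                    for i in range(c_in):
                        acc += x[src, i] * w[u, i, j]
            out[t, j] = acc
    return out


def lstm_oracle(x_t, h_prev, c_prev, p):
    """Independent transcription of the six gate equations."""
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    hx = np.concatenate([h_prev, x_t])
    f = sig(hx @ p.w_f.data + p.b_f.data)
    i = sig(hx @ p.w_i.data + p.b_i.data)
    c_tilde = np.tanh(hx @ p.w_c.data + p.b_c.data)
    c = f * c_prev + i * c_tilde
    o = sig(hx @ p.w_o.data + p.b_o.data)
    return o * np.tanh(c), c


def _layer(w, b, dilation=1, activation="linear"):
    w = np.asarray(w, dtype=float)
    return ConvLayerParams(
        kernel_size=w.shape[0], n_filters=w.shape[2],
        weights=Tensor(w), bias=Tensor(np.asarray(b, dtype=float)),
        dilation=dilation, activation=activation,
    )


class TestConv1d:
    def test_width_one_identity_kernel(self, rng):
        x = rng.normal(size=(10, 3))
        w = np.zeros((1, 3, 1))
        w[0, 0, 0] = 1.0  # pass channel 0 through
        out = conv1d(x, _layer(w, [0.0]))
        assert np.allclose(out.numpy()[:, 0], x[:, 0])

    @pytest.mark.parametrize("kernel,dilation", [(3, 1), (3, 2), (5, 3)])
    def test_receptive_field_span(self, kernel, dilation):
        # an impulse spreads over exactly (k-1)*d + 1 positions
        length = 41
        x = np.zeros((length, 1))
        x[length // 2, 0] = 1.0
        w = np.ones((kernel, 1, 1))
        out = conv1d(x, _layer(w, [0.0], dilation=dilation)).numpy()[:, 0]
        nz = np.nonzero(out)[0]
        assert len(nz) == kernel  # one tap per kernel element
        assert nz[-1] - nz[0] + 1 == (kernel - 1) * dilation + 1  # full span

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.normal(size=(10, 3))
        w = rng.normal(size=(3, 3, 2))
        b = rng.normal(size=2)
        out = conv1d(x, _layer(w, b)).numpy()
        assert np.allclose(out, conv_oracle(x, w, b, 1), atol=1e-12)

    def test_dilated_matches_oracle(self, rng):
        x = rng.normal(size=(12, 2))
        w = rng.normal(size=(4, 2, 3))
        b = rng.normal(size=3)
        out = conv1d(x, _layer(w, b, dilation=2)).numpy()
        assert np.allclose(out, conv_oracle(x, w, b, 2), atol=1e-12)

    def test_fan_in_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="channel"):
            conv1d(rng.normal(size=(10, 4)), _layer(np.zeros((3, 3, 2)), np.zeros(2)))

    def test_same_length_output(self, rng):
        x = rng.normal(size=(17, 2))
        out = conv1d(x, _layer(rng.normal(size=(16, 2, 5)), np.zeros(5), dilation=2))
        assert out.shape == (17, 5)


class TestLSTMStep:
    def test_zero_parameters_closed_form(self):
        p = _lstm_params(np.random.default_rng(0), 3, 2)
        for t in p.tensors():
            t.data[:] = 0.0
        c_prev = np.array([0.4, -0.8])
        h, c = lstm_step(np.ones(3), np.zeros(2), c_prev, p)
        # f = i = o = sigmoid(0) = 0.5, candidate = tanh(0) = 0
        assert np.allclose(c.numpy(), 0.5 * c_prev)
        assert np.allclose(h.numpy(), 0.5 * np.tanh(0.5 * c_prev))

    def test_zero_cell_and_params_gives_zero_hidden(self):
        p = _lstm_params(np.random.default_rng(0), 3, 2)
        for t in p.tensors():
            t.data[:] = 0.0
        h, _ = lstm_step(np.ones(3), np.zeros(2), np.zeros(2), p)
        assert np.allclose(h.numpy(), 0.0)

    def test_matches_six_equation_oracle(self, rng):
        p = _lstm_params(rng, 5, 4)
        x, h0, c0 = rng.normal(size=5), rng.normal(size=4), rng.normal(size=4)
        h, c = lstm_step(x, h0, c0, p)
        h_ref, c_ref = lstm_oracle(x, h0, c0, p)
        assert np.allclose(h.numpy(), h_ref, atol=1e-10)
        assert np.allclose(c.numpy(), c_ref, atol=1e-10)

    def test_dimension_mismatch_errors(self, rng):
        p = _lstm_params(rng, 5, 4)
        with pytest.raises(ValueError):
            lstm_step(rng.normal(size=5), rng.normal(size=3), rng.normal(size=3), p)


class TestBiLSTM:
    def test_output_width_is_twice_hidden(self, rng):
        fwd = _lstm_params(rng, 6, 16)
        bwd = _lstm_params(rng, 6, 16)
        out = bilstm_encode(rng.normal(size=(9, 6)), fwd, bwd)
        assert out.shape == (9, 32)  # 16 + 16 per position

    def test_matches_unidirectional_oracle(self, rng):
        fwd = _lstm_params(rng, 4, 3)
        bwd = _lstm_params(rng, 4, 3)
        x = rng.normal(size=(3, 4))

        def run(params, xs):
            h, c = np.zeros(3), np.zeros(3)
            states = []
            for t in range(len(xs)):
                h, c = lstm_oracle(xs[t], h, c, params)
                states.append(h)
            return np.stack(states)

        expected = np.concatenate([run(fwd, x), run(bwd, x[::-1])[::-1]], axis=1)
        assert np.allclose(bilstm_encode(x, fwd, bwd).numpy(), expected, atol=1e-10)

    def test_reversal_symmetry(self, rng):
        fwd = _lstm_params(rng, 4, 3)
        bwd = _lstm_params(rng, 4, 3)
        x = rng.normal(size=(6, 4))
        base = bilstm_encode(x, fwd, bwd).numpy()
        flipped = bilstm_encode(x[::-1].copy(), bwd, fwd).numpy()
        # reversing input + swapping directions reverses rows and swaps halves
        swapped = np.concatenate([flipped[:, 3:], flipped[:, :3]], axis=1)[::-1]
        assert np.allclose(base, swapped, atol=1e-12)


class TestFrontend:
    def test_small_config_shapes_and_slices(self, small_cfg, rng):
        params = init_params(small_cfg, seed=0)
        tokens = rng.integers(0, small_cfg.vocab_size, size=small_cfg.max_len)
        out = frontend(tokens, small_cfg, params).numpy()
        assert out.shape == (small_cfg.max_len, small_cfg.d_model)
        # channel order: BiLSTM first, CNN branch second
        from confrna import autograd as ag
        embedded = ag.embedding(params.embedding, tokens)
        recurrent = bilstm_encode(embedded, params.lstm_fwd, params.lstm_bwd).numpy()
        convolved = embedded
        for layer in params.cnn:
            convolved = conv1d(convolved, layer)
        assert np.allclose(out[:, : 2 * small_cfg.lstm_hidden], recurrent)
        assert np.allclose(out[:, 2 * small_cfg.lstm_hidden:], convolved.numpy())

    def test_all_pad_input_is_finite(self, small_cfg):
        params = init_params(small_cfg, seed=0)
        tokens = np.full(small_cfg.max_len, small_cfg.vocab_size - 1)
        assert np.isfinite(frontend(tokens, small_cfg, params).numpy()).all()

    def test_wrong_length_errors(self, small_cfg):
        params = init_params(small_cfg, seed=0)
        with pytest.raises(ValueError, match="length"):
            frontend(np.zeros(10, dtype=int), small_cfg, params)


class TestFuseAndBlock:
    def test_fuse_zero_attention_projection_is_identity(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=1)
        params.fuse_mha.w_o.data[:] = 0.0
        x = rng.normal(size=(8, micro_cfg.d_model))
        out = mlp_attention_fuse(x, params.fuse_mlp, params.fuse_mha)
        assert np.array_equal(out.numpy(), x)

    def test_block_zero_attention_projection_is_identity(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=1)
        params.block1.mha.w_o.data[:] = 0.0
        x = rng.normal(size=(8, micro_cfg.d_model))
        assert np.array_equal(block(x, params.block1).numpy(), x)

    def test_block_preserves_shape(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=1)
        x = rng.normal(size=(8, micro_cfg.d_model))
        assert block(x, params.block1).shape == x.shape

    def test_block_wrong_channels_errors(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=1)
        with pytest.raises(ValueError, match="channels"):
            block(rng.normal(size=(8, micro_cfg.d_model + 1)), params.block1)


class TestDownsample:
    def test_headline_shape(self, rng):
        out = downsample(rng.normal(size=(224, 128)))
        assert out.shape == (112, 256)

    def test_lossless_inverse(self, rng):
        x = rng.normal(size=(10, 4))
        recovered = downsample(x).numpy().reshape(10, 4)
        assert np.array_equal(recovered, x)

    def test_index_arithmetic_on_numbered_grid(self):
        length, channels = 6, 3
        x = np.arange(length * channels).reshape(length, channels)
        out = downsample(x).numpy()
        for t in range(length // 2):
            for c in range(2 * channels):
                assert out[t, c] == x[2 * t + c // channels, c % channels]

    def test_odd_length_errors(self, rng):
        with pytest.raises(ValueError, match="odd"):
            downsample(rng.normal(size=(7, 4)))


class TestForward:
    def test_probabilities_sum_to_one(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=2)
        tokens = rng.integers(0, micro_cfg.vocab_size, size=(3, micro_cfg.max_len))
        probs = forward(tokens, micro_cfg, params).numpy()
        assert probs.shape == (3, micro_cfg.n_classes)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform(self, micro_cfg, rng):
        params = init_params(micro_cfg, seed=2)
        params.head.w2.data[:] = 0.0
        params.head.b2.data[:] = 0.0
        tokens = rng.integers(0, micro_cfg.vocab_size, size=micro_cfg.max_len)
        probs = forward(tokens, micro_cfg, params).numpy()
        assert np.allclose(probs, 1.0 / micro_cfg.n_classes)

    def test_deterministic_inference(self, micro_cfg, rng):
        model = ConF(micro_cfg, seed=3)
        tokens = rng.integers(0, micro_cfg.vocab_size, size=(2, micro_cfg.max_len))
        assert np.array_equal(model.predict_proba(tokens), model.predict_proba(tokens))

    def test_default_config_has_thirteen_classes(self):
        assert ModelConfig().n_classes == 13


class TestGradients:
    def test_autodiff_matches_finite_differences(self, micro_cfg, rng):
        """Central-difference gradient check on a sampled parameter subset."""
        model = ConF(micro_cfg, seed=4)
        tokens = rng.integers(0, micro_cfg.vocab_size, size=(4, micro_cfg.max_len))
        labels = rng.integers(0, micro_cfg.n_classes, size=4)

        def loss_value():
            return float(cross_entropy(model.logits(tokens), labels).data)

        loss = cross_entropy(model.logits(tokens), labels)
        model.zero_grad()
        loss.backward()

        eps = 1e-6
        checked = 0
        for tensor in rng.choice(model.parameters(), size=6, replace=False):
            if tensor.grad is None:
                continue
            flat_idx = int(rng.integers(tensor.data.size))
            idx = np.unravel_index(flat_idx, tensor.data.shape)
            original = tensor.data[idx]
            tensor.data[idx] = original + eps
            up = loss_value()
            tensor.data[idx] = original - eps
            down = loss_value()
            tensor.data[idx] = original
            numeric = (up - down) / (2 * eps)
            analytic = tensor.grad[idx]
            denom = max(abs(numeric), abs(analytic), 1e-8)
            assert abs(numeric - analytic) / denom < 1e-4
            checked += 1
        assert checked >= 4


class TestCheckpoint:
    def test_save_load_round_trip(self, micro_cfg, rng, tmp_path):
        model = ConF(micro_cfg, seed=5)
        tokens = rng.integers(0, micro_cfg.vocab_size, size=(2, micro_cfg.max_len))
        expected = model.predict_proba(tokens)
        model.save(tmp_path / "ckpt.npz")
        again = ConF.load(tmp_path / "ckpt.npz")
        assert again.cfg == micro_cfg
        assert np.array_equal(again.predict_proba(tokens), expected)


def test_stage_shapes_small_config(small_cfg):
    """Front-end L x d_model -> fuse -> block -> L/2 x 2 d_model -> classes."""
    params = init_params(small_cfg, seed=6)
    cfg = small_cfg
    ds = generate(easy_four_family_config(seed=3, n_per_family=1))
    tokens = tokenize_dataset(ds, build_vocab(cfg.k), cfg.max_len)
    x = frontend(tokens, cfg, params)
    assert x.shape == (4, cfg.max_len, cfg.d_model)
    fused = mlp_attention_fuse(x, params.fuse_mlp, params.fuse_mha)
    assert fused.shape == x.shape
    b1 = block(fused, params.block1)
    assert b1.shape == x.shape
    down = downsample(b1)
    assert down.shape == (4, cfg.max_len // 2, 2 * cfg.d_model)
    b2 = block(down, params.block2)
    assert b2.shape == down.shape
    probs = forward(tokens, cfg, params)
    assert probs.shape == (4, cfg.n_classes)
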