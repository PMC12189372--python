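import numpy as np
import pytest

from plantrbp.seqio import LabeledSequence
from plantrbp.textcnn import (
    DimensionMismatchError,
    ImprovedTextCNN,
    OriginalTextCNN,
    TextCNNConfig,
    attend,
    encode_residue_indices,
    load_model,
)


def test_config_rejects_oversized_kernels():
    with pytest.raises(ValueError, match="kernel sizes"):
        TextCNNConfig(input_dim=424, kernel_sizes=(500,))


def test_branch_and_fusion_shapes():
    """Three kernel sizes x 64 filters give three 64-dim pooled vectors and
    a 192-dim fused representation, whatever the input length."""
    for n in (424, 420, 100):
        net = ImprovedTextCNN(TextCNNConfig(input_dim=n, seed=0))
        X = np.random.default_rng(0).normal(size=(8, n))
        _, (branch_cache, head_cache) = net._forward(net._check_input(X))
        tokens = head_cache[0]
        assert tokens.shape == (8, 3, 64)
        fused = head_cache[2]
        assert fused.shape == (8, 192)


def test_attention_flag_only_changes_fusion():
    cfg_on = TextCNNConfig(input_dim=50, seed=1)
    cfg_off = TextCNNConfig(input_dim=50, use_attention=False, seed=1)
    X = np.random.default_rng(2).normal(size=(4, 50))
    for cfg in (cfg_on, cfg_off):
        net = ImprovedTextCNN(cfg)
        p = net.predict_proba(X)
        assert p.shape == (4,)
        assert ((p >= 0) & (p <= 1)).all()


def test_attention_uniform_for_identical_tokens(rng):
    v = rng.normal(size=6)
    fused, weights = attend(np.stack([v, v, v]))
    np.testing.assert_allclose(weights, np.full((3, 3), 1 / 3), atol=1e-12)
    np.testing.assert_allclose(fused, np.tile(v, 3), atol=1e-12)


def test_attention_matches_direct_formula(rng):
    T = rng.normal(size=(5, 3, 4))
    fused, weights = attend(T)
    for b in range(5):
        S = T[b] @ T[b].T / np.sqrt(4)
        A = np.exp(S) / np.exp(S).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(weights[b], A, atol=1e-6)
        np.testing.assert_allclose(fused[b], (A @ T[b]).ravel(), atol=1e-6)
    np.testing.assert_allclose(weights.sum(axis=-1), 1.0, atol=1e-6)
    assert (weights >= 0).all()


def test_attention_rejects_ragged_branches():
    with pytest.raises(ValueError):
        attend([np.zeros(3), np.zeros(4)])


def _numeric_gradients(net, X, y):
    def loss():
        p, _ = net._forward(net._check_input(X))
        p = np.clip(p, 1e-7, 1 - 1e-7)
        return -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))

    p, cache = net._forward(net._check_input(X), train=True,
                            rng=np.random.default_rng(9))
    grads = net._backward(cache, (np.clip(p, 1e-7, 1 - 1e-7) - y) / len(y))
    worst = 0.0
    for k, g in grads.items():
        num = np.zeros_like(g)
        it = np.nditer(net.params[k], flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = net.params[k][i]
            net.params[k][i] = old + 1e-6
            lp = loss()
            net.params[k][i] = old - 1e-6
            lm = loss()
            net.params[k][i] = old
            num[i] = (lp - lm) / 2e-6
        if k == "Emb":
            num[0] = 0  # padding row is pinned
        worst = max(worst, np.max(np.abs(num - g)) / (np.max(np.abs(num)) + 1e-12))
    return worst


def test_improved_model_gradients_match_finite_differences(rng):
    cfg = TextCNNConfig(input_dim=18, kernel_sizes=(3, 4), filters_per_kernel=4,
                        dense_units=5, dropout_rate=0.0, seed=1)
    net = ImprovedTextCNN(cfg, dtype=np.float64)
    X = rng.normal(size=(6, 18))
    y = rng.integers(0, 2, 6).astype(float)
    assert _numeric_gradients(net, X, y) < 1e-5


def test_original_model_gradients_match_finite_differences(rng):
    cfg = TextCNNConfig(input_dim=15, kernel_sizes=(3,), filters_per_kernel=4,
                        dense_units=5, dropout_rate=0.0, seed=1)
    net = OriginalTextCNN(vocab_size=8, embed_dim=3, max_len=15, config=cfg,
                          dtype=np.float64)
    X = rng.integers(0, 8, (6, 15))
    y = rng.integers(0, 2, 6).astype(float)
    assert _numeric_gradients(net, X, y) < 1e-5


class _ScriptedNet(ImprovedTextCNN):
    """Freezes learning so the validation loss plateaus immediately."""

    def _adam_step(self, grads):
        pass


def test_patience_arithmetic_on_plateau(rng):
    cfg = TextCNNConfig(input_dim=12, kernel_sizes=(3,), filters_per_kernel=3,
                        dense_units=4, dropout_rate=0.0, patience=5,
                        max_epochs=50, seed=0)
    net = _ScriptedNet(cfg)
    X = rng.normal(size=(20, 12))
    y = np.tile([0, 1], 10)
    history = net.fit(X[:16], y[:16], X[16:], y[16:])
    # epoch 1 sets the best; 5 consecutive non-decreases then stop
    assert history.best_epoch == 1
    assert history.stopped_epoch == 6
    assert history.stopped_epoch - history.best_epoch <= cfg.patience


def test_training_is_deterministic(rng):
    cfg = TextCNNConfig(input_dim=30, kernel_sizes=(3, 4), filters_per_kernel=6,
                        dense_units=8, max_epochs=4, seed=11)
    X = rng.normal(size=(60, 30))
    y = rng.integers(0, 2, 60)
    h1 = ImprovedTextCNN(cfg).fit(X[:48], y[:48], X[48:], y[48:])
    h2 = ImprovedTextCNN(cfg).fit(X[:48], y[:48], X[48:], y[48:])
    np.testing.assert_allclose(h1.val_loss, h2.val_loss, atol=1e-6)
    np.testing.assert_allclose(h1.train_loss, h2.train_loss, atol=1e-6)


def test_single_class_training_labels_error(rng):
    net = ImprovedTextCNN(TextCNNConfig(input_dim=10, kernel_sizes=(3,)))
    X = rng.normal(size=(10, 10))
    with pytest.raises(ValueError, match="single class"):
        net.fit(X, np.ones(10), X, np.ones(10))


def test_learns_separable_features():
    """Validation accuracy >= 0.95 on linearly separable 424-dim inputs."""
    rng = np.random.default_rng(0)
    y = np.tile([0, 1], 200)
    X = rng.normal(size=(400, 424)) + 2.0 * y[:, None]
    cfg = TextCNNConfig(seed=3)
    net = ImprovedTextCNN(cfg)
    history = net.fit(X[:320], y[:320], X[320:], y[320:])
    assert max(history.val_acc) >= 0.95
    assert history.stopped_epoch <= cfg.max_epochs


def test_predict_contracts(rng):
    net = ImprovedTextCNN(TextCNNConfig(input_dim=20, kernel_sizes=(3,), seed=0))
    X = rng.normal(size=(5, 20))
    p = net.predict_proba(np.vstack([X, X[:1]]))
    # duplicated row scores identically (to single-precision accumulation)
    assert p[0] == pytest.approx(p[-1], abs=1e-6)
    assert ((p >= 0) & (p <= 1)).all()
    with pytest.raises(DimensionMismatchError, match="expected 20"):
        net.predict_proba(rng.normal(size=(5, 21)))


def test_residue_integer_encoding_pads_and_truncates():
    seqs = [LabeledSequence("a", "ACDEFG", 1)]
    enc = encode_residue_indices(seqs, max_len=10)
    assert enc.shape == (1, 10)
    assert (enc[0, 6:] == 0).all()
    assert enc[0, 0] == 1  # 'A' is index 1; 0 is padding
    assert encode_residue_indices(seqs, max_len=3).shape == (1, 3)


def test_original_textcnn_outputs_probabilities(rng):
    cfg = TextCNNConfig(input_dim=30, kernel_sizes=(3, 4), filters_per_kernel=4,
                        dense_units=6, seed=0)
    net = OriginalTextCNN(vocab_size=21, embed_dim=4, max_len=30, config=cfg)
    assert net.params["Emb"].shape == (21, 4)
    X = rng.integers(0, 21, (6, 30))
    p = net.predict_proba(X)
    assert ((p >= 0) & (p <= 1)).all()


def test_save_and_load_roundtrip(tmp_path, rng):
    cfg = TextCNNConfig(input_dim=25, kernel_sizes=(3,), filters_per_kernel=4,
                        dense_units=6, seed=2)
    net = ImprovedTextCNN(cfg)
    X = rng.normal(size=(4, 25))
    net.save(tmp_path / "m")
    back = load_model(tmp_path / "m")
    np.testing.assert_allclose(net.predict_proba(X), back.predict_proba(X),
                               atol=1e-7)
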