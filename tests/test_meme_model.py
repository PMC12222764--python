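"""Fusion head: attention algebra, losses, training contracts, variants."""

import math

import numpy as np
import pytest

from meme_ed import nn
from meme_ed.concepts import CONCEPT_ORDER, ConceptKind
from meme_ed.meme_model import (
    MemeHyperparams,
    MemeModelState,
    attention_weights,
    binary_loss,
    build_variant,
    fine_tune_head,
    forward,
    fuse_self_attention,
    multilabel_loss,
    predict_proba,
    single_concept_input,
    train_head,
)

DIM = 32


def _state(kind="meme", seed=0, task_mode="binary", dim=DIM):
    hp = MemeHyperparams(task_mode=task_mode, seed=seed)
    model = build_variant(kind, dim, hp, np.random.default_rng(seed))
    return MemeModelState(kind=kind, dim=dim, hyperparams=hp,
                          arrays=model.state_arrays())


# ---------------------------------------------------------------------------
# losses


def test_zero_logit_losses_are_ln2_per_term():
    assert multilabel_loss([[0.0]], [[1.0]]) == pytest.approx(math.log(2), abs=1e-10)
    assert multilabel_loss([[0.0, 0.0]], [[1.0, 0.0]]) == pytest.approx(
        2 * math.log(2), abs=1e-10
    )
    assert binary_loss([0.0], [0.0]) == pytest.approx(math.log(2), abs=1e-10)


def test_loss_limits():
    assert multilabel_loss([[25.0]], [[1.0]]) < 1e-8
    n = 50
    z = np.where(np.arange(n) % 2 == 0, 20.0, -20.0)
    y = (z > 0).astype(float)
    assert binary_loss(z, y) < 1e-8 * n


def test_binary_equals_multilabel_with_one_column():
    rng = np.random.default_rng(0)
    z = rng.normal(size=20)
    y = rng.integers(0, 2, 20).astype(float)
    assert binary_loss(z, y) == pytest.approx(
        multilabel_loss(z.reshape(-1, 1), y.reshape(-1, 1)), abs=1e-12
    )


def test_multilabel_loss_matches_elementwise_oracle():
    """Direct -[y ln p + (1-y) ln(1-p)] summation on random batches."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        z = rng.normal(scale=3, size=(8, 3))
        y = rng.integers(0, 2, (8, 3)).astype(float)
        p = 1 / (1 + np.exp(-z))
        oracle = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert multilabel_loss(z, y) == pytest.approx(oracle, abs=1e-10)


def test_loss_shape_mismatch_errors():
    with pytest.raises(ValueError):
        multilabel_loss(np.zeros((2, 3)), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# attention


def test_attention_rows_are_simplex_on_random_states():
    rng = np.random.default_rng(1)
    for seed in range(5):
        state = _state(seed=seed)
        x = rng.normal(size=(6, DIM)).astype(np.float32)
        w = attention_weights(x, state)
        assert w.shape == (1, 6, 6)
        assert np.all(w >= 0)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)


def test_identical_concept_vectors_give_uniform_attention():
    state = _state(seed=3)
    x = np.tile(np.random.default_rng(2).normal(size=(1, DIM)), (6, 1))
    w = attention_weights(x.astype(np.float32), state)
    assert np.allclose(w, 1.0 / 6.0, atol=1e-6)


def test_single_concept_attention_is_identity_weight():
    state = _state(kind="single:triage", seed=0)
    x = np.random.default_rng(4).normal(size=(1, DIM)).astype(np.float32)
    w = attention_weights(x, state)
    assert w.shape == (1, 1, 1)
    assert w[0, 0, 0] == pytest.approx(1.0, abs=1e-7)
    fused = fuse_self_attention(x, state)
    wv = state.arrays["0.Wv"]
    assert np.allclose(fused, (x @ wv).reshape(-1), atol=1e-5)


def test_attention_gradient_matches_numerical():
    rng = np.random.default_rng(0)
    layer = nn.SelfAttention(8, 2, rng)
    x = rng.normal(size=(2, 3, 8)).astype(np.float32)
    out = layer.forward(x.copy(), train=True)
    g = rng.normal(size=out.shape).astype(np.float32)
    dx = layer.backward(g)
    eps = 1e-3
    for idx in [(0, 0, 0), (1, 2, 7), (0, 1, 3)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fp = float((layer.forward(xp, train=True) * g).sum())
        fm = float((layer.forward(xm, train=True) * g).sum())
        num = (fp - fm) / (2 * eps)
        assert dx[idx] == pytest.approx(num, rel=0.05, abs=1e-3)


# ---------------------------------------------------------------------------
# forward


def test_zero_classifier_gives_half_probabilities():
    state = _state()
    state.arrays["4.W"] = np.zeros_like(state.arrays["4.W"])
    state.arrays["4.b"] = np.zeros_like(state.arrays["4.b"])
    x = np.random.default_rng(0).normal(size=(6, DIM)).astype(np.float32)
    assert forward(x, state) == pytest.approx(0.0, abs=0)
    assert predict_proba(state, x[None])[0, 0] == pytest.approx(0.5)


def test_relu_kill_leaves_classifier_bias():
    state = _state()
    # force all FC pre-activations negative
    state.arrays["2.W"] = np.zeros_like(state.arrays["2.W"])
    state.arrays["2.b"] = np.full_like(state.arrays["2.b"], -5.0)
    state.arrays["4.b"] = np.full_like(state.arrays["4.b"], 0.73)
    x = np.random.default_rng(1).normal(size=(6, DIM)).astype(np.float32)
    assert forward(x, state)[0] == pytest.approx(0.73, abs=1e-6)


def test_forward_deterministic():
    state = _state()
    x = np.random.default_rng(5).normal(size=(6, DIM)).astype(np.float32)
    assert np.array_equal(forward(x, state), forward(x, state))


def test_dimension_mismatch_errors():
    state = _state()
    with pytest.raises(ValueError):
        fuse_self_attention(np.zeros((6, DIM + 1), dtype=np.float32), state)


# ---------------------------------------------------------------------------
# variants


def test_variant_shapes_and_parameter_counts():
    hp = MemeHyperparams()
    rng = np.random.default_rng(0)
    meme = build_variant("meme", DIM, hp, rng)
    msem = build_variant("msem", DIM, hp, np.random.default_rng(0))
    count = lambda m: sum(p.size for l, n in m.parameters() for p in [l.params[n]])
    assert count(meme) > count(msem)
    with pytest.raises(ValueError):
        build_variant("single:nonsense", DIM, hp)
    X = np.zeros((4, 6, DIM), dtype=np.float32)
    assert single_concept_input(X, ConceptKind.ARRIVAL).shape == (4, 1, DIM)


# ---------------------------------------------------------------------------
# training


def _toy_task(n=400, dim=DIM, seed=0):
    """Linearly separable signal in one concept position."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 6, dim)).astype(np.float32)
    w = rng.normal(size=dim)
    logits = X[:, 1, :] @ w * 2.0
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
    return X, y.reshape(-1, 1)


def test_training_is_seed_reproducible():
    X, y = _toy_task()
    hp = MemeHyperparams(task_mode="binary", seed=9, epochs=3)
    s1 = train_head(X[:300], y[:300], X[300:], y[300:], hp)
    s2 = train_head(X[:300], y[:300], X[300:], y[300:], hp)
    assert s1.arrays.keys() == s2.arrays.keys()
    for k in s1.arrays:
        assert np.array_equal(s1.arrays[k], s2.arrays[k])
    assert s1.train_log == s2.train_log


def test_training_learns_separable_signal_and_inputs_stay_frozen():
    X, y = _toy_task(n=600)
    before = X.copy()
    hp = MemeHyperparams(task_mode="binary", seed=0, epochs=10)
    state = train_head(X[:450], y[:450], X[450:], y[450:], hp)
    assert np.array_equal(X, before)  # embeddings are constants
    losses = [e["train_loss"] for e in state.train_log]
    assert losses[-1] < losses[0]
    # head-only state: attention + FC + classifier arrays, nothing else
    assert set(state.arrays) == {"0.Wq", "0.Wk", "0.Wv", "2.W", "2.b", "4.W", "4.b"}


def test_training_requires_validation_and_matching_labels():
    X, y = _toy_task(n=60)
    hp = MemeHyperparams(task_mode="binary", seed=0, epochs=1)
    with pytest.raises(ValueError, match="validation"):
        train_head(X, y, X[:0], y[:0], hp)
    with pytest.raises(ValueError, match="task_mode"):
        train_head(X, np.hstack([y, y, y]), X[:10], np.hstack([y, y, y])[:10], hp)


def test_state_round_trips_exactly(tmp_path):
    X, y = _toy_task(n=80)
    hp = MemeHyperparams(task_mode="binary", seed=1, epochs=2)
    state = train_head(X[:60], y[:60], X[60:], y[60:], hp)
    state.save(tmp_path / "m")
    loaded = MemeModelState.load(tmp_path / "m")
    for k in state.arrays:
        assert np.array_equal(state.arrays[k], loaded.arrays[k])
    x = X[:5]
    assert np.array_equal(predict_proba(state, x), predict_proba(loaded, x))


def test_fine_tune_changes_parameters_deterministically():
    X, y = _toy_task(n=120)
    hp = MemeHyperparams(task_mode="binary", seed=0, epochs=2)
    state = train_head(X[:90], y[:90], X[90:], y[90:], hp)
    ft1 = fine_tune_head(state, X[:16], y[:16], epochs=2, seed=5)
    ft2 = fine_tune_head(state, X[:16], y[:16], epochs=2, seed=5)
    assert any(
        not np.array_equal(state.arrays[k], ft1.arrays[k]) for k in state.arrays
    )
    for k in ft1.arrays:
        assert np.array_equal(ft1.arrays[k], ft2.arrays[k])


def test_multilabel_training_smoke():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(200, 6, DIM)).astype(np.float32)
    y = rng.integers(0, 2, (200, 3)).astype(float)
    hp = MemeHyperparams(task_mode="multilabel", seed=0, epochs=2)
    state = train_head(X[:150], y[:150], X[150:], y[150:], hp)
    assert predict_proba(state, X[:4]).shape == (4, 3)
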