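import numpy as np
import pytest

from bactgene.tokenizer import encode_sequence
from bactgene.training import cross_entropy
from bactgene.transformer import (ModelConfig, TransformerClassifier,
                                  attention_head, multi_head_attention,
                                  softmax)


def naive_attention(M, Wq, Wk, Wv):
    """Dense step-by-step oracle for a single attention head."""
    Q, K, V = M @ Wq, M @ Wk, M @ Wv
    d_k = Q.shape[1]
    S = Q @ K.T / np.sqrt(d_k)
    E = np.exp(S - S.max(axis=1, keepdims=True))
    W = E / E.sum(axis=1, keepdims=True)
    return W @ V, W


def test_attention_single_token_is_one():
    M = np.random.default_rng(0).normal(size=(1, 4))
    W = np.eye(4)
    _, weights = attention_head(M, W, W, W)
    assert np.allclose(weights, [[1.0]])


def test_attention_identical_embeddings_uniform():
    M = np.tile(np.random.default_rng(1).normal(size=(1, 4)), (5, 1))
    W = np.random.default_rng(2).normal(size=(4, 4))
    _, weights = attention_head(M, W, W, W)
    assert np.allclose(weights, np.full((5, 5), 0.2))


@pytest.mark.parametrize("seed", range(20))
def test_attention_head_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(5, 8))
    Wq, Wk, Wv = (rng.normal(size=(8, 4)) for _ in range(3))
    values, weights = attention_head(M, Wq, Wk, Wv)
    o_values, o_weights = naive_attention(M, Wq, Wk, Wv)
    assert np.allclose(values, o_values, atol=1e-5)
    assert np.allclose(weights, o_weights, atol=1e-5)


def test_attention_all_masked_errors():
    M = np.zeros((3, 4))
    W = np.eye(4)
    with pytest.raises(ValueError):
        attention_head(M, W, W, W, mask=np.zeros(3))


def test_multi_head_single_head_identity():
    rng = np.random.default_rng(3)
    M = rng.normal(size=(6, 4))
    heads = [tuple(rng.normal(size=(4, 4)) for _ in range(3))]
    out = multi_head_attention(M, heads, np.eye(4))
    assert np.allclose(out, attention_head(M, *heads[0])[0])


def test_multi_head_zero_values_zero_output():
    rng = np.random.default_rng(4)
    M = rng.normal(size=(6, 4))
    heads = [(rng.normal(size=(4, 2)), rng.normal(size=(4, 2)),
              np.zeros((4, 2))) for _ in range(2)]
    out = multi_head_attention(M, heads, rng.normal(size=(4, 4)))
    assert np.allclose(out, 0.0)


def test_multi_head_matches_concat_oracle():
    rng = np.random.default_rng(5)
    M = rng.normal(size=(7, 8))
    heads = [tuple(rng.normal(size=(8, 2)) for _ in range(3))
             for _ in range(4)]
    Wo = rng.normal(size=(8, 8))
    concat = np.concatenate(
        [naive_attention(M, *h)[0] for h in heads], axis=1)
    assert np.allclose(multi_head_attention(M, heads, Wo), concat @ Wo,
                       atol=1e-10)
    with pytest.raises(ValueError):
        multi_head_attention(M, heads[:2], Wo)


def _model(max_positions=16, **kw):
    cfg = ModelConfig(vocab_size=50, max_positions=max_positions,
                      n_layers=2, d_hidden=16, n_heads=4, dtype="float64",
                      **kw)
    return TransformerClassifier(cfg, seed=7)


def _batch(model, B=3, L=10, seed=0):
    rng = np.random.default_rng(seed)
    ids = rng.integers(4, 50, size=(B, L))
    ids[:, 0] = 2
    mask = np.ones((B, L), dtype=int)
    if B > 1:
        mask[1, 7:] = 0
    if B > 2:
        mask[2, 5:] = 0
    ids[mask == 0] = 0
    return ids, mask


def test_attention_rows_stochastic_and_pads_zero():
    model = _model()
    ids, mask = _batch(model)
    cache = model.forward(ids, mask, collect_attention=True)
    for A in cache["attentions"]:
        n_real = mask.sum(1)
        for b in range(len(ids)):
            real = A[b, :, :int(n_real[b]), :]
            assert np.allclose(real.sum(-1), 1.0, atol=1e-5)
            # padded keys receive zero mass
            assert np.all(real[:, :, int(n_real[b]):] == 0.0)


def test_classify_invariant_to_pad_embeddings():
    model = _model()
    ids, mask = _batch(model)
    p1 = model.forward(ids, mask)["probs"]
    model.params["tok_emb"][0] += 37.0  # perturb the [PAD] embedding row
    p2 = model.forward(ids, mask)["probs"]
    assert np.allclose(p1, p2, atol=1e-5)


def test_classify_symmetric_with_zeroed_head():
    model = _model()
    model.params["Wc"][:] = 0.0
    model.params["bc"][:] = 0.0
    ids, mask = _batch(model, B=1, L=10)
    probs = model.forward(ids, mask)["probs"]
    assert np.allclose(probs, 0.5)


def test_classify_deterministic():
    model = _model()
    ids, mask = _batch(model)
    assert np.array_equal(model.forward(ids, mask)["probs"],
                          model.forward(ids, mask)["probs"])


def test_softmax_closed_form():
    # logits (2, 0): p_pos = e^2 / (e^2 + 1) with the positive logit 2
    p = softmax(np.array([[0.0, 2.0]]))
    assert np.isclose(p[0, 1], 0.8808, atol=1e-4)


def test_classify_wrong_length_errors(vocab, tiny_tis_model):
    ts = encode_sequence("A" * 60, vocab, stride=1, max_len=60)
    with pytest.raises(ValueError):
        tiny_tis_model.classify(ts)


def test_attention_maps_tis_geometry(vocab, tiny_tis_model):
    ts = encode_sequence("ACGT" * 15, vocab, stride=1, max_len=57)
    maps = tiny_tis_model.get_attention_maps(ts)
    assert len(maps) == tiny_tis_model.config.n_layers
    for m in maps:
        assert m.weights.shape == (2, 57, 57)
        assert np.allclose(m.weights.sum(-1), 1.0, atol=1e-5)
    maps2 = tiny_tis_model.get_attention_maps(ts)
    assert all(np.array_equal(a.weights, b.weights)
               for a, b in zip(maps, maps2))


def test_backward_matches_numerical_gradient():
    model = _model(max_positions=9)
    rng = np.random.default_rng(0)
    B, L = 2, 7
    ids = rng.integers(0, 50, size=(B, L))
    mask = np.ones((B, L), dtype=int)
    mask[1, 5:] = 0
    y = np.array([0, 1])

    def loss():
        c = model.forward(ids, mask)
        return -np.log(c["probs"][np.arange(B), y]).mean(), c

    base, cache = loss()
    onehot = np.zeros_like(cache["probs"])
    onehot[np.arange(B), y] = 1.0
    grads = model.backward(cache, (cache["probs"] - onehot) / B)
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for name, P in model.params.items():
        flat_idx = check_rng.choice(P.size, size=min(4, P.size),
                                    replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, P.shape)
            old = P[idx]
            P[idx] = old + eps
            lp, _ = loss()
            P[idx] = old - eps
            lm, _ = loss()
            P[idx] = old
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4,
                                                     abs=1e-7), name


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(vocab_size=10, max_positions=8, d_hidden=10, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(vocab_size=10, max_positions=2)


def test_save_load_roundtrip(tmp_path):
    model = _model()
    ids, mask = _batch(model)
    p1 = model.forward(ids, mask)["probs"]
    model.save(tmp_path / "m.npz")
    back = TransformerClassifier.load(tmp_path / "m.npz")
    assert back.config == model.config
    assert np.array_equal(back.forward(ids, mask)["probs"], p1)
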