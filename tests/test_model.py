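import numpy as np
import pytest

from circmil.instancing import WindowGeometry, extract_instances
from circmil.model import (BagNet, ModelConfig, attention_pool, classify_bag,
                           encode_instance, encode_prevectorized_bag,
                           load_checkpoint, save_checkpoint)
from circmil.seqio import SequenceRecord


def naive_attention_pool(C, V, w):
    """Independent oracle: scalar loops over the pooling definition."""
    k, M = C.shape
    L = V.shape[0]
    logits = np.zeros(k)
    for i in range(k):
        for l in range(L):
            acc = 0.0
            for m in range(M):
                acc += V[l, m] * C[i, m]
            logits[i] += w[l] * np.tanh(acc)
    e = np.exp(logits - logits.max())
    alpha = e / e.sum()
    z = np.zeros(M)
    for i in range(k):
        z += alpha[i] * C[i]
    return alpha, z


def test_attention_pool_matches_naive_oracle(rng):
    for _ in range(100):
        k = int(rng.integers(1, 11))
        M = int(rng.integers(1, 9))
        L = int(rng.integers(1, 7))
        C = rng.standard_normal((k, M))
        V = rng.standard_normal((L, M))
        w = rng.standard_normal(L)
        alpha, z = attention_pool(C, V, w)
        a_ref, z_ref = naive_attention_pool(C, V, w)
        np.testing.assert_allclose(alpha, a_ref, atol=1e-6)
        np.testing.assert_allclose(z, z_ref, atol=1e-6)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)


def test_attention_pool_identical_rows_uniform(rng):
    C = np.tile(rng.standard_normal(4), (5, 1))
    alpha, z = attention_pool(C, rng.standard_normal((3, 4)), rng.standard_normal(3))
    np.testing.assert_allclose(alpha, np.full(5, 0.2), atol=1e-12)
    np.testing.assert_allclose(z, C[0], atol=1e-12)


def test_attention_pool_single_instance(rng):
    C = rng.standard_normal((1, 6))
    alpha, z = attention_pool(C, rng.standard_normal((2, 6)), rng.standard_normal(2))
    assert alpha == pytest.approx([1.0])
    np.testing.assert_allclose(z, C[0])


def test_attention_pool_rejects_empty():
    with pytest.raises(ValueError):
        attention_pool(np.empty((0, 3)), np.ones((2, 3)), np.ones(2))


def test_default_config_shapes():
    cfg = ModelConfig()
    net = BagNet(cfg, seed=0)
    assert net.att_V.shape == (30, 100)
    assert net.att_w.shape == (30, 1)
    assert net.embedding.W.shape == (15, 4)
    feat = encode_instance("ACGT" * 18, net)   # 72-nt window
    assert feat.shape == (100,)


def test_encode_instance_deterministic_and_sensitive(tiny_net, rng):
    inst = "".join("ATGC"[c] for c in rng.integers(0, 4, 70))
    f1 = encode_instance(inst, tiny_net)
    f2 = encode_instance(inst, tiny_net)
    np.testing.assert_array_equal(f1, f2)
    # perturbing the final position changes the feature
    alt = inst[:-1] + ("A" if inst[-1] != "A" else "C")
    f3 = encode_instance(alt, tiny_net)
    assert np.abs(f1 - f3).max() > 0


def test_classify_bag_output_contract(tiny_net, geometry, rng, make_record):
    rec = make_record(rng, 100)
    bag = extract_instances(rec, geometry)
    out = classify_bag(tiny_net, bag)
    assert out.instance_features.shape == (len(bag), 5)
    assert out.attention.sum() == pytest.approx(1.0, abs=1e-6)
    assert (out.attention >= 0).all()
    np.testing.assert_allclose(out.weighted_feature,
                               out.attention @ out.instance_features, atol=1e-5)
    assert 0.0 < out.probability < 1.0
    assert out.label == int(out.probability >= 0.5)


def test_bag_probability_permutation_invariant(tiny_net, geometry, rng, make_record):
    rec = make_record(rng, 150)
    bag = extract_instances(rec, geometry)
    out = classify_bag(tiny_net, bag)
    perm = rng.permutation(len(bag))
    shuffled = extract_instances(rec, geometry)
    shuffled.instances = [bag.instances[i] for i in perm]
    shuffled.starts = [bag.starts[i] for i in perm]
    out2 = classify_bag(tiny_net, shuffled)
    assert out2.probability == pytest.approx(out.probability, abs=1e-6)
    np.testing.assert_allclose(out2.attention, out.attention[perm], atol=1e-6)


def test_identical_instances_give_uniform_attention(tiny_net):
    rec = SequenceRecord("x", "ACGTAC" * 4)
    bag = extract_instances(rec, WindowGeometry(window=6, step=6))
    assert len(set(bag.instances)) == 1
    out = classify_bag(tiny_net, bag)
    np.testing.assert_allclose(out.attention, 1.0 / len(bag), atol=1e-6)
    np.testing.assert_allclose(out.weighted_feature, out.instance_features[0],
                               atol=1e-5)


def test_prevectorized_bag_glyph_shapes(rng):
    cfg = ModelConfig(use_embedding=False, input_dim=28, rnn_hidden=10,
                      fcn_hidden=10, feature_dim=10, attention_hidden=5)
    net = BagNet(cfg, seed=0)
    bag = np.zeros((16, 28, 28), dtype=np.float32)
    out = encode_prevectorized_bag(net, bag)
    np.testing.assert_allclose(out.attention, 1.0 / 16, atol=1e-6)
    assert 0.0 < out.probability < 1.0

    noisy = rng.standard_normal((7, 28, 28)).astype(np.float32)
    out1 = encode_prevectorized_bag(net, noisy)
    perm = rng.permutation(7)
    out2 = encode_prevectorized_bag(net, noisy[perm])
    assert out2.probability == pytest.approx(out1.probability, abs=1e-6)


def test_prevectorized_rejects_wrong_shapes(rng):
    cfg = ModelConfig(use_embedding=False, input_dim=28, rnn_hidden=4,
                      fcn_hidden=4, feature_dim=4, attention_hidden=2)
    net = BagNet(cfg, seed=0)
    with pytest.raises(ValueError):
        encode_prevectorized_bag(net, np.zeros((3, 28)))
    with pytest.raises(ValueError):
        net.instance_features(np.zeros((3, 5, 9), dtype=np.float32))


def test_checkpoint_roundtrip(tiny_net, geometry, rng, tmp_path, make_record):
    rec = make_record(rng, 90)
    bag = extract_instances(rec, geometry)
    before = classify_bag(tiny_net, bag).probability
    save_checkpoint(tiny_net, tmp_path / "model")
    restored = load_checkpoint(tmp_path / "model")
    after = classify_bag(restored, bag).probability
    assert after == pytest.approx(before, abs=1e-7)
    assert restored.config == tiny_net.config
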