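"""Patch CNN: exact parameter counting, build/train/predict contracts."""

import numpy as np
import pytest
from dataclasses import replace

from octskin import patchcnn
from octskin.patchcnn import ModelConfig, load_preset, count_parameters, build_model
from octskin.patchset import PatchSet, PatchSpec


# a deliberately tiny architecture so training tests run in seconds
TINY = ModelConfig(
    input_size=23,
    conv_kernels=(3, 3, 3),
    conv_filters=(4, 8, 8),
    pool_kernels=(2, 2, 2),
    pool_strides=(2, 2, 2),
    pool_rounding=("floor", "floor", "floor"),
    fc1_units=8,
    batch_size=64,
    max_epochs=6,
    patience=6,
    seed=5,
    name="tiny",
)


def _closed_form_count(cfg: ModelConfig) -> int:
    """Independent arithmetic: sizes then the parameter sum, written out."""
    n = cfg.input_size
    c_in, total = 1, 0
    for i in range(3):
        k, f = cfg.conv_kernels[i], cfg.conv_filters[i]
        total += (k * k * c_in + 1) * f
        n = n - k + 1 if cfg.conv_padding[i] == "valid" else n
        pk, s = cfg.pool_kernels[i], cfg.pool_strides[i]
        q = (n - pk) / s
        n = int(np.floor(q) if cfg.pool_rounding[i] == "floor" else np.ceil(q)) + 1
        c_in = f
    total += (n * n * c_in + 1) * cfg.fc1_units
    total += (cfg.fc1_units + 1) * cfg.n_outputs
    return total


@pytest.mark.parametrize("cfg", [
    TINY,
    load_preset("cnn-gs-skin"),
    load_preset("cnn-gs-baseline"),
    replace(load_preset("cnn-gs-skin"), conv_kernels=(5, 3, 3), fc1_units=17),
])
def test_count_matches_independent_arithmetic(cfg):
    assert count_parameters(cfg) == _closed_form_count(cfg)


def test_count_errors_name_the_layer():
    bad = replace(TINY, input_size=9)  # collapses inside the second block
    with pytest.raises(ValueError, match=r"(conv|pool)\d"):
        count_parameters(bad)


def test_build_model_introspected_total_matches_count():
    for cfg in (TINY, load_preset("cnn-gs-skin")):
        assert build_model(cfg).n_params == count_parameters(cfg)


def test_build_model_seeded_weights_identical():
    m1, m2 = build_model(TINY), build_model(TINY)
    for a, b in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(a, b)
    m3 = build_model(replace(TINY, seed=6))
    assert any(not np.array_equal(a, b) for a, b in zip(m1.parameters(), m3.parameters()))


def _toy_patchsets(n_per_class=80, seed=0):
    """Classes distinguishable by a bright bar at a class-specific row."""
    rng = np.random.default_rng(seed)
    ps = TINY.input_size
    patches, labels = [], []
    for c in range(3):
        x = rng.normal(0.3, 0.08, size=(n_per_class, ps, ps))
        if c > 0:
            x[:, 5 + 6 * c, :] += 0.6
        patches.append(x)
        labels.append(np.full(n_per_class, c))
    patches = np.clip(np.concatenate(patches), 0, 1).astype(np.float32)
    labels = np.concatenate(labels)
    centers = np.zeros((labels.size, 2), dtype=np.int64)
    spec = PatchSpec(patch_size=ps)
    order = rng.permutation(labels.size)
    cut = int(0.8 * labels.size)
    mk = lambda idx: PatchSet(centers=centers[idx], patches=patches[idx],
                              spec=spec, labels=labels[idx])
    return mk(order[:cut]), mk(order[cut:])


def test_train_learns_and_is_deterministic():
    train_set, val_set = _toy_patchsets()
    m1 = build_model(TINY)
    r1 = patchcnn.train(m1, train_set, val_set, TINY)
    assert r1.train_loss[min(4, len(r1.train_loss) - 1)] < r1.train_loss[0]
    assert r1.stopping_epoch <= TINY.max_epochs - 1
    assert all(0.0 <= a <= 1.0 for a in r1.val_acc)

    m2 = build_model(TINY)
    r2 = patchcnn.train(m2, train_set, val_set, TINY)
    assert r1.to_dict() == r2.to_dict()
    for a, b in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(a, b)


def test_train_rejects_empty_sets():
    train_set, val_set = _toy_patchsets(n_per_class=4)
    empty = train_set.take(np.array([], dtype=int))
    with pytest.raises(ValueError):
        patchcnn.train(build_model(TINY), empty, val_set, TINY)


def test_predict_batch_contracts():
    train_set, _ = _toy_patchsets(n_per_class=10)
    model = build_model(TINY)
    probs = patchcnn.predict_batch(model, train_set)
    assert probs.shape == (len(train_set), TINY.n_outputs)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    # duplicated patch -> identical probability vector
    dup = np.stack([train_set.patches[0], train_set.patches[0]])
    p = patchcnn.predict_batch(model, dup)
    assert np.array_equal(p[0], p[1])
    # chunked vs single-batch equivalence
    whole = model.predict_proba(train_set.patches)
    chunked = np.concatenate([
        model.predict_proba(train_set.patches[:7]),
        model.predict_proba(train_set.patches[7:]),
    ])
    assert np.allclose(whole, chunked, atol=1e-6)


def test_predict_rejects_wrong_patch_size():
    model = build_model(TINY)
    with pytest.raises(ValueError):
        model.predict_proba(np.zeros((2, 31, 31), dtype=np.float32))


def test_save_load_round_trip(tmp_path):
    model = build_model(TINY)
    path = tmp_path / "tiny.npz"
    model.save(path)
    loaded = patchcnn.PatchCNN.load(path)
    x = np.random.default_rng(1).random((5, TINY.input_size, TINY.input_size)).astype(np.float32)
    assert np.array_equal(model.predict_proba(x), loaded.predict_proba(x))
    assert loaded.config == TINY


def test_predict_parallel_equivalence(tmp_path):
    model = build_model(TINY)
    path = tmp_path / "tiny.npz"
    model.save(path)
    x = np.random.default_rng(2).random((90, TINY.input_size, TINY.input_size)).astype(np.float32)
    single = patchcnn.predict_parallel(path, x, n_workers=1)
    assert np.allclose(single, model.predict_proba(x), atol=1e-6)
    multi = patchcnn.predict_parallel(path, x, n_workers=3)
    assert np.abs(multi - single).max() <= 1e-6


def test_predict_parallel_caps_workers_and_checks_path(tmp_path, caplog):
    model = build_model(TINY)
    path = tmp_path / "tiny.npz"
    model.save(path)
    x = np.random.default_rng(3).random((2, TINY.input_size, TINY.input_size)).astype(np.float32)
    import logging
    with caplog.at_level(logging.WARNING, logger="octskin.patchcnn"):
        out = patchcnn.predict_parallel(path, x, n_workers=8)
    assert out.shape == (2, 4)
    assert any("capping" in r.message for r in caplog.records)
    with pytest.raises(FileNotFoundError):
        patchcnn.predict_parallel(tmp_path / "missing.npz", x, n_workers=2)


def test_loss_switch_changes_training_not_architecture():
    ce = TINY
    kl = replace(TINY, loss="kl_divergence")
    assert count_parameters(ce) == count_parameters(kl)
    m_ce, m_kl = build_model(ce), build_model(kl)
    for a, b in zip(m_ce.parameters(), m_kl.parameters()):
        assert np.array_equal(a, b)
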