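"""Fusion model: variants, token encoding, splitting, training, prediction."""

import numpy as np
import pytest

from octva.errors import ConfigurationError, TrainingError, ValidationError
from octva.fusion import (
    TrainConfig,
    VARIANTS,
    VAFusionNet,
    encode_tokens,
    extract_image_features,
    predict,
    split_dataset,
    train_model,
    transformer_fuse,
)
from octva.nn import Tensor


@pytest.fixture(scope="module")
def tiny_net():
    cfg = TrainConfig(image_size=16)
    return VAFusionNet(VARIANTS["V"], cfg, np.random.default_rng(0)), cfg


def _inputs(n=2, size=16, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    return {
        "himg": rng.normal(size=(n, 1, size, size)),
        "vimg": rng.normal(size=(n, 1, size, size)),
        "preop_va": rng.normal(size=(n, 1)),
        "indices": rng.normal(size=(n, 7)),
    }


def test_variant_modality_table():
    assert VARIANTS["I"].uses_himg and not VARIANTS["I"].uses_vimg
    assert VARIANTS["III"].uses_himg and VARIANTS["III"].uses_vimg
    assert not VARIANTS["III"].uses_preop_va
    assert VARIANTS["V"].uses_indices
    # sequence lengths: modalities + prediction token
    assert [VARIANTS[k].n_tokens for k in "I II III IV V".split()] == [2, 2, 3, 4, 5]


@pytest.mark.parametrize("vid,length", [("I", 2), ("III", 3), ("IV", 4), ("V", 5)])
def test_token_sequence_length_per_variant(vid, length):
    cfg = TrainConfig(image_size=16)
    net = VAFusionNet(VARIANTS[vid], cfg, np.random.default_rng(1))
    inp = _inputs()
    seq = encode_tokens(
        net,
        himg=inp["himg"] if VARIANTS[vid].uses_himg else None,
        vimg=inp["vimg"] if VARIANTS[vid].uses_vimg else None,
        preop_va=inp["preop_va"] if VARIANTS[vid].uses_preop_va else None,
        indices=inp["indices"] if VARIANTS[vid].uses_indices else None,
    )
    assert seq.length == length
    assert seq.tokens.shape == (2, length, cfg.d_model)
    assert seq.modalities[-1] == "pred"


def test_missing_required_modality_named():
    cfg = TrainConfig(image_size=16)
    net = VAFusionNet(VARIANTS["IV"], cfg, np.random.default_rng(2))
    inp = _inputs()
    with pytest.raises(ConfigurationError, match="preop_va"):
        encode_tokens(net, himg=inp["himg"], vimg=inp["vimg"], preop_va=None)


def test_fused_output_is_finite_scalar_per_eye(tiny_net):
    net, _ = tiny_net
    seq = encode_tokens(net, **_inputs(n=3))
    out = transformer_fuse(net, seq)
    assert out.shape == (3,)
    assert np.all(np.isfinite(out))


def test_prediction_invariant_to_modality_token_permutation(tiny_net):
    """No positional encoding: permuting the modality tokens (prediction
    token kept last) leaves the fused output unchanged."""
    net, _ = tiny_net
    seq = encode_tokens(net, **_inputs(n=2))
    base = transformer_fuse(net, seq)
    perm = np.array([2, 0, 3, 1, 4])  # shuffle modalities, pred stays last
    shuffled = type(seq)(
        tokens=Tensor(seq.tokens.data[:, perm, :]), modalities=seq.modalities
    )
    np.testing.assert_allclose(transformer_fuse(net, shuffled), base, atol=1e-10)


def test_zeroed_head_outputs_bias(tiny_net):
    net, _ = tiny_net
    saved_w, saved_b = net.head.w.data.copy(), net.head.b.data.copy()
    try:
        net.head.w.data[:] = 0.0
        net.head.b.data[:] = 0.7
        out = transformer_fuse(net, encode_tokens(net, **_inputs(n=2)))
        np.testing.assert_allclose(out, 0.7, atol=1e-12)
    finally:
        net.head.w.data, net.head.b.data = saved_w, saved_b


def test_extract_image_features_width_and_determinism(noisy_phantom):
    _, img, _ = noisy_phantom
    a = extract_image_features(img, seed=3)
    b = extract_image_features(img, seed=3)
    assert a.shape == (512,)
    np.testing.assert_array_equal(a, b)
    other = extract_image_features(img.pixels * 0.5 + 10.0, seed=3)
    assert not np.allclose(a, other)


def test_malformed_image_rejected():
    with pytest.raises(ValidationError):
        extract_image_features(np.array([1.0, 2.0]))


# ---- dataset splitting -------------------------------------------------


def test_split_sizes_small_cohort():
    records = list(range(10))
    tr, va, te = split_dataset(records, seed=0)
    assert (len(tr), len(va), len(te)) == (6, 2, 2)


def test_split_disjoint_exhaustive_seeded():
    records = list(range(101))
    a = split_dataset(records, seed=5)
    b = split_dataset(records, seed=5)
    c = split_dataset(records, seed=6)
    assert [x for part in a for x in part] == [x for part in b for x in part]
    assert sorted(x for part in a for x in part) == records
    assert any(
        pa != pb for pa, pb in zip(a[0], c[0])
    )  # different seed, different shuffle


def test_split_bad_fractions_rejected():
    with pytest.raises(ValidationError):
        split_dataset(list(range(10)), fractions=(0.5, 0.2, 0.2))


# ---- training ----------------------------------------------------------


def test_constant_labels_converge_to_constant(tiny_cohort):
    for rec in tiny_cohort:
        rec.extras["saved_postop"] = rec.postop_bcva
    try:
        for rec in tiny_cohort:
            rec.postop_bcva = 0.3
        cfg = TrainConfig(max_epochs=80, image_size=16, batch_size=32, seed=0)
        tr, va = tiny_cohort[:16], tiny_cohort[16:]
        model = train_model("I", tr, va, cfg)
        preds = predict(model, va)
        assert np.mean(np.abs(preds - 0.3)) < 0.02
    finally:
        for rec in tiny_cohort:
            rec.postop_bcva = rec.extras.pop("saved_postop")


def test_training_log_and_schedule(tiny_cohort):
    cfg = TrainConfig(max_epochs=3, image_size=16, seed=1)
    model = train_model("I", tiny_cohort[:16], tiny_cohort[16:], cfg)
    assert len(model.log) == 3
    assert model.log[0]["lr"] == pytest.approx(0.01)
    assert np.isfinite(model.best_val_mae)


def test_empty_train_set_rejected():
    with pytest.raises(TrainingError):
        train_model("I", [], [], TrainConfig(max_epochs=1, image_size=16))


def test_unlabeled_training_record_rejected(tiny_cohort):
    rec = tiny_cohort[0]
    saved = rec.postop_bcva
    try:
        rec.postop_bcva = None
        with pytest.raises(TrainingError, match=rec.eye_id):
            train_model(
                "I", [rec], tiny_cohort[1:3], TrainConfig(max_epochs=1, image_size=16)
            )
    finally:
        rec.postop_bcva = saved


def test_predict_deterministic_and_requires_images(tiny_cohort):
    cfg = TrainConfig(max_epochs=2, image_size=16, seed=2)
    model = train_model("I", tiny_cohort[:16], tiny_cohort[16:], cfg)
    rec = tiny_cohort[0]
    a = predict(model, rec)
    b = predict(model, rec)
    assert a == b
    from octva.io import CohortRecord

    bare = CohortRecord(eye_id="x", device_id="spectralis", preop_bcva=0.5)
    with pytest.raises(ConfigurationError):
        predict(model, bare)


def test_same_seed_training_reproducible(tiny_cohort):
    cfg = TrainConfig(max_epochs=2, image_size=16, seed=7)
    m1 = train_model("I", tiny_cohort[:16], tiny_cohort[16:], cfg)
    m2 = train_model("I", tiny_cohort[:16], tiny_cohort[16:], cfg)
    np.testing.assert_array_equal(
        predict(m1, tiny_cohort[16:]), predict(m2, tiny_cohort[16:])
    )
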