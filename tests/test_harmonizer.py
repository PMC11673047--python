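import numpy as np
import pytest

from ctharmony import nn
from ctharmony import phantom as ph
from ctharmony import harmonizer as hz

TINY = dict(base_channels=4, n_scales=2, patch_size=32, batch_size=2)


@pytest.fixture(scope="module")
def tiny_cohort():
    return ph.make_cohort(4, seed=11)


def test_spec_validation():
    with pytest.raises(ValueError, match="divisible"):
        hz.HarmonizerSpec(patch_size=40, n_scales=2, unshuffle_factor=4)
    with pytest.raises(ValueError, match="nonnegative"):
        hz.HarmonizerSpec(lambda_rec=-1)


def test_generator_is_shape_preserving_and_identity_at_init(rng):
    spec = hz.HarmonizerSpec(**TINY, seed=0)
    gen = hz.build_generator(spec)
    x = rng.standard_normal((1, 1, 64, 64))
    out = gen(nn.Tensor(x)).data
    assert out.shape == x.shape
    # zero-initialized output head -> exact identity
    assert np.array_equal(out, x)


def test_parameter_count_is_function_of_spec():
    spec = hz.HarmonizerSpec(**TINY, seed=0)
    a = hz.build_generator(spec).n_parameters()
    b = hz.build_generator(spec).n_parameters()
    assert a == b > 0


def test_discriminator_contract(rng):
    spec = hz.HarmonizerSpec(**TINY, seed=0)
    disc = hz.build_discriminator(spec)
    x = rng.standard_normal((2, 1, 64, 64))
    scalar, pixel_map = disc(nn.Tensor(x))
    assert scalar.data.size == 1
    assert pixel_map.shape == (2, 1, 64, 64)
    assert np.isfinite(scalar.item())
    assert np.all(np.isfinite(pixel_map.data))
    scalar2, map2 = disc(nn.Tensor(x))
    assert scalar.item() == scalar2.item()
    assert np.array_equal(pixel_map.data, map2.data)


def test_train_requires_target_protocol(tiny_cohort):
    spec = hz.HarmonizerSpec(**TINY, target_label="XYZ", steps=1, seed=0)
    with pytest.raises(ValueError, match="XYZ"):
        hz.train(tiny_cohort, spec)


def test_null_objective_leaves_weights_unchanged(tiny_cohort):
    spec = hz.HarmonizerSpec(**TINY, steps=3, seed=2,
                             lambda_rec=0, lambda_rec_l2=0, lambda_adv=0)
    model = hz.train(tiny_cohort, spec)
    fresh = hz.build_generator(spec)
    for a, b in zip(model.generator.params(), fresh.params()):
        assert np.array_equal(a.data, b.data)


def test_training_is_deterministic(tiny_cohort):
    spec = hz.HarmonizerSpec(**TINY, steps=8, seed=3)
    m1 = hz.train(tiny_cohort, spec)
    m2 = hz.train(tiny_cohort, spec)
    assert m1.history["rec_l1"] == m2.history["rec_l1"]
    for a, b in zip(m1.generator.params(), m2.generator.params()):
        assert np.array_equal(a.data, b.data)


def test_short_regression_training_reduces_reconstruction_loss(tiny_cohort):
    spec = hz.HarmonizerSpec(**TINY, steps=60, seed=4, lambda_adv=0)
    model = hz.train(tiny_cohort, spec)
    hist = model.history["rec_l1"]
    assert np.mean(hist[-10:]) < np.mean(hist[:10])


def test_identity_model_round_trips_stack(tiny_cohort):
    stack = tiny_cohort[0][0]
    out = hz.harmonize(hz.identity_harmonizer(), stack)
    for label in stack.images:
        expected = np.clip(stack.images[label], -1100, 3000)
        assert np.array_equal(out.images[label], expected)


def test_harmonize_requires_model_target(tiny_cohort):
    stack = tiny_cohort[0][0]
    partial = ph.ProtocolStack(
        subject_id="x",
        images={"FBP": stack.images["FBP"], "M40": stack.images["M40"]},
        target_label="FBP",
    )
    model = hz.identity_harmonizer()
    with pytest.raises(KeyError, match="IR"):
        hz.harmonize(model, partial)


def test_harmonized_output_is_finite_and_clamped(tiny_cohort):
    spec = hz.HarmonizerSpec(**TINY, steps=10, seed=5)
    model = hz.train(tiny_cohort, spec)
    out = hz.harmonize(model, tiny_cohort[0][0])
    for img in out.images.values():
        assert np.all(np.isfinite(img))
        assert img.min() >= -1100 and img.max() <= 3000


def test_tiled_inference_handles_non_divisible_shapes():
    spec = hz.HarmonizerSpec(**TINY, seed=0)
    model = hz.identity_harmonizer(spec)
    img = np.random.default_rng(0).normal(50, 10, size=(70, 90))
    stack = ph.ProtocolStack("odd", {"IR": img, "FBP": img + 5.0})
    out = hz.harmonize(model, stack)
    assert out.images["FBP"].shape == (70, 90)
    assert np.array_equal(out.images["FBP"], img + 5.0)


def test_save_load_round_trip(tiny_cohort, tmp_path):
    spec = hz.HarmonizerSpec(**TINY, steps=5, seed=6)
    model = hz.train(tiny_cohort, spec)
    model.save(tmp_path / "model.pkl")
    loaded = hz.TrainedHarmonizer.load(tmp_path / "model.pkl")
    assert loaded.spec == model.spec
    stack = tiny_cohort[0][0]
    a = hz.harmonize(model, stack)
    b = hz.harmonize(loaded, stack)
    for label in stack.images:
        assert np.array_equal(a.images[label], b.images[label])
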