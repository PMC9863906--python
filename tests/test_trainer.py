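"""Training-loop contracts: no-op schedules, determinism, parameter
isolation between the two optimisers, stitching, checkpoints."""

import numpy as np
import pytest

from voxsegan.losses import LossConfig, l1_to_constant
from voxsegan.networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    build_discriminator,
    build_generator,
)
from voxsegan.nn import Adam
from voxsegan.phantom import MultimodalCase, PhantomConfig, generate_phantom
from voxsegan.prep import normalize_intensity, sample_tumour_patches
from voxsegan.trainer import (
    TrainConfig,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
    voxel_accuracy,
)


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = PhantomConfig(grid_size=32, tumour_radius_range=(5.0, 8.0),
                        n_cases=2, seed=9)
    cases = [normalize_intensity(generate_phantom(cfg, i)) for i in range(2)]
    rng = np.random.default_rng(1)
    patches = [p for c in cases for p in sample_tumour_patches(c, 32, 2, rng)]
    return cases, patches


def _nets(seed=0, filters=2):
    gen = build_generator(GeneratorSpec(base_filters=filters), seed=seed)
    disc = build_discriminator(DiscriminatorSpec(base_filters=filters),
                               seed=seed + 1)
    return gen, disc


def test_zero_epochs_is_a_noop(tiny_setup):
    _, patches = tiny_setup
    gen, disc = _nets()
    before = [p.data.copy() for p in gen.params()]
    gen2, disc2, hist = train(gen, disc, patches,
                              TrainConfig(epochs=0, patch_size=32))
    assert hist.records == []
    for p, b in zip(gen2.params(), before):
        assert np.array_equal(p.data, b)


def test_empty_dataset_with_epochs_rejected():
    gen, disc = _nets()
    with pytest.raises(ValueError, match="non-empty"):
        train(gen, disc, [], TrainConfig(epochs=1, patch_size=32))


def test_history_record_count(tiny_setup):
    _, patches = tiny_setup
    gen, disc = _nets()
    config = TrainConfig(epochs=2, batch_size=3, patch_size=32, seed=4)
    _, _, hist = train(gen, disc, patches, config)
    steps = (len(patches) + 2) // 3
    assert len(hist.records) == 2 * steps
    df = hist.to_frame()
    assert list(df.columns) == ["epoch", "step", "GL", "adv_term",
                                "dice_term", "DL"]


def test_identical_seed_gives_bit_identical_history(tiny_setup):
    _, patches = tiny_setup

    def run():
        gen, disc = _nets(seed=5)
        _, _, hist = train(gen, disc, patches,
                           TrainConfig(epochs=2, batch_size=2, patch_size=32,
                                       seed=17))
        return hist.to_frame(), [p.data.copy() for p in gen.params()]

    df1, w1 = run()
    df2, w2 = run()
    assert df1.equals(df2)
    for a, b in zip(w1, w2):
        assert np.array_equal(a, b)


def test_optimiser_updates_are_isolated(tiny_setup):
    """A discriminator step must not move generator weights, and vice
    versa (the loops share arrays only through activations)."""
    _, patches = tiny_setup
    gen, disc = _nets(seed=2)
    x = patches[0].image.transpose(3, 0, 1, 2)[None].astype(np.float32)
    y = patches[0].labels_onehot.transpose(3, 0, 1, 2)[None].astype(np.float32)

    opt_d = Adam(disc.params(), 1e-2)
    gen_before = [p.data.copy() for p in gen.params()]
    fake = gen.forward(x, training=True)
    out = disc.forward(np.concatenate([x, fake], axis=1), training=True)
    _, grad = l1_to_constant(out, 0.0, with_grad=True)
    disc.backward(grad)
    opt_d.step()
    for p, b in zip(gen.params(), gen_before):
        assert np.array_equal(p.data, b)

    opt_g = Adam(gen.params(), 1e-2)
    disc_before = [p.data.copy() for p in disc.params()]
    fake = gen.forward(x, training=True)
    out = disc.forward(np.concatenate([x, fake], axis=1), training=False)
    _, grad = l1_to_constant(out, 1.0, with_grad=True)
    din = disc.backward(grad)
    gen.backward(din[:, 4:].astype(np.float32))
    opt_g.step()
    for p, b in zip(disc.params(), disc_before):
        assert np.array_equal(p.data, b)


class _ConstantGenerator:
    """Stub emitting fixed class probabilities for stitching tests."""

    def __init__(self, probs=(0.1, 0.6, 0.2, 0.1)):
        self.probs = np.asarray(probs, dtype=np.float32)

    def forward(self, x, training=False):
        n, _, d, h, w = x.shape
        out = np.empty((n, 4, d, h, w), dtype=np.float32)
        out[:] = self.probs[None, :, None, None, None]
        return out


def test_predict_constant_generator_gives_constant_volume(tiny_setup):
    cases, _ = tiny_setup
    labels = predict(_ConstantGenerator(), cases[0], 16, 8)
    assert labels.shape == cases[0].labels.shape
    assert np.all(labels == 1)  # argmax of (0.1, 0.6, 0.2, 0.1)


def test_predict_single_patch_matches_direct_forward(tiny_setup):
    cases, _ = tiny_setup
    gen, _ = _nets(seed=3)
    labels = predict(gen, cases[0], 32)
    x = cases[0].image.transpose(3, 0, 1, 2)[None].astype(np.float32)
    direct = np.argmax(gen.forward(x, training=False)[0], axis=0)
    assert np.array_equal(labels, direct)


def test_overlap_averaging_of_equal_probabilities(tiny_setup):
    """Stitching overlapping patches with identical class probabilities
    reproduces those probabilities (mean of equal values)."""
    cases, _ = tiny_setup
    labels = predict(_ConstantGenerator((0.7, 0.1, 0.1, 0.1)),
                     cases[0], 16, 4)
    assert np.all(labels == 0)


def test_predict_rejects_small_volume():
    img = np.zeros((16, 16, 16, 4), dtype=np.float32)
    case = MultimodalCase("s", img, np.zeros((16, 16, 16), dtype=np.int16))
    gen, _ = _nets()
    with pytest.raises(ValueError, match="smaller than patch"):
        predict(gen, case, 32)


def test_voxel_accuracy():
    a = np.zeros((4, 4, 4), dtype=np.int16)
    b = a.copy()
    b[0, 0, 0] = 3
    assert voxel_accuracy(a, b) == pytest.approx(63 / 64)


def test_checkpoint_round_trip(tmp_path, tiny_setup):
    _, patches = tiny_setup
    gen, disc = _nets(seed=8)
    config = TrainConfig(epochs=1, batch_size=2, patch_size=32, seed=1)
    gen, disc, _ = train(gen, disc, patches, config)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, gen, disc, config)
    gen2, disc2, config2 = load_checkpoint(path)
    assert config2 == config
    for a, b in zip(gen.params(), gen2.params()):
        assert np.array_equal(a.data, b.data)
    x = patches[0].image.transpose(3, 0, 1, 2)[None].astype(np.float32)
    assert np.array_equal(gen.forward(x), gen2.forward(x))
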