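"""Canonical desk-scale study conditions.

The full-scale configuration (128³ patches, base 64 filters, 100 epochs,
batch 4) is far beyond a single CPU, so the package defines one fixed
desk-scale surrogate used by the examples, the regression tests and the
acceptance script: 64³ phantoms, 32³ patches, base 8 filters, 30 epochs,
batch 4, with 5 training and 2 held-out cases.  Twenty training patches
are drawn as three tumour-centred crops plus one tiled (background-heavy)
crop per training case.  The learning rate for this ~150-step schedule is
2e-3; the 2e-4 default of :class:`~voxsegan.trainer.TrainConfig` is
matched to full-scale step counts and moves the model too little here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .losses import LossConfig
from .networks import DiscriminatorSpec, GeneratorSpec, build_discriminator, build_generator
from .phantom import PhantomConfig, generate_phantom
from .prep import extract_patches, normalize_intensity, sample_tumour_patches
from .trainer import TrainConfig, evaluate_cases, train

N_TRAIN_CASES = 5
N_HELDOUT_CASES = 2
PATCHES_PER_CASE = 3       # tumour-centred
DESK_PATCH = 32
DESK_BASE_FILTERS = 8
DESK_EPOCHS = 30
DESK_LR = 2e-3
PREDICT_STRIDE = 16


def desk_scale_phantoms(seed: int) -> tuple[list, list]:
    """(train_cases, heldout_cases), intensity-normalised."""
    cfg = PhantomConfig(n_cases=N_TRAIN_CASES + N_HELDOUT_CASES, seed=seed)
    cases = [normalize_intensity(generate_phantom(cfg, i))
             for i in range(cfg.n_cases)]
    return cases[:N_TRAIN_CASES], cases[N_TRAIN_CASES:]


def desk_scale_patches(train_cases: list, seed: int) -> list:
    """3 tumour-centred + 1 tiled patch per case -> 20 training patches."""
    rng = np.random.default_rng([seed, 1])
    patches = []
    for case in train_cases:
        patches += sample_tumour_patches(case, DESK_PATCH, PATCHES_PER_CASE, rng)
        tiles = extract_patches(case, DESK_PATCH, DESK_PATCH)
        patches.append(tiles[int(rng.integers(len(tiles)))])
    return patches


def desk_scale_run(seed: int) -> dict:
    """Train the desk-scale model and evaluate on held-out phantoms.

    Returns the trained networks, training history, per-epoch generator
    loss means and the held-out evaluation table.
    """
    train_cases, heldout = desk_scale_phantoms(seed)
    patches = desk_scale_patches(train_cases, seed)
    gen = build_generator(GeneratorSpec(base_filters=DESK_BASE_FILTERS),
                          seed=seed)
    disc = build_discriminator(
        DiscriminatorSpec(base_filters=DESK_BASE_FILTERS), seed=seed + 1)
    config = TrainConfig(epochs=DESK_EPOCHS, batch_size=4,
                         patch_size=DESK_PATCH, learning_rate=DESK_LR,
                         seed=seed)
    gen, disc, history = train(gen, disc, patches, config, LossConfig())
    gl_per_epoch = history.epoch_mean("GL")
    heldout_df: pd.DataFrame = evaluate_cases(gen, heldout, DESK_PATCH,
                                              PREDICT_STRIDE)
    return {
        "gen": gen,
        "disc": disc,
        "history": history,
        "gl_per_epoch": gl_per_epoch,
        "heldout": heldout_df,
        "n_patches": len(patches),
        "config": config,
    }
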