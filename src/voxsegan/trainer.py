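"""Alternating adversarial training and sliding-window prediction.

Each step takes one discriminator update (minimising DL on a batch, with
the generator output treated as a constant) followed by one generator
update (minimising GL through the frozen discriminator).  The loop is a
pure function of (networks, dataset order, config.seed), so runs with
identical inputs produce bit-identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import networks as net_mod
from .losses import LossConfig, generalized_dice_loss, l1_to_constant
from .nn import Adam
from .phantom import MultimodalCase
from .prep import SegmentationPatch, augment_patch, extract_patches
from .metrics import dice_coefficient


@dataclass
class TrainConfig:
    """Optimisation schedule and reproducibility knobs."""

    epochs: int = 100
    batch_size: int = 4
    patch_size: int = 128
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    seed: int = 0
    device: str = "cpu"          # informational; execution is CPU numpy
    checkpoint_every: int = 0    # epochs; 0 disables periodic checkpoints
    augment: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patch_size % 16:
            raise ValueError("patch_size must be divisible by 16")


@dataclass
class TrainHistory:
    """Per-step loss records; one row per (epoch, step)."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["epoch", "step", "GL", "adv_term", "dice_term", "DL"]
        return pd.DataFrame(self.records, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def epoch_mean(self, column: str) -> np.ndarray:
        df = self.to_frame()
        return df.groupby("epoch")[column].mean().to_numpy()


def _to_batch(patches: list[SegmentationPatch]) -> tuple[np.ndarray, np.ndarray]:
    """Channels-last patches -> channels-first float32 batches."""
    x = np.stack([p.image.transpose(3, 0, 1, 2) for p in patches])
    y = np.stack([p.labels_onehot.transpose(3, 0, 1, 2) for p in patches])
    return x.astype(np.float32), y.astype(np.float32)


def train(gen, disc, dataset: list[SegmentationPatch], config: TrainConfig,
          loss_config: LossConfig | None = None,
          checkpoint_dir: str | Path | None = None,
          log=None) -> tuple[object, object, TrainHistory]:
    """Run the adversarial loop; returns (gen, disc, history)."""
    loss_config = loss_config or LossConfig()
    history = TrainHistory()
    if config.epochs == 0:
        return gen, disc, history
    if not dataset:
        raise ValueError("dataset must be non-empty when epochs > 0")

    rng = np.random.default_rng(config.seed)
    opt_g = Adam(gen.params(), config.learning_rate, config.beta1, config.beta2)
    opt_d = Adam(disc.params(), config.learning_rate, config.beta1, config.beta2)
    n = len(dataset)
    steps = (n + config.batch_size - 1) // config.batch_size

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for step in range(steps):
            idx = order[step * config.batch_size:(step + 1) * config.batch_size]
            batch = [dataset[i] for i in idx]
            if config.augment:
                batch = [augment_patch(p, rng) for p in batch]
            x, y = _to_batch(batch)

            # --- discriminator update (generator output held constant)
            y_fake = gen.forward(x, training=True)
            disc.zero_grad()
            d_real = disc.forward(np.concatenate([x, y], axis=1), training=True)
            loss_real, g_real = l1_to_constant(d_real, 1.0, with_grad=True)
            disc.backward(g_real)
            d_fake = disc.forward(np.concatenate([x, y_fake], axis=1),
                                  training=True)
            loss_fake, g_fake = l1_to_constant(d_fake, 0.0, with_grad=True)
            disc.backward(g_fake)
            dl = loss_real + loss_fake
            opt_d.step()

            # --- generator update (discriminator frozen)
            gen.zero_grad()
            y_fake = gen.forward(x, training=True)
            disc.zero_grad()  # discard gradients from the pass-through below
            d_fake = disc.forward(np.concatenate([x, y_fake], axis=1),
                                  training=False)
            adv, g_adv = l1_to_constant(d_fake, 1.0, with_grad=True)
            d_input_grad = disc.backward(g_adv)
            dice, g_dice = generalized_dice_loss(y, y_fake, loss_config,
                                                 with_grad=True)
            dy_fake = d_input_grad[:, x.shape[1]:] + loss_config.alpha * g_dice
            gen.backward(dy_fake.astype(np.float32))
            opt_g.step()
            disc.zero_grad()

            gl = adv + loss_config.alpha * dice
            history.records.append({
                "epoch": epoch, "step": step, "GL": gl, "adv_term": adv,
                "dice_term": dice, "DL": dl,
            })
        if log is not None:
            log(f"epoch {epoch + 1}/{config.epochs}  "
                f"GL={gl:.4f} (adv={adv:.4f}, dice={dice:.4f})  DL={dl:.4f}")
        if (checkpoint_dir is not None and config.checkpoint_every
                and (epoch + 1) % config.checkpoint_every == 0):
            save_checkpoint(Path(checkpoint_dir) /
                            f"checkpoint_epoch{epoch + 1:04d}.npz",
                            gen, disc, config)
    return gen, disc, history


def predict(gen, case: MultimodalCase, patch_size: int,
            stride: int | None = None) -> np.ndarray:
    """Tile the (already normalised) case, average class probabilities in
    patch overlaps, and argmax to an integer label volume."""
    patches = extract_patches(case, patch_size, stride)
    shape = case.labels.shape
    prob_sum = np.zeros(shape + (4,), dtype=np.float64)
    count = np.zeros(shape, dtype=np.float64)
    for patch in patches:
        x = patch.image.transpose(3, 0, 1, 2)[None].astype(np.float32)
        probs = gen.forward(x, training=False)[0].transpose(1, 2, 3, 0)
        ox, oy, oz = patch.origin
        sl = (slice(ox, ox + patch_size), slice(oy, oy + patch_size),
              slice(oz, oz + patch_size))
        prob_sum[sl] += probs
        count[sl] += 1.0
    probs = prob_sum / count[..., None]
    return np.argmax(probs, axis=-1).astype(np.int16)


def voxel_accuracy(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Fraction of voxels whose predicted class matches the truth."""
    if pred_labels.shape != true_labels.shape:
        raise ValueError("grid mismatch")
    return float((pred_labels == true_labels).mean())


def evaluate_cases(gen, cases: list[MultimodalCase], patch_size: int,
                   stride: int | None = None) -> pd.DataFrame:
    """Whole-tumour DSC + voxel accuracy per held-out case."""
    rows = []
    for case in cases:
        pred = predict(gen, case, patch_size, stride)
        rows.append({
            "case_id": case.case_id,
            "dsc_whole": dice_coefficient(pred, case.labels, region="whole"),
            "accuracy": voxel_accuracy(pred, case.labels),
        })
    return pd.DataFrame(rows)


def save_checkpoint(path: str | Path, gen, disc,
                    config: TrainConfig | None = None) -> None:
    """Self-describing checkpoint: specs + weights (+ train config)."""
    meta = {
        "generator_spec": net_mod.spec_to_dict(gen.spec),
        "discriminator_spec": net_mod.spec_to_dict(disc.spec),
        "train_config": asdict(config) if config else None,
    }
    arrays = {}
    for i, p in enumerate(gen.params()):
        arrays[f"gen_{i:04d}"] = p.data
    for i, p in enumerate(disc.params()):
        arrays[f"disc_{i:04d}"] = p.data
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild (gen, disc, train_config) from a checkpoint file."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    gspec = net_mod.generator_spec_from_dict(meta["generator_spec"])
    dspec = net_mod.discriminator_spec_from_dict(meta["discriminator_spec"])
    gen = net_mod.build_generator(gspec)
    disc = net_mod.build_discriminator(dspec)
    for i, p in enumerate(gen.params()):
        p.data[...] = data[f"gen_{i:04d}"]
    for i, p in enumerate(disc.params()):
        p.data[...] = data[f"disc_{i:04d}"]
    cfg = meta.get("train_config")
    config = TrainConfig(**cfg) if cfg else None
    return gen, disc, config
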