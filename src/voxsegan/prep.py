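"""Volume preparation: NIfTI reading, intensity normalisation, patch
extraction / one-hot encoding, and label-preserving augmentation.

All public contracts are channels-last with 0-based (x, y, z) voxel
coordinates.  Patch side lengths must be divisible by 16 so that four
stride-2 halvings in the networks land on integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import MODALITIES, MultimodalCase, N_CLASSES

PATCH_DIVISOR = 16


@dataclass
class SegmentationPatch:
    """A cube crop: image channels + one-hot labels + source-corner origin."""

    image: np.ndarray          # (P, P, P, 4)
    labels_onehot: np.ndarray  # (P, P, P, 4), exactly one 1 per voxel
    origin: tuple[int, int, int]

    def __post_init__(self):
        p = self.image.shape[0]
        if self.image.shape != (p, p, p, len(MODALITIES)):
            raise ValueError(f"image must be a 4-channel cube, got "
                             f"{self.image.shape}")
        if self.labels_onehot.shape != (p, p, p, N_CLASSES):
            raise ValueError("one-hot labels must match the image cube")
        if p % PATCH_DIVISOR:
            raise ValueError(
                f"patch side {p} must be divisible by {PATCH_DIVISOR}")

    @property
    def size(self) -> int:
        return self.image.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.labels_onehot, axis=-1).astype(np.int16)


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Integer label volume -> channels-last one-hot float32 volume."""
    out = np.zeros(labels.shape + (n_classes,), dtype=np.float32)
    idx = np.indices(labels.shape)
    out[(*idx, labels.astype(np.intp))] = 1.0
    return out


def read_case(modality_paths: dict[str, str | Path],
              seg_path: str | Path,
              case_id: str | None = None) -> MultimodalCase:
    """Load a case from five NIfTI files (fixed modality order T1, T1gd,
    T2, FLAIR) and validate grid agreement and label values."""
    missing = [m for m in MODALITIES if m not in modality_paths]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    seg_img = nib.load(str(seg_path))
    labels = np.asarray(seg_img.dataobj)
    channels = []
    for m in MODALITIES:
        img = nib.load(str(modality_paths[m]))
        vol = np.asarray(img.dataobj, dtype=np.float32)
        if vol.shape != labels.shape:
            raise ValueError(
                f"grid mismatch: {m} volume {vol.shape} vs label grid "
                f"{labels.shape}")
        channels.append(vol)
    if not np.all(np.isin(np.unique(labels), np.arange(N_CLASSES))):
        bad = np.setdiff1d(np.unique(labels), np.arange(N_CLASSES))
        raise ValueError(f"label values outside {{0,1,2,3}}: {bad.tolist()}")
    spacing = tuple(float(z) for z in seg_img.header.get_zooms()[:3])
    return MultimodalCase(
        case_id=case_id or Path(seg_path).name.split("_seg")[0],
        image=np.stack(channels, axis=-1),
        labels=labels.astype(np.int16),
        spacing=spacing,
    )


def read_case_from_manifest_row(row: dict) -> MultimodalCase:
    paths = {m: row[f"{m}_path"] for m in MODALITIES}
    return read_case(paths, row["seg_path"], case_id=row["case_id"])


def normalize_intensity(case: MultimodalCase,
                        method: str = "zscore") -> MultimodalCase:
    """Normalise each modality channel independently.

    ``zscore`` (default): zero mean, unit (population) standard deviation
    over nonzero voxels; ``minmax``: rescale the nonzero-voxel range to
    [0, 1].  Constant channels map to all zeros under either method.
    """
    if method not in ("zscore", "minmax"):
        raise ValueError(f"unknown normalisation method {method!r}")
    out = np.empty_like(case.image, dtype=np.float32)
    for m in range(case.image.shape[-1]):
        chan = case.image[..., m].astype(np.float64)
        mask = chan != 0
        ref = chan[mask] if mask.any() else chan.ravel()
        if method == "zscore":
            mu, sd = ref.mean(), ref.std()
            out[..., m] = 0.0 if sd == 0 else (chan - mu) / sd
        else:
            lo, hi = ref.min(), ref.max()
            out[..., m] = 0.0 if hi == lo else (chan - lo) / (hi - lo)
    return MultimodalCase(case.case_id, out, case.labels.copy(), case.spacing)


def _corner_positions(extent: int, patch: int, stride: int) -> list[int]:
    """0, S, 2S, … plus a final corner flush with the end of the axis."""
    positions = list(range(0, extent - patch + 1, stride))
    last = extent - patch
    if positions[-1] != last:
        positions.append(last)
    return positions


def extract_patches(case: MultimodalCase, patch_size: int,
                    stride: int | None = None) -> list[SegmentationPatch]:
    """Tile the volume into overlapping cubes covering every voxel."""
    stride = stride or patch_size
    shape = case.labels.shape
    if min(shape) < patch_size:
        raise ValueError(
            f"volume {shape} smaller than patch {patch_size} on some axis; "
            "pad the volume to at least the patch size first")
    onehot = one_hot(case.labels)
    patches = []
    for ox in _corner_positions(shape[0], patch_size, stride):
        for oy in _corner_positions(shape[1], patch_size, stride):
            for oz in _corner_positions(shape[2], patch_size, stride):
                sl = (slice(ox, ox + patch_size), slice(oy, oy + patch_size),
                      slice(oz, oz + patch_size))
                patches.append(SegmentationPatch(
                    image=np.ascontiguousarray(case.image[sl]),
                    labels_onehot=np.ascontiguousarray(onehot[sl]),
                    origin=(ox, oy, oz),
                ))
    return patches


def sample_tumour_patches(case: MultimodalCase, patch_size: int, n: int,
                          rng: np.random.Generator,
                          jitter: int = 4) -> list[SegmentationPatch]:
    """Draw ``n`` training patches centred on the tumour centroid with a
    small random corner jitter (clipped to the volume).

    Tumour-centred oversampling is the usual counter to class imbalance
    when cropping sub-volumes for training; falls back to volume-centred
    patches when the case has no tumour.
    """
    shape = case.labels.shape
    if min(shape) < patch_size:
        raise ValueError(
            f"volume {shape} smaller than patch {patch_size} on some axis")
    tumour = np.argwhere(case.labels > 0)
    centre = (tumour.mean(axis=0) if len(tumour)
              else np.asarray(shape, dtype=float) / 2)
    onehot = one_hot(case.labels)
    patches = []
    for _ in range(n):
        corner = []
        for ax in range(3):
            c = centre[ax] - patch_size / 2 + rng.integers(-jitter, jitter + 1)
            corner.append(int(np.clip(round(c), 0, shape[ax] - patch_size)))
        sl = tuple(slice(c, c + patch_size) for c in corner)
        patches.append(SegmentationPatch(
            image=np.ascontiguousarray(case.image[sl]),
            labels_onehot=np.ascontiguousarray(onehot[sl]),
            origin=tuple(corner)))
    return patches


def augment_patch(patch: SegmentationPatch,
                  rng: np.random.Generator) -> SegmentationPatch:
    """Random axis flips (p = 0.5 each) and an axial-plane 90° rotation,
    applied identically to image and one-hot channels.

    All transforms are voxel permutations, so intensities and per-class
    counts are untouched and no interpolation artefacts are introduced.
    """
    img, lab = patch.image, patch.labels_onehot
    for axis in range(3):
        if rng.random() < 0.5:
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k=k, axes=(0, 1))
        lab = np.rot90(lab, k=k, axes=(0, 1))
    return SegmentationPatch(np.ascontiguousarray(img),
                             np.ascontiguousarray(lab), patch.origin)


def flip_patch(patch: SegmentationPatch, axis: int) -> SegmentationPatch:
    """Deterministic single-axis flip (augmentation building block)."""
    return SegmentationPatch(
        np.ascontiguousarray(np.flip(patch.image, axis=axis)),
        np.ascontiguousarray(np.flip(patch.labels_onehot, axis=axis)),
        patch.origin)
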