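"""Seeded multimodal brain-tumour phantoms.

Each phantom emulates the structure of a BraTS-style case: four
co-registered MRI modality volumes (T1, T1gd, T2, FLAIR) over the same
grid, plus an integer label volume with the nested tumour classes

    0 background (incl. healthy brain) · 1 edema (ED)
    2 non-enhancing core (NET)         · 3 enhancing/active (ET)

Geometry is concentric ellipsoids: an enhancing core inside the
non-enhancing core inside the edema, the whole tumour placed fully
inside a brain ellipsoid.  Intensities are a per-(modality, class) mean
table plus additive Gaussian noise, which makes the classes separable
but overlapping — the regime that motivates dice-weighted training in
the first place.  Everything is a pure function of (seed, case_index).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

MODALITIES = ("t1", "t1gd", "t2", "flair")
N_CLASSES = 4

# Rows: T1, T1gd, T2, FLAIR; columns: background, ED, NET, ET.
# Chosen so edema is FLAIR/T2-bright and the active rim is T1gd-bright,
# with class contrasts a few times the default noise level.
DEFAULT_INTENSITY_TABLE = np.array([
    [0.30, 0.25, 0.20, 0.35],   # T1
    [0.30, 0.28, 0.25, 0.90],   # T1gd
    [0.35, 0.75, 0.60, 0.50],   # T2
    [0.30, 0.85, 0.65, 0.55],   # FLAIR
])

# Fractions of the edema radius occupied by the nested cores.
NET_FRACTION = 0.65
ET_FRACTION = 0.35

# Mild per-axis anisotropy of the brain ellipsoid.
BRAIN_AXES = (1.0, 0.85, 0.75)


@dataclass
class PhantomConfig:
    """Cohort-level phantom parameters (all lengths in voxels)."""

    grid_size: int = 64
    brain_radius_frac: float = 0.85
    tumour_radius_range: tuple[float, float] = (8.0, 14.0)
    class_intensity_table: np.ndarray = field(
        default_factory=lambda: DEFAULT_INTENSITY_TABLE.copy())
    noise_sigma: float = 0.08
    n_cases: int = 10
    seed: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.class_intensity_table = np.asarray(
            self.class_intensity_table, dtype=float)
        if self.class_intensity_table.shape != (len(MODALITIES), N_CLASSES):
            raise ValueError(
                "class_intensity_table must be 4 modalities x 4 classes, got "
                f"{self.class_intensity_table.shape}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.tumour_radius_range
        if lo > hi or lo < 0:
            raise ValueError("tumour_radius_range must be 0 <= min <= max")
        if hi >= self.grid_size / 2:
            raise ValueError(
                f"max tumour radius {hi} must be < grid_size/2 "
                f"({self.grid_size / 2})")


@dataclass
class MultimodalCase:
    """One case: 4-channel image, integer labels, voxel spacing (mm)."""

    case_id: str
    image: np.ndarray      # (G, G, G, 4) channels-last
    labels: np.ndarray     # (G, G, G) values in {0, 1, 2, 3}
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.image.shape[:-1] != self.labels.shape:
            raise ValueError(
                f"image grid {self.image.shape[:-1]} != "
                f"label grid {self.labels.shape}")
        if self.image.shape[-1] != len(MODALITIES):
            raise ValueError("image must have one channel per modality")
        bad = np.setdiff1d(np.unique(self.labels), np.arange(N_CLASSES))
        if bad.size:
            raise ValueError(f"labels outside {{0,1,2,3}}: {bad.tolist()}")


def _ellipsoid_mask(grid: int, centre: np.ndarray, semi_axes: np.ndarray
                    ) -> np.ndarray:
    ax = np.arange(grid, dtype=float)
    dx = (ax[:, None, None] - centre[0]) / semi_axes[0]
    dy = (ax[None, :, None] - centre[1]) / semi_axes[1]
    dz = (ax[None, None, :] - centre[2]) / semi_axes[2]
    return dx**2 + dy**2 + dz**2 <= 1.0


def generate_phantom(config: PhantomConfig, case_index: int) -> MultimodalCase:
    """Generate one phantom, fully determined by (config.seed, case_index)."""
    if case_index >= config.n_cases:
        raise ValueError(
            f"case_index {case_index} >= n_cases {config.n_cases}")
    rng = np.random.default_rng([config.seed, case_index])
    g = config.grid_size
    centre_brain = np.full(3, (g - 1) / 2.0)
    brain_semi = config.brain_radius_frac * (g / 2.0) * np.asarray(BRAIN_AXES)

    labels = np.zeros((g, g, g), dtype=np.int16)
    lo, hi = config.tumour_radius_range
    radius = float(rng.uniform(lo, hi))
    # draw a tumour centre until its bounding sphere fits inside the brain
    # ellipsoid (shrunk semi-axes); rejection terminates fast for sane configs
    tumour_centre = centre_brain.copy()
    if radius > 0:
        inner = np.maximum(brain_semi - radius, 1e-3)
        for _ in range(1000):
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u**2).sum() <= 1.0:
                tumour_centre = centre_brain + u * inner
                break
        # per-axis eccentricity of the edema ellipsoid, bounded so that the
        # tumour never leaves its bounding sphere of `radius`
        ecc = rng.uniform(0.75, 1.0, size=3)
        ed_semi = radius * ecc
        labels[_ellipsoid_mask(g, tumour_centre, ed_semi)] = 1
        labels[_ellipsoid_mask(g, tumour_centre, ed_semi * NET_FRACTION)] = 2
        labels[_ellipsoid_mask(g, tumour_centre, ed_semi * ET_FRACTION)] = 3

    table = config.class_intensity_table
    image = table.T[labels]                      # (G,G,G,4) class means
    image = np.ascontiguousarray(image, dtype=np.float64)
    if config.noise_sigma > 0:
        image += rng.normal(0.0, config.noise_sigma, size=image.shape)
    return MultimodalCase(
        case_id=f"case{case_index:03d}",
        image=image.astype(np.float32),
        labels=labels,
        spacing=config.spacing,
    )


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> list[dict]:
    """Write ``n_cases`` phantoms as NIfTI files plus a CSV manifest.

    Per case: one ``<case_id>_<modality>.nii.gz`` per modality and one
    ``<case_id>_seg.nii.gz``.  Returns the manifest rows in case order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for idx in range(config.n_cases):
        case = generate_phantom(config, idx)
        affine = np.diag(list(config.spacing) + [1.0])
        row: dict = {"case_id": case.case_id, "seed": config.seed}
        try:
            for m, name in enumerate(MODALITIES):
                path = out_dir / f"{case.case_id}_{name}.nii.gz"
                nib.save(nib.Nifti1Image(case.image[..., m], affine), path)
                row[f"{name}_path"] = str(path)
            seg_path = out_dir / f"{case.case_id}_seg.nii.gz"
            nib.save(
                nib.Nifti1Image(case.labels.astype(np.int16), affine), seg_path)
            row["seg_path"] = str(seg_path)
        except OSError as exc:
            raise OSError(f"failed writing case {case.case_id} under "
                          f"{out_dir}: {exc}") from exc
        rows.append(row)

    manifest = out_dir / "manifest.csv"
    fieldnames = (["case_id"] + [f"{m}_path" for m in MODALITIES]
                  + ["seg_path", "seed"])
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return rows
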