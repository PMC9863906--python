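"""Segmentation quality metrics and cohort reporting.

Per case the package reports the Dice score coefficient (DSC), peak
signal-to-noise ratio (PSNR, dB) and structural similarity (SSIM)
between predicted and ground-truth label maps, and aggregates a cohort
as arithmetic column means — the standard per-image table layout used
for GAN-based tumour segmentation results.

PSNR and SSIM are computed on the label maps linearly rescaled to
[0, 1] (dynamic range 1) unless the caller states another range.  SSIM
follows the standard luminance/contrast/structure form with a uniform
window (default 7 per axis) and stabilisation constants
C1 = (0.01 L)², C2 = (0.03 L)², using the unbiased covariance
normalisation, so it agrees with the common reference implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter


@dataclass
class CaseMetrics:
    case_id: str
    dsc: float     # in [0, 1]
    psnr: float    # dB, +inf for identical maps
    ssim: float    # in [-1, 1]


@dataclass
class CohortReport:
    rows: list[CaseMetrics]
    mean_dsc: float
    mean_psnr: float
    mean_ssim: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{"case_id": r.case_id, "SSIM": r.ssim, "PSNR": r.psnr,
              "DSC": r.dsc} for r in self.rows])
        mean_row = pd.DataFrame(
            [{"case_id": "mean", "SSIM": self.mean_ssim,
              "PSNR": self.mean_psnr, "DSC": self.mean_dsc}])
        return pd.concat([df, mean_row], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def dice_coefficient(pred_labels: np.ndarray, true_labels: np.ndarray,
                     region: str = "whole"):
    """DSC = 2|A∩B| / (|A| + |B|) between binarised masks.

    ``region="whole"`` binarises as label > 0 (whole tumour) and returns a
    scalar; ``region="per-class"`` returns a dict {class: DSC} over
    classes 1–3.  Two empty masks score 1 by convention.
    """
    _check_grids(pred_labels, true_labels)

    def _dsc(a: np.ndarray, b: np.ndarray) -> float:
        na, nb = int(a.sum()), int(b.sum())
        if na + nb == 0:
            return 1.0
        return 2.0 * int((a & b).sum()) / (na + nb)

    if region == "whole":
        return _dsc(pred_labels > 0, true_labels > 0)
    if region == "per-class":
        return {c: _dsc(pred_labels == c, true_labels == c)
                for c in (1, 2, 3)}
    raise ValueError(f"unknown region {region!r}")


def psnr(pred_map: np.ndarray, true_map: np.ndarray,
         max_value: float = 1.0) -> float:
    """10·log10(max² / MSE) in dB; identical maps give +inf."""
    _check_grids(pred_map, true_map)
    mse = float(np.mean((np.asarray(pred_map, dtype=np.float64)
                         - np.asarray(true_map, dtype=np.float64)) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value**2 / mse)


def ssim(pred_map: np.ndarray, true_map: np.ndarray, window: int = 7,
         data_range: float = 1.0) -> float:
    """Mean local structural similarity with a uniform window.

    Works on 2D slices or 3D volumes; edges within half a window of the
    border are excluded from the mean, matching the usual convention.
    """
    _check_grids(pred_map, true_map)
    if window > min(pred_map.shape):
        raise ValueError(
            f"window {window} larger than grid {pred_map.shape}")
    x = np.asarray(pred_map, dtype=np.float64)
    y = np.asarray(true_map, dtype=np.float64)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    n = window ** x.ndim
    cov_norm = n / (n - 1)           # unbiased local (co)variance

    def f(a):
        return uniform_filter(a, size=window)

    ux, uy = f(x), f(y)
    uxx, uyy, uxy = f(x * x), f(y * y), f(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / \
        ((ux**2 + uy**2 + c1) * (vx + vy + c2))
    pad = (window - 1) // 2
    core = s[tuple(slice(pad, dim - pad) for dim in s.shape)]
    return float(core.mean())


def case_metrics(case_id: str, pred_labels: np.ndarray,
                 true_labels: np.ndarray, n_classes: int = 4,
                 ssim_window: int = 7) -> CaseMetrics:
    """DSC/PSNR/SSIM row for one case; label maps rescaled to [0, 1]
    (divide by n_classes − 1) for the signal-quality metrics."""
    scale = float(n_classes - 1)
    pred = np.asarray(pred_labels, dtype=np.float64) / scale
    true = np.asarray(true_labels, dtype=np.float64) / scale
    return CaseMetrics(
        case_id=case_id,
        dsc=dice_coefficient(pred_labels, true_labels, region="whole"),
        psnr=psnr(pred, true, max_value=1.0),
        ssim=ssim(pred, true, window=ssim_window, data_range=1.0),
    )


def aggregate_report(rows: list[CaseMetrics]) -> CohortReport:
    """Arithmetic column means over per-case rows."""
    if not rows:
        raise ValueError("cannot aggregate an empty list of case metrics")
    return CohortReport(
        rows=list(rows),
        mean_dsc=float(np.mean([r.dsc for r in rows])),
        mean_psnr=float(np.mean([r.psnr for r in rows])),
        mean_ssim=float(np.mean([r.ssim for r in rows])),
    )


def report_from_frame(df: pd.DataFrame) -> CohortReport:
    """Build a cohort report from a per-case table with columns
    case_id/SSIM/PSNR/DSC (case-insensitive)."""
    cols = {c.lower(): c for c in df.columns}
    for needed in ("ssim", "psnr", "dsc"):
        if needed not in cols:
            raise ValueError(f"missing column {needed!r} in metrics table")
    id_col = cols.get("case_id") or cols.get("image")
    rows = [
        CaseMetrics(
            case_id=str(rec[id_col]) if id_col else f"case{i:03d}",
            dsc=float(rec[cols["dsc"]]),
            psnr=float(rec[cols["psnr"]]),
            ssim=float(rec[cols["ssim"]]),
        )
        for i, (_, rec) in enumerate(df.iterrows())
    ]
    return aggregate_report(rows)
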