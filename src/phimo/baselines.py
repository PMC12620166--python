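"""Baseline motion-correction methods and evaluation metrics.

ORBA (outlier-rejecting bootstrap aggregation) treats motion as a
probabilistic undersampling problem: it reconstructs the same k-space under
several random variable-density exclusion masks and averages the results.
HR/QR suppresses motion events by a weighted average of full-, half- and
quarter-resolution acquisitions of the central k-space.  The metrics cover
line detection (MAE, accuracy, precision/recall against a binary reference
mask, with "motion-corrupted" as the positive class) and T2* map quality
(per-slice MAE in ms and SSIM inside a brain/susceptibility evaluation
mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .forward import (
    CoilSensitivityMaps,
    ExclusionMask,
    KSpaceVolume,
    variable_density_line_mask,
)
from .motion import ReferenceMask
from .recon import UnrolledConfig, unrolled_reconstruct

__all__ = [
    "MetricReport",
    "orba_reconstruct",
    "hrqr_combine",
    "hrqr_line_ranges",
    "mask_metrics",
    "t2star_map_metrics",
]

SSIM_DYNAMIC_RANGE_MS = 200.0
SSIM_WINDOW = 7


@dataclass
class MetricReport:
    """Mask metrics and per-slice map metrics for one method."""

    method: str
    mask_metrics: dict = field(default_factory=dict)
    map_metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "method": self.method,
            "mask_metrics": _clean(self.mask_metrics),
            "map_metrics": _clean(self.map_metrics),
        }


def orba_reconstruct(
    y: KSpaceVolume,
    csm: CoilSensitivityMaps,
    recon_cfg: UnrolledConfig | None = None,
    weights: list | None = None,
    n_masks: int = 15,
    exclusion_rate: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Average reconstructions over random variable-density bootstrap masks.

    Each of the ``n_masks`` masks excludes ``round(rate * Y)`` lines with
    density decreasing toward the k-space center and is expanded with the
    KeepCenter override; the voxelwise mean of the reconstructions is
    returned.  Deterministic for a given seed.
    """
    if n_masks < 1:
        raise ValueError("n_masks must be at least 1")
    recon_cfg = recon_cfg or UnrolledConfig()
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_masks):
        mask = variable_density_line_mask(y.pe_size, exclusion_rate, seed=rng, keepcenter=True)
        from .forward import expand_mask_keepcenter

        plane = expand_mask_keepcenter(mask, y.ro_size, keepcenter=recon_cfg.keepcenter)
        y_w = plane * y.data
        x = unrolled_reconstruct(y_w, mask, csm, recon_cfg, weights=weights)
        acc = x if acc is None else acc + x
    return acc / n_masks


def hrqr_line_ranges(Y: int) -> tuple[slice, slice]:
    """Central-half and central-quarter PE line windows."""
    half = Y // 2
    quarter = Y // 4
    h0 = (Y - half) // 2
    q0 = (Y - quarter) // 2
    return slice(h0, h0 + half), slice(q0, q0 + quarter)


def hrqr_combine(
    y_full: KSpaceVolume,
    y_half: KSpaceVolume,
    y_quarter: KSpaceVolume,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> KSpaceVolume:
    """Weighted average of redundant central k-space acquisitions.

    The central quarter of PE lines averages all three acquisitions, the
    rest of the central half averages full + half, and peripheral lines copy
    the full acquisition unchanged — which is why motion confined to
    peripheral lines cannot be corrected by this scheme.
    """
    wf, wh, wq = weights
    for other in (y_half, y_quarter):
        if other.data.shape != y_full.data.shape:
            raise ValueError("acquisitions must share one co-registered grid")
    Y = y_full.pe_size
    half_sl, quarter_sl = hrqr_line_ranges(Y)
    out = y_full.data.copy()
    half_idx = set(range(half_sl.start, half_sl.stop))
    quarter_idx = set(range(quarter_sl.start, quarter_sl.stop))
    for line in sorted(half_idx):
        if line in quarter_idx:
            num = (
                wf * y_full.data[:, :, :, line]
                + wh * y_half.data[:, :, :, line]
                + wq * y_quarter.data[:, :, :, line]
            )
            out[:, :, :, line] = num / (wf + wh + wq)
        else:
            num = wf * y_full.data[:, :, :, line] + wh * y_half.data[:, :, :, line]
            out[:, :, :, line] = num / (wf + wh)
    return KSpaceVolume(out, y_full.te_ms, y_full.tr_ms)


def mask_metrics(
    pred: ExclusionMask,
    ref: ReferenceMask,
    threshold: float = 0.5,
    n_curve_points: int = 101,
) -> dict:
    """Line-detection metrics of a continuous mask against a binary reference.

    MAE compares the continuous weights directly.  For classification, a
    weight below ``threshold`` predicts "motion-corrupted" (the positive
    class, matching reference label 0); accuracy, precision and recall are
    computed on that class, and the precision-recall curve sweeps
    ``n_curve_points`` thresholds over [0, 1].
    """
    p = np.asarray(pred.line_weights, dtype=float)
    r = np.asarray(ref.line_labels, dtype=int)
    if p.size != r.size:
        raise ValueError("prediction and reference must have equal length")
    mae = float(np.mean(np.abs(p - r)))
    truth_pos = r == 0

    def _prf(thr: float):
        pred_pos = p < thr
        tp = int(np.sum(pred_pos & truth_pos))
        fp = int(np.sum(pred_pos & ~truth_pos))
        fn = int(np.sum(~pred_pos & truth_pos))
        tn = int(np.sum(~pred_pos & ~truth_pos))
        acc = (tp + tn) / p.size
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        return acc, prec, rec

    acc, prec, rec = _prf(threshold)
    thresholds = np.linspace(0.0, 1.0, n_curve_points)
    curve = np.array([_prf(t) for t in thresholds])
    return {
        "mae": mae,
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "pr_curve": {
            "threshold": thresholds,
            "precision": curve[:, 1],
            "recall": curve[:, 2],
        },
    }


def t2star_map_metrics(
    map_ms: np.ndarray,
    ref_map_ms: np.ndarray,
    brain_mask: np.ndarray,
    sg_map: np.ndarray,
    sg_threshold: float = 100.0,
) -> dict:
    """Per-slice MAE (ms) and SSIM of a T2* map against a reference map.

    Evaluation is restricted to brain voxels with susceptibility gradients
    below ``sg_threshold`` μT/m.  SSIM uses a fixed dynamic range of
    ``SSIM_DYNAMIC_RANGE_MS`` on maps clamped to that range, with voxels
    outside the evaluation mask set to zero in both images.  Slices with an
    empty evaluation mask are skipped.
    """
    map_ms = np.asarray(map_ms, dtype=float)
    ref_map_ms = np.asarray(ref_map_ms, dtype=float)
    if map_ms.shape != ref_map_ms.shape:
        raise ValueError("maps must be aligned")
    eval_mask = np.asarray(brain_mask, dtype=bool) & (np.asarray(sg_map) < sg_threshold)
    mae_per_slice = {}
    ssim_per_slice = {}
    for s in range(map_ms.shape[0]):
        m = eval_mask[s]
        if not m.any():
            continue
        mae_per_slice[s] = float(np.mean(np.abs(map_ms[s][m] - ref_map_ms[s][m])))
        a = np.where(m, np.clip(map_ms[s], 0, SSIM_DYNAMIC_RANGE_MS), 0.0)
        b = np.where(m, np.clip(ref_map_ms[s], 0, SSIM_DYNAMIC_RANGE_MS), 0.0)
        ssim_per_slice[s] = float(
            structural_similarity(
                a, b, data_range=SSIM_DYNAMIC_RANGE_MS, win_size=SSIM_WINDOW
            )
        )
    return {
        "mae_ms": mae_per_slice,
        "ssim": ssim_per_slice,
        "mae_ms_mean": float(np.mean(list(mae_per_slice.values()))) if mae_per_slice else np.nan,
        "ssim_mean": float(np.mean(list(ssim_per_slice.values()))) if ssim_per_slice else np.nan,
    }
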