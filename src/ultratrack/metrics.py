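"""Reconstruction and tracking quality metrics."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["EvaluationSummary", "ncc", "tracking_error", "summarize"]


class ConstantInputError(ValueError):
    """NCC is undefined for a zero-variance (constant) input."""


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation between two equally shaped arrays.

    Mean-centred, variance-normalised voxelwise correlation in [-1, 1];
    1 means identical up to a positive affine intensity change. Raises
    :class:`ConstantInputError` on constant input rather than silently
    returning 0 — a constant reconstruction is a degenerate model, not a
    zero-correlation one.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise ConstantInputError("NCC undefined: at least one input is constant")
    return float(np.clip((da * db).sum() / denom, -1.0, 1.0))


def tracking_error(estimated, truth, spacing_mm) -> float:
    """Euclidean distance in mm between two voxel positions with anisotropic spacing."""
    est = np.asarray(estimated, dtype=float).reshape(3)
    tru = np.asarray(truth, dtype=float).reshape(3)
    sp = np.asarray(spacing_mm, dtype=float).reshape(3)
    return float(np.linalg.norm((est - tru) * sp))


@dataclass
class EvaluationSummary:
    """Aggregate quality figures for one (subject, regime, k, sequence) cell."""

    mean_error_mm: float
    std_error_mm: float  # population std of per-frame errors
    per_frame_errors: list = field(default_factory=list)
    mean_ncc: float | None = None
    k: int | None = None
    regime: str | None = None
    std_error_mm_sample: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_row(self, **extra) -> pd.DataFrame:
        d = asdict(self)
        d.pop("per_frame_errors")
        d.update(extra)
        return pd.DataFrame([d])


def summarize(result, truth, round_truth: bool = True) -> EvaluationSummary:
    """Per-frame mm errors of a tracking result against an annotated track.

    Only frames carrying an annotation contribute. Ground-truth positions are
    continuous; because the tracker reports voxel-grid positions they are
    rounded to the nearest voxel before comparison (``round_truth=False``
    compares against the continuous positions instead). Reports the
    population std to match "mean +/- std" summaries; the sample std is kept
    alongside.
    """
    frames = np.asarray(result.frames)
    est = np.asarray(result.positions_vox, dtype=float)
    spacing = np.asarray(truth.spacing_mm, dtype=float)
    errors = []
    for f, p in zip(truth.frame_index, truth.position_vox):
        hit = np.nonzero(frames == f)[0]
        if len(hit) == 0:
            continue
        gt = np.round(p) if round_truth else p
        errors.append(tracking_error(est[hit[0]], gt, spacing))
    if not errors:
        raise ValueError("no annotated frame overlaps the tracked frames")
    arr = np.asarray(errors)
    return EvaluationSummary(
        mean_error_mm=float(arr.mean()),
        std_error_mm=float(arr.std()),
        std_error_mm_sample=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        per_frame_errors=[float(e) for e in arr],
    )
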