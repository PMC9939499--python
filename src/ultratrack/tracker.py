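"""Greedy latent-space landmark tracking.

Per frame, the landmark is relocated by an iterative greedy search on the
voxel lattice: all patches in the 12-neighbourhood of the current position
are encoded, each candidate's latent vector is compared to a small set of
breathing-phase reference latents, and the search moves to the candidate
with the smallest L2 distance to *any* reference as long as that strictly
improves on the current position. The search for frame ``t`` starts at the
result for frame ``t - 1``, exploiting the slow, continuous character of
respiratory organ motion. An exhaustive region-of-interest search — the
slow template-matching baseline — is provided as well and doubles as the
test oracle for the greedy search.

The tracker is encoder-agnostic: it consumes any callable mapping a batch
of patches ``(n, 24, 24, 24)`` to latents ``(n, k)``, which is exactly what
:meth:`ultratrack.swae.AutoencoderModel.encode` provides.

A structural property of the 12-neighbourhood (offsets with exactly two
nonzero components) is that every move changes ``x + y + z`` by 0 or ±2:
the search graph decomposes into two disconnected sublattices of constant
coordinate-sum parity, each an FCC lattice. A greedy track therefore stays
on the parity class of its initial position for the whole sequence, which
bounds attainable accuracy at about one voxel; the exhaustive baseline is
only a meaningful oracle for the greedy search when restricted to the same
parity class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import tracking_error
from .patches import HALF, Patch, PatchBoundsError, extract_patch, is_admissible, neighborhood_12
from .volume import LandmarkTrack, VolumeSequence

__all__ = [
    "ReferenceSet",
    "TrackerConfig",
    "TrackingResult",
    "PhaseDetectionError",
    "reference_distance",
    "greedy_step",
    "track_frame",
    "track_sequence",
    "select_references",
    "exhaustive_search",
]

PHASE_LABELS = ("end_inhale", "end_exhale", "mid_inhale", "mid_exhale")


class PhaseDetectionError(ValueError):
    """Raised when four distinct breathing phases cannot be identified."""


@dataclass
class ReferenceSet:
    """Reference latents of the target captured at distinct breathing phases."""

    latents: np.ndarray                 # (n_ref, k)
    phase_labels: tuple[str, ...]
    source_patches: list[Patch] = field(default_factory=list)
    source_sequence_id: str = ""
    source_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.latents = np.atleast_2d(np.asarray(self.latents, dtype=np.float64))
        if len(self.latents) != len(self.phase_labels):
            raise ValueError("one phase label per reference required")

    @property
    def k(self) -> int:
        return self.latents.shape[1]

    def __len__(self) -> int:
        return len(self.latents)


@dataclass
class TrackerConfig:
    step_vox: int = 1
    max_iterations_per_frame: int = 200

    def validate(self) -> None:
        if self.step_vox < 1 or self.max_iterations_per_frame < 1:
            raise ValueError("step_vox and max_iterations_per_frame must be >= 1")


@dataclass
class TrackingResult:
    """Per-frame output of a tracking run."""

    frames: np.ndarray                # (T,)
    positions_vox: np.ndarray         # (T, 3) voxel-grid positions
    latent_distances: np.ndarray      # (T,) best distance to the reference set
    iterations_used: np.ndarray       # (T,)
    spacing_mm: np.ndarray
    errors_mm: dict[int, float] = field(default_factory=dict)  # frame -> error

    def to_csv(self, path) -> None:
        mm = self.positions_vox * self.spacing_mm
        pd.DataFrame(
            {
                "frame": self.frames,
                "x_vox": self.positions_vox[:, 0],
                "y_vox": self.positions_vox[:, 1],
                "z_vox": self.positions_vox[:, 2],
                "x_mm": mm[:, 0],
                "y_mm": mm[:, 1],
                "z_mm": mm[:, 2],
                "latent_distance": self.latent_distances,
                "n_iter": self.iterations_used,
                "error_mm": [self.errors_mm.get(int(f), np.nan) for f in self.frames],
            }
        ).to_csv(path, index=False)

    def summary_json(self, path) -> None:
        errs = np.asarray(list(self.errors_mm.values()))
        summary = {
            "n_frames": int(len(self.frames)),
            "n_annotated": int(len(errs)),
            "mean_error_mm": float(errs.mean()) if len(errs) else None,
            "std_error_mm": float(errs.std()) if len(errs) else None,
            "mean_iterations": float(self.iterations_used.mean()),
            "max_iterations": int(self.iterations_used.max()),
        }
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)


def reference_distance(z: np.ndarray, refs: ReferenceSet) -> float:
    """Smallest L2 distance from ``z`` to any reference latent."""
    z = np.asarray(z, dtype=np.float64).reshape(-1)
    if z.shape[0] != refs.k:
        raise ValueError(f"latent dimension {z.shape[0]} does not match references k={refs.k}")
    return float(np.linalg.norm(refs.latents - z, axis=1).min())


def _batch_reference_distance(zs: np.ndarray, refs: ReferenceSet) -> np.ndarray:
    diff = zs[:, None, :] - refs.latents[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def _encode_positions(seq: VolumeSequence, frame: int, positions: list[np.ndarray],
                      encoder) -> np.ndarray:
    batch = np.stack([extract_patch(seq, frame, p).data for p in positions])
    return np.atleast_2d(np.asarray(encoder(batch)))


def greedy_step(seq: VolumeSequence, frame: int, current_pos, refs: ReferenceSet,
                encoder, config: TrackerConfig) -> tuple[np.ndarray, float, bool]:
    """One greedy move: evaluate the admissible 12-neighbourhood, take the best.

    Returns ``(position, distance, converged)``; ``converged`` is True when no
    admissible neighbour is strictly closer to the reference set than the
    current position (ties keep the current position; among candidates, ties
    resolve to the first in the fixed lexicographic offset order).
    """
    config.validate()
    current = np.asarray(current_pos, dtype=int).reshape(3)
    if not is_admissible(seq.grid_shape, current):
        raise PatchBoundsError(f"current position {tuple(current)} admits no full patch")
    candidates = [p for p in neighborhood_12(current, config.step_vox)
                  if is_admissible(seq.grid_shape, p)]
    zs = _encode_positions(seq, frame, [current] + candidates, encoder)
    dists = _batch_reference_distance(zs, refs)
    d_current = dists[0]
    if len(candidates) == 0:
        return current, float(d_current), True
    best = int(np.argmin(dists[1:]))
    if dists[1 + best] < d_current:
        return candidates[best], float(dists[1 + best]), False
    return current, float(d_current), True


def track_frame(seq: VolumeSequence, frame: int, start_pos, refs: ReferenceSet,
                encoder, config: TrackerConfig) -> tuple[np.ndarray, float, int]:
    """Repeat greedy steps until a local optimum or the iteration cap.

    Returns ``(position, distance, iterations_used)``; strict-improvement
    acceptance guarantees the per-iteration distance sequence is strictly
    decreasing, so termination needs no cap in exact arithmetic (the cap is a
    safety net).
    """
    pos = np.asarray(start_pos, dtype=int).reshape(3)
    dist = np.inf
    for it in range(1, config.max_iterations_per_frame + 1):
        pos, dist, converged = greedy_step(seq, frame, pos, refs, encoder, config)
        if converged:
            return pos, dist, it
    return pos, dist, config.max_iterations_per_frame


def track_sequence(seq: VolumeSequence, frames, init_pos, refs: ReferenceSet,
                   encoder, config: TrackerConfig | None = None,
                   truth: LandmarkTrack | None = None) -> TrackingResult:
    """Track across frames, each search starting at the previous frame's result.

    ``init_pos`` seeds the first frame (itself refined by the greedy search).
    If ``truth`` is given, per-frame mm errors are recorded for every
    annotated frame, against the ground truth rounded to the voxel grid.
    """
    config = config or TrackerConfig()
    frames = np.asarray(list(frames), dtype=int)
    if len(frames) == 0:
        raise ValueError("no frames to track")
    positions = np.empty((len(frames), 3), dtype=int)
    dists = np.empty(len(frames))
    iters = np.empty(len(frames), dtype=int)
    pos = np.asarray(init_pos, dtype=float)
    pos = np.round(pos).astype(int)
    for i, f in enumerate(frames):
        pos, d, it = track_frame(seq, int(f), pos, refs, encoder, config)
        positions[i], dists[i], iters[i] = pos, d, it
    result = TrackingResult(
        frames=frames,
        positions_vox=positions,
        latent_distances=dists,
        iterations_used=iters,
        spacing_mm=seq.spacing_mm,
    )
    if truth is not None:
        for f, p in zip(truth.frame_index, truth.position_vox):
            hit = np.nonzero(frames == f)[0]
            if len(hit):
                result.errors_mm[int(f)] = tracking_error(
                    positions[hit[0]], np.round(p), seq.spacing_mm
                )
    return result


def _principal_axis_signal(track: LandmarkTrack) -> np.ndarray:
    """Project the mm trajectory onto its principal displacement axis."""
    x = track.position_mm
    centred = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # Orient the axis along the dominant original coordinate so that "up" is
    # reproducible regardless of SVD sign conventions.
    lead = int(np.argmax(np.abs(axis)))
    if axis[lead] < 0:
        axis = -axis
    return centred @ axis


def select_references(other_track: LandmarkTrack, other_seq: VolumeSequence,
                      encoder) -> ReferenceSet:
    """Pick four breathing-phase reference patches from the *other* window.

    The annotated trajectory is projected onto its principal displacement
    axis; the two extrema give the end-inhale / end-exhale references and the
    frames nearest the mid-excursion level on the two branches between them
    give the mid-inhale / mid-exhale references. Patches are extracted at the
    annotated (rounded) positions and encoded.
    """
    if len(other_track) < 4:
        raise PhaseDetectionError(
            f"need >= 4 annotated frames to identify phases, got {len(other_track)}"
        )
    s = _principal_axis_signal(other_track)
    span = float(s.max() - s.min())
    if span < 1e-9:
        raise PhaseDetectionError("constant trajectory: no breathing phases identifiable")
    imax, imin = int(np.argmax(s)), int(np.argmin(s))
    lo, hi = sorted((imax, imin))
    inner = np.arange(lo + 1, hi)
    outer = np.asarray([i for i in range(len(s)) if i <= lo or i >= hi])
    outer = outer[(outer != imax) & (outer != imin)]
    if len(inner) == 0 or len(outer) == 0:
        raise PhaseDetectionError(
            "could not find mid-excursion frames: found only the two extrema "
            f"(max at index {imax}, min at index {imin})"
        )
    mid_level = 0.5 * (s.max() + s.min())
    i_mid_inner = int(inner[np.argmin(np.abs(s[inner] - mid_level))])
    i_mid_outer = int(outer[np.argmin(np.abs(s[outer] - mid_level))])
    # Branch from the maximum towards the minimum is the exhale branch.
    inner_is_exhale = imax < imin
    picks = {
        "end_inhale": imax,
        "end_exhale": imin,
        "mid_exhale": i_mid_inner if inner_is_exhale else i_mid_outer,
        "mid_inhale": i_mid_outer if inner_is_exhale else i_mid_inner,
    }
    patches, latents, frames = [], [], []
    for label in PHASE_LABELS:
        i = picks[label]
        frame = int(other_track.frame_index[i])
        center = np.round(other_track.position_vox[i]).astype(int)
        patch = extract_patch(other_seq, frame, center)
        patches.append(patch)
        latents.append(np.asarray(encoder(patch.data[None]))[0])
        frames.append(frame)
    return ReferenceSet(
        latents=np.stack(latents),
        phase_labels=PHASE_LABELS,
        source_patches=patches,
        source_sequence_id=other_track.sequence_id,
        source_frames=tuple(frames),
    )


def exhaustive_search(seq: VolumeSequence, frame: int, roi, refs: ReferenceSet,
                      encoder, batch_size: int = 256) -> tuple[np.ndarray, float]:
    """Template-matching baseline: global argmin of the reference distance over a ROI.

    ``roi`` is an iterable of voxel positions (each admitting a full patch).
    Ties break to the lexicographically smallest position. Quadratic in the
    ROI size — kept as the slow oracle the greedy search approximates.
    """
    positions = np.asarray([np.asarray(p, dtype=int).reshape(3) for p in roi])
    if len(positions) == 0:
        raise ValueError("empty region of interest")
    order = np.lexsort((positions[:, 2], positions[:, 1], positions[:, 0]))
    positions = positions[order]
    for p in positions:
        if not is_admissible(seq.grid_shape, p):
            raise PatchBoundsError(f"ROI position {tuple(p)} admits no full patch")
    best_pos, best_d = None, np.inf
    for lo in range(0, len(positions), batch_size):
        chunk = positions[lo:lo + batch_size]
        zs = _encode_positions(seq, frame, list(chunk), encoder)
        dists = _batch_reference_distance(zs, refs)
        i = int(np.argmin(dists))
        if dists[i] < best_d:
            best_pos, best_d = chunk[i], float(dists[i])
    return best_pos, best_d
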