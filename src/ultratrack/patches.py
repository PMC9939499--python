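"""Patch extraction, random sampling, sequence splitting and neighbourhoods.

The model consumes cubic intensity patches of ``24**3 = 13824`` voxels. A
patch centred at voxel ``c`` spans ``[c - 12, c + 12)`` on each axis (the
even size forces a convention; this one is used identically everywhere,
including error accounting). Intensities are min-max normalised to [0, 1]
per *volume*, never per patch, so relative contrast between patches is
preserved.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .volume import VolumeSequence

__all__ = [
    "PATCH_SIZE",
    "HALF",
    "Patch",
    "DatasetSplit",
    "PatchBoundsError",
    "split_sequence",
    "sample_patches",
    "extract_patch",
    "neighborhood_12",
    "admissible_center_range",
    "is_admissible",
    "normalize_volume",
    "save_patches",
    "load_patches",
]

PATCH_SIZE = 24
HALF = PATCH_SIZE // 2


class PatchBoundsError(ValueError):
    """A requested patch does not fit inside its source volume."""


@dataclass
class Patch:
    """A 24x24x24 intensity block with its provenance."""

    data: np.ndarray
    center_vox: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != (PATCH_SIZE,) * 3:
            raise ValueError(f"patch shape must be {(PATCH_SIZE,) * 3}, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("patch contains non-finite values")
        self.center_vox = np.asarray(self.center_vox, dtype=int).reshape(3)


@dataclass
class DatasetSplit:
    """Temporal train/validation frame ranges of one sequence."""

    training_frames: range
    validation_frames: range


def split_sequence(n_frames: int) -> DatasetSplit:
    """Split frames 2:1 — the first two thirds train, the last third validates.

    ``floor(2n/3)`` frames go to training, the remainder to validation, so the
    two ranges are disjoint, ordered and jointly cover every frame.
    """
    if n_frames < 3:
        raise ValueError(f"need at least 3 frames to split, got {n_frames}")
    cut = (2 * n_frames) // 3
    return DatasetSplit(training_frames=range(0, cut), validation_frames=range(cut, n_frames))


def admissible_center_range(dim: int) -> tuple[int, int]:
    """Inclusive range of admissible patch-centre indices along one axis."""
    if dim < PATCH_SIZE:
        raise PatchBoundsError(f"axis of {dim} voxels cannot hold a {PATCH_SIZE}-voxel patch")
    return HALF, dim - HALF


def is_admissible(grid_shape, center_vox) -> bool:
    """True iff a full patch centred at ``center_vox`` fits inside the grid."""
    c = np.asarray(center_vox, dtype=int)
    g = np.asarray(grid_shape, dtype=int)
    return bool(np.all(c - HALF >= 0) and np.all(c + HALF <= g))


def extract_patch(seq: VolumeSequence, frame: int, center_vox) -> Patch:
    """Extract the patch spanning ``[c - 12, c + 12)`` around ``center_vox``."""
    c = np.asarray(center_vox, dtype=int).reshape(3)
    if not 0 <= frame < seq.n_frames:
        raise PatchBoundsError(f"frame {frame} outside sequence of {seq.n_frames} frames")
    if not is_admissible(seq.grid_shape, c):
        raise PatchBoundsError(
            f"patch at centre {tuple(c)} does not fit inside grid {seq.grid_shape}"
        )
    lo = c - HALF
    block = seq.data[frame, lo[0]:lo[0] + PATCH_SIZE, lo[1]:lo[1] + PATCH_SIZE,
                     lo[2]:lo[2] + PATCH_SIZE]
    return Patch(data=block.copy(), center_vox=c, frame_index=frame)


def sample_patches(seq: VolumeSequence, frames, n: int, seed: int) -> list[Patch]:
    """Draw ``n`` patches with frame and centre chosen uniformly at random.

    Frames come uniformly from ``frames``; centres uniformly from every
    position admitting a fully in-bounds patch. Reproducible under ``seed``.
    """
    frames = np.asarray(list(frames), dtype=int)
    if len(frames) == 0:
        raise ValueError("empty frame range")
    ranges = [admissible_center_range(d) for d in seq.grid_shape]
    rng = np.random.default_rng(seed)
    picked_frames = rng.choice(frames, size=n, replace=True)
    centers = np.stack(
        [rng.integers(lo, hi + 1, size=n) for lo, hi in ranges], axis=1
    )
    return [extract_patch(seq, int(f), c) for f, c in zip(picked_frames, centers)]


# The 12 edge-adjacent lattice offsets: exactly two nonzero components, each
# +/- step. Fixed lexicographic order gives deterministic tie-breaking.
_OFFSETS_12 = sorted(
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if sum(o != 0 for o in off) == 2
)


def neighborhood_12(center_vox, step_vox: int = 1) -> list[np.ndarray]:
    """The 12 edge-adjacent neighbours of a lattice site, at distance step*sqrt(2).

    Bounds filtering is the caller's job; positions are returned in a fixed
    lexicographic offset order.
    """
    if step_vox < 1:
        raise ValueError("step_vox must be >= 1")
    c = np.asarray(center_vox, dtype=int).reshape(3)
    return [c + step_vox * np.asarray(off, dtype=int) for off in _OFFSETS_12]


def normalize_volume(vol: np.ndarray) -> np.ndarray:
    """Min-max normalise one volume (or a whole (T, X, Y, Z) sequence) to [0, 1]."""
    vol = np.asarray(vol, dtype=np.float32)
    lo, hi = float(vol.min()), float(vol.max())
    if hi <= lo:
        raise ValueError("constant volume cannot be normalised")
    return (vol - lo) / (hi - lo)


def save_patches(path, patches: list[Patch], meta: dict | None = None) -> None:
    """Serialise a patch set as one compressed array container + JSON sidecar."""
    data = np.stack([p.data for p in patches])
    centers = np.stack([p.center_vox for p in patches])
    frames = np.asarray([p.frame_index for p in patches])
    np.savez_compressed(path, data=data, centers=centers, frames=frames)
    sidecar = str(path) + ".json" if not str(path).endswith(".npz") else str(path)[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"n": len(patches), **(meta or {})}, fh, indent=2)


def load_patches(path) -> list[Patch]:
    with np.load(path) as arc:
        return [
            Patch(data=d, center_vox=c, frame_index=int(f))
            for d, c, f in zip(arc["data"], arc["centers"], arc["frames"])
        ]
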