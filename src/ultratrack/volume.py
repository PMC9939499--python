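"""4D ultrasound containers: volume sequences and landmark tracks.

Coordinate convention used throughout the package: 0-based voxel indices in
axis order (x, y, z) matching the NIfTI affine; millimetre values are always
``voxel_index * spacing_mm``. A sequence is stored as a ``(T, X, Y, Z)``
array; on disk it is a 4D NIfTI-1 file with time as the fourth dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["VolumeSequence", "LandmarkTrack"]


@dataclass
class VolumeSequence:
    """A time series of 3D intensity volumes.

    Parameters
    ----------
    data:
        ``(T, X, Y, Z)`` float array of intensities, expected in ``[0, 1]``.
    spacing_mm:
        Voxel spacing per spatial axis in millimetres.
    frame_rate_hz:
        Temporal sampling rate in volumes per second.
    sequence_id:
        Free-form identifier used for provenance bookkeeping (e.g. which
        short-term window references were taken from).
    """

    data: np.ndarray
    spacing_mm: np.ndarray
    frame_rate_hz: float
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError(f"sequence data must be (T, X, Y, Z), got shape {self.data.shape}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def frame(self, t: int) -> np.ndarray:
        """Return the 3D volume at frame ``t``."""
        return self.data[t]

    def save_nifti(self, path) -> None:
        """Write the sequence as a 4D NIfTI-1 file (x, y, z, t on disk)."""
        affine = np.diag([*self.spacing_mm, 1.0])
        img = nib.Nifti1Image(np.moveaxis(self.data, 0, -1), affine)
        img.header.set_zooms((*self.spacing_mm, 1.0 / self.frame_rate_hz))
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    @classmethod
    def load_nifti(cls, path, sequence_id: str = "") -> "VolumeSequence":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[..., None]
        zooms = img.header.get_zooms()
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(
            data=np.moveaxis(arr, -1, 0),
            spacing_mm=np.asarray(zooms[:3], dtype=float),
            frame_rate_hz=1.0 / dt,
            sequence_id=sequence_id or str(path),
        )


@dataclass
class LandmarkTrack:
    """Landmark annotations: one continuous 3D voxel position per listed frame."""

    frame_index: np.ndarray
    position_vox: np.ndarray
    spacing_mm: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int).reshape(-1)
        self.position_vox = np.asarray(self.position_vox, dtype=float).reshape(-1, 3)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        if len(self.frame_index) != len(self.position_vox):
            raise ValueError("frame_index and position_vox lengths differ")
        if len(self.frame_index) > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def position_mm(self) -> np.ndarray:
        return self.position_vox * self.spacing_mm

    def position_at(self, frame: int) -> np.ndarray:
        """Position annotated at ``frame``; raises ``KeyError`` if absent."""
        hits = np.nonzero(self.frame_index == frame)[0]
        if len(hits) == 0:
            raise KeyError(f"no annotation at frame {frame}")
        return self.position_vox[hits[0]]

    def subset(self, frames: np.ndarray, sequence_id: str | None = None) -> "LandmarkTrack":
        mask = np.isin(self.frame_index, frames)
        return LandmarkTrack(
            frame_index=self.frame_index[mask],
            position_vox=self.position_vox[mask],
            spacing_mm=self.spacing_mm,
            sequence_id=self.sequence_id if sequence_id is None else sequence_id,
        )

    def min_margin_vox(self, grid_shape) -> float:
        """Smallest distance (in voxels) from any annotated position to a volume face."""
        grid = np.asarray(grid_shape, dtype=float)
        low = self.position_vox.min(axis=0)
        high = (grid - 1) - self.position_vox.max(axis=0)
        return float(min(low.min(), high.min()))

    def to_csv(self, path) -> None:
        mm = self.position_mm
        pd.DataFrame(
            {
                "frame": self.frame_index,
                "x_vox": self.position_vox[:, 0],
                "y_vox": self.position_vox[:, 1],
                "z_vox": self.position_vox[:, 2],
                "x_mm": mm[:, 0],
                "y_mm": mm[:, 1],
                "z_mm": mm[:, 2],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sequence_id: str = "") -> "LandmarkTrack":
        df = pd.read_csv(path)
        vox = df[["x_vox", "y_vox", "z_vox"]].to_numpy(dtype=float)
        mm = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(vox != 0, mm / vox, np.nan)
        spacing = np.nanmedian(ratio, axis=0)
        spacing = np.where(np.isfinite(spacing), spacing, 1.0)
        return cls(
            frame_index=df["frame"].to_numpy(dtype=int),
            position_vox=vox,
            spacing_mm=spacing,
            sequence_id=sequence_id or str(path),
        )
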