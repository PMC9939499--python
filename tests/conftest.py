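"""Shared fixtures: small phantoms and mock coordinate encoders.

The tracker is encoder-agnostic, so most tracking tests use a mock encoder
that reads a voxel-coordinate code straight out of the patch centre: the
phantom volume stores ``x + Nx*y + Nx*Ny*z`` at voxel (x, y, z), and the
encoder decodes that integer back into (x, y, z). Latent L2 distance then
equals Euclidean voxel distance, giving a convex distance field with a
known global optimum — the setting where greedy search must match
exhaustive search exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

import ultratrack as ut


@pytest.fixture(scope="session")
def small_phantom():
    """A 24-frame, 48^3 phantom with default motion (fast to generate)."""
    cfg = ut.PhantomConfig(grid_shape=(48, 48, 48), n_frames=24, seed=5,
                           translation_amplitude_mm=(1.0, 2.0, 6.0))
    seq, track = ut.generate_sequence(cfg)
    return cfg, seq, track


@pytest.fixture(scope="session")
def static_phantom():
    cfg = ut.PhantomConfig(grid_shape=(48, 48, 48), n_frames=6, seed=3,
                           translation_amplitude_mm=(0.0, 0.0, 0.0),
                           rotation_amplitude_deg=0.0,
                           deformation_amplitude_mm=0.0)
    seq, track = ut.generate_sequence(cfg)
    return cfg, seq, track


def make_coordinate_sequence(n: int = 40, n_frames: int = 1) -> ut.VolumeSequence:
    """Volume whose voxel value encodes its own (x, y, z) index."""
    x, y, z = np.indices((n, n, n), dtype=np.float32)
    code = x + n * y + n * n * z
    data = np.broadcast_to(code, (n_frames, n, n, n)).copy()
    return ut.VolumeSequence(data=data, spacing_mm=(1, 1, 1), frame_rate_hz=1.0,
                             sequence_id="coordinate-mock")


def make_coordinate_encoder(n: int):
    """Batch encoder mapping a patch to its centre voxel coordinates."""

    def encode(batch: np.ndarray) -> np.ndarray:
        codes = batch[:, 12, 12, 12].astype(np.float64)
        x = codes % n
        y = (codes // n) % n
        z = codes // (n * n)
        return np.stack([x, y, z], axis=1)

    return encode


@pytest.fixture(scope="session")
def coordinate_world():
    n = 40
    return make_coordinate_sequence(n), make_coordinate_encoder(n)


@pytest.fixture(scope="session")
def tiny_arch():
    """Architecture small enough for seconds-scale training in unit tests."""
    return ut.ArchitectureConfig(conv_channels=(2, 4, 4, 8), fc_hidden=(32, 16))


@pytest.fixture(scope="session")
def tiny_patches(small_phantom):
    _, seq, _ = small_phantom
    return ut.sample_patches(seq, range(10), 64, seed=11)
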