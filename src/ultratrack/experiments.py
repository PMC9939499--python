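"""Canned validation experiments at single-CPU scale.

These are the package's reference experiments: each builds its own inputs
(phantoms, patch sets, mock latent fields), runs the method and returns the
measured quantities. They are driven both by the acceptance test suite and
by ``scripts/acceptance.py``. Problem sizes follow docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift

from . import metrics, swae, tracker
from .patches import PATCH_SIZE, extract_patch, sample_patches, split_sequence
from .phantom import PhantomConfig, annotate_short_term_windows, generate_sequence
from .swae import ArchitectureConfig, TrainingConfig, sample_ball_prior, sliced_wasserstein
from .tracker import ReferenceSet, TrackerConfig, exhaustive_search, track_frame, track_sequence
from .volume import LandmarkTrack, VolumeSequence

__all__ = [
    "PATCH_VOXELS", "data_reduction_percent", "coordinate_world",
    "oracle_agreement", "sw_estimator_checks", "overfit_one_patch_ncc",
    "TrendResult", "trend_suite", "TrackingSuiteResult", "tracking_suite",
]

PATCH_VOXELS = PATCH_SIZE**3  # 13824


def data_reduction_percent(k: int) -> float:
    """Percentage of the patch dimensionality removed by a k-dim code."""
    return 100.0 * (1.0 - k / PATCH_VOXELS)


# ---------------------------------------------------------------------------
# Mock latent world: voxel values encode their own coordinates, so latent
# distance equals Euclidean voxel distance — a convex field with a known
# optimum, used to validate the greedy search against exhaustive search.

def coordinate_world(n: int = 40):
    x, y, z = np.indices((n, n, n), dtype=np.float32)
    code = x + n * y + n * n * z
    seq = VolumeSequence(data=code[None], spacing_mm=(1, 1, 1), frame_rate_hz=1.0,
                         sequence_id="coordinate-mock")

    def encode(batch: np.ndarray) -> np.ndarray:
        codes = batch[:, PATCH_SIZE // 2, PATCH_SIZE // 2, PATCH_SIZE // 2].astype(np.float64)
        return np.stack([codes % n, (codes // n) % n, codes // (n * n)], axis=1)

    return seq, encode


def oracle_agreement(n: int = 40, target=(22.23, 17.71, 20.12),
                     start_stride: int = 1) -> dict:
    """Fraction of admissible starts from which greedy == parity-class exhaustive.

    Every 12-neighbourhood move preserves the parity of x+y+z, so the
    exhaustive oracle is evaluated per parity class of the admissible grid.
    """
    seq, encode = coordinate_world(n)
    refs = ReferenceSet(latents=np.asarray([target], dtype=float),
                        phase_labels=("end_inhale",))
    half = PATCH_SIZE // 2
    rng_axis = range(half, n - half + 1)
    grid = [(x, y, z) for x in rng_axis for y in rng_axis for z in rng_axis]
    oracle = {
        par: exhaustive_search(seq, 0, [p for p in grid if sum(p) % 2 == par],
                               refs, encode)[0]
        for par in (0, 1)
    }
    cfg = TrackerConfig()
    starts = grid[::start_stride]
    hits = sum(
        np.array_equal(track_frame(seq, 0, s, refs, encode, cfg)[0],
                       oracle[sum(s) % 2])
        for s in starts
    )
    return {"agreement": hits / len(starts), "n_starts": len(starts)}


# ---------------------------------------------------------------------------

def sw_estimator_checks(seed: int = 0, k: int = 8, n_projections: int = 64,
                        sizes=(64, 256, 1024), n_reps: int = 3) -> dict:
    """Exact small cases plus the same-distribution decay of the SW estimate."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(20, 5))
    out = {
        "identical_sets": sliced_wasserstein(z, z.copy(), n_projections, seed),
        "two_point_1d": sliced_wasserstein([[0.0]], [[1.0]], n_projections, seed),
    }
    decay = {}
    for m in sizes:
        vals = []
        for _ in range(n_reps):
            a = sample_ball_prior(m, k, 1.0, rng)
            b = sample_ball_prior(m, k, 1.0, rng)
            vals.append(sliced_wasserstein(a, b, n_projections,
                                           seed=int(rng.integers(2**31))))
        decay[m] = float(np.mean(vals))
    out["decay"] = decay
    ms = np.log(np.asarray(sizes, dtype=float))
    vs = np.log(np.asarray([decay[m] for m in sizes]))
    out["decay_log_slope"] = float(np.polyfit(ms, vs, 1)[0])
    return out


# ---------------------------------------------------------------------------

def overfit_one_patch_ncc(k: int, seed: int = 0, steps: int = 1000,
                          learning_rate: float = 3e-3) -> float:
    """Drive a full-resolution model to memorise one phantom patch; return NCC.

    beta = 0 so the check isolates the reconstruction path (the prior term is
    meaningless for a single repeated sample).
    """
    cfg = PhantomConfig(grid_shape=(48, 48, 48), n_frames=4, seed=seed + 17)
    seq, track = generate_sequence(cfg)
    patch = extract_patch(seq, 0, np.round(track.position_vox[0]).astype(int))
    tc = TrainingConfig(alpha=1.0, beta=0.0, max_epochs=steps, patience=steps,
                        learning_rate=learning_rate, val_split=0.5, seed=seed)
    model = swae.train([patch, patch], k, tc)
    return metrics.ncc(patch.data, model.reconstruct(patch.data))


# ---------------------------------------------------------------------------
# Trend suite: 2 phantom subjects, 2000 training patches each, pooled
# training, held-out NCC and tracking error across latent sizes.

TREND_KS = (8, 32, 128)
TREND_SEEDS = (0, 1, 2)
# Full resolution with a narrow conv trunk: the reconstruction ceiling must
# keep rising with k for a capacity trend to be visible, which rules the
# blocky half-resolution variant out here; narrow widths keep nine
# trainings inside a single-CPU budget.
TREND_ARCH = ArchitectureConfig(conv_channels=(2, 4, 4, 8), fc_hidden=(256, 128))
TREND_CONFIG = TrainingConfig(max_epochs=2, patience=2, learning_rate=2e-3)

# The tracking experiments are insensitive to the output ceiling, so they
# use the fast half-resolution variant.
TRACKING_ARCH = ArchitectureConfig(half_resolution=True)


@dataclass
class TrendResult:
    ncc_by_k: dict          # k -> list of per-seed mean held-out NCC
    median_ncc_by_k: dict   # k -> median over seeds
    error_by_k: dict        # k -> list of per-(seed, subject) mean errors (mm)
    mean_error_by_k: dict   # k -> mean over seeds and subjects


def _trend_subjects(seed: int, n_train: int, n_val: int):
    subjects = []
    for s in range(2):
        cfg = PhantomConfig(n_frames=100, seed=seed + 10 + s)
        seq, track = generate_sequence(cfg)
        split = split_sequence(seq.n_frames)
        subjects.append({
            "seq": seq,
            "train": sample_patches(seq, split.training_frames, n_train,
                                    seed=seed + 100 + s),
            "val": sample_patches(seq, split.validation_frames, n_val,
                                  seed=seed + 200 + s),
            "windows": annotate_short_term_windows(seq, track, window_s=3.0,
                                                   every_n=2),
        })
    return subjects


def _window_error(subject, model) -> float:
    l1, l2 = subject["windows"]
    refs = tracker.select_references(l2, subject["seq"], model.encode)
    frames = range(int(l1.frame_index[0]), int(l1.frame_index[-1]) + 1)
    res = track_sequence(subject["seq"], frames, l1.position_vox[0], refs,
                         model.encode, truth=l1)
    return metrics.summarize(res, l1).mean_error_mm


def trend_suite(seed: int = 0, ks=TREND_KS, seeds=TREND_SEEDS,
                n_train: int = 2000, n_val: int = 200,
                track_ks=(8, 128)) -> TrendResult:
    """Reconstruction-vs-k and tracking-vs-k at the scaled-down study size."""
    subjects = _trend_subjects(seed, n_train, n_val)
    pooled = subjects[0]["train"] + subjects[1]["train"]
    xv = np.stack([p.data for s in subjects for p in s["val"]])
    ncc_by_k: dict = {k: [] for k in ks}
    error_by_k: dict = {k: [] for k in track_ks}
    for k in ks:
        for s_off in seeds:
            tc = dataclasses.replace(TREND_CONFIG, seed=seed + s_off)
            model = swae.train(pooled, k, tc, arch=TREND_ARCH)
            recs = model.decode(model.encode(xv))
            ncc_by_k[k].append(
                float(np.mean([metrics.ncc(a, b) for a, b in zip(xv, recs)]))
            )
            if k in error_by_k:
                for subject in subjects:
                    error_by_k[k].append(_window_error(subject, model))
    return TrendResult(
        ncc_by_k=ncc_by_k,
        median_ncc_by_k={k: float(np.median(v)) for k, v in ncc_by_k.items()},
        error_by_k=error_by_k,
        mean_error_by_k={k: float(np.mean(v)) for k, v in error_by_k.items()},
    )


# ---------------------------------------------------------------------------
# Tracking suite: a ~10 mm-excursion phantom, one trained k=64 model,
# normal tracking plus the large-jump failure scenario.

@dataclass
class TrackingSuiteResult:
    excursion_mm: float
    mean_error_mm: float      # over both annotated windows, normal motion
    max_error_mm: float
    jump_mm: float
    pre_jump_mean_error_mm: float
    post_jump_min_error_mm: float
    post_jump_mean_error_mm: float


def tracking_suite(seed: int = 0, k: int = 64, n_train: int = 2000,
                   jump_mm: float = 20.0) -> TrackingSuiteResult:
    cfg = PhantomConfig(n_frames=100, seed=seed + 31,
                        translation_amplitude_mm=(1.5, 3.0, 9.0))
    seq, track = generate_sequence(cfg)
    split = split_sequence(seq.n_frames)
    l1, l2 = annotate_short_term_windows(seq, track, window_s=3.0, every_n=2)
    excursion = float(np.ptp(track.position_mm, axis=0).max())

    tc = dataclasses.replace(TREND_CONFIG, seed=seed)
    model = swae.train(sample_patches(seq, split.training_frames, n_train,
                                      seed=seed + 300),
                       k, tc, arch=TRACKING_ARCH)

    errors: list[float] = []
    for window, source in ((l1, l2), (l2, l1)):
        refs = tracker.select_references(source, seq, model.encode)
        frames = range(int(window.frame_index[0]), int(window.frame_index[-1]) + 1)
        res = track_sequence(seq, frames, window.position_vox[0], refs,
                             model.encode, truth=window)
        errors.extend(res.errors_mm.values())

    # Failure scenario: all frames from the middle of L1 on are shifted by
    # jump_mm along z, a single-frame target jump the greedy search cannot
    # follow.
    frames = np.arange(int(l1.frame_index[0]), int(l1.frame_index[-1]) + 1)
    t_jump = int(frames[len(frames) // 2])
    jump_vox = jump_mm / seq.spacing_mm[2]
    data = seq.data.copy()
    for t in range(t_jump, seq.n_frames):
        data[t] = nd_shift(seq.data[t], (0, 0, jump_vox), order=1, mode="nearest")
    jumped = VolumeSequence(data=data, spacing_mm=seq.spacing_mm,
                            frame_rate_hz=seq.frame_rate_hz,
                            sequence_id=seq.sequence_id + "+jump")
    pos = track.position_vox.copy()
    pos[t_jump:, 2] += jump_vox
    truth = LandmarkTrack(frame_index=track.frame_index, position_vox=pos,
                          spacing_mm=seq.spacing_mm).subset(l1.frame_index)
    # References come from the unshifted recording of the other window —
    # the jump happens later, during tracking.
    refs = tracker.select_references(l2, seq, model.encode)
    res = track_sequence(jumped, frames, truth.position_vox[0], refs,
                         model.encode, truth=truth)
    pre = [e for f, e in res.errors_mm.items() if f < t_jump]
    post = [e for f, e in res.errors_mm.items() if f >= t_jump]
    return TrackingSuiteResult(
        excursion_mm=excursion,
        mean_error_mm=float(np.mean(errors)),
        max_error_mm=float(np.max(errors)),
        jump_mm=jump_mm,
        pre_jump_mean_error_mm=float(np.mean(pre)),
        post_jump_min_error_mm=float(np.min(post)),
        post_jump_mean_error_mm=float(np.mean(post)),
    )
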