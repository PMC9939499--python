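"""Greedy search, reference handling and the exhaustive-search oracle.

All tests run with mock encoders (no trained model): the tracker only ever
sees a callable from patch batches to latent vectors.
"""

import numpy as np
import pytest

import ultratrack as ut
from ultratrack.patches import PatchBoundsError
from ultratrack.tracker import PhaseDetectionError

from conftest import make_coordinate_encoder, make_coordinate_sequence


def refs_at(target, k_label="end_inhale"):
    """Single-reference set whose latent is the target voxel coordinate."""
    return ut.ReferenceSet(latents=np.asarray([target], dtype=float),
                           phase_labels=(k_label,))


class TestReferenceDistance:
    def test_zero_at_a_reference(self):
        refs = ut.ReferenceSet(latents=[[1.0, 2.0]], phase_labels=("end_inhale",))
        assert ut.reference_distance([1.0, 2.0], refs) == 0.0

    def test_min_over_references_hand_computed(self):
        refs = ut.ReferenceSet(latents=[[0.0, 0.0], [10.0, 0.0]],
                               phase_labels=("end_inhale", "end_exhale"))
        assert ut.reference_distance([4.0, 0.0], refs) == pytest.approx(4.0)

    def test_singleton_degenerates_to_l2(self):
        refs = ut.ReferenceSet(latents=[[1.0, 1.0, 1.0]], phase_labels=("end_inhale",))
        assert ut.reference_distance([2.0, 2.0, 2.0], refs) == pytest.approx(np.sqrt(3))

    def test_dimension_mismatch(self):
        refs = ut.ReferenceSet(latents=[[0.0, 0.0]], phase_labels=("end_inhale",))
        with pytest.raises(ValueError):
            ut.reference_distance([1.0, 2.0, 3.0], refs)


class TestGreedySearch:
    def test_step_moves_toward_target_then_converges(self, coordinate_world):
        seq, encoder = coordinate_world
        refs = refs_at((20, 20, 24))
        cfg = ut.TrackerConfig()
        pos, dist, converged = ut.greedy_step(seq, 0, (20, 20, 20), refs, encoder, cfg)
        assert not converged
        assert np.linalg.norm(pos - np.array([20, 20, 24])) < 4.0
        # iterating reaches a fixed point where no edge-neighbour improves
        final, d, _ = ut.track_frame(seq, 0, (20, 20, 20), refs, encoder, cfg)
        again, d2, converged = ut.greedy_step(seq, 0, final, refs, encoder, cfg)
        assert converged and np.array_equal(again, final)

    def test_local_optimum_is_fixed_point(self, coordinate_world):
        seq, encoder = coordinate_world
        refs = refs_at((18, 18, 18))
        pos, dist, converged = ut.greedy_step(seq, 0, (18, 18, 18), refs, encoder,
                                              ut.TrackerConfig())
        assert converged
        assert tuple(pos) == (18, 18, 18)
        assert dist == 0.0

    def test_out_of_bounds_candidates_skipped(self, coordinate_world):
        from ultratrack.patches import is_admissible

        seq, encoder = coordinate_world
        # centre on the admissibility boundary: some neighbours fall outside,
        # and the target pull points straight at the border
        refs = refs_at((0, 0, 0))
        pos, dist, _ = ut.greedy_step(seq, 0, (12, 12, 12), refs, encoder,
                                      ut.TrackerConfig())
        assert is_admissible(seq.grid_shape, pos)

    def test_inadmissible_start_rejected(self, coordinate_world):
        seq, encoder = coordinate_world
        with pytest.raises(PatchBoundsError):
            ut.greedy_step(seq, 0, (5, 20, 20), refs_at((20, 20, 20)), encoder,
                           ut.TrackerConfig())

    def test_max_iterations_budget(self, coordinate_world):
        seq, encoder = coordinate_world
        refs = refs_at((27, 20, 20))
        cfg = ut.TrackerConfig(max_iterations_per_frame=1)
        pos, _, n_iter = ut.track_frame(seq, 0, (13, 20, 20), refs, encoder, cfg)
        assert n_iter == 1
        assert np.abs(pos - np.array([13, 20, 20])).sum() <= 2

    def test_monotone_distance_across_iterations(self, coordinate_world):
        seq, encoder = coordinate_world
        refs = refs_at((24, 23, 22))
        cfg = ut.TrackerConfig()
        pos = np.array([14, 14, 14])
        dists = []
        for _ in range(40):
            pos, d, converged = ut.greedy_step(seq, 0, pos, refs, encoder, cfg)
            if converged:
                break
            dists.append(d)
        assert len(dists) >= 2
        assert all(b < a for a, b in zip(dists, dists[1:]))


class TestExhaustiveOracle:
    def test_single_voxel_roi(self, coordinate_world):
        seq, encoder = coordinate_world
        pos, dist = ut.exhaustive_search(seq, 0, [(15, 15, 15)], refs_at((20, 20, 20)),
                                         encoder)
        assert tuple(pos) == (15, 15, 15)

    def test_empty_roi(self, coordinate_world):
        seq, encoder = coordinate_world
        with pytest.raises(ValueError):
            ut.exhaustive_search(seq, 0, [], refs_at((20, 20, 20)), encoder)

    def test_returned_distance_is_global_minimum(self, coordinate_world):
        seq, encoder = coordinate_world
        refs = refs_at((17.3, 21.2, 19.1))
        roi = [(x, y, z) for x in range(14, 22) for y in range(18, 25)
               for z in range(16, 22)]
        pos, dist = ut.exhaustive_search(seq, 0, roi, refs, encoder)
        for p in roi:
            z = encoder(np.stack([ut.extract_patch(seq, 0, p).data]))[0]
            assert dist <= ut.reference_distance(z, refs) + 1e-12

    def test_greedy_equals_exhaustive_on_convex_field(self, coordinate_world):
        # greedy moves preserve the parity of x+y+z, so the oracle is the
        # exhaustive argmin over the start's parity class
        seq, encoder = coordinate_world
        refs = refs_at((22.23, 17.71, 20.12))  # general position: no distance ties
        cfg = ut.TrackerConfig()
        box = [(x, y, z) for x in range(14, 27) for y in range(14, 27)
               for z in range(14, 27)]
        by_parity = {
            par: [p for p in box if sum(p) % 2 == par] for par in (0, 1)
        }
        oracle = {par: ut.exhaustive_search(seq, 0, pts, refs, encoder)[0]
                  for par, pts in by_parity.items()}
        starts = [p for p in box if all(v % 3 == 0 for v in p)] + [(14, 26, 15)]
        for start in starts:
            pos, _, _ = ut.track_frame(seq, 0, start, refs, encoder, cfg)
            assert np.array_equal(pos, oracle[sum(start) % 2])


class TestTrackSequence:
    def test_static_phantom_keeps_position(self, static_phantom):
        _, seq, track = static_phantom
        n = seq.grid_shape[0]
        world = make_coordinate_sequence(n, seq.n_frames)
        encoder = make_coordinate_encoder(n)
        start = np.round(track.position_vox[0]).astype(int)
        refs = refs_at(tuple(start))
        res = ut.track_sequence(world, range(seq.n_frames), start, refs, encoder)
        assert np.all(res.positions_vox == start)
        assert np.all(res.latent_distances == 0.0)

    def test_plateau_field_persists_without_error(self, coordinate_world):
        seq, _ = coordinate_world

        def flat_encoder(batch):
            return np.zeros((len(batch), 3))

        refs = ut.ReferenceSet(latents=np.zeros((1, 3)), phase_labels=("end_inhale",))
        res = ut.track_sequence(seq, range(1), (20, 20, 20), refs, flat_encoder)
        assert np.array_equal(res.positions_vox[0], (20, 20, 20))

    def test_errors_recorded_only_for_annotated_frames(self, coordinate_world):
        seq, encoder = coordinate_world
        truth = ut.LandmarkTrack(frame_index=[0], position_vox=[(20, 20, 20)],
                                 spacing_mm=(1, 1, 1))
        refs = refs_at((20, 20, 20))
        res = ut.track_sequence(seq, [0], (20, 20, 20), refs, encoder, truth=truth)
        assert res.errors_mm == {0: 0.0}

    def test_result_csv_and_summary(self, coordinate_world, tmp_path):
        seq, encoder = coordinate_world
        refs = refs_at((20, 20, 20))
        truth = ut.LandmarkTrack(frame_index=[0], position_vox=[(20, 20, 20)],
                                 spacing_mm=(1, 1, 1))
        res = ut.track_sequence(seq, [0], (18, 18, 18), refs, encoder, truth=truth)
        res.to_csv(tmp_path / "r.csv")
        res.summary_json(tmp_path / "r.json")
        assert (tmp_path / "r.csv").is_file() and (tmp_path / "r.json").is_file()


class TestSelectReferences:
    @staticmethod
    def _sinusoid_world(period=20, n_frames=40):
        n = 48
        seq = make_coordinate_sequence(n, n_frames)
        t = np.arange(n_frames)
        z = 24 + 8 * np.sin(2 * np.pi * t / period)
        pos = np.stack([np.full(n_frames, 24.0), np.full(n_frames, 24.0), z], axis=1)
        track = ut.LandmarkTrack(frame_index=t, position_vox=pos, spacing_mm=(1, 1, 1),
                                 sequence_id="L2")
        return seq, track, make_coordinate_encoder(n)

    def test_sinusoid_phases_found(self):
        seq, track, encoder = self._sinusoid_world()
        refs = ut.select_references(track, seq, encoder)
        assert len(refs) == 4
        picked = dict(zip(refs.phase_labels, refs.source_frames))
        assert picked["end_inhale"] % 20 == 5
        assert picked["end_exhale"] % 20 == 15
        assert min(abs(picked["mid_exhale"] % 20 - 10), 1) <= 1
        assert picked["mid_inhale"] % 20 in (0, 1, 19)

    def test_constant_trajectory_rejected(self):
        n = 48
        seq = make_coordinate_sequence(n, 10)
        track = ut.LandmarkTrack(frame_index=np.arange(10),
                                 position_vox=[(24, 24, 24)] * 10,
                                 spacing_mm=(1, 1, 1))
        with pytest.raises(PhaseDetectionError):
            ut.select_references(track, seq, make_coordinate_encoder(n))

    def test_source_sequence_recorded(self):
        seq, track, encoder = self._sinusoid_world()
        refs = ut.select_references(track, seq, encoder)
        assert refs.source_sequence_id == "L2"

    def test_too_few_annotations(self):
        n = 48
        seq = make_coordinate_sequence(n, 4)
        track = ut.LandmarkTrack(frame_index=[0, 1, 2],
                                 position_vox=[(24, 24, 24), (24, 24, 26), (24, 24, 22)],
                                 spacing_mm=(1, 1, 1))
        with pytest.raises(PhaseDetectionError):
            ut.select_references(track, seq, make_coordinate_encoder(n))
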