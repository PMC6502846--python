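"""Detection by template matching, track linking, cropping, height traces."""

import numpy as np
import pytest

from mackinetics import (
    Detection,
    PoreGeometry,
    SyntheticConfig,
    count_pores,
    crop_track,
    detect_pores,
    height_trace,
    link_tracks,
    make_template,
    render_movie,
    simulate_assembly_events,
)
from mackinetics.movie import MovieStack
from mackinetics.tracking import CroppedSequence, PoreTrack, filter_tracks


def _embed(template, shape, top_left):
    frame = np.zeros(shape)
    r, c = top_left
    frame[r:r + template.shape[0], c:c + template.shape[1]] = template
    return frame


class TestDetect:
    def test_perfect_match_single_detection(self, geometry):
        template = make_template(geometry, 2.0)
        half = template.shape[0] // 2
        frame = _embed(template, (64, 64), (20, 31))
        dets = detect_pores(frame, template)
        assert len(dets) == 1
        assert dets[0].position == (20 + half, 31 + half)
        assert dets[0].score == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_produces_no_detections(self, geometry):
        """False-positive rate of the 0.6 threshold on membrane-level noise."""
        template = make_template(geometry, 2.0)
        rng = np.random.default_rng(42)
        hits = sum(
            len(detect_pores(rng.normal(0, 0.3, (128, 128)), template))
            for _ in range(100)
        )
        assert hits == 0

    def test_two_separated_pores_detected_at_centres(self, geometry):
        config = SyntheticConfig(
            n_complexes=2, noise_sd=0.0, t_max=13.0, seed=8, k_init=1e6, k_plus=1e6
        )
        trajectories = simulate_assembly_events(config, geometry)
        frame = render_movie(trajectories, geometry, config).frames[-1]
        template = make_template(geometry, config.pixel_size)
        dets = detect_pores(frame, template)
        assert len(dets) == 2
        truth = {
            tuple((np.asarray(t.position) / config.pixel_size).round().astype(int))
            for t in trajectories
        }
        for det in dets:
            assert min(
                np.hypot(det.row - r, det.col - c) for r, c in truth
            ) <= 1.0

    def test_template_larger_than_frame_raises(self, geometry):
        template = make_template(geometry, 2.0)
        with pytest.raises(ValueError):
            detect_pores(np.zeros((8, 8)), template)

    def test_border_exclusion(self, geometry):
        """No detection centre closer than half a template width to the edge."""
        template = make_template(geometry, 2.0)
        half = template.shape[0] // 2
        frame = np.zeros((64, 64))
        frame[:template.shape[0], :template.shape[1]] = template  # corner pore
        for det in detect_pores(frame, template):
            assert half <= det.row < 64 - half
            assert half <= det.col < 64 - half


class TestCounts:
    def test_background_movie_counts_zero(self, geometry):
        config = SyntheticConfig(n_complexes=0, noise_sd=0.0, t_max=32.5, seed=0)
        movie = render_movie([], geometry, config)
        template = make_template(geometry, config.pixel_size)
        assert np.all(count_pores(movie, template) == 0)

    def test_static_pores_count_constant(self, geometry):
        config = SyntheticConfig(
            n_complexes=4, noise_sd=0.0, t_max=32.5, seed=3, k_init=1e6, k_plus=1e6
        )
        trajectories = simulate_assembly_events(config, geometry)
        movie = render_movie(trajectories, geometry, config)
        template = make_template(geometry, config.pixel_size)
        counts = count_pores(movie, template)
        assert counts[0] == 0  # frame 0 is at t = 0, before any insertion
        assert np.all(counts[1:] == 4)

    def test_monotone_appearance_counts_non_decreasing(
        self, geometry, small_noiseless_movie
    ):
        config, _, movie = small_noiseless_movie
        template = make_template(geometry, config.pixel_size)
        counts = count_pores(movie, template)
        assert np.all(np.diff(counts) >= 0)


def _det(frame, row, col, score=0.9):
    return Detection(frame, row, col, score)


class TestLinking:
    def test_stationary_detection_single_track(self):
        frames = [[_det(k, 30, 40)] for k in range(10)]
        tracks = link_tracks(frames)
        assert len(tracks) == 1
        assert tracks[0].birth_frame == 0
        assert tracks[0].last_frame == 9
        assert tracks[0].pre_existing

    @pytest.mark.parametrize("gap,expected_tracks", [(3, 1), (4, 2)])
    def test_gap_closing_boundary(self, gap, expected_tracks):
        """Absent for max_gap frames -> same track; one more -> new track."""
        present = [0, 1, 2] + [3 + gap, 4 + gap]
        frames = [
            [_det(k, 30, 40)] if k in present else []
            for k in range(max(present) + 1)
        ]
        tracks = link_tracks(frames, max_gap_frames=3)
        assert len(tracks) == expected_tracks

    def test_distant_simultaneous_detections_unlinkable(self):
        frames = [[_det(k, 10, 10), _det(k, 10, 110)] for k in range(4)]
        tracks = link_tracks(frames, max_link_dist_px=30)
        assert len(tracks) == 2

    def test_every_detection_in_exactly_one_track(self, geometry):
        config = SyntheticConfig(
            n_complexes=6, noise_sd=0.2, t_max=325.0, seed=12, k_init=10.0
        )
        trajectories = simulate_assembly_events(config, geometry)
        movie = render_movie(trajectories, geometry, config)
        template = make_template(geometry, config.pixel_size)
        from mackinetics.detect import detect_movie

        per_frame = detect_movie(movie, template)
        tracks = link_tracks(per_frame)
        linked = [d for t in tracks for d in t.detections]
        flat = [d for frame in per_frame for d in frame]
        assert len(linked) == len(flat)
        assert set(map(id, linked)) == set(map(id, flat))

    def test_deterministic_assignment(self):
        frames = [
            [_det(0, 30, 40), _det(0, 35, 45)],
            [_det(1, 31, 41), _det(1, 34, 44)],
        ]
        a = link_tracks(frames)
        b = link_tracks(frames)
        assert [
            [d.position for d in t.detections] for t in a
        ] == [[d.position for d in t.detections] for t in b]

    def test_curation_drops_short_tracks(self):
        frames = [[_det(0, 10, 10)], [_det(1, 10, 10)], [], [], [_det(4, 60, 60)]]
        tracks = link_tracks(frames)
        assert len(filter_tracks(tracks, min_detections=2)) == 1


class TestCropAndTrace:
    def test_crop_side_from_radius(self, small_noiseless_movie):
        _, _, movie = small_noiseless_movie
        track = PoreTrack(0, [_det(k, 128, 128) for k in range(3, 10)])
        crop = crop_track(movie, track, radius_nm=25.0, pre_frames=2)
        assert crop.frames.shape[1:] == (25, 25)
        assert crop.start_frame == 1

    def test_birth_frame_zero_clamps(self, small_noiseless_movie):
        _, _, movie = small_noiseless_movie
        track = PoreTrack(0, [_det(0, 128, 128)])
        crop = crop_track(movie, track, pre_frames=5)
        assert crop.start_frame == 0

    def test_crop_contains_global_maximum(self, geometry, small_noiseless_movie):
        config, trajectories, movie = small_noiseless_movie
        done = next(t for t in trajectories if t.completed)
        r, c = (np.asarray(done.position) / config.pixel_size).round().astype(int)
        track = PoreTrack(0, [_det(movie.n_frames - 1, r, c)])
        crop = crop_track(movie, track, pre_frames=0)
        assert crop.frames[-1].max() == movie.frames[-1].max()

    def test_out_of_bounds_crop_padded_and_flagged(self, small_noiseless_movie):
        _, _, movie = small_noiseless_movie
        track = PoreTrack(0, [_det(0, 3, 3)])
        crop = crop_track(movie, track)
        assert crop.padded
        assert crop.frames.shape[1:] == (25, 25)

    def test_all_zero_crop_degenerate(self):
        crop = CroppedSequence(
            0, np.zeros((10, 25, 25), np.float32), np.arange(10) * 6.5, 0, (12, 12),
            False,
        )
        trace = height_trace(crop)
        assert trace.degenerate
        assert np.all(trace.mean_heights == 0)
        assert trace.normalized_heights is None

    def test_step_trace_amplitude_is_coverage_times_height(self):
        """Pore covering fraction f at height H appearing at frame k gives a
        step of amplitude f*H in the mean-height trace."""
        side, k, H = 25, 6, 10.0
        frames = np.zeros((15, side, side), np.float32)
        frames[k:, 5:12, 5:12] = H
        f = 7 * 7 / side**2
        trace = height_trace(
            CroppedSequence(0, frames, np.arange(15) * 6.5, 0, (12, 12), False)
        )
        assert np.allclose(trace.mean_heights[:k], 0)
        assert np.allclose(trace.mean_heights[k:], f * H)

    def test_normalized_trace_bounded(self, rng):
        frames = rng.normal(0.5, 0.05, (40, 25, 25)).astype(np.float32)
        frames[20:] += 1.0
        trace = height_trace(
            CroppedSequence(0, frames, np.arange(40) * 6.5, 0, (12, 12), False)
        )
        assert trace.normalized_heights.min() > -0.5
        assert trace.normalized_heights.max() < 1.5
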