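"""Generator tests: event statistics, rendering geometry, reproducibility."""

import numpy as np
import pytest

from mackinetics import (
    PoreGeometry,
    SyntheticConfig,
    make_template,
    render_movie,
    simulate_assembly_events,
)
from mackinetics.detect import _correlation_map
from mackinetics.synthetic import (
    InvalidParameterError,
    N_ADDITIONS,
    PlacementError,
    _render_feature,
    appearance_counts,
    trajectories_to_frame,
)


def _big_field_config(**kw):
    defaults = dict(
        n_complexes=10_000, k_init=1 / 912, k_plus=1e6, c9_conc=1.0,
        t_max=1e9, image_shape=(8192, 8192), noise_sd=0.0, seed=0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestEventSampling:
    def test_zero_initiation_rate_never_initiates(self):
        config = SyntheticConfig(n_complexes=20, k_init=0.0, t_max=1e6, seed=0)
        trajectories = simulate_assembly_events(config)
        assert all(not t.initiated for t in trajectories)

    def test_fast_propagation_completes_instantly(self):
        config = SyntheticConfig(
            n_complexes=20, k_init=10.0, k_plus=1e9, t_max=650.0, seed=0
        )
        for traj in simulate_assembly_events(config):
            assert traj.completed
            assert traj.completion_time < 1e-3

    def test_initiation_times_match_exponential_law(self):
        """Sample mean and variance of t_init vs the analytic exponential."""
        tau = 912.0
        trajectories = simulate_assembly_events(_big_field_config())
        t_init = np.array([t.t_init for t in trajectories])
        n = t_init.size
        se_mean = tau / np.sqrt(n)
        assert abs(t_init.mean() - tau) < 3 * se_mean
        # exponential variance tau^2; SE of sample variance ~ tau^2 sqrt(8/n)
        assert abs(t_init.var(ddof=1) - tau**2) < 3 * tau**2 * np.sqrt(8 / n)

    def test_completion_time_mean_matches_erlang(self):
        lam = 1 / 6.6
        config = _big_field_config(k_init=10.0, k_plus=lam)
        comp = np.array(
            [t.completion_time for t in simulate_assembly_events(config)]
        )
        expected = N_ADDITIONS / lam
        se = np.sqrt(N_ADDITIONS) / lam / np.sqrt(comp.size)
        assert abs(comp.mean() - expected) < 3 * se

    def test_event_times_strictly_increasing(self):
        config = SyntheticConfig(n_complexes=30, k_init=5.0, t_max=3250.0, seed=2)
        for traj in simulate_assembly_events(config):
            if traj.initiated and len(traj.t_additions):
                events = np.concatenate([[traj.t_init], traj.t_additions])
                assert np.all(np.diff(events) > 0)

    def test_same_seed_bit_identical(self):
        config = SyntheticConfig(n_complexes=10, seed=7, t_max=650.0)
        a = simulate_assembly_events(config)
        b = simulate_assembly_events(config)
        for ta, tb in zip(a, b):
            assert ta.position == tb.position
            assert ta.t_init == tb.t_init
            assert np.array_equal(ta.t_additions, tb.t_additions)
        movie_a = render_movie(a, PoreGeometry(), config)
        movie_b = render_movie(b, PoreGeometry(), config)
        assert np.array_equal(movie_a.frames, movie_b.frames)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(k_init=-1.0)
        with pytest.raises(InvalidParameterError):
            SyntheticConfig(c9_conc=0.0)

    def test_overcrowded_image_raises_placement_error(self):
        config = SyntheticConfig(n_complexes=100, image_shape=(48, 48), seed=0)
        with pytest.raises(PlacementError):
            simulate_assembly_events(config)

    def test_min_pairwise_separation_honoured(self, geometry):
        config = SyntheticConfig(n_complexes=30, seed=3)
        pos = np.array([t.position for t in simulate_assembly_events(config, geometry)])
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        template_nm = make_template(geometry, config.pixel_size).shape[0] * config.pixel_size
        assert d.min() >= template_nm


class TestRendering:
    def test_empty_noiseless_movie_is_all_zero(self, geometry):
        config = SyntheticConfig(n_complexes=0, noise_sd=0.0, t_max=32.5, seed=0)
        movie = render_movie([], geometry, config)
        assert np.all(movie.frames == 0)

    def test_completed_pore_max_is_ring_height(self, geometry, small_noiseless_movie):
        _, trajectories, movie = small_noiseless_movie
        assert any(t.completed for t in trajectories)
        assert movie.frames[-1].max() == pytest.approx(geometry.ring_height)

    def test_rendered_centroids_match_positions(self, geometry):
        """Centroid of each rendered complete ring within 0.5 px of truth."""
        config = SyntheticConfig(
            n_complexes=10, noise_sd=0.0, t_max=65.0, seed=4, k_init=1e4, k_plus=1e6
        )
        trajectories = simulate_assembly_events(config, geometry)
        frame = render_movie(trajectories, geometry, config).frames[-1]
        half = int(np.ceil(geometry.ring_outer_diameter / 2 / config.pixel_size)) + 1
        for traj in trajectories:
            assert traj.completed
            r, c = np.asarray(traj.position) / config.pixel_size
            ri, ci = int(round(r)), int(round(c))
            patch = frame[ri - half:ri + half + 1, ci - half:ci + half + 1]
            yy, xx = np.mgrid[ri - half:ri + half + 1, ci - half:ci + half + 1]
            w = patch / patch.sum()
            assert abs((yy * w).sum() - r) < 0.5
            assert abs((xx * w).sum() - c) < 0.5

    def test_arc_readout_non_decreasing(self, geometry, small_noiseless_movie):
        """Rendered arc pixel count for every pore never shrinks over time."""
        config, trajectories, movie = small_noiseless_movie
        half = int(geometry.ring_outer_diameter / config.pixel_size)
        for traj in trajectories:
            r, c = (np.asarray(traj.position) / config.pixel_size).round().astype(int)
            area = [
                (movie.frames[k, r - half:r + half + 1, c - half:c + half + 1]
                 > geometry.ring_height / 2).sum()
                for k in range(movie.n_frames)
            ]
            assert np.all(np.diff(area) >= 0)

    def test_oversized_geometry_raises(self):
        config = SyntheticConfig(n_complexes=0, image_shape=(16, 16), t_max=6.5)
        big = PoreGeometry(lumen_diameter=30, ring_outer_diameter=100)
        with pytest.raises(Exception):
            render_movie([], big, config)


class TestTemplate:
    def test_self_correlation_is_one(self, geometry):
        template = make_template(geometry, 2.0)
        frame = np.zeros((45, 45), dtype=float)
        frame[15:30, 15:30] = template
        corr = _correlation_map(frame, template)
        assert corr.max() == pytest.approx(1.0, abs=1e-6)

    def test_template_symmetric_without_stalk(self, geometry):
        template = make_template(geometry, 2.0)
        assert np.allclose(template, np.rot90(template, 2))

    def test_template_max_is_ring_height(self, geometry):
        assert make_template(geometry, 2.0).max() == pytest.approx(
            geometry.ring_height
        )

    def test_template_side_is_odd_and_covers_ring(self, geometry):
        template = make_template(geometry, 2.0)
        assert template.shape[0] % 2 == 1
        assert template.shape[0] >= geometry.ring_outer_diameter / 2.0 + 4


class TestGroundTruthTable:
    def test_event_table_round_trip(self):
        config = SyntheticConfig(n_complexes=8, k_init=5.0, t_max=650.0, seed=5)
        trajectories = simulate_assembly_events(config)
        df = trajectories_to_frame(trajectories)
        assert set(df.columns) == {"complex_id", "event_index", "time_s", "row_nm", "col_nm"}
        for traj in trajectories:
            if traj.initiated:
                sub = df[df.complex_id == traj.complex_id]
                assert sub.iloc[0].time_s == pytest.approx(traj.t_init)
                assert len(sub) == 1 + len(traj.t_additions)

    def test_appearance_counts_monotone_and_saturating(self):
        config = SyntheticConfig(n_complexes=40, k_init=5.0, t_max=3250.0, seed=6)
        trajectories = simulate_assembly_events(config)
        times = np.arange(0, 3250.0, 6.5)
        counts = appearance_counts(trajectories, times)
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] == sum(t.initiated for t in trajectories)
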