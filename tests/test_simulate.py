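"""Simulator: geometry, event statistics, rendering and dataset round-trips."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from cortexkymo.errors import InvalidGeometryError
from cortexkymo.simulate import (
    GroundTruthEvent,
    SimulationConfig,
    build_geometry,
    emit_dataset,
    load_dataset,
    render_movie,
    sample_events,
)


def union_area_oracle(R, r, d, step=0.01, extent=8.0):
    """Numeric integration of the union-of-disks indicator on a fine subgrid."""
    xs = np.arange(-R - 1, extent, step)
    ys = np.arange(-R - 1, R + 1, step)
    X, Y = np.meshgrid(xs, ys)
    inside = (X**2 + Y**2 <= R**2) | ((X - d) ** 2 + Y**2 <= r**2)
    return inside.sum() * step**2


class TestGeometry:
    def test_unbudded_cell_is_single_disk_without_landmarks(self):
        cfg = SimulationConfig(mother_radius=2.5, bud_radius=0.0, pixel_size=0.1)
        g = build_geometry(cfg)
        assert g.neck_landmarks is None
        area = g.mask.sum() * cfg.pixel_size**2
        assert area == pytest.approx(math.pi * 2.5**2, rel=0.02)
        assert set(g.boundary.region_labels) == {"whole"}

    def test_budded_mask_area_matches_union_of_disks(self):
        cfg = SimulationConfig(mother_radius=2.5, bud_radius=1.0, center_spacing=3.2, pixel_size=0.1)
        g = build_geometry(cfg)
        area = g.mask.sum() * cfg.pixel_size**2
        oracle = union_area_oracle(2.5, 1.0, 3.2)
        assert area == pytest.approx(oracle, rel=0.03)

    def test_pixel_size_changes_resolution_not_physical_boundary(self):
        fine = build_geometry(SimulationConfig(pixel_size=0.1, seed=0))
        coarse = build_geometry(SimulationConfig(pixel_size=0.2, seed=0))
        assert fine.mask.shape[0] == pytest.approx(2 * coarse.mask.shape[0], abs=2)
        # physical outline is resolution independent
        assert coarse.perimeter == pytest.approx(fine.perimeter, abs=0.2)
        d = np.linalg.norm(coarse.boundary.points[:, None] - fine.boundary.points[None], axis=2)
        assert d.min(axis=1).max() <= 0.2  # within 1 px at the coarse scale

    def test_bud_larger_than_mother_rejected(self):
        with pytest.raises(InvalidGeometryError):
            SimulationConfig(mother_radius=1.0, bud_radius=1.5)

    def test_neck_landmarks_lie_on_both_circles(self, budded_config, budded_geometry):
        cfg, g = budded_config, budded_geometry
        for p in g.neck_landmarks:
            assert np.linalg.norm(p - g.mother_center) == pytest.approx(cfg.mother_radius, abs=1e-9)
            assert np.linalg.norm(p - g.bud_center) == pytest.approx(cfg.bud_radius, abs=1e-9)

    def test_region_arcs_sum_to_perimeter(self, budded_geometry):
        g = budded_geometry
        total = g.region_perimeter("daughter") + g.region_perimeter("mother")
        assert total == pytest.approx(g.perimeter, abs=1e-9)


class TestEventSampling:
    def test_zero_rates_give_no_events(self, budded_geometry):
        cfg = budded_geometry.config.replace(event_rate_daughter=0.0, event_rate_mother=0.0)
        assert sample_events(cfg, budded_geometry) == []

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(event_rate_daughter=-0.1)

    def test_event_count_follows_poisson_mean(self):
        # lambda = rate * perimeter * duration; most seeds within 3 sqrt(lambda)
        cfg = SimulationConfig(event_rate_daughter=0.02, event_rate_mother=0.02, n_frames=400)
        g = build_geometry(cfg)
        lam = 0.02 * g.perimeter * 400.0
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            n = len(sample_events(cfg.replace(seed=s), g))
            hits += abs(n - lam) <= 3 * math.sqrt(lam)
        assert hits >= int(0.9 * n_seeds)

    def test_region_rate_ratio_recovered_in_the_large_sample_limit(self):
        cfg = SimulationConfig(event_rate_daughter=0.02, event_rate_mother=0.004, n_frames=1000)
        g = build_geometry(cfg)
        nd = nm = 0
        for s in range(20):
            for ev in sample_events(cfg.replace(seed=s), g):
                if ev.region == "daughter":
                    nd += 1
                else:
                    nm += 1
        assert nd + nm >= 2000
        expected = (0.02 * g.region_perimeter("daughter")) / (0.004 * g.region_perimeter("mother"))
        assert nd / nm == pytest.approx(expected, rel=0.15)

    def test_lifetime_sample_mean_converges(self):
        cfg = SimulationConfig(event_rate_daughter=0.1, event_rate_mother=0.1, n_frames=700,
                               lifetime_mean=30.0, lifetime_cv=0.3, seed=5)
        g = build_geometry(cfg)
        lifetimes = [ev.lifetime for ev in sample_events(cfg, g)]
        assert len(lifetimes) >= 1000
        assert np.mean(lifetimes) == pytest.approx(30.0, rel=0.05)

    def test_arc_positions_fall_in_the_labeled_region(self, budded_config, budded_geometry):
        cfg = budded_config.replace(event_rate_daughter=0.05, event_rate_mother=0.05, n_frames=200)
        b = budded_geometry.boundary
        for ev in sample_events(cfg, budded_geometry):
            i = int(ev.arc_position // b.arc_step) % len(b)  # each point owns one arc step
            assert b.region_labels[i] == ev.region
            assert 0.0 <= ev.arc_position < budded_geometry.perimeter


def _noise_off(cfg):
    return cfg.replace(shot_noise=False, read_noise_sd=0.0)


class TestRendering:
    def test_blank_scene_renders_the_camera_offset_exactly(self):
        cfg = _noise_off(SimulationConfig(n_frames=3, diffuse_density=0.0,
                                          event_rate_daughter=0.0, event_rate_mother=0.0))
        g = build_geometry(cfg)
        movie, _ = render_movie(g, [], cfg)
        assert np.all(movie.data == cfg.camera_offset)

    def test_single_event_conserves_photons(self):
        cfg = _noise_off(SimulationConfig(n_frames=3, diffuse_density=0.0))
        g = build_geometry(cfg)
        ev = GroundTruthEvent(0, "mother", g.perimeter * 0.5, 0.0, 10.0, 80.0, 0.0)
        movie, _ = render_movie(g, [ev], cfg)
        sigma_px = cfg.psf_sigma / cfg.pixel_size
        expected = 80.0 * 2 * math.pi * sigma_px**2
        for t in range(3):
            total = (movie.data[0, t] - cfg.camera_offset).sum()
            assert total == pytest.approx(expected, rel=0.01)

    def test_prenoise_photon_budget_includes_diffuse_and_events(self):
        cfg = _noise_off(SimulationConfig(n_frames=2, diffuse_density=50.0))
        g = build_geometry(cfg)
        ev = GroundTruthEvent(0, "daughter", 0.1, 0.0, 10.0, 120.0, 0.0)
        movie, _ = render_movie(g, [ev], cfg)
        sigma_px = cfg.psf_sigma / cfg.pixel_size
        psf_norm = 2 * math.pi * sigma_px**2
        diffuse_budget = 50.0 * g.boundary.arc_step * len(g.boundary) * psf_norm
        total = (movie.data[0, 0] - cfg.camera_offset).sum()
        assert total == pytest.approx(diffuse_budget + 120.0 * psf_norm, rel=0.01)

    def test_same_seed_renders_bit_identical_movies(self, budded_config, budded_geometry):
        cfg = budded_config
        events = sample_events(cfg, budded_geometry)
        m1, _ = render_movie(budded_geometry, events, cfg)
        m2, _ = render_movie(budded_geometry, events, cfg)
        assert np.array_equal(m1.data, m2.data)

    def test_internalizing_event_moves_inward_at_end_of_life(self):
        cfg = _noise_off(SimulationConfig(n_frames=12, diffuse_density=0.0, internalization_depth=0.3))
        g = build_geometry(cfg)
        ev = GroundTruthEvent(0, "mother", g.perimeter * 0.5, 2.0, 10.0, 100.0, 0.3)
        movie, _ = render_movie(g, [ev], cfg)
        p0 = np.array(np.unravel_index(np.argmax(movie.data[0, 3]), movie.data[0, 3].shape))
        p_end = np.array(np.unravel_index(np.argmax(movie.data[0, 9]), movie.data[0, 9].shape))
        shift = np.linalg.norm(p_end - p0) * cfg.pixel_size
        assert 0.15 <= shift <= 0.45


class TestDataset:
    def test_round_trip_reproduces_arrays_and_counts(self, tmp_path):
        cfg = SimulationConfig(n_frames=8, n_channels=2, seed=3)
        out = emit_dataset(cfg, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        quantized = np.clip(np.rint(out["movie"].data), 0, 65535).astype(np.uint16)
        assert np.array_equal(back["movie"].data, quantized)
        assert np.array_equal(back["mask"], out["geometry"].mask)
        assert len(back["truth"]) == len(out["truth"])
        assert back["movie"].data.shape[0] == 2
        assert back["movie"].data[0].shape == back["movie"].data[1].shape
        pd.testing.assert_frame_equal(back["truth"], out["truth"])

    def test_two_channel_coupling_duplicates_a_fraction_of_events(self):
        cfg = SimulationConfig(n_frames=300, n_channels=2, channel2_fraction=0.5,
                               event_rate_daughter=0.02, event_rate_mother=0.02, seed=9)
        g = build_geometry(cfg)
        events = sample_events(cfg, g)
        _, truth = render_movie(g, events, cfg)
        n1 = (truth["channel"] == 0).sum()
        n2 = (truth["channel"] == 1).sum()
        assert n1 >= 50
        assert n2 / n1 == pytest.approx(0.5, abs=0.15)
        # channel-2 events are re-renders of channel-1 events, time shifted
        ch2 = truth[truth["channel"] == 1]
        ch1 = truth.set_index("event_id")
        for _, r in ch2.iterrows():
            parent = ch1.loc[r["event_id"]]
            parent = parent[parent["channel"] == 0] if isinstance(parent, pd.DataFrame) else parent
            assert float(np.atleast_1d(parent["arc_position_um"])[0]) == r["arc_position_um"]
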