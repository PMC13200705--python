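"""Spot detection, greedy linking vs. assignment oracle, lifetimes, coincidence."""

import itertools

import numpy as np
import pytest

from cortexkymo.events import (
    Detection,
    EventTrack,
    coincidence_fraction,
    compute_lifetimes,
    detect_movie,
    detect_puncta,
    link_tracks,
)
from cortexkymo.experiments import (
    _truth_frame_positions,
    coincidence_experiment,
    event_movie_config,
    run_lifetime_condition,
)
from cortexkymo.simulate import build_geometry, render_movie, sample_events


def render_spot(shape, x, y, amp, sigma_px):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2))


class TestDetectPuncta:
    def test_flat_frame_yields_nothing(self):
        assert detect_puncta(np.full((40, 40), 5.0), psf_sigma=0.15, pixel_size=0.1) == []

    def test_single_spot_localized_to_half_pixel(self):
        img = 10.0 + render_spot((60, 60), x=20.0, y=30.0, amp=50.0, sigma_px=1.5)
        dets = detect_puncta(img, psf_sigma=0.15, pixel_size=0.1)
        assert len(dets) == 1
        assert dets[0].x / 0.1 == pytest.approx(20.0, abs=0.5)
        assert dets[0].y / 0.1 == pytest.approx(30.0, abs=0.5)

    def test_non_positive_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_puncta(np.zeros((10, 10)), psf_sigma=0.0, pixel_size=0.1)

    def test_recall_and_precision_on_simulated_frames(self):
        # default diffuse band, puncta at peak SNR ~ 8 over the camera background
        cfg = event_movie_config(20.0, seed=1).replace(n_frames=100, diffuse_density=30.0)
        g = build_geometry(cfg)
        movie, truth = render_movie(g, sample_events(cfg, g), cfg)
        dets = detect_movie(movie.channel(0), cfg.psf_sigma, cfg.pixel_size)
        tp = fp = n_truth = 0
        for t in range(cfg.n_frames):
            pos = _truth_frame_positions(g, truth, t, cfg.frame_interval)
            n_truth += len(pos)
            used = set()
            for d in [x for x in dets if x.frame == t]:
                if len(pos):
                    dist = np.hypot(pos[:, 0] - d.x, pos[:, 1] - d.y)
                    j = int(np.argmin(dist))
                    if dist[j] <= 2 * cfg.pixel_size and j not in used:
                        tp += 1
                        used.add(j)
                        continue
                fp += 1
        assert n_truth > 50
        assert tp / n_truth >= 0.9  # recall
        assert tp / (tp + fp) >= 0.9  # precision


class TestKymographMode:
    def test_event_tracked_in_1d_along_the_arc(self):
        from cortexkymo.events import detect_kymograph
        from cortexkymo.kymo import circumferential_kymograph
        from cortexkymo.simulate import GroundTruthEvent, SimulationConfig

        cfg = SimulationConfig(n_frames=20, diffuse_density=0.0, shot_noise=False,
                               read_noise_sd=0.0, internalization_depth=0.0)
        g = build_geometry(cfg)
        s0 = g.perimeter * 0.4
        ev = GroundTruthEvent(0, "mother", s0, 3.0, 15.0, 100.0, 0.0)
        movie, _ = render_movie(g, [ev], cfg)
        k = circumferential_kymograph(movie, g.boundary)
        dets = detect_kymograph(k.values, cfg.psf_sigma, k.arc_step)
        tracks = link_tracks(dets, max_disp=0.3, max_gap=1, min_frames=3)
        assert len(tracks) == 1
        assert tracks[0].first_frame == 3
        assert tracks[0].last_frame == 14
        assert tracks[0].mean_position()[0] == pytest.approx(s0, abs=2 * k.arc_step)


def det(frame, x, y, amp=10.0):
    return Detection(frame=frame, x=x, y=y, amplitude=amp, snr=10.0)


def brute_force_linking(detections, max_disp, max_gap):
    """Exhaustive minimal-total-distance frame-to-frame assignment (tiny inputs)."""
    by_frame: dict[int, list] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    tracks: list[list] = []
    open_tracks: list[list] = []
    for f in sorted(by_frame):
        open_tracks = [t for t in open_tracks if f - t[-1].frame <= max_gap + 1]
        dets = by_frame[f]
        best, best_cost = None, np.inf
        for k in range(min(len(open_tracks), len(dets)), -1, -1):
            for tr_sel in itertools.permutations(range(len(open_tracks)), k):
                for de_sel in itertools.combinations(range(len(dets)), k):
                    cost = 0.0
                    ok = True
                    for ti, di in zip(tr_sel, de_sel):
                        last = open_tracks[ti][-1]
                        dd = np.hypot(dets[di].x - last.x, dets[di].y - last.y)
                        if dd > max_disp:
                            ok = False
                            break
                        cost += dd
                    if ok and (best is None or k > len(best[0]) or (k == len(best[0]) and cost < best_cost)):
                        best, best_cost = (tr_sel, de_sel), cost
            if best is not None:
                break
        assigned = set()
        if best is not None:
            for ti, di in zip(*best):
                open_tracks[ti].append(dets[di])
                assigned.add(di)
        for di, d in enumerate(dets):
            if di not in assigned:
                t = [d]
                tracks.append(t)
                open_tracks.append(t)
    return tracks


class TestLinkTracks:
    def test_stationary_spot_forms_one_track(self):
        dets = [det(f, 1.0, 1.0) for f in range(3, 13)]
        tracks = link_tracks(dets, max_disp=0.4, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].first_frame == 3
        assert tracks[0].last_frame == 12

    def test_distant_spots_never_merge(self):
        dets = []
        for f in range(5):
            dets += [det(f, 0.0, 0.0), det(f, 2.0, 0.0)]  # 20 px apart at 0.1 µm/px
        tracks = link_tracks(dets, max_disp=0.5, max_gap=1)
        assert len(tracks) == 2
        assert all(len(t.detections) == 5 for t in tracks)

    def test_single_frame_gap_is_bridged_and_matches_assignment_oracle(self):
        frames = [0, 1, 2, 4, 5]  # missing frame 3
        dets = [det(f, 1.0, 1.0) for f in frames]
        tracks = link_tracks(dets, max_disp=0.4, max_gap=1)
        assert len(tracks) == 1
        oracle = brute_force_linking(dets, max_disp=0.4, max_gap=1)
        assert len(oracle) == len(tracks)
        assert [d.frame for d in tracks[0].detections] == [d.frame for d in oracle[0]]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_sparse_random_instances_match_assignment_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dets = []
        for f in range(6):
            for _ in range(rng.integers(0, 3)):
                dets.append(det(f, float(rng.uniform(0, 3)), float(rng.uniform(0, 3))))
        greedy = link_tracks(dets, max_disp=0.3, max_gap=1)
        oracle = brute_force_linking(dets, max_disp=0.3, max_gap=1)
        assert len(greedy) == len(oracle)
        assert sum(len(t.detections) for t in greedy) == len(dets)

    def test_every_detection_used_at_most_once(self, rng):
        dets = [det(int(f), float(x), float(y))
                for f, x, y in zip(rng.integers(0, 10, 60), rng.uniform(0, 2, 60), rng.uniform(0, 2, 60))]
        tracks = link_tracks(dets, max_disp=0.5, max_gap=1)
        ids = [id(d) for t in tracks for d in t.detections]
        assert len(ids) == len(set(ids))
        assert len(ids) <= len(dets)


class TestComputeLifetimes:
    def test_lifetime_counts_both_endpoints(self):
        tr = EventTrack(0, [det(f, 1.0, 1.0) for f in range(5, 15)])
        table = compute_lifetimes([tr], frame_interval=2.0, n_frames=100)
        assert table.iloc[0]["lifetime_s"] == 20.0

    def test_movie_edge_tracks_are_censored_and_excluded(self):
        first = EventTrack(0, [det(f, 1.0, 1.0) for f in range(0, 5)])
        last = EventTrack(1, [det(f, 1.0, 1.0) for f in range(95, 100)])
        interior = EventTrack(2, [det(f, 1.0, 1.0) for f in range(40, 50)])
        table = compute_lifetimes([first, last, interior], 1.0, 100)
        assert list(table["track_id"]) == [2]
        kept = compute_lifetimes([first, last, interior], 1.0, 100, censor_policy="keep")
        assert kept["censored"].tolist() == [True, True, False]

    def test_invalid_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            compute_lifetimes([], 0.0, 10)

    def test_full_pipeline_recovers_simulated_mean_lifetime(self):
        res = run_lifetime_condition(30.0, 120, seed=4)
        assert res["estimated_mean_s"] == pytest.approx(30.0, abs=3.0)
        assert res["recall"] >= 0.9

    def test_estimated_means_preserve_true_lifetime_ordering(self):
        means = [run_lifetime_condition(m, 60, seed=8)["estimated_mean_s"] for m in (10.0, 20.0, 40.0)]
        assert means[0] < means[1] < means[2]


class TestCoincidence:
    def _track(self, tid, frames, x=1.0):
        return EventTrack(tid, [det(f, x, 1.0) for f in frames])

    def test_identical_sets_fully_coincide(self):
        a = [self._track(0, range(5)), self._track(1, range(10, 15), x=3.0)]
        frac, pairs = coincidence_fraction(a, a, dist_thresh=0.1, min_overlap=2)
        assert frac == 1.0
        assert len(pairs) == 2

    def test_temporally_disjoint_sets_do_not_coincide(self):
        a = [self._track(0, range(0, 5))]
        b = [self._track(1, range(10, 15))]
        assert coincidence_fraction(a, b, 0.1, 2)[0] == 0.0

    def test_each_track_matches_at_most_once(self):
        a = [self._track(0, range(5)), self._track(1, range(5))]
        b = [self._track(9, range(5))]
        frac, pairs = coincidence_fraction(a, b, dist_thresh=0.1, min_overlap=2)
        assert len(pairs) == 1
        assert frac == 0.5

    def test_simulated_half_coupling_recovered(self):
        res = coincidence_experiment(seed=1)
        assert res["n_tracks_a"] >= 50
        assert res["fraction"] == pytest.approx(0.5, abs=0.1)
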