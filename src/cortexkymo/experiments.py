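"""Reusable synthetic experiments: parameter-recovery studies on simulated movies.

Each function runs the real pipeline stages (render → detect → link →
lifetimes, or render → project → trace → average → ANOVA) on simulator
output and returns the recovered quantities next to the ground truth.  They
are the engine behind the numbered analysis drivers, the validation tests
and the acceptance script.

Study conditions (chosen once; see docs/methods.md):

* Event movies image one medium-budded cell (mother 2.0 µm, bud 1.0 µm,
  0.1 µm/px) for 300 frames at Δt = 1 s, puncta at peak SNR ≈ 8 over the
  camera background, and an active-site density of ~0.1 events per µm of
  outline — sparse enough that nearest-neighbor linking is well posed.
  Event counts are reached by pooling several cells per condition, as
  lifetime datasets pool events across many cells.
* Profile cohorts image small cells (mother 1.8 µm, 0.12 µm/px, 6 frames)
  with a bright diffuse cortex band and no puncta; bud size varies across
  cells.  The replicated power/type-I studies redraw all noise per cell and
  per replicate but reuse the deterministic noise-free photon image per
  distinct geometry, which is a pure function of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary import REGION_DAUGHTER, REGION_MOTHER, Boundary
from .events import detect_movie, link_tracks, assign_regions, compute_lifetimes
from .kymo import circumferential_kymograph, circumferential_kymograph_naive, max_project_time
from .movie import Movie
from .profiles import average_profiles, cortex_trace, polarization_metrics, resample_profiles, _interior_mask
from .simulate import Geometry, SimulationConfig, build_geometry, render_movie, sample_events
from .stats import one_way_anova

__all__ = [
    "event_movie_config",
    "profile_cohort_config",
    "run_lifetime_condition",
    "lifetime_recovery_experiment",
    "lifetime_ordering_experiment",
    "ProfileCohortSimulator",
    "recruitment_separation_experiment",
    "polarization_recovery_experiment",
    "tip_profile_experiment",
    "kymograph_oracle_check",
    "coincidence_experiment",
]

ACTIVE_SITE_DENSITY = 0.1  # simultaneous events per µm of outline


def event_movie_config(lifetime_mean: float, seed: int, *, lifetime_cv: float = 0.3,
                       n_frames: int = 300, frame_interval: float = 1.0) -> SimulationConfig:
    """One-cell event-movie condition at fixed active-site density and SNR ≈ 8."""
    rate = ACTIVE_SITE_DENSITY / lifetime_mean
    return SimulationConfig(
        mother_radius=2.0,
        bud_radius=1.0,
        pixel_size=0.1,
        frame_interval=frame_interval,
        n_frames=n_frames,
        event_rate_daughter=rate,
        event_rate_mother=rate,
        lifetime_mean=lifetime_mean,
        lifetime_cv=lifetime_cv,
        punctum_amplitude=100.0,
        diffuse_density=60.0,
        read_noise_sd=5.0,
        camera_offset=100.0,
        seed=seed,
    )


def _truth_frame_positions(geometry: Geometry, truth: pd.DataFrame, t: int, dt: float) -> np.ndarray:
    """Ground-truth (x, y) of every event active in frame t, with internalization."""
    tsec = t * dt
    rows = truth[(truth["birth_s"] <= tsec) & (tsec < truth["death_s"])]
    out = []
    for _, r in rows.iterrows():
        p = geometry.position_at_arc(r["arc_position_um"])
        tau = r["death_s"] - tsec
        depth = r["internalization_depth_um"] if tau <= dt else (
            0.5 * r["internalization_depth_um"] if tau <= 2 * dt else 0.0
        )
        if depth:
            p = p + depth * geometry.inward_at_arc(r["arc_position_um"])
        out.append(p)
    return np.array(out) if out else np.empty((0, 2))


def _truth_frame_span(truth_row, dt: float, n_frames: int) -> tuple[int, int]:
    """First/last movie frame in which an event is rendered."""
    f0 = int(np.ceil(truth_row["birth_s"] / dt - 1e-9))
    f1 = int(np.ceil(truth_row["death_s"] / dt - 1e-9)) - 1
    return max(f0, 0), min(f1, n_frames - 1)


def match_tracks_to_truth(tracks, truth: pd.DataFrame, geometry: Geometry, dt: float,
                          n_frames: int, dist: float = 0.3):
    """Greedy one-to-one matching of tracks to ground-truth events.

    A track matches an event when their frame spans overlap and the track's
    detections lie within ``dist`` (µm) of the event position in at least
    half of the overlapping frames.  Returns (matched flags per truth row,
    matched track ids).
    """
    matched = np.zeros(len(truth), dtype=bool)
    used: set[int] = set()
    positions = {i: geometry.position_at_arc(r["arc_position_um"]) for i, (_, r) in enumerate(truth.iterrows())}
    spans = [ _truth_frame_span(r, dt, n_frames) for _, r in truth.iterrows() ]
    for i, (_, r) in enumerate(truth.iterrows()):
        f0, f1 = spans[i]
        if f1 < f0:
            continue
        best, best_score = None, 0
        for tr in tracks:
            if tr.track_id in used:
                continue
            score = 0
            overlap = 0
            for d in tr.detections:
                if f0 <= d.frame <= f1:
                    overlap += 1
                    if np.hypot(d.x - positions[i][0], d.y - positions[i][1]) <= dist:
                        score += 1
            if overlap and score >= max(1, overlap // 2) and score > best_score:
                best, best_score = tr, score
        if best is not None:
            matched[i] = True
            used.add(best.track_id)
    return matched, used


def run_lifetime_condition(lifetime_mean: float, target_events: int, seed: int, *,
                           lifetime_cv: float = 0.3, frame_interval: float = 1.0,
                           n_frames: int = 300, k_threshold: float = 5.0,
                           max_disp: float = 0.4, max_gap: int = 1, min_frames: int = 3) -> dict:
    """Pool simulated cells until ~target_events events, run detect→link→lifetime.

    Returns the recovered lifetime table plus truth bookkeeping (detection
    recall over uncensored events, number of cells pooled).
    """
    base = event_movie_config(lifetime_mean, seed, lifetime_cv=lifetime_cv,
                              n_frames=n_frames, frame_interval=frame_interval)
    geometry = build_geometry(base)
    per_movie = (base.event_rate_daughter * geometry.region_perimeter(REGION_DAUGHTER)
                 + base.event_rate_mother * geometry.region_perimeter(REGION_MOTHER)
                 ) * base.n_frames * base.frame_interval
    n_movies = max(1, int(np.ceil(target_events / per_movie)))
    lifetimes, n_truth_unc, n_matched, n_events = [], 0, 0, 0
    for m in range(n_movies):
        cfg = base.replace(seed=int(np.random.default_rng([seed, 10 + m]).integers(2**31)))
        events = sample_events(cfg, geometry)
        movie, truth = render_movie(geometry, events, cfg)
        dets = detect_movie(movie.channel(0), cfg.psf_sigma, cfg.pixel_size, k_threshold)
        tracks = link_tracks(dets, max_disp=max_disp, max_gap=max_gap, min_frames=min_frames)
        assign_regions(tracks, geometry.boundary)
        table = compute_lifetimes(tracks, cfg.frame_interval, cfg.n_frames, cell_id=m + 1)
        lifetimes.append(table)
        n_events += len(truth)
        spans = [_truth_frame_span(r, cfg.frame_interval, cfg.n_frames) for _, r in truth.iterrows()]
        unc = truth[[f0 >= 1 and f1 <= cfg.n_frames - 2 and f1 >= f0 for f0, f1 in spans]]
        matched, _ = match_tracks_to_truth(tracks, unc, geometry, cfg.frame_interval, cfg.n_frames)
        n_truth_unc += len(unc)
        n_matched += int(matched.sum())
    table = pd.concat(lifetimes, ignore_index=True)
    return {
        "lifetimes": table,
        "estimated_mean_s": float(table["lifetime_s"].mean()),
        "true_mean_s": lifetime_mean,
        "n_tracks": len(table),
        "n_events": n_events,
        "n_uncensored_truth": n_truth_unc,
        "recall": n_matched / n_truth_unc if n_truth_unc else float("nan"),
        "n_cells": n_movies,
    }


def lifetime_recovery_experiment(seed: int, target_events: int = 200,
                                 lifetime_mean: float = 30.0, lifetime_cv: float = 0.3) -> dict:
    """Recover a 30 s (CV 0.3) mean lifetime from ~200 pooled events at Δt = 1 s."""
    return run_lifetime_condition(lifetime_mean, target_events, seed, lifetime_cv=lifetime_cv)


def lifetime_ordering_experiment(seed: int, true_means=(10.0, 20.0, 40.0),
                                 target_events: int = 100) -> dict:
    """Three lifetime conditions; recovered means must preserve the true order."""
    results = [run_lifetime_condition(m, target_events, seed + k)
               for k, m in enumerate(true_means)]
    groups = {f"mean{int(m)}s": r["lifetimes"]["lifetime_s"].to_numpy()
              for m, r in zip(true_means, results)}
    anova = one_way_anova(groups)
    return {
        "true_means_s": list(true_means),
        "estimated_means_s": [r["estimated_mean_s"] for r in results],
        "n_per_condition": [r["n_tracks"] for r in results],
        "anova": anova,
        "conditions": results,
    }


# ---------------------------------------------------------------------------
# profile cohorts


def profile_cohort_config(diffuse_polarization: float, bud_radius: float, seed: int, *,
                          diffuse_profile: str = "flat", n_frames: int = 6) -> SimulationConfig:
    """Diffuse-signal-only small-cell condition for cortex-profile studies."""
    return SimulationConfig(
        mother_radius=1.8,
        bud_radius=bud_radius,
        pixel_size=0.12,
        frame_interval=1.0,
        n_frames=n_frames,
        event_rate_daughter=0.0,
        event_rate_mother=0.0,
        diffuse_density=600.0,
        diffuse_polarization=diffuse_polarization,
        diffuse_profile=diffuse_profile,
        read_noise_sd=5.0,
        camera_offset=100.0,
        margin=0.6,
        seed=seed,
    )


BUD_RADIUS_PANEL = (0.8, 0.9, 1.0, 1.1, 1.2)


class ProfileCohortSimulator:
    """Renders cohorts of diffuse-signal cells and measures cortex profiles.

    The noise-free photon image of each distinct (bud radius, polarization,
    profile shape) condition is deterministic, so it is computed once and
    cached; shot and read noise are redrawn independently for every cell of
    every replicate.
    """

    def __init__(self, band_halfwidth: float = 0.25):
        self.band_halfwidth = band_halfwidth
        self._cache: dict = {}

    def _condition(self, pol: float, bud_radius: float, profile: str):
        key = (pol, bud_radius, profile)
        if key not in self._cache:
            cfg = profile_cohort_config(pol, bud_radius, 0, diffuse_profile=profile)
            geometry = build_geometry(cfg)
            movie, _ = render_movie(geometry, [], cfg.replace(shot_noise=False, read_noise_sd=0.0))
            photons = movie.data[0, 0] - cfg.camera_offset  # noise-free photon image
            interior = _interior_mask(geometry.boundary, photons.shape, cfg.pixel_size,
                                      3.0 * self.band_halfwidth)
            self._cache[key] = (cfg, geometry, photons, interior)
        return self._cache[key]

    def render_cell(self, pol: float, bud_radius: float, rng: np.random.Generator,
                    profile: str = "flat", cell_id: int = 1):
        """One noisy cell: render, max-project, trace daughter (and mother) cortex."""
        cfg, geometry, photons, interior = self._condition(pol, bud_radius, profile)
        frames = rng.poisson(np.clip(photons, 0, None), size=(cfg.n_frames, *photons.shape)).astype(float)
        frames += cfg.camera_offset
        frames += rng.normal(0.0, cfg.read_noise_sd, size=frames.shape)
        proj = frames.max(axis=0)
        b = geometry.boundary
        b = Boundary(points=b.points, cell_id=cell_id, region_labels=b.region_labels)
        bg = float(np.median(proj[interior]))
        daughter = cortex_trace(proj, b, REGION_DAUGHTER, cfg.pixel_size,
                                band_halfwidth=self.band_halfwidth,
                                background="constant", background_value=bg)
        mother = cortex_trace(proj, b, REGION_MOTHER, cfg.pixel_size,
                              band_halfwidth=self.band_halfwidth,
                              background="constant", background_value=bg)
        return daughter, mother

    def cohort_daughter_means(self, pol: float, n_cells: int, rng: np.random.Generator,
                              profile: str = "flat") -> np.ndarray:
        """Per-cell mean daughter-cortex intensity for one condition.

        Bud size is drawn per cell, so cell-to-cell geometry variation enters
        the within-group variance like any other biological variability.
        """
        means = np.empty(n_cells)
        buds = rng.choice(BUD_RADIUS_PANEL, size=n_cells)
        for i in range(n_cells):
            d, _ = self.render_cell(pol, float(buds[i]), rng, profile=profile, cell_id=i + 1)
            means[i] = d.mean_intensity
        return means


def recruitment_separation_experiment(seed: int, *, effect: float = 0.30, n_cells: int = 30,
                                      n_power_reps: int = 100, n_null_reps: int = 1000,
                                      base_polarization: float = 3.0,
                                      alpha: float = 0.05) -> dict:
    """Power and type-I error of ANOVA on per-cell mean daughter-cortex intensity.

    Condition B's daughter diffuse density is ``effect`` lower than A's
    (polarization scaled by 1 − effect); the null renders both cohorts from
    condition A.  Every cell of every replicate gets fresh noise.
    """
    sim = ProfileCohortSimulator()
    rng = np.random.default_rng([21, seed])
    rejections = 0
    for _ in range(n_power_reps):
        a = sim.cohort_daughter_means(base_polarization, n_cells, rng)
        b = sim.cohort_daughter_means(base_polarization * (1.0 - effect), n_cells, rng)
        if one_way_anova({"a": a, "b": b}).p < alpha:
            rejections += 1
    power = rejections / n_power_reps
    rng = np.random.default_rng([22, seed])
    false_pos = 0
    for _ in range(n_null_reps):
        a = sim.cohort_daughter_means(base_polarization, n_cells, rng)
        b = sim.cohort_daughter_means(base_polarization, n_cells, rng)
        if one_way_anova({"a": a, "b": b}).p < alpha:
            false_pos += 1
    return {
        "power": power,
        "type1_rate": false_pos / n_null_reps,
        "n_cells": n_cells,
        "effect": effect,
        "n_power_reps": n_power_reps,
        "n_null_reps": n_null_reps,
    }


def polarization_recovery_experiment(seed: int, pol_values=(1.0, 2.0, 5.0),
                                     n_cells: int = 20) -> dict:
    """Recover the daughter:mother diffuse polarization ratio per condition."""
    sim = ProfileCohortSimulator()
    ratios = []
    for k, pol in enumerate(pol_values):
        rng = np.random.default_rng([31, seed, k])
        daughters, mothers = [], []
        for i in range(n_cells):
            bud = BUD_RADIUS_PANEL[i % len(BUD_RADIUS_PANEL)]
            d, m = sim.render_cell(pol, bud, rng, cell_id=i + 1)
            daughters.append(d)
            mothers.append(m)
        _, ratio = polarization_metrics(daughters, mothers)
        ratios.append(ratio)
    return {"true_ratios": list(pol_values), "recovered_ratios": ratios, "n_cells": n_cells}


def tip_profile_experiment(seed: int, n_cells: int = 15, polarization: float = 3.0) -> dict:
    """Tip-polarized diffuse signal: the averaged daughter profile peaks mid-trace."""
    sim = ProfileCohortSimulator()
    rng = np.random.default_rng([41, seed])
    profiles = []
    for i in range(n_cells):
        bud = BUD_RADIUS_PANEL[i % len(BUD_RADIUS_PANEL)]
        d, _ = sim.render_cell(polarization, bud, rng, profile="tip", cell_id=i + 1)
        profiles.append(d)
    band = average_profiles(resample_profiles(profiles))
    peak_rel = float(np.argmax(band.mean) / (len(band.mean) - 1))
    return {"band": band, "peak_rel_position": peak_rel, "n_cells": n_cells}


# ---------------------------------------------------------------------------
# oracle and coincidence checks


def _random_circle_boundary(rng: np.random.Generator, pixel_size: float = 0.1) -> Boundary:
    """A random circular outline fitting a 32×32 frame with band margin."""
    r = rng.uniform(0.55, 0.9)
    cx = 1.55 + rng.uniform(-0.2, 0.2)
    cy = 1.55 + rng.uniform(-0.2, 0.2)
    n = max(8, int(round(2 * np.pi * r / pixel_size)))
    th = rng.uniform(0, 2 * np.pi) + 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
    return Boundary(points=pts)


def kymograph_oracle_check(seed: int, n_instances: int = 20, reducer: str = "max") -> dict:
    """Vectorized vs. naive triple-loop kymograph on random small instances."""
    rng = np.random.default_rng([51, seed])
    max_abs_diff = 0.0
    for _ in range(n_instances):
        frames = rng.random((5, 32, 32)) * rng.uniform(10, 1000)
        movie = Movie(data=frames[None], pixel_size=0.1, frame_interval=1.0)
        b = _random_circle_boundary(rng)
        fast = circumferential_kymograph(movie, b).values
        slow = circumferential_kymograph_naive(movie, b, reducer=reducer)
        max_abs_diff = max(max_abs_diff, float(np.max(np.abs(fast - slow))))
    return {"n_instances": n_instances, "max_abs_diff": max_abs_diff}


def coincidence_experiment(seed: int, target_events: int = 120) -> dict:
    """Two-channel coupling: half of channel-1 events re-rendered in channel 2."""
    cfg = event_movie_config(20.0, seed).replace(
        n_channels=2, channel2_fraction=0.5, channel2_offset=0.0,
        event_rate_daughter=ACTIVE_SITE_DENSITY / 20.0, event_rate_mother=ACTIVE_SITE_DENSITY / 20.0,
    )
    geometry = build_geometry(cfg)
    per_movie = (cfg.event_rate_daughter + cfg.event_rate_mother) / 2 * geometry.perimeter \
        * cfg.n_frames * cfg.frame_interval * 2
    n_movies = max(1, int(np.ceil(target_events / per_movie)))
    n_a = 0
    n_pairs = 0
    for m in range(n_movies):
        c = cfg.replace(seed=int(np.random.default_rng([seed, 60 + m]).integers(2**31)))
        events = sample_events(c, geometry)
        movie, truth = render_movie(geometry, events, c)
        tracks = []
        for ch in range(2):
            dets = detect_movie(movie.channel(ch), c.psf_sigma, c.pixel_size)
            tracks.append(link_tracks(dets, min_frames=3))
        from .events import coincidence_fraction

        frac, pairs = coincidence_fraction(tracks[0], tracks[1], dist_thresh=0.3, min_overlap=2)
        n_a += len(tracks[0])
        n_pairs += len(pairs)
    return {"fraction": n_pairs / n_a if n_a else float("nan"),
            "true_fraction": cfg.channel2_fraction, "n_tracks_a": n_a}
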