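"""End-to-end pipeline: simulate/load -> boundary -> kymo -> events -> profiles -> stats.

Every stage writes its numeric artifacts (CSV + TIFF) under the output
directory and records them in a machine-readable manifest; identical
(config, seed) give identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import boundary as bnd
from . import events as ev
from . import kymo as ky
from . import profiles as pr
from . import stats as st
from .config import RunConfig
from .errors import CortexKymoError, PipelineError
from .movie import Movie, read_movie_tiffs
from .simulate import emit_dataset

log = logging.getLogger("cortexkymo")


def _stage(manifest: dict, name: str, t0: float) -> None:
    manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
    log.info("stage %s done in %.2fs", name, manifest["timings_s"][name])


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "timings_s": {}, "seed": config.seed}
    art = manifest["artifacts"]

    # --- acquire data -----------------------------------------------------
    t0 = time.perf_counter()
    landmarks = None
    if config.simulation is not None:
        sim_cfg = config.simulation.to_simulation_config(config.seed)
        ds = emit_dataset(sim_cfg, out_dir / "dataset")
        movie: Movie = ds["movie"]  # type: ignore[assignment]
        mask = ds["geometry"].mask  # type: ignore[union-attr]
        if ds["geometry"].neck_landmarks is not None:  # type: ignore[union-attr]
            landmarks = ds["geometry"].neck_landmarks  # type: ignore[union-attr]
        art["dataset"] = str(out_dir / "dataset")
    else:
        inp = config.inputs
        movie = read_movie_tiffs(inp.movie_paths, inp.pixel_size, inp.frame_interval)
        if inp.mask_path:
            mask = tifffile.imread(inp.mask_path)
        else:
            # no external segmentation: threshold the temporal median projection
            mask = bnd.segment_fallback(np.median(movie.channel(0), axis=0))
        if inp.landmarks_path:
            landmarks = pd.read_csv(inp.landmarks_path)[["x_um", "y_um"]].to_numpy(float)
    _stage(manifest, "acquire", t0)

    # --- boundary ---------------------------------------------------------
    t0 = time.perf_counter()
    cell_ids = sorted(int(c) for c in np.unique(mask) if c != 0)
    if not cell_ids:
        raise PipelineError("boundary", "no cells in mask (0 labels)")
    boundaries = []
    for cid in cell_ids:
        try:
            b = bnd.extract_boundary(mask, cid, movie.pixel_size)
            b = bnd.partition_regions(b, landmarks)
        except CortexKymoError as err:
            raise PipelineError("boundary", f"cell {cid}: {err}") from err
        boundaries.append(b)
    pd.concat([b.to_frame() for b in boundaries]).to_csv(out_dir / "boundaries.csv", index=False)
    art["boundaries"] = str(out_dir / "boundaries.csv")
    _stage(manifest, "boundary", t0)

    # --- kymographs and projections ---------------------------------------
    t0 = time.perf_counter()
    proj = ky.max_project_time(movie)
    tifffile.imwrite(out_dir / "max_projection.tif", proj.astype(np.float32), photometric="minisblack")
    art["max_projection"] = str(out_dir / "max_projection.tif")
    kymos = {}
    for b in boundaries:
        for c in range(movie.n_channels):
            try:
                k = ky.circumferential_kymograph(
                    movie, b, band_halfwidth=config.kymo.band_halfwidth, reducer=config.kymo.reducer, channel=c
                )
            except CortexKymoError as err:
                raise PipelineError("kymo", f"cell {b.cell_id}: {err}") from err
            stem = out_dir / f"kymograph_cell{b.cell_id}_ch{c + 1}"
            k.save(stem)
            kymos[(b.cell_id, c)] = k
            art[f"kymograph_cell{b.cell_id}_ch{c + 1}"] = str(stem.with_suffix(".tif"))
    _stage(manifest, "kymo", t0)

    # --- events: detect, link, lifetimes ----------------------------------
    t0 = time.perf_counter()
    ep = config.events
    lifetime_tables = []
    for b in boundaries:
        for c in range(movie.n_channels):
            dets = ev.detect_movie(movie.channel(c), ep.psf_sigma, movie.pixel_size, ep.k_threshold)
            tracks = ev.link_tracks(dets, max_disp=ep.max_disp, max_gap=ep.max_gap, min_frames=ep.min_frames)
            ev.assign_regions(tracks, b)
            for tr in tracks:
                tr.channel = c
            table = ev.compute_lifetimes(
                tracks, movie.frame_interval, movie.n_frames, censor_policy=ep.censor_policy, cell_id=b.cell_id
            )
            lifetime_tables.append(table)
    lifetime_columns = ["cell_id", "track_id", "region", "channel", "first_frame", "last_frame", "lifetime_s", "censored"]
    non_empty = [t for t in lifetime_tables if len(t)]
    lifetimes = (
        pd.concat(non_empty, ignore_index=True) if non_empty else pd.DataFrame(columns=lifetime_columns)
    )
    lifetimes.to_csv(out_dir / "lifetimes.csv", index=False)
    art["lifetimes"] = str(out_dir / "lifetimes.csv")
    _stage(manifest, "events", t0)

    # --- profiles ----------------------------------------------------------
    t0 = time.perf_counter()
    pp = config.profiles
    daughter_profiles, mother_profiles = [], []
    for b in boundaries:
        for region, bucket in (("daughter", daughter_profiles), ("mother", mother_profiles)):
            if (b.region_labels == region).any():
                bucket.append(
                    pr.cortex_trace(
                        proj[0], b, region, movie.pixel_size, band_halfwidth=pp.band_halfwidth, background=pp.background
                    )
                )
    per_cell, ratio = pr.polarization_metrics(daughter_profiles, mother_profiles)
    per_cell.to_csv(out_dir / "profile_means.csv", index=False)
    art["profile_means"] = str(out_dir / "profile_means.csv")
    if daughter_profiles:
        band = pr.average_profiles(pr.resample_profiles(daughter_profiles))
        band.to_frame().to_csv(out_dir / "daughter_profile_band.csv", index=False)
        art["daughter_profile_band"] = str(out_dir / "daughter_profile_band.csv")
    manifest["polarization_ratio"] = None if np.isnan(ratio) else ratio
    _stage(manifest, "profiles", t0)

    # --- stats --------------------------------------------------------------
    t0 = time.perf_counter()
    usable = lifetimes[~lifetimes["censored"].astype(bool)] if len(lifetimes) else lifetimes
    groups = {
        reg: grp["lifetime_s"].to_numpy()
        for reg, grp in (usable.groupby("region") if len(usable) else ())
        if len(grp) >= 2
    }
    if len(groups) >= 2:
        res = st.one_way_anova(groups)
        res.to_frame().to_csv(out_dir / "anova.csv", index=False)
        res.group_summary.to_csv(out_dir / "group_summary.csv", index=False)
        art["anova"] = str(out_dir / "anova.csv")
        art["group_summary"] = str(out_dir / "group_summary.csv")
    _stage(manifest, "stats", t0)

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
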