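#!/usr/bin/env python
"""Emit a reference synthetic dataset: one polarized medium-budded cell.

Writes the two-channel movie, label mask, neck landmarks, analytic boundary
and ground-truth event table under results/dataset/. Downstream drivers
(02-05) consume this dataset or regenerate their own conditions.
"""

from pathlib import Path

from cortexkymo.simulate import SimulationConfig, emit_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"

config = SimulationConfig(
    n_frames=180,
    event_rate_daughter=0.006,
    event_rate_mother=0.002,
    lifetime_mean={"daughter": 25.0, "mother": 40.0},
    lifetime_cv={"daughter": 0.3, "mother": 0.6},
    diffuse_density=60.0,
    diffuse_polarization=3.0,
    n_channels=2,
    channel2_fraction=0.5,
    channel2_offset=1.0,
    seed=1,
)

if __name__ == "__main__":
    paths = emit_dataset(config, OUT)
    truth = paths["truth"]
    print(f"wrote dataset to {OUT}")
    print(f"  {len(truth)} ground-truth events "
          f"({(truth['channel'] == 0).sum()} ch1, {(truth['channel'] == 1).sum()} ch2)")
    print(f"  movie: {paths['movie'].data.shape} (C, T, Y, X) at "
          f"{paths['movie'].pixel_size} um/px, dt = {paths['movie'].frame_interval} s")
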