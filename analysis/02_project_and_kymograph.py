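#!/usr/bin/env python
"""Projections, a montage and circumferential kymographs of the reference dataset.

Loads results/dataset/ (run 01_simulate_dataset.py first), traces the cell
outline from the mask, partitions it at the neck landmarks and writes, per
channel: the maximum-intensity projection, a 10-frame montage and the
circumferential kymograph (raw float TIFF + row/column CSV sidecars + PNG
preview).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile

from cortexkymo.boundary import extract_boundary, partition_regions
from cortexkymo.kymo import circumferential_kymograph, max_project_time, montage
from cortexkymo.simulate import load_dataset

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    ds = load_dataset(ROOT / "dataset")
    movie = ds["movie"]
    out = ROOT / "kymographs"
    out.mkdir(parents=True, exist_ok=True)

    b = extract_boundary(ds["mask"], 1, movie.pixel_size)
    b = partition_regions(b, ds.get("landmarks"))
    print(f"outline: {len(b)} points, perimeter {b.perimeter:.2f} um, "
          f"daughter arc {b.region_arc_length('daughter'):.2f} um")

    proj = max_project_time(movie)
    tifffile.imwrite(out / "max_projection.tif", proj.astype(np.float32), photometric="minisblack")

    for c in range(movie.n_channels):
        tile = montage(movie, frame_stride=movie.n_frames // 10 or 1, channel=c)
        tifffile.imwrite(out / f"montage_ch{c + 1}.tif", tile.astype(np.float32))
        k = circumferential_kymograph(movie, b, channel=c)
        k.save(out / f"kymograph_ch{c + 1}")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(k.to_display(), aspect="auto", cmap="magma",
                  extent=[0, k.times[-1], k.arc_positions[-1], 0])
        ax.set_xlabel("time (s)")
        ax.set_ylabel("arc position (um, origin = bud tip)")
        fig.tight_layout()
        fig.savefig(out / f"kymograph_ch{c + 1}.png", dpi=150)
        plt.close(fig)
        print(f"channel {c + 1}: kymograph {k.values.shape} (rows x frames), "
              f"peak row value {k.values.max():.0f} counts")
    print(f"wrote projections, montages and kymographs to {out}")
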