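"""In-memory container for calibrated fluorescence time-lapse movies.

A movie is a (channels, frames, rows, cols) array plus the two pieces of
physical calibration every downstream stage needs: the pixel size in
micrometres and the frame interval in seconds.  Pixel centres sit at integer
array indices, so the physical position of pixel (r, c) is
(x, y) = (c * pixel_size, r * pixel_size).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class Movie:
    """A 1- or 2-channel time-lapse stack with physical calibration.

    Attributes
    ----------
    data : ndarray, shape (C, T, Y, X)
        Intensity values. Float during simulation/analysis; uint16 on disk.
    pixel_size : float
        Lateral calibration, µm per pixel.
    frame_interval : float
        Time between consecutive frames, seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel convenience
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("movie data must be (C, T, Y, X) or (T, Y, X)")
        if 0 in self.data.shape:
            raise ValueError("movie has a zero-sized axis")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape (rows, cols)."""
        return self.data.shape[2], self.data.shape[3]

    def channel(self, c: int) -> np.ndarray:
        """Frames of one channel, shape (T, Y, X)."""
        return self.data[c]

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


def write_movie_tiffs(movie: Movie, out_dir: str | Path, stem: str = "movie") -> list[Path]:
    """Write one multi-page TIFF per channel; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(movie.n_channels):
        p = out_dir / f"{stem}_ch{c + 1}.tif"
        tifffile.imwrite(p, movie.data[c], photometric="minisblack")
        paths.append(p)
    return paths


def read_movie_tiffs(paths: list[str | Path], pixel_size: float, frame_interval: float) -> Movie:
    """Assemble a Movie from per-channel multi-page TIFFs."""
    stacks = [tifffile.imread(p) for p in paths]
    data = np.stack([s[None] if s.ndim == 2 else s for s in stacks])
    return Movie(data=data, pixel_size=pixel_size, frame_interval=frame_interval)
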