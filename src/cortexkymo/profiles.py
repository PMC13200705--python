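"""Cortex intensity line profiles: extraction, resampling, averaging, polarization.

A cortex profile is the background-subtracted intensity along one region of
the cell outline (typically the daughter arc, neck → tip → neck), measured
on a maximum-intensity projection of the movie.  Profiles from cells of
different bud sizes are compared by mapping each trace onto a common
relative arc coordinate in [0, 1] and interpolating all traces to the mean
trace length before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import binary_erosion
from skimage.draw import polygon
from skimage.morphology import disk

from .boundary import Boundary
from .kymo import sample_band

__all__ = [
    "CortexProfile",
    "ProfileBand",
    "cortex_trace",
    "resample_profiles",
    "average_profiles",
    "polarization_metrics",
]


@dataclass
class CortexProfile:
    """Background-subtracted cortex intensity along one region's arc."""

    cell_id: int
    region: str
    arc_positions: np.ndarray  # µm from the region start, strictly increasing
    intensities: np.ndarray  # counts above the interior background
    background: float = 0.0  # the subtracted per-cell background level

    def __post_init__(self) -> None:
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.arc_positions) != len(self.intensities):
            raise ValueError("arc_positions and intensities length mismatch")
        if len(self.arc_positions) > 1 and not np.all(np.diff(self.arc_positions) > 0):
            raise ValueError("arc_positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensities))


@dataclass
class ProfileBand:
    """Position-wise mean profile with a t-based 95% confidence band."""

    mean: np.ndarray
    ci_halfwidth: np.ndarray  # NaN when undefined (single profile)
    n: int
    ci_defined: bool

    def to_frame(self) -> pd.DataFrame:
        x = np.linspace(0.0, 1.0, len(self.mean))
        return pd.DataFrame({"rel_arc": x, "mean": self.mean, "ci95_halfwidth": self.ci_halfwidth})


def _interior_mask(boundary: Boundary, shape: tuple[int, int], pixel_size: float, erosion_um: float) -> np.ndarray:
    """Rasterize the cell interior from the outline and erode it."""
    rr, cc = polygon(boundary.points[:, 1] / pixel_size, boundary.points[:, 0] / pixel_size, shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    radius = max(1, int(round(erosion_um / pixel_size)))
    return binary_erosion(mask, structure=disk(radius))


def cortex_trace(
    projection: np.ndarray,
    boundary: Boundary,
    region: str,
    pixel_size: float,
    band_halfwidth: float = 0.25,
    background: str = "interior_median",
    background_value: float | None = None,
) -> CortexProfile:
    """Extract one region's cortex profile from a maximum-intensity projection.

    Per boundary point the intensity is the max over the normal band (same
    sampling as the kymograph); the per-cell background is the median over
    the cell interior eroded by 3 × band_halfwidth (``"interior_median"``),
    a caller-provided constant (``"constant"``), or zero (``"none"``).
    """
    if not (boundary.region_labels == region).any():
        raise ValueError(f"boundary of cell {boundary.cell_id} has no region {region!r}")
    band = sample_band(projection, boundary, pixel_size, band_halfwidth, reducer="max")
    if background == "interior_median":
        interior = _interior_mask(boundary, projection.shape, pixel_size, 3.0 * band_halfwidth)
        bg = float(np.median(projection[interior])) if interior.any() else 0.0
    elif background == "constant":
        bg = float(background_value or 0.0)
    elif background == "none":
        bg = 0.0
    else:
        raise ValueError("background must be 'interior_median', 'constant' or 'none'")
    idx = boundary.region_indices(region)
    arc = np.arange(len(idx)) * boundary.arc_step
    return CortexProfile(
        cell_id=boundary.cell_id,
        region=region,
        arc_positions=arc,
        intensities=band[idx] - bg,
        background=bg,
    )


def resample_profiles(profiles: list[CortexProfile]) -> np.ndarray:
    """Interpolate all profiles to the mean trace length on relative arc [0, 1].

    Returns a (n_profiles, N) matrix with N = round(mean of trace lengths).
    Endpoints are preserved exactly by linear interpolation.
    """
    if not profiles:
        raise ValueError("no profiles to resample")
    regions = {p.region for p in profiles}
    if len(regions) > 1:
        raise ValueError(f"profiles mix regions {sorted(regions)}")
    N = max(2, int(round(np.mean([p.n_samples for p in profiles]))))
    xq = np.linspace(0.0, 1.0, N)
    out = np.empty((len(profiles), N))
    for i, p in enumerate(profiles):
        if p.n_samples == 1:
            out[i] = p.intensities[0]
            continue
        x = (p.arc_positions - p.arc_positions[0]) / (p.arc_positions[-1] - p.arc_positions[0])
        out[i] = np.interp(xq, x, p.intensities)
    return out


def average_profiles(matrix: np.ndarray) -> ProfileBand:
    """Position-wise mean and t-based 95% CI half-width across cells."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("expected a (n_profiles, N) matrix")
    n = matrix.shape[0]
    mean = matrix.mean(axis=0)
    if n < 2:
        return ProfileBand(mean=mean, ci_halfwidth=np.full_like(mean, np.nan), n=n, ci_defined=False)
    sem = matrix.std(axis=0, ddof=1) / np.sqrt(n)
    half = sps.t.ppf(0.975, n - 1) * sem
    return ProfileBand(mean=mean, ci_halfwidth=half, n=n, ci_defined=True)


def polarization_metrics(
    daughter_profiles: list[CortexProfile],
    mother_profiles: list[CortexProfile],
) -> tuple[pd.DataFrame, float]:
    """Per-cell mean cortex intensities and the cohort daughter:mother ratio.

    The ratio is mean(per-cell daughter means) / mean(per-cell mother means);
    a non-positive mother mean yields NaN rather than an infinity.
    """
    rows = [
        {"cell_id": p.cell_id, "region": p.region, "mean_intensity": p.mean_intensity}
        for p in [*daughter_profiles, *mother_profiles]
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "region", "mean_intensity"])
    d = df.loc[df["region"] == "daughter", "mean_intensity"]
    m = df.loc[df["region"] == "mother", "mean_intensity"]
    if len(d) == 0 or len(m) == 0 or m.mean() <= 0:
        return df, float("nan")
    return df, float(d.mean() / m.mean())
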