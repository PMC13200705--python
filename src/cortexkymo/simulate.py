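"""Synthetic budded-yeast time-lapse generator with exhaustive ground truth.

The generator emulates the imaging situation the analysis pipeline is built
for: a medium-budded yeast cell whose plasma-membrane outline carries (i) a
diffuse cortical fluorescence band that can be polarized toward the daughter
cell and (ii) transient, diffraction-limited endocytic puncta whose birth
rate and lifetime distribution differ between mother and daughter.  Every
random quantity is recorded as ground truth so each downstream stage
(boundary tracing, kymographs, puncta tracking, line profiles, statistics)
can be validated by parameter recovery.

Geometry is two fused disks — mother and bud tangent at the neck — the
simplest shape with a well-defined mother/daughter partition of the outline.
The neck landmarks are the two intersection points of the disk boundaries.

The imaging model per frame is

    photons = diffuse cortical band + active puncta (2D Gaussian PSF)
              + optional uniform cytoplasm
    counts  = Poisson(photons) + camera_offset + N(0, read_noise_sd²)

with both noise terms individually switchable so exact-value tests are
possible.  Identical (config, seed) produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .boundary import REGION_DAUGHTER, REGION_MOTHER, REGION_WHOLE, Boundary
from .errors import InvalidGeometryError
from .movie import Movie

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "Geometry",
    "build_geometry",
    "sample_events",
    "render_movie",
    "emit_dataset",
    "load_dataset",
]


def _per_region(value, region: str) -> float:
    """Resolve a scalar-or-{region: value} parameter for one region."""
    if isinstance(value, dict):
        return float(value[region])
    return float(value)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic movie generator.

    Lengths are µm, times are seconds, intensities are photons (pre-camera)
    or counts (post-camera).  ``lifetime_mean`` and ``lifetime_cv`` accept
    either a scalar (both regions) or a ``{"daughter": v, "mother": v}``
    mapping.  ``bud_radius = 0`` yields an unbudded cell.
    """

    mother_radius: float = 2.0
    bud_radius: float = 1.0
    center_spacing: float | None = None  # default: mother_radius + 0.7 * bud_radius
    pixel_size: float = 0.1
    frame_interval: float = 1.0
    n_frames: int = 180
    event_rate_daughter: float = 0.004  # events per µm of outline per second
    event_rate_mother: float = 0.002
    lifetime_mean: float | dict = 30.0  # seconds
    lifetime_cv: float | dict = 0.3
    punctum_amplitude: float = 120.0  # peak photons of the PSF spot
    diffuse_density: float = 30.0  # photons per µm of outline per sample
    diffuse_polarization: float = 1.0  # daughter:mother diffuse density ratio
    diffuse_profile: str = "flat"  # "flat" or "tip" (raised-cosine bump at bud tip)
    cytoplasm_density: float = 0.0  # photons per interior pixel
    internalization_depth: float = 0.2  # µm inward over the last 2 frames of life
    psf_sigma: float = 0.077  # 0.21·λ/NA, λ = 0.51 µm, NA = 1.4
    camera_offset: float = 100.0  # counts
    read_noise_sd: float = 5.0  # counts
    shot_noise: bool = True
    n_channels: int = 1
    channel2_fraction: float = 0.5  # fraction of events re-rendered in channel 2
    channel2_offset: float = 1.0  # seconds, channel-2 event delay
    margin: float = 0.8  # µm of background around the cell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mother_radius <= 0:
            raise InvalidGeometryError("mother_radius must be positive")
        if self.bud_radius < 0:
            raise InvalidGeometryError("bud_radius must be non-negative")
        if self.bud_radius > self.mother_radius:
            raise InvalidGeometryError("bud_radius may not exceed mother_radius")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.event_rate_daughter < 0 or self.event_rate_mother < 0:
            raise ValueError("event rates must be non-negative")
        for region in (REGION_DAUGHTER, REGION_MOTHER):
            if (self.event_rate_daughter > 0 or self.event_rate_mother > 0) and _per_region(
                self.lifetime_mean, region
            ) <= 0:
                raise ValueError("lifetime_mean must be positive when events occur")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if min(self.punctum_amplitude, self.diffuse_density, self.cytoplasm_density) < 0:
            raise ValueError("intensities must be non-negative")
        if self.diffuse_profile not in ("flat", "tip"):
            raise ValueError("diffuse_profile must be 'flat' or 'tip'")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")

    @property
    def spacing(self) -> float:
        if self.center_spacing is not None:
            return float(self.center_spacing)
        return self.mother_radius + 0.7 * self.bud_radius

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_flat_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("lifetime_mean", "lifetime_cv"):
            if isinstance(d[key], dict):
                d[key] = ";".join(f"{k}={v}" for k, v in d[key].items())
        return d


@dataclass(frozen=True)
class GroundTruthEvent:
    """One simulated endocytic event: where, when, how bright."""

    event_id: int
    region: str
    arc_position: float  # µm along the boundary, origin at the bud tip
    birth_time: float  # s
    death_time: float  # s
    amplitude: float  # peak photons
    internalization_depth: float  # µm
    channel: int = 0

    def __post_init__(self) -> None:
        if self.death_time <= self.birth_time:
            raise ValueError("death_time must exceed birth_time")

    @property
    def lifetime(self) -> float:
        return self.death_time - self.birth_time


@dataclass
class Geometry:
    """Rasterized cell plus the analytic outline it was rasterized from."""

    mask: np.ndarray  # uint16 label image, cell = 1
    boundary: Boundary  # analytic outline, arc origin at bud tip (or top point)
    neck_landmarks: np.ndarray | None  # (2, 2) µm, or None when unbudded
    mother_center: np.ndarray  # (x, y) µm
    bud_center: np.ndarray | None
    config: SimulationConfig

    @property
    def perimeter(self) -> float:
        return self.boundary.perimeter

    def region_perimeter(self, region: str) -> float:
        labels = self.boundary.region_labels
        if region == REGION_WHOLE:
            return self.perimeter
        return self.boundary.region_arc_length(region) if (labels == region).any() else 0.0

    def position_at_arc(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) on the outline at arc position s (µm), by interpolation."""
        b = self.boundary
        arc = np.concatenate([b.arc_length, [b.perimeter]])
        pts = np.vstack([b.points, b.points[:1]])
        s = np.mod(np.asarray(s, dtype=float), b.perimeter)
        x = np.interp(s, arc, pts[:, 0])
        y = np.interp(s, arc, pts[:, 1])
        return np.column_stack([x, y]) if x.ndim else np.array([x, y])

    def inward_at_arc(self, s: float) -> np.ndarray:
        """Inward unit normal at arc position s (toward the owning disk centre)."""
        p = self.position_at_arc(float(s))
        centre = self.mother_center
        if self.bud_center is not None:
            # the point belongs to whichever disk's boundary it lies on
            if abs(np.linalg.norm(p - self.bud_center) - self.config.bud_radius) < abs(
                np.linalg.norm(p - centre) - self.config.mother_radius
            ):
                centre = self.bud_center
        v = centre - p
        return v / np.linalg.norm(v)


def build_geometry(config: SimulationConfig) -> Geometry:
    """Rasterize the fused-disk cell and construct its analytic outline.

    The outline is sampled at a uniform arc step of one pixel size, ordered
    counter-clockwise.  For a budded cell the arc-length origin sits at the
    bud tip, so the daughter arc is centred on s = 0 and the neck landmarks
    are at ± half the daughter arc length.
    """
    R, r, d, ps = config.mother_radius, config.bud_radius, config.spacing, config.pixel_size
    m = config.margin
    if r > 0 and d >= R + r:
        raise InvalidGeometryError("disks do not overlap: center_spacing too large")
    if r > 0 and d <= R - r:
        raise InvalidGeometryError("bud disk lies inside the mother: center_spacing too small")

    cx, cy = m + R, m + R
    width = 2 * m + R + (d + r if r > 0 else R)
    height = 2 * m + 2 * R
    W, H = int(np.ceil(width / ps)), int(np.ceil(height / ps))
    xs = np.arange(W) * ps
    ys = np.arange(H) * ps
    X, Y = np.meshgrid(xs, ys)
    mother_center = np.array([cx, cy])
    inside = (X - cx) ** 2 + (Y - cy) ** 2 <= R**2
    if r > 0:
        bud_center = np.array([cx + d, cy])
        inside |= (X - bud_center[0]) ** 2 + (Y - bud_center[1]) ** 2 <= r**2
    else:
        bud_center = None
    mask = inside.astype(np.uint16)

    if r == 0:
        n = max(8, int(round(2 * np.pi * R / ps)))
        # origin at the topmost point (smallest y), CCW
        theta = -np.pi / 2 + 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([cx + R * np.cos(theta), cy + R * np.sin(theta)])
        bnd = Boundary(points=pts, region_labels=np.full(n, REGION_WHOLE, dtype="<U8"))
        return Geometry(mask, bnd, None, mother_center, None, config)

    # circle-circle intersection: half-chord geometry of the neck
    a = (d**2 + R**2 - r**2) / (2 * d)
    h = np.sqrt(R**2 - a**2)
    theta0 = np.arctan2(h, a)  # mother-centred angle of the upper neck point
    psi0 = np.arctan2(h, a - d)  # bud-centred angle of the upper neck point
    bud_arc = 2 * psi0 * r
    mother_arc = (2 * np.pi - 2 * theta0) * R
    perim = bud_arc + mother_arc

    def point_at(s: np.ndarray) -> np.ndarray:
        """Arc position -> (x, y); s = 0 at the bud tip, CCW."""
        s = np.mod(s, perim)
        out = np.empty((len(s), 2))
        half = bud_arc / 2
        on_bud_lead = s < half  # bud tip -> upper neck point
        on_bud_trail = s >= perim - half  # lower neck point -> bud tip
        on_mother = ~(on_bud_lead | on_bud_trail)
        psi = np.where(on_bud_lead, s / r, (s - perim) / r)
        out[:, 0] = cx + d + r * np.cos(psi)
        out[:, 1] = cy + r * np.sin(psi)
        th = theta0 + (s[on_mother] - half) / R
        out[on_mother, 0] = cx + R * np.cos(th)
        out[on_mother, 1] = cy + R * np.sin(th)
        return out

    n = max(8, int(round(perim / ps)))
    s = np.arange(n) * (perim / n)
    pts = point_at(s)
    half = bud_arc / 2
    labels = np.where((s < half) | (s >= perim - half), REGION_DAUGHTER, REGION_MOTHER).astype("<U8")
    bnd = Boundary(points=pts, region_labels=labels)
    landmarks = np.array([[a + cx, cy + h], [a + cx, cy - h]])
    return Geometry(mask, bnd, landmarks, mother_center, bud_center, config)


def _region_arc_intervals(geometry: Geometry, region: str) -> list[tuple[float, float]]:
    """Arc-position intervals [lo, hi) covered by a region, in µm."""
    b = geometry.boundary
    step = b.arc_step
    idx = np.nonzero(b.region_labels == region)[0]
    if len(idx) == 0:
        return []
    # contiguous runs in index space; each point owns [i*step, (i+1)*step)
    runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    return [(run[0] * step, (run[-1] + 1) * step) for run in runs]


def sample_events(config: SimulationConfig, geometry: Geometry) -> list[GroundTruthEvent]:
    """Draw ground-truth events: Poisson births, gamma lifetimes, uniform arc.

    Births are a homogeneous Poisson process per region with intensity
    rate × region perimeter over the movie duration; lifetimes are gamma with
    the configured (mean, CV); arc positions are uniform over the region's
    outline.  All draws come from a seed-derived stream in a fixed order.
    """
    rng = np.random.default_rng([1, config.seed])
    duration = config.n_frames * config.frame_interval
    events: list[GroundTruthEvent] = []
    regions = (
        [(REGION_DAUGHTER, config.event_rate_daughter), (REGION_MOTHER, config.event_rate_mother)]
        if config.bud_radius > 0
        else [(REGION_WHOLE, config.event_rate_mother)]
    )
    eid = 0
    for region, rate in regions:
        P = geometry.region_perimeter(region)
        if rate <= 0 or P <= 0:
            continue
        n = rng.poisson(rate * P * duration)
        births = np.sort(rng.uniform(0.0, duration, size=n))
        mean = _per_region(config.lifetime_mean, region if region != REGION_WHOLE else REGION_MOTHER)
        cv = _per_region(config.lifetime_cv, region if region != REGION_WHOLE else REGION_MOTHER)
        if cv <= 0:
            lifetimes = np.full(n, mean)
        else:
            shape = 1.0 / cv**2
            lifetimes = rng.gamma(shape, mean / shape, size=n)
        intervals = _region_arc_intervals(geometry, region)
        lengths = np.array([hi - lo for lo, hi in intervals])
        u = rng.uniform(0.0, lengths.sum(), size=n)
        arcs = np.empty(n)
        offsets = np.concatenate([[0.0], np.cumsum(lengths)])
        for k in range(n):
            j = int(np.searchsorted(offsets, u[k], side="right") - 1)
            j = min(j, len(intervals) - 1)
            arcs[k] = intervals[j][0] + (u[k] - offsets[j])
        for k in range(n):
            events.append(
                GroundTruthEvent(
                    event_id=eid,
                    region=region,
                    arc_position=float(arcs[k]),
                    birth_time=float(births[k]),
                    death_time=float(births[k] + max(lifetimes[k], 1e-9)),
                    amplitude=config.punctum_amplitude,
                    internalization_depth=config.internalization_depth,
                    channel=0,
                )
            )
            eid += 1
    return events


def _add_gaussian(img: np.ndarray, x_px: float, y_px: float, amp: float, sigma_px: float) -> None:
    """Add a peak-normalized 2D Gaussian spot in place (local window)."""
    H, W = img.shape
    w = int(np.ceil(4 * sigma_px + 1))
    r0, r1 = max(0, int(np.floor(y_px)) - w), min(H, int(np.floor(y_px)) + w + 1)
    c0, c1 = max(0, int(np.floor(x_px)) - w), min(W, int(np.floor(x_px)) + w + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None] - y_px
    xx = np.arange(c0, c1)[None, :] - x_px
    img[r0:r1, c0:c1] += amp * np.exp(-(xx**2 + yy**2) / (2 * sigma_px**2))


def _diffuse_band(geometry: Geometry, config: SimulationConfig) -> np.ndarray:
    """Static photon image of the diffuse cortical membrane signal."""
    H, W = geometry.mask.shape
    img = np.zeros((H, W))
    if config.diffuse_density <= 0:
        return img
    b = geometry.boundary
    ps, sig = config.pixel_size, config.psf_sigma / config.pixel_size
    step = b.arc_step
    labels = b.region_labels
    dens = np.where(labels == REGION_DAUGHTER, config.diffuse_density * config.diffuse_polarization, config.diffuse_density)
    if config.diffuse_profile == "tip" and (labels == REGION_DAUGHTER).any():
        # raised-cosine bump peaking at the bud tip (s = 0), mean weight 1
        d_idx = np.nonzero(labels == REGION_DAUGHTER)[0]
        L = b.region_arc_length(REGION_DAUGHTER)
        s = b.arc_length[d_idx]
        s = np.where(s > b.perimeter / 2, s - b.perimeter, s)  # signed distance from tip
        u = s / L + 0.5  # relative position in [0, 1], tip at 0.5
        dens = dens.astype(float)
        dens[d_idx] *= 1.0 + np.cos(2 * np.pi * (u - 0.5))
    for p, a in zip(b.points, dens * step):
        _add_gaussian(img, p[0] / ps, p[1] / ps, float(a), sig)
    return img


def render_movie(
    geometry: Geometry,
    events: list[GroundTruthEvent],
    config: SimulationConfig,
) -> tuple[Movie, pd.DataFrame]:
    """Render the photon model frame by frame and apply the camera model.

    Returns the Movie (float64 counts) and the ground-truth event table.
    Events extending past the movie are truncated at render time; the table
    keeps their true death times.
    """
    H, W = geometry.mask.shape
    if H == 0 or W == 0:
        raise ValueError("zero-size frames")
    cfg = config
    ps = cfg.pixel_size
    sig = cfg.psf_sigma / ps
    dt = cfg.frame_interval
    diffuse = _diffuse_band(geometry, cfg)
    cyto = cfg.cytoplasm_density * (geometry.mask > 0)
    static = diffuse + cyto

    channel_events: list[list[GroundTruthEvent]] = [list(events)]
    if cfg.n_channels == 2:
        rng_ch = np.random.default_rng([3, cfg.seed])
        picked = rng_ch.random(len(events)) < cfg.channel2_fraction
        ch2 = [
            dataclasses.replace(
                ev,
                channel=1,
                birth_time=ev.birth_time + cfg.channel2_offset,
                death_time=ev.death_time + cfg.channel2_offset,
            )
            for ev, keep in zip(events, picked)
            if keep
        ]
        channel_events.append(ch2)

    noise_rng = np.random.default_rng([2, cfg.seed])
    data = np.empty((cfg.n_channels, cfg.n_frames, H, W))
    for c, evs in enumerate(channel_events):
        # precompute positions and inward normals once per event
        pos = [geometry.position_at_arc(ev.arc_position) for ev in evs]
        inward = [geometry.inward_at_arc(ev.arc_position) for ev in evs]
        for t in range(cfg.n_frames):
            tsec = t * dt
            photons = static.copy()
            for ev, p, nin in zip(evs, pos, inward):
                if not (ev.birth_time <= tsec < ev.death_time):
                    continue
                tau = ev.death_time - tsec  # time to disappearance
                if tau <= dt:
                    depth = ev.internalization_depth
                elif tau <= 2 * dt:
                    depth = 0.5 * ev.internalization_depth
                else:
                    depth = 0.0
                q = p + depth * nin
                _add_gaussian(photons, q[0] / ps, q[1] / ps, ev.amplitude, sig)
            if cfg.shot_noise:
                photons = noise_rng.poisson(np.clip(photons, 0, None)).astype(float)
            frame = photons + cfg.camera_offset
            if cfg.read_noise_sd > 0:
                frame = frame + noise_rng.normal(0.0, cfg.read_noise_sd, size=frame.shape)
            data[c, t] = frame

    all_events = [ev for evs in channel_events for ev in evs]
    truth = pd.DataFrame(
        [
            {
                "event_id": ev.event_id,
                "channel": ev.channel,
                "region": ev.region,
                "arc_position_um": ev.arc_position,
                "birth_s": ev.birth_time,
                "death_s": ev.death_time,
                "lifetime_s": ev.lifetime,
                "amplitude": ev.amplitude,
                "internalization_depth_um": ev.internalization_depth,
                "x_um": geometry.position_at_arc(ev.arc_position)[0],
                "y_um": geometry.position_at_arc(ev.arc_position)[1],
            }
            for ev in all_events
        ],
        columns=[
            "event_id",
            "channel",
            "region",
            "arc_position_um",
            "birth_s",
            "death_s",
            "lifetime_s",
            "amplitude",
            "internalization_depth_um",
            "x_um",
            "y_um",
        ],
    )
    movie = Movie(data=data, pixel_size=ps, frame_interval=dt)
    return movie, truth


def simulate(config: SimulationConfig) -> tuple[Geometry, list[GroundTruthEvent], Movie, pd.DataFrame]:
    """Convenience: geometry -> events -> rendered movie, in one call."""
    geometry = build_geometry(config)
    events = sample_events(config, geometry)
    movie, truth = render_movie(geometry, events, config)
    return geometry, events, movie, truth


def _quantize(data: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(data), 0, 65535).astype(np.uint16)


def emit_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Simulate and write a complete dataset to disk.

    Writes one 16-bit TIFF stack per channel (counts rounded to integers),
    the label mask, the ground-truth CSV, neck landmarks, the analytic
    boundary, and a flat ``key: value`` echo of the configuration.  Returns a
    manifest dict of the written paths plus the in-memory objects.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry, events, movie, truth = simulate(config)
    paths: dict[str, object] = {}
    for c in range(movie.n_channels):
        p = out_dir / f"movie_ch{c + 1}.tif"
        tifffile.imwrite(p, _quantize(movie.data[c]), photometric="minisblack")
        paths[f"movie_ch{c + 1}"] = p
    tifffile.imwrite(out_dir / "mask.tif", geometry.mask)
    paths["mask"] = out_dir / "mask.tif"
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    paths["ground_truth"] = out_dir / "ground_truth.csv"
    geometry.boundary.to_frame().to_csv(out_dir / "boundary.csv", index=False)
    paths["boundary"] = out_dir / "boundary.csv"
    if geometry.neck_landmarks is not None:
        pd.DataFrame(geometry.neck_landmarks, columns=["x_um", "y_um"]).to_csv(
            out_dir / "landmarks.csv", index=False
        )
        paths["landmarks"] = out_dir / "landmarks.csv"
    with open(out_dir / "config.txt", "w") as fh:
        for k, v in config.to_flat_dict().items():
            fh.write(f"{k}: {v}\n")
    paths["config"] = out_dir / "config.txt"
    paths["geometry"] = geometry
    paths["movie"] = movie
    paths["truth"] = truth
    return paths


def load_dataset(out_dir: str | Path) -> dict:
    """Read back a dataset written by :func:`emit_dataset`."""
    out_dir = Path(out_dir)
    cfg_kv: dict[str, str] = {}
    for line in (out_dir / "config.txt").read_text().splitlines():
        k, _, v = line.partition(":")
        cfg_kv[k.strip()] = v.strip()
    pixel_size = float(cfg_kv["pixel_size"])
    frame_interval = float(cfg_kv["frame_interval"])
    stacks = sorted(out_dir.glob("movie_ch*.tif"))
    data = np.stack([tifffile.imread(p) for p in stacks])
    movie = Movie(data=data, pixel_size=pixel_size, frame_interval=frame_interval)
    out = {
        "movie": movie,
        "mask": tifffile.imread(out_dir / "mask.tif"),
        "truth": pd.read_csv(out_dir / "ground_truth.csv"),
        "config_raw": cfg_kv,
    }
    lm = out_dir / "landmarks.csv"
    if lm.exists():
        out["landmarks"] = pd.read_csv(lm)[["x_um", "y_um"]].to_numpy(float)
    return out
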