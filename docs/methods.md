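# Methods

`cortexkymo` quantifies polarized recruitment of endocytic proteins at the
plasma membrane of budded yeast from 1–2-channel fluorescence time-lapse
movies. Three measurements are produced: circumferential kymographs of the
cell outline, lifetimes of transient cortical puncta (endocytic sites), and
averaged cortex intensity line profiles with a daughter:mother polarization
ratio. A synthetic movie generator with complete ground truth underpins all
validation; every number in the test suite and in `scripts/acceptance.py` is
recovered by running the real pipeline on simulated data.

## The generative model

**Geometry.** A cell is the union of two disks: the mother (radius *R*) and
the bud (radius *r* ≤ *R*) with center spacing *d* ∈ (*R* − *r*, *R* + *r*);
default *d* = *R* + 0.7 *r*. The plasma-membrane outline is the analytic
boundary of the union, sampled at a uniform arc step of one pixel,
counter-clockwise, with the arc-length origin at the bud tip so daughter
traces run neck → tip → neck with the tip at mid-trace. The bud neck is the
chord of intersection; its two endpoints are the neck landmarks used to
partition the outline into *daughter* and *mother* arcs. `bud_radius = 0`
produces an unbudded cell with a single *whole* region.

**Signal.** Per frame the photon image is

```
photons = diffuse cortical band + Σ active puncta + cytoplasm
counts  = Poisson(photons) + camera_offset + N(0, read_noise_sd²)
```

- *Diffuse band*: one isotropic Gaussian of width `psf_sigma` per outline
  sample, amplitude `diffuse_density × arc_step`, with the daughter arc
  scaled by `diffuse_polarization`. The optional `diffuse_profile="tip"`
  multiplies the daughter density by a raised cosine `1 + cos(2πs/L)`
  (mean 1, maximal at the tip), emulating tip-concentrated recruitment.
- *Puncta*: births are a homogeneous Poisson process per region with
  intensity `event_rate × region perimeter` over the movie; lifetimes are
  gamma with configurable `(mean, CV)` per region (exponential is CV = 1);
  arc positions are uniform on the region. A punctum is a peak-normalized
  2D Gaussian of width `psf_sigma` and peak `punctum_amplitude` photons,
  displaced along the inward normal by `internalization_depth`/2 in its
  second-to-last frame and by the full depth in its last frame — the
  terminal inward movement seen for internalizing endocytic sites.
- *Noise*: Poisson shot noise is applied to the photon signal (not to the
  camera pedestal), then offset and Gaussian read noise. Both terms switch
  off independently for exact-value tests. All randomness flows from
  seed-derived `numpy` Generator streams with fixed draw order, so identical
  (config, seed) give bit-identical movies.

Defaults: pixel size 0.1 µm, Δt 1 s, `psf_sigma` 0.077 µm (0.21 λ/NA with
λ = 0.51 µm, NA = 1.4), offset 100 counts, read noise 5 counts,
amplitude 120, diffuse density 30 photons/µm. Event rates default to
0.004 (daughter) and 0.002 (mother) events µm⁻¹ s⁻¹ — order-of-magnitude
choices giving a realistically sparse cortex (no measured rates are
available to calibrate against).

**What the generator does not emulate:** photobleaching, motile cytoplasmic
compartments (only a uniform cytoplasmic background is available), 3D/z
structure, cell growth, and segmentation errors beyond what the Otsu
fallback produces. Passing tests therefore demonstrate correctness of the
measurement pipeline under this model, not robustness to every property of
real movies.

## Boundary tracing

External label masks are accepted as-is; without one, an Otsu threshold of
the temporal median projection (holes filled, components < 200 px dropped)
provides a fallback. The outline of a labeled component is the subpixel
0.5-level marching-squares contour, which for binary input is a 45°
staircase whose length overestimates smooth outlines by ~4%. The contour is
therefore resampled at a quarter-pixel step and smoothed along arc length
with a periodic Gaussian of σ = 0.5 px before final resampling to a one-pixel
arc step. This brings a 3 µm disk's perimeter within ~1.8% and keeps the
corner rounding of a genuinely sharp 2 µm square below 3%; the residual
displacement of the traced edge is well under one pixel (Hausdorff distance
to the generating outline ≈ 0.07 µm at 0.1 µm/px). Components with interior
holes or touching the image border are rejected rather than silently
truncated. The outline is traced once per movie and held fixed across
frames; the cells analyzed are adhered and the movies short, so growth is
negligible over the acquisition.

Partitioning: the two contour points nearest the neck landmarks (within
2 arc steps, else an error) split the closed contour into two arcs; the
shorter is labeled daughter (an override exists for unusually large buds).
Points are assigned by half-open arcs, so daughter + mother arc lengths sum
to the perimeter exactly. The origin then moves to the daughter-arc
midpoint (the bud tip).

## Circumferential kymographs

Entry (*i*, *t*) is the reduction (max by default, mean available) of
bilinearly interpolated intensities sampled along the outward/inward normal
at boundary point *i* over ±`band_halfwidth` (default 0.25 µm) at half-pixel
spacing, in frame *t*. The band tolerates 1–2 px tracing error. A
transparent triple-loop reference implementation
(`circumferential_kymograph_naive`) is kept in the package; the vectorized
path must reproduce it bit-for-bit, and does on randomized instances.
Kymographs are saved as raw 32-bit float TIFF with CSV sidecars mapping rows
to (arc, region) and columns to time; the percentile-normalized version is
for display only.

## Event detection, linking, lifetimes

Movie-level detection first subtracts the per-pixel temporal median of the
stack: static structure — the diffuse membrane band, cytoplasmic haze, the
camera pedestal — cancels while transient puncta survive, which keeps the
detector's false-positive rate low even over a bright polarized cortex
(switchable off). Detection per frame is then a difference-of-Gaussians
band-pass (σ = `psf_sigma` and 2σ), local maxima separated by ≥ 2σ, kept
when the filtered amplitude exceeds `k_threshold` (default 5) × robust
noise (1.4826 × MAD of the filtered frame), with 3-point parabolic subpixel
refinement. A 1D variant
(`detect_kymograph`) applies the same logic per kymograph column for
tracking in arc-position space.

Linking is greedy nearest-neighbor (candidates within `max_disp`, default
0.4 µm, assigned by increasing distance, ties to the brighter detection)
with gap closing up to `max_gap` (default 1) missing frames — appropriate
for sparse, near-stationary cortical sites, and verified against an
exhaustive minimal-cost assignment oracle on small instances. Tracks with
fewer than `min_frames` detections (default 3 in the pipeline) are
discarded: over a bright diffuse membrane band, shot noise occasionally
crosses the detector threshold, and these spurious 1–2-detection tracks
otherwise contaminate lifetime statistics. Real events at the simulated
conditions span ≥ 5 frames essentially always.

Lifetime = (last − first + 1) × Δt, so a single-frame event has lifetime Δt.
Tracks touching the first or last movie frame are censored and excluded
from lifetime statistics by default (switchable to keep-but-flag). On
simulated data the estimator carries a small (< Δt + censoring) bias; at
mean 30 s, CV 0.3, Δt = 1 s it recovers the mean within ±3 s from ~200
pooled events.

Two-channel coincidence: tracks from channels A and B match when their
same-frame detections stay within `dist_thresh` for ≥ `min_overlap` frames;
pairs are chosen greedily by decreasing overlap, one-to-one. The reported
fraction is matched A-tracks / all A-tracks.

## Cortex profiles and polarization

Profiles are taken on the maximum-intensity projection of the movie: per
boundary point, the max over the same normal band as the kymograph; the
per-cell background (median over the interior eroded by 3 × band_halfwidth)
is subtracted by default (unsubtracted and constant-background modes exist).
A profile is restricted to one region's contiguous arc. For averaging,
profiles are mapped to relative arc position [0, 1] (daughter traces:
neck → tip → neck) and linearly interpolated to the mean trace length;
the cohort band is the position-wise mean ± t-based 95% CI.

The polarization ratio is mean(per-cell daughter means) / mean(per-cell
mother means); a non-positive denominator yields NaN, never infinity.

One numerical caveat: at sub-Nyquist PSF sampling (σ < ~1.5 px) the
bilinearly interpolated crest of the thin membrane band aliases against the
pixel grid by ±10–20% depending on the local edge phase. This is a sampling
property, not a defect of the trace; it averages out along the arc and
across cells, but single-point profile values at σ ≈ 0.8 px should not be
over-interpreted. The profile-flatness contract is verified at σ = 5 px,
where the effect is < 2%. The recovered polarization ratio also compresses
slightly toward 1 (≈ 4.2 recovered for a true ratio of 5 at the simulated
brightness) because maximum projections and band maxima add a common
noise-driven offset to both regions; the recovery stays within 20% and is
strictly monotone in the true ratio.

## Statistics

Group comparisons use classical fixed-effects one-way ANOVA
(F = MS_between/MS_within, df = (k − 1, N − k); cross-checked against
`scipy.stats.f_oneway` to machine precision, and F = t² for two groups).
Error bars are t-based 95% CIs. Star labels: **** p < 10⁻⁴,
*** p < 10⁻³, ** p < 0.01, * p < 0.05, else ns; only the two strictest
rungs are standard in the figure convention being followed, the rest
complete the conventional ladder. No post-hoc pairwise correction is
applied — only the omnibus test is reported. A zero within-group variance
with unequal means is flagged degenerate (F = ∞, p = 0) rather than raising.

## Validation experiment sizes

The replicated experiments are sized to run on one CPU in minutes while
keeping every estimate comfortably inside its tolerance:

- Event movies: one 2.0/1.0 µm cell, 300 frames at Δt = 1 s, active-site
  density ~0.1 events per µm of outline; conditions reach their target event
  counts (100–200) by pooling several cells, as real lifetime datasets pool
  events across cells. Puncta peak SNR ≈ 8 over the camera background.
- Power/calibration cohorts: 30 cells per arm, bud radius drawn per cell
  from {0.8 … 1.2} µm, diffuse signal only, 6 frames per cell at
  0.12 µm/px; 100 replicates for power against a 30% daughter-density
  deficit, 1000 for the null rejection rate. The deterministic noise-free
  photon image is cached per distinct geometry; all noise is redrawn per
  cell and replicate.
- Polarization/tip cohorts: 20 and 15 cells, same rendering.

## Known limitations

- Greedy linking can merge two co-active events closer than `max_disp`,
  slightly inflating long-lifetime estimates (the 40 s condition recovers
  ≈ 36 s); global assignment is deliberately out of scope.
- No automatic neck detection: landmarks come from ground truth or external
  annotation.
- The detector's global-MAD noise estimate under-weights signal-dependent
  noise on bright structures; the min-detections track filter compensates.
- Lifetimes are right-discretized to whole frames and censored tracks are
  dropped, so means carry a small positive discretization and negative
  censoring bias (both ≪ the tolerances used).
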