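# cortexkymo

Quantification of polarized endocytic-protein recruitment at the plasma
membrane of budded yeast, from 1–2-channel fluorescence time-lapse movies.

Budding yeast grows by polarized secretion into the daughter cell (the bud),
and clathrin-mediated endocytosis (CME) sites — visible as transient
cortical puncta of tagged adaptors and cargo such as AP180/Yap1802 and the
v-SNARE Snc2 — initiate preferentially on the daughter cortex. Comparing
mutants and conditions requires three measurements per cell:

1. **Circumferential kymographs** — the cell outline is traced, partitioned
   at the bud neck into daughter and mother arcs, and unrolled so that arc
   position runs along one axis and time along the other; puncta appear as
   horizontal streaks whose length is the event lifetime, and laterally
   translating cargo appears as sloped streaks.
2. **Cortical puncta lifetimes** — spots are detected per frame
   (difference-of-Gaussians matched to the PSF), linked through time
   (nearest-neighbor with gap closing), and each uncensored track
   contributes a lifetime (last − first + 1)·Δt, pooled per condition.
3. **Cortex line profiles** — on the maximum-intensity projection, the
   background-subtracted intensity along a region's arc is interpolated to
   the cohort's mean trace length, averaged with a t-based 95% CI band, and
   summarized as the daughter:mother polarization ratio
   mean(daughter cortex means)/mean(mother cortex means).

Conditions are compared by one-way ANOVA with mean ± 95% CI error bars and
conventional significance stars (**** p < 10⁻⁴).

Because no public movies accompany this analysis, the package ships a
**synthetic movie generator** (`cortexkymo.simulate`): a two-disk budded
cell whose outline carries a polarized diffuse band plus Poisson-born
cortical puncta with gamma lifetimes, rendered through a Gaussian PSF and
an sCMOS-style noise model, with exhaustive ground truth. Every stage of
the pipeline is validated by parameter recovery on this generator (see
`docs/methods.md`).

## Worked example

```python
from cortexkymo import (SimulationConfig, build_geometry, sample_events,
                        render_movie, circumferential_kymograph,
                        detect_movie, link_tracks, compute_lifetimes)

cfg = SimulationConfig(n_frames=180, event_rate_daughter=0.006,
                       event_rate_mother=0.002, lifetime_mean=25.0,
                       diffuse_polarization=3.0, seed=1)
geometry = build_geometry(cfg)
events = sample_events(cfg, geometry)
movie, truth = render_movie(geometry, events, cfg)

kymo = circumferential_kymograph(movie, geometry.boundary)   # rows×frames
dets = detect_movie(movie.channel(0), cfg.psf_sigma, cfg.pixel_size)
tracks = link_tracks(dets, min_frames=3)
lifetimes = compute_lifetimes(tracks, cfg.frame_interval, cfg.n_frames)
print(len(truth), "true events ->", len(lifetimes), "uncensored tracks,",
      f"mean lifetime {lifetimes['lifetime_s'].mean():.1f} s")
```

prints (seed 1):

```
9 true events -> 6 uncensored tracks, mean lifetime 28.3 s
```

Nine events were simulated (their realized mean lifetime is 27.7 s); events
overlapping the movie start or end are censored and excluded, and the
recovered mean lifetime of the remaining tracks (28.3 s) matches the
simulated dynamics.

The numbered drivers under `analysis/` run the full synthetic studies and
write their tables under `results/`:

```
01_simulate_dataset.py      two-channel reference dataset + ground truth
02_project_and_kymograph.py projections, montage, kymographs (+ PNG preview)
03_event_lifetimes.py       lifetime recovery and 10/20/40 s ordering + ANOVA
04_cortex_profiles.py       polarization-ratio recovery, tip-profile band
05_recruitment_power.py     power / type-I error of cortex-intensity ANOVA
```

A CLI wraps the same pipeline for movies on disk or simulated input
(`cortexkymo run-all --config run.yaml --out OUT --seed 1`, plus per-stage
subcommands `simulate`, `boundary`, `kymo`, `events`, `profiles`, `stats`).
Configs are YAML; unknown keys and out-of-range values are rejected by name,
and identical (config, seed) runs are byte-identical.

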