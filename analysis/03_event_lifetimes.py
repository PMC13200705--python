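#!/usr/bin/env python
"""Lifetime recovery and condition ordering on simulated endocytic events.

Two experiments, both through the full detect -> link -> lifetime pipeline:

1. Recovery: ~200 events with gamma lifetimes (mean 30 s, CV 0.3) at
   dt = 1 s; reports the recovered mean and the detection recall over
   uncensored events.
2. Ordering: three conditions with true mean lifetimes 10/20/40 s
   (~100 events each), compared by one-way ANOVA — the short/regular vs.
   long/variable regimes that distinguish daughter from mother endocytic
   dynamics.

Writes results/lifetimes/{lifetime_table.csv,lifetime_summary.csv,anova.csv}.
"""

from pathlib import Path

import pandas as pd

from cortexkymo.experiments import lifetime_ordering_experiment, lifetime_recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results" / "lifetimes"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)

    rec = lifetime_recovery_experiment(seed=1, target_events=200)
    print(f"recovery: true mean 30.0 s -> estimated {rec['estimated_mean_s']:.1f} s "
          f"from {rec['n_tracks']} uncensored tracks ({rec['n_cells']} cells); "
          f"detection recall {rec['recall']:.2f}")

    order = lifetime_ordering_experiment(seed=1, true_means=(10.0, 20.0, 40.0), target_events=100)
    tables = []
    for mean, cond in zip(order["true_means_s"], order["conditions"]):
        t = cond["lifetimes"].copy()
        t["condition"] = f"mean{int(mean)}s"
        t["true_mean_s"] = mean
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT / "lifetime_table.csv", index=False)

    summary = pd.DataFrame(
        {
            "condition": [f"mean{int(m)}s" for m in order["true_means_s"]],
            "true_mean_s": order["true_means_s"],
            "estimated_mean_s": order["estimated_means_s"],
            "n_tracks": order["n_per_condition"],
        }
    )
    summary.to_csv(OUT / "lifetime_summary.csv", index=False)
    anova = order["anova"]
    anova.to_frame().to_csv(OUT / "anova.csv", index=False)

    print("ordering:")
    print(summary.to_string(index=False))
    print(f"one-way ANOVA: F({anova.df_between},{anova.df_within}) = {anova.F:.1f}, "
          f"p = {anova.p:.3g} {anova.star}")
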