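#!/usr/bin/env python
"""Step 6: stroke-etiology rerun and dual-outcome consistency map.

Reruns stability selection with the CE-vs-LAA etiology contrast as outcome,
restricted per sex to the recanalization-stable clusters, then reports which
clusters are stable for both outcomes, their overlap across sexes, and the
outcome class in which each cluster's median is highest.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from bccstrat.consistency import (
    build_consistency_map,
    consistency_report,
    etiology_stability,
    overlap_summary,
)
from bccstrat.clustering import make_representatives
from bccstrat.simulate import read_cohort_csv

if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--repeats", type=int, default=100)
    ap.add_argument("--seed", type=int, default=18)
    args = ap.parse_args()

    cohort = read_cohort_csv(str(args.results / "cohort.csv"))
    part = {r.variable: int(r.cluster)
            for r in pd.read_csv(args.results / "clusters.csv").itertuples()}
    stable = json.loads((args.results / "stable_sets.json").read_text())
    recan_stable = {s: set(stable[s]) for s in ("F", "M")}

    X = cohort[list(part)]
    et = etiology_stability(
        X, cohort["etiology"].to_numpy(), cohort["sex"].to_numpy(), part,
        recan_stable, K=5, R=args.repeats, seed=args.seed,
    )
    reps_by_sex, recan_labels, et_labels = {}, {}, {}
    for s in ("F", "M"):
        mask = (cohort["sex"] == s).to_numpy()
        reps_by_sex[s], _, _ = make_representatives(X.loc[mask], part)
        recan_labels[s] = cohort.loc[mask, "recanalization"].to_numpy()
        et_labels[s] = cohort.loc[mask, "etiology"].to_numpy()
    cmap = build_consistency_map(recan_stable, et, reps_by_sex, recan_labels, et_labels)

    (args.results / "consistency.json").write_text(json.dumps({
        "recan_stable": {s: sorted(v) for s, v in cmap.recan_stable.items()},
        "etiology_stable": {s: sorted(v) for s, v in cmap.etiology_stable.items()},
        "both_stable": {s: sorted(v) for s, v in cmap.both_stable.items()},
        "direction": cmap.direction,
    }, indent=1))
    (args.results / "consistency_report.md").write_text(consistency_report(cmap))

    for s, label in (("F", "women"), ("M", "men")):
        print(f"{label}: {len(cmap.recan_stable[s])} recanalization-stable clusters, "
              f"{len(cmap.both_stable[s])} also stable for etiology")
    ov = overlap_summary(cmap.both_stable["F"], cmap.both_stable["M"])
    print(f"dual-outcome clusters: {ov['shared']} shared, "
          f"{ov['female_specific']} female-specific, {ov['male_specific']} male-specific")
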