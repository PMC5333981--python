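#!/usr/bin/env python
"""Run the full per-sample analysis over the simulated cohort.

For every sample from 01_simulate_cohort.py: distance-excess profiles against
both reference regions (lumen and adjacent tissue, sharing the same
Monte-Carlo control draws) and kernel-density hotspot metrics.  One JSON per
sample goes to results/cohort/samples/.
"""

import json
import sys
import time
from pathlib import Path

import pandas as pd

from vesselbelt import RoiSet, analyze_sample
from vesselbelt.seeds import derive_seed

ROOT_SEED = 20260921
REPO = Path(__file__).resolve().parents[1]
BASE = REPO / "results" / "cohort"
POINTS = REPO / "scratch" / "cohort" / "points"


def main() -> None:
    if not POINTS.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    outdir = BASE / "samples"
    outdir.mkdir(parents=True, exist_ok=True)
    rois = RoiSet.from_geojson(BASE / "rois.geojson")
    manifest = json.loads((BASE / "truth.json").read_text())
    t0 = time.perf_counter()
    for meta in manifest:
        sid = meta["sample_id"]
        table = pd.read_csv(POINTS / f"{sid}.csv")
        result = analyze_sample(
            table, rois, sample_id=sid, group=meta["group"],
            seed=derive_seed(ROOT_SEED, f"analyze-{sid}"),
        )
        result.to_json(outdir / f"{sid}.json")
    elapsed = time.perf_counter() - t0
    print(f"analyzed {len(manifest)} samples in {elapsed:.1f} s -> {outdir}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
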