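#!/usr/bin/env python
"""Model-free ("simple") analysis of the synthetic datasets.

Reads the response metrics directly off each cell's data points, and off
cubic-B-spline-smoothed versions resampled at 1000 equidistant times, then
compares the population medians with the model-based Monte-Carlo medians
from 05_predict_response.py.  On 15-point schedules the raw response time
is quantized to the sampling grid, which is exactly why the data-driven
and model-based numbers drift apart -- the discrepancy this script prints
is the point, not a bug.

Writes results/simple/exp<N>_metrics.csv and summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from mignlme import population_medians, raw_metrics, read_dataset, smooth_resample

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "simple"
    out.mkdir(parents=True, exist_ok=True)
    mc_summary_path = ROOT / "prediction" / "summary.json"
    mc = json.loads(mc_summary_path.read_text()) if mc_summary_path.exists() else {}

    summary = {}
    for exp in (1, 2, 3, 4):
        dataset = read_dataset(ROOT / "data" / f"exp{exp}.csv")
        shift = dataset.program.shift_time
        raw = [raw_metrics(c, shift) for c in dataset.cells]
        smoothed = [raw_metrics(smooth_resample(c).as_cell(), shift)
                    for c in dataset.cells if len(c) >= 4]
        med_raw = population_medians(raw)
        med_smooth = population_medians(smoothed)
        summary[f"exp{exp}"] = {"raw": med_raw, "smoothed": med_smooth}

        pd.DataFrame([m.__dict__ for m in raw]).to_csv(
            out / f"exp{exp}_metrics.csv", index=False)

        model = mc.get(f"exp{exp}", {}).get("medians", {})
        print(f"\n=== experiment {exp} ===")
        for metric, unit in (("response_time", "s"), ("amplitude", "%"),
                             ("duration", "s")):
            line = (f"{metric:>14}: raw {med_raw[metric] or float('nan'):7.1f} {unit}"
                    f" | smoothed {med_smooth[metric] or float('nan'):7.1f} {unit}")
            if model:
                line += f" | model MC {model[metric]:7.1f} {unit}"
            print(line)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    print(f"\nwrote simple-analysis results to {out}")


if __name__ == "__main__":
    main()
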