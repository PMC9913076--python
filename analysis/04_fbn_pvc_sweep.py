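#!/usr/bin/env python
"""Effect of discretization level and partial-volume correction on robustness.

Computes the overall ICC (across all aggregation methods per feature) for
each of the 10 configurations and summarizes the percent of features per
robustness category (poor/moderate/good/excellent at 0.5/0.75/0.9), overall
and per family.  Reads results/features.tsv (02).
"""

from pathlib import Path

import pandas as pd

from texagg.pipeline import ExperimentConfig, run_sweep_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    features = pd.read_csv(RESULTS / "features.tsv", sep="\t")
    cfg = ExperimentConfig()
    out = run_sweep_experiment(cfg, features)
    for key, tab in out.items():
        tab.to_csv(RESULTS / f"{key}.tsv", sep="\t", index=False)
    print("percent of all 95 features per overall-ICC category:")
    print(out["categories_all"].round(1).to_string(index=False))


if __name__ == "__main__":
    main()
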