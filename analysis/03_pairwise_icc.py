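#!/usr/bin/env python
"""Pairwise ICC of aggregation-method pairs at FBN 128 on uncorrected images.

For GLCM/GLRLM the nine method pairs compare averaged-vs-merged within a
dimension and matched strategies across dimensions; the other four families
compare 2D/2.5D/3D.  Reads results/features.tsv (02) and writes per-family
ICC tables plus a category heat-map-style matrix (feature x comparison).
"""

import argparse
from pathlib import Path

import pandas as pd

from texagg.pipeline import ExperimentConfig, run_pairwise_experiment


RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pair-variant", choices=["text", "figure"], default="text")
    args = ap.parse_args()

    features = pd.read_csv(RESULTS / "features.tsv", sep="\t")
    cfg = ExperimentConfig(pair_variant=args.pair_variant)
    tables = run_pairwise_experiment(cfg, features)
    for family, tab in tables.items():
        tab.to_csv(RESULTS / f"pairwise_icc_{family.lower()}.tsv", sep="\t", index=False)
        heat = tab.pivot(index="feature", columns="comparison", values="category")
        heat.to_csv(RESULTS / f"icc_heatmap_{family.lower()}.tsv", sep="\t")
        same_dim = tab[tab["comparison"].isin(
            {f"{a}-{b}" for a, b in cfg.pairs_for_family(family)[:3]}
        )]
        print(
            f"{family}: median ICC same-dimension pairs "
            f"{same_dim['icc'].median():.3f}; all pairs {tab['icc'].median():.3f}; "
            f"excellent {100 * (tab['category'] == 'excellent').mean():.0f}%"
        )


if __name__ == "__main__":
    main()
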