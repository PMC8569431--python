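"""Phenotype-array restoration analysis.

Generates the full synthetic plate design (252 plates), normalises to 92
features, embeds with PCA, classifies each evolved strain x stress
temperature against the ancestor's stressed and 37 degC states, clusters
the samples (Ward/Euclidean) and runs the group-level restoration
comparisons.  Strategy labels from 02 drive the generalist-vs-other
contrast when present.  Writes results/biolog/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fluctevo import io as fio
from fluctevo.pipeline import PipelineConfig, RunReport, _biolog_stage
from fluctevo.plots import plot_pca_scores


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--strategy", type=Path, default=Path("results/growth/strategy_calls.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/biolog"))
    args = ap.parse_args()

    strategy = None
    if args.strategy.exists():
        strategy = pd.read_csv(args.strategy, sep="\t")

    config = PipelineConfig(seed=args.seed)
    report = RunReport(config=config.to_dict())
    _biolog_stage(config, report, strategy)

    headline = report.tables["restoration_headline"]
    print("headline restoration calls by temperature:")
    print(headline.groupby(["temperature_C", "headline"]).size().unstack(fill_value=0).to_string())
    print("group tests:")
    print(report.tables["restoration_group_tests"].to_string(index=False))

    for name in ("pca_scores", "restoration_calls", "restoration_headline", "restoration_group_tests"):
        fio.write_tsv(report.tables[name], args.out / f"{name}.tsv")
    (args.out / "dendrogram.nwk").parent.mkdir(parents=True, exist_ok=True)
    (args.out / "dendrogram.nwk").write_text(report.tables["dendrogram"]["newick"].iloc[0] + "\n")
    scores = report.tables["pca_scores"].set_index("plate_id")
    meta = pd.DataFrame(index=scores.index)
    meta["temperature_C"] = [int(p.split("_")[1].rstrip("C")) for p in scores.index]
    plot_pca_scores(scores, meta, args.out / "pca_scores.png")
    print(f"tables and figure written to {args.out}/")


if __name__ == "__main__":
    main()
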