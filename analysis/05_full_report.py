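"""End-to-end pipeline run with the consolidated report.

Equivalent to ``fluctevo all --seed N --out results/report``: runs
simulate -> growth -> mutations -> biolog on synthetic data with one
top-level seed and writes every stage table plus the JSON/text report.
"""

import argparse
import json
from pathlib import Path

from fluctevo.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/report"))
    args = ap.parse_args()

    report = run_pipeline(PipelineConfig(seed=args.seed, out_dir=args.out))
    print(json.dumps(report.summary(), indent=2, default=str))


if __name__ == "__main__":
    main()
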