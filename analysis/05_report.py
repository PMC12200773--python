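#!/usr/bin/env python
"""Assemble the run report: weighted prevalence by country, the
association table, convergence diagnostics and posterior predictive
checks, plus dropped-row accounting and the resolved configuration.

Reads the artifacts of the previous steps under <out-dir>; writes
report.json, report.txt and prevalence.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from droughtlink.config import PipelineConfig
from droughtlink.diagnostics import build_report
from droughtlink.model import CATEGORIES, weighted_prevalence


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--config", type=Path, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig.from_file(args.config) if args.config else PipelineConfig()
    cfg.seed = args.seed
    linked = pd.read_csv(
        args.out_dir / "exposure.csv",
        dtype={"district_id": str, "country_id": str},
    )
    prev = pd.concat(
        {o: weighted_prevalence(linked, outcome=o) for o in ("lifetime", "recent")},
        names=["outcome"],
    )
    prev.to_csv(args.out_dir / "prevalence.csv")
    print("weighted recent-outcome prevalence by country (%):")
    print(prev.loc["recent", "prevalence_pct"].round(1).to_string())

    summaries, diagnostics = {}, {}
    for cat in CATEGORIES:
        with open(args.out_dir / f"model_{cat}.json") as fh:
            s = json.load(fh)
        summaries[cat] = s
        diagnostics[cat] = {
            "parameters": {
                k: {"rhat": v["rhat"], "ess_bulk": v["ess_bulk"]}
                for k, v in s["parameters"].items()
                if "rhat" in v
            },
            "failing": [],
        }
    flag_cols = CATEGORIES
    distribution = {
        "total": {c: int(linked[c].sum()) for c in flag_cols},
        "exclusive": {
            c: int((linked[c] & (linked[flag_cols].sum(axis=1) == 1)).sum())
            for c in flag_cols
        },
    }
    build_report(summaries, diagnostics, distribution, cfg.echo(), args.out_dir)
    print(f"report written to {args.out_dir / 'report.json'} "
          f"and {args.out_dir / 'report.txt'}")


if __name__ == "__main__":
    main()
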