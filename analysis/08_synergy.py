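#!/usr/bin/env python
"""Jin's combination-index analysis of the published two-drug viability arms.

The default table carries the printed dead-cell fractions for the botanical
drug at two doses (1.69%, 1.79%), the chemotherapeutic alone (30.63%), and
the combinations (47.2%, 52.18%); q > 1.15 scores the combination
synergistic."""

import argparse
from pathlib import Path

import pandas as pd

from phytosig import io, synergy as syn
from phytosig.pipeline import DEFAULT_COMBINATION_ARMS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--combinations", type=Path, default=None,
                    help="CSV with columns label,D1,D2,D12 (effect fractions)")
    ap.add_argument("--outdir", type=Path, default=Path("results/synergy"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    if args.combinations:
        table = io.read_combinations(args.combinations)
    else:
        table = io.CombinationTable(pd.DataFrame(DEFAULT_COMBINATION_ARMS))
    result = syn.evaluate_table(table)
    result.to_csv(args.outdir / "synergy.tsv", sep="\t", index=False)
    print(result[["label", "D1", "D2", "D12", "q_rounded", "interaction"]].to_string(index=False))


if __name__ == "__main__":
    main()
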