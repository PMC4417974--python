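#!/usr/bin/env python
"""Generate the synthetic study: 19 arrays (3 vehicle + 11 treated across
product batches 6J1/6J2/9J1 + 5 single-sample comparator agents), 5,000
probes, 10% differentially expressed at 1 log2 unit, batch shifts of 1 log2
unit, residual noise 0.5. Writes the expression matrix, annotations, the
probe→gene map and the ground-truth record under results/data/."""

import argparse
from pathlib import Path

from phytosig import io, simulate as sim


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    config = sim.SimulationConfig(seed=args.seed)
    matrix, truth = sim.generate_expression(config)
    probe_map = sim.generate_probe_map(config)

    io.write_expression(matrix, args.outdir / "expression.tsv", args.outdir / "annotations.tsv")
    io.write_probe_map(probe_map, args.outdir / "probe_map.tsv")
    truth.to_json(args.outdir / "truth.json")

    n_de = len(truth.de_probes_up) + len(truth.de_probes_down)
    print(f"wrote {matrix.shape[0]} probes x {matrix.shape[1]} samples to {args.outdir}")
    print(
        f"planted: {n_de} DE probes over "
        f"{len(truth.de_genes_up | truth.de_genes_down)} genes "
        f"({len(truth.de_genes_up)} up, {len(truth.de_genes_down)} down)"
    )


if __name__ == "__main__":
    main()
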