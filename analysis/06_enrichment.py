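#!/usr/bin/env python
"""Over-representation analysis of the enriched signature.

Generates a gene-set collection with one planted signature-enriched pathway
plus null background sets, runs the hypergeometric ORA with the retention
filters (p < 0.05, q < 0.05, overlap >= 4), and reports what is retained."""

import argparse
from pathlib import Path

from phytosig import enrichment as enr
from phytosig import io, simulate as sim


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--cliquedir", type=Path, default=Path("results/cliques"))
    ap.add_argument("--outdir", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    probe_map = io.read_probe_map(args.datadir / "probe_map.tsv")
    universe = sorted({s[0] for s in probe_map.values() if len(s) == 1})
    query = io.read_tags(args.cliquedir / "enriched_up.grp") + io.read_tags(
        args.cliquedir / "enriched_down.grp"
    )
    collection = sim.generate_gene_sets(query, universe, seed=args.seed + 211)
    io.write_gmt(collection, args.outdir / "gene_sets.gmt")

    table = enr.run_ora(query, collection, universe)
    table.to_csv(args.outdir / "ora.tsv", sep="\t", index=False)
    retained = table[table["retained"]]
    print(f"query: {len(query)} genes against {len(collection)} sets "
          f"(universe {len(universe)} genes)")
    print(f"retained sets: {list(retained['name'])}")
    top = table.iloc[0]
    print(f"top set {top['name']}: overlap {top['overlap_count']}, "
          f"p = {top['p_hyper']:.3g}, q = {top['q_bh']:.3g}")


if __name__ == "__main__":
    main()
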