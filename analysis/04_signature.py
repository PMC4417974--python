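#!/usr/bin/env python
"""Derive the treatment gene signature from the adjusted 14-sample arm.

Moderated-t significance at P < 0.01, collapse to uniquely mapped gene
symbols, gene-level 1.3-fold criterion; reports the full probe→gene
accounting and, because this is synthetic data, sensitivity/FDR against the
planted truth."""

import argparse
import json
from pathlib import Path

from phytosig import io, signature as sg


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/signature"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    adjusted = io.read_expression(args.datadir / "adjusted.tsv", args.datadir / "annotations.tsv")
    arm = adjusted.subset_samples(
        [s for s, g in adjusted.groups().items() if g in ("vehicle", "treated")]
    )
    probe_map = io.read_probe_map(args.datadir / "probe_map.tsv")
    result = sg.run_signature_stage(arm, probe_map)

    result.stats.to_csv(args.outdir / "stats.tsv", sep="\t")
    io.write_tags(sorted(result.signature.up), args.outdir / "signature_up.grp")
    io.write_tags(sorted(result.signature.down), args.outdir / "signature_down.grp")
    (args.outdir / "accounting.json").write_text(json.dumps(result.accounting, indent=1))

    print(json.dumps(result.accounting, indent=1))
    truth = json.loads((args.datadir / "truth.json").read_text())
    true_up, true_down = set(truth["de_genes_up"]), set(truth["de_genes_down"])
    tp = len(result.signature.up & true_up) + len(result.signature.down & true_down)
    called = len(result.signature.up | result.signature.down)
    print(f"vs planted truth: sensitivity {tp / len(true_up | true_down):.3f}, "
          f"FDR {(called - tp) / max(1, called):.3f}")


if __name__ == "__main__":
    main()
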