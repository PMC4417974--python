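#!/usr/bin/env python
"""Batch-consistency QC of the 16 treated+comparator samples.

Relative-expression transform, all 120 pairwise Pearson correlations,
HCT_R2E-seriated correlation matrix maps, and correlation PCA. The question
the figure answers: do the drug's product batches behave as one homogeneous
group against the comparator agents?"""

import argparse
from pathlib import Path

import pandas as pd

from phytosig import consistency as cons
from phytosig import io, preprocess as pp


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    adjusted = io.read_expression(args.datadir / "adjusted.tsv", args.datadir / "annotations.tsv")
    qc = adjusted.subset_samples(
        [s for s, g in adjusted.groups().items() if g in ("treated", "comparator")]
    )
    rel = pp.relative_expression(qc)
    pairs, summary = cons.pairwise_consistency(rel)
    pairs.to_csv(args.outdir / "pairs.tsv", sep="\t", index=False)

    corr = cons.pearson_matrix(rel, axis="samples")
    seriated = cons.hct_r2e(corr)
    pd.DataFrame({"sample_id": seriated.order}).to_csv(
        args.outdir / "seriation_order.tsv", sep="\t", index=False
    )
    cons.render_matrix_map(corr.values, corr.labels, seriated.order, args.outdir / "corr_sorted.png")
    cons.render_matrix_map(corr.values, corr.labels, corr.labels, args.outdir / "corr_unsorted.png")
    pca = cons.pca_correlation(rel)
    pd.DataFrame(pca.coordinates, index=pca.labels, columns=["pc1", "pc2"]).to_csv(
        args.outdir / "pca.tsv", sep="\t"
    )

    groups = dict(qc.groups())
    treated_block = [s for s in seriated.order if groups[s] == "treated"]
    first = seriated.order.index(treated_block[0])
    contiguous = seriated.order[first : first + len(treated_block)] == treated_block
    print(f"{summary['n_pairs']} sample pairs; r range "
          f"[{summary['min_r']:.4f}, {summary['max_r']:.4f}]")
    print(f"treated samples contiguous in HCT_R2E leaf order: {contiguous}")
    print(f"PC1/PC2 variance fractions: {pca.variance_fractions[0]:.2f}, "
          f"{pca.variance_fractions[1]:.2f}")


if __name__ == "__main__":
    main()
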