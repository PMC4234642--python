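#!/usr/bin/env python
"""Ranked-list GO enrichment scan on a synthetic microarray gene list.

Emulates the microarray arm: a differential-expression-ranked list at array
scale (20 000 genes) carries the M-band (GO:0031430) annotation on 1.6% of
the most up-regulated half but only 0.69% of the most down-regulated half —
the asymmetry reported for the growth-restricted fetal hearts.  Annotations
are propagated up a miniature cellular-component hierarchy, every term is
tested at 30 sliding rank cuts with Fisher's exact test, and p-values are
BH-adjusted jointly.  The M-band block comes out over-represented among
up-regulated genes with raw p far below 0.001; decoy terms stay null.

Run from the repository root:  python analysis/04_geneset_scan.py [--seed 1]
"""

import argparse
from pathlib import Path

from sarcoshg.geneset import (
    AnnotationMap,
    load_mband_genes,
    load_synthetic_go_cc,
    partition_scan,
    summarize_terms,
)
from sarcoshg.simulate import simulate_ranked_list


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=20000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    ranked, amap = simulate_ranked_list(
        args.n_genes,
        block_term="GO:0031430",
        frac_up=0.016,
        frac_down=0.0069,
        seed=args.seed,
        n_decoy_terms=5,
        decoy_size=200,
    )
    amap = AnnotationMap(
        gene_to_terms=amap.gene_to_terms, dag_edges=load_synthetic_go_cc()
    )
    scan = partition_scan(ranked, amap, n_partitions=30)
    scan.to_csv(args.results / "geneset_scan.tsv", sep="\t", index=False)

    summary = summarize_terms(scan)
    print("per-term summary (best partition each):")
    cols = ["term", "cut_rank", "pct_annotated_above", "pct_annotated_below",
            "direction", "p_raw", "p_adj"]
    print(summary[cols].head(8).to_string(index=False))

    best = summary.iloc[0]
    print(
        f"\nM-band block: {best.pct_annotated_above:.2f}% annotated above the best cut vs "
        f"{best.pct_annotated_below:.2f}% below; raw p = {best.p_raw:.2e}, "
        f"BH-adjusted p = {best.p_adj:.2e} ({best.direction}-regulated)"
    )
    print("\nreference M-band genes (reported fold changes):")
    print(load_mband_genes().to_string(index=False))
    print(f"\nwrote {args.results}/geneset_scan.tsv")


if __name__ == "__main__":
    main()
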