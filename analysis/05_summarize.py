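#!/usr/bin/env python
"""Category summaries and the pair matrix heatmap.

Aggregates the scan into one row per lifestyle-pair category (pairs,
hit counts, IS percentage, mosaic counts and medians, trace-count
distribution, null probability) and renders the pair matrix: mosaic
density per 10 kb below the diagonal, mean HR-trace count above,
excluded pairs black.

Usage: python analysis/05_summarize.py [--cohort results/cohort] [--outdir results]
"""

import argparse
from pathlib import Path

import pandas as pd

from mosaicscan import read_fasta, read_metadata
from mosaicscan.genomes import apply_metadata
from mosaicscan.pipeline import RunConfig, run_scan, write_outputs
from mosaicscan.report import render_matrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--proximal-cols", type=int, default=250)
    args = ap.parse_args()

    genomes = read_fasta(args.cohort / "cohort.fasta")
    apply_metadata(genomes, read_metadata(args.cohort / "metadata.tsv"))
    pairs = pd.read_csv(args.cohort / "pairs.tsv", sep="\t")

    config = RunConfig(
        skip_ani=True,
        pairs=list(zip(pairs["g1_id"], pairs["g2_id"])),
        proximal_cols=args.proximal_cols,
    )
    result = run_scan(genomes, config)
    write_outputs(result, args.outdir)
    render_matrix(result.matrix, args.outdir / "pair_matrix.svg")

    shown = result.summaries[result.summaries["n_pairs"] > 0]
    print(shown.to_string(index=False))
    print(f"\nwrote tables and pair_matrix.svg to {args.outdir}")


if __name__ == "__main__":
    main()
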