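#!/usr/bin/env python
"""Scan the cohort for hydrogenase / maturation / nitrogenase homologs.

Exact Smith-Waterman search of every proteome against the query panel,
per-family e-value thresholds, reciprocal-best-hit confirmation against
the query source proteome, and catalytic-residue checks for every present
structural subunit. Writes presence matrix, hits and motif reports under
results/survey/.
"""

import argparse
from pathlib import Path

import pandas as pd

from hydroscan.pipeline import cmd_scan


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genomes", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/survey"))
    args = parser.parse_args()

    cmd_scan(args.genomes, args.outdir)
    matrix = pd.read_csv(args.outdir / "presence_matrix.tsv", sep="\t", index_col=0)
    hits = pd.read_csv(args.outdir / "hits.tsv", sep="\t")
    print(f"scanned {len(matrix)} genomes against {matrix.shape[1]} families")
    print(f"  {len(hits)} hits passed their family thresholds; "
          f"{int(hits.rbh.sum())} reciprocal-best confirmed "
          f"({len(hits) - int(hits.rbh.sum())} paralogous/cross-family rejected)")
    print(f"  present calls: {(matrix == 'P').sum().sum()}, "
          f"degenerate: {(matrix == 'D').sum().sum()}")


if __name__ == "__main__":
    main()
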