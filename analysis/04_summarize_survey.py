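#!/usr/bin/env python
"""Stratified co-occurrence summaries and species-tree annotation.

Reduces each genome to three-state categories (complete / incomplete /
absent) for hox, hup and nif, and tabulates their combinations overall
and stratified by habitat and morphological subsection. If a newick
species tree is supplied, emits a per-leaf annotation table (gene-content
marks, degenerate flags, arrangement labels).
"""

import argparse
from pathlib import Path

import pandas as pd

from hydroscan.pipeline import cmd_summarize


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genomes", type=Path, default=Path("results/cohort"))
    parser.add_argument("--outdir", type=Path, default=Path("results/survey"))
    parser.add_argument("--tree", type=Path, default=None)
    args = parser.parse_args()

    cmd_summarize(args.genomes, args.outdir, tree_path=args.tree)
    for axis in ("overall", "habitat", "subsection"):
        table = pd.read_csv(args.outdir / f"summary_{axis}.tsv", sep="\t")
        print(f"--- {axis} ---")
        for row in table.itertuples(index=False):
            print(f"  {row.stratum:12s} {row.combination:18s} "
                  f"{row.count:3d}/{row.denominator:<3d} "
                  f"{row.percentage_display:3d}%")


if __name__ == "__main__":
    main()
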