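#!/usr/bin/env python
"""Curate the leaf alignment for reconstruction: strip insertion columns
supported by at most one leaf, then remove divergent blocks.

Gapped columns are retained (allow_gaps) because the downstream indel
reconstruction needs them; the block filter still removes runs of
non-conserved columns.  Writes the curated alignment plus the block report
and the kept-column map back to the original simulation coordinates, which
the later recovery comparison uses.
"""

import argparse
import json
from pathlib import Path

from carasr.alignment import (
    gblocks_filter,
    read_fasta_alignment,
    strip_rare_insertion_columns,
    write_fasta_alignment,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/curated"))
    ap.add_argument("--max-support", type=int, default=1)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    msa = read_fasta_alignment(args.in_dir / "alignment.fasta")
    n0 = msa.n_columns
    msa, removed = strip_rare_insertion_columns(msa, args.max_support)
    kept_after_strip = [j for j in range(n0) if j not in set(removed)]
    msa, report = gblocks_filter(msa, allow_gaps=True)
    kept = [kept_after_strip[j] for j in report.kept_columns]

    write_fasta_alignment(msa, args.out_dir / "alignment.fasta")
    report.to_frame().to_csv(args.out_dir / "blocks.tsv", sep="\t", index=False)
    (args.out_dir / "kept_columns.json").write_text(json.dumps(kept))
    print(f"curation: {n0} -> {len(kept_after_strip)} (insertion strip, "
          f"{len(removed)} columns) -> {msa.n_columns} (block filter, "
          f"{len(report.kept_intervals)} blocks)")


if __name__ == "__main__":
    main()
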