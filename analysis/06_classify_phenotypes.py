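#!/usr/bin/env python
"""Phenotype classification of the transcribed strain summary table:
growth groups (purine/8-azaguanine), functional categories from V%, and
growth/uptake concordance.
"""

import argparse
from pathlib import Path

import mutscan as ms


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    summary = ms.build_summary(ms.table1_fixture())
    summary.table.to_csv(args.outdir / "phenotype_summary.tsv",
                         sep="\t", index=False)

    print(summary.table.to_string(index=False))
    print(f"\nmutant category counts: {summary.category_counts}")
    n_diff = int(
        (summary.table[~summary.table.is_control].category != "equivalent").sum()
    )
    print(f"mutants differing from wild type: {n_diff}")
    print(f"distinct growth groups: {len(summary.growth_groups)} "
          f"{summary.growth_groups}")
    print(f"discordant strains: {summary.discordant or 'none'}")
    print(f"wrote phenotype_summary.tsv to {args.outdir}/")


if __name__ == "__main__":
    main()
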