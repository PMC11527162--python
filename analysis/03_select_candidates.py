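#!/usr/bin/env python
"""Nominate mutagenesis candidates within the derived motifs.

Takes the first two characterized sequences of the synthetic family as
target and reference orthologs, lists their residue differences, applies
the exclusion rules (invariant / conserved-in-plant-and-fungal /
too-variable / must-differ) over the substrate-binding motifs, and
annotates the survivors with synthetic topology segments.
"""

import argparse
from pathlib import Path

import mutscan as ms
from mutscan.selection import candidates_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results"))
    ap.add_argument("--motifs", nargs="*", default=["M2", "M4"],
                    help="motif ids to restrict selection to")
    args = ap.parse_args()

    family = ms.read_alignment(
        args.indir / "family.fasta", "fasta",
        ms.read_group_map(args.indir / "family_groups.tsv"),
    )
    target, reference = family.ids[0], family.ids[1]
    profile = ms.compute_profile(family)
    motifs = ms.derive_motifs(profile)
    diffs = ms.pairwise_differences(family, target, reference)
    print(f"{target} vs {reference}: {len(diffs)} differing columns")

    candidates, audits = ms.select_candidates(
        family, profile, motifs, diffs, target,
        ms.SelectionParams(restrict_to_motifs=args.motifs),
    )
    kept = sum(a.kept for a in audits)
    print(f"audited {len(audits)} motif columns: {kept} kept, "
          f"{len(audits) - kept} discarded")

    annotated = ms.annotate_topology(candidates, ms.synthetic_topology())
    frame = candidates_to_frame(annotated)
    frame.to_csv(args.indir / "candidates.tsv", sep="\t", index=False)
    for c, loc in annotated:
        print(f"  candidate {c.mutation_name} (motif {c.motif_id}, {loc})")
    print(f"wrote candidates.tsv to {args.indir}/")


if __name__ == "__main__":
    main()
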