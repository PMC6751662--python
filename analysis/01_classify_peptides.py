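#!/usr/bin/env python
"""Classify the peptide panel by C-terminal motif and align the C-termini.

Writes the curated panel as FASTA, a motif-class table, and a right-anchored
C-terminal alignment with Lesk color categories, and demonstrates the
penultimate-Arg-to-Ala control peptides used to break RFamide motifs.
"""

import argparse
from pathlib import Path

import pandas as pd

from flpnpr.panels import CURATED_PEPTIDES
from flpnpr.peptides import (
    align_cterm,
    alignment_to_text,
    classify_motif,
    penultimate_arg_to_ala,
    write_fasta,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    write_fasta(CURATED_PEPTIDES, args.outdir / "peptides.fasta")

    rows = []
    for p in CURATED_PEPTIDES:
        mut = None
        if p.sequence[-2] == "R":
            mut = penultimate_arg_to_ala(p)
        rows.append(
            {
                "id": p.id,
                "species": p.species,
                "sequence": p.sequence,
                "amidated": p.amidated,
                "motif_class": classify_motif(p).value,
                "arg_to_ala_control": mut.id if mut else "",
                "control_class": classify_motif(mut).value if mut else "",
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "motif_classes.tsv", sep="\t", index=False)

    aln = align_cterm(CURATED_PEPTIDES)
    text = alignment_to_text(aln)
    (args.outdir / "cterm_alignment.txt").write_text(text + "\n")

    print("C-terminal alignment (right-anchored):")
    print(text)
    print()
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
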