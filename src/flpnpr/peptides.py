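"""Amidated neuropeptides: C-terminal motif classification, C-terminus-anchored
alignment, and penultimate-Arg-to-Ala control peptides.

RFamide peptides are grouped by the last four residues of the amidated
C-terminus: NPF/Y-type carry R-x-R-F/Y (the NPY-family hallmark),
FMRFamide-type carry aromatic-hydrophobic-R-F, and short-NPF-type carry
hydrophobic-hydrophobic-R-F. The penultimate arginine is essential for
receptor activation, which the R->A control peptides probe.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: aromatic residues (Omega in motif notation); His excluded by default
AROMATIC = frozenset("FWY")
#: hydrophobic residues (Psi); Gly/Pro excluded by default
HYDROPHOBIC = frozenset("AVLIMFWC")

#: Lesk residue property categories (as used to color alignments)
LESK_CATEGORIES = {
    **{aa: "small_nonpolar" for aa in "GAST"},
    **{aa: "hydrophobic" for aa in "CVILPFYMW"},
    **{aa: "polar" for aa in "NQH"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "positive" for aa in "KR"},
}

PAD = "-"


class MotifClass(enum.Enum):
    """C-terminal consensus class of an amidated peptide."""

    NPF_Y_LIKE = "RxRF/Ya"
    FMRFAMIDE = "OmegaPsiRFa"
    SNPF = "PsiPsiRFa"
    OTHER = "other"


@dataclass(frozen=True)
class Peptide:
    """One peptide isoform, N-to-C one-letter sequence, with amidation state."""

    id: str
    sequence: str
    amidated: bool = True
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def classify_motif(
    p: Peptide,
    aromatic: frozenset[str] = AROMATIC,
    hydrophobic: frozenset[str] = HYDROPHOBIC,
) -> MotifClass:
    """Classify a peptide by its last four residues.

    Requires amidation; peptides shorter than four residues are OTHER.
    Precedence: NPF/Y-like (R at -4, R at -2, F/Y at -1) over FMRFamide-type
    (aromatic at -4) over sNPF-type (hydrophobic at -4), so the NPY-hallmark
    second arginine wins whenever present.
    """
    if not p.amidated or len(p.sequence) < 4:
        return MotifClass.OTHER
    r4, r3, r2, r1 = p.sequence[-4:]
    if r4 == "R" and r2 == "R" and r1 in "FY":
        return MotifClass.NPF_Y_LIKE
    if r4 in aromatic and r3 in hydrophobic and r2 == "R" and r1 == "F":
        return MotifClass.FMRFAMIDE
    if r4 in hydrophobic and r3 in hydrophobic and r2 == "R" and r1 == "F":
        return MotifClass.SNPF
    return MotifClass.OTHER


@dataclass(frozen=True)
class CTermAlignment:
    """Right-anchored alignment of a peptide panel."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]  # equal-width, padded on the N-terminal side
    width: int

    def lesk_rows(self) -> tuple[tuple[str, ...], ...]:
        """Per-residue Lesk property categories; padding maps to ''."""
        return tuple(
            tuple(LESK_CATEGORIES.get(ch, "") for ch in row) for row in self.rows
        )


def align_cterm(panel: Sequence[Peptide]) -> CTermAlignment:
    """Right-justify a panel to the (amidated) C-terminus."""
    if not panel:
        raise ValueError("panel must be non-empty")
    width = max(len(p) for p in panel)
    rows = tuple(PAD * (width - len(p)) + p.sequence for p in panel)
    return CTermAlignment(ids=tuple(p.id for p in panel), rows=rows, width=width)


def penultimate_arg_to_ala(p: Peptide) -> Peptide:
    """Exchange the penultimate arginine for alanine (control peptide).

    The id is suffixed ``[R{n}A]`` with the 1-based position of the exchanged
    residue, following mutant-peptide nomenclature.
    """
    if len(p.sequence) < 2 or p.sequence[-2] != "R":
        raise ValueError(f"{p.id!r} lacks the penultimate arginine")
    n = len(p.sequence) - 1  # 1-based position of residue -2
    seq = p.sequence[:-2] + "A" + p.sequence[-1]
    return replace(p, id=f"{p.id}[R{n}A]", sequence=seq)


# ---------------------------------------------------------------------------
# FASTA I/O; amidation encoded as an "amidated" token in the description
# ---------------------------------------------------------------------------


def write_fasta(panel: Iterable[Peptide], path: str | Path) -> None:
    records = []
    for p in panel:
        desc = " ".join(
            x for x in (("amidated" if p.amidated else "free-acid"), p.species) if x
        )
        records.append(SeqRecord(Seq(p.sequence), id=p.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[Peptide]:
    panel = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc_tokens = rec.description.split()[1:]  # first token repeats the id
        amidated = "amidated" in desc_tokens
        species = ""
        rest = [t for t in desc_tokens if t not in ("amidated", "free-acid")]
        if rest:
            species = rest[0]
        panel.append(
            Peptide(id=rec.id, sequence=str(rec.seq), amidated=amidated, species=species)
        )
    return panel


def alignment_to_text(aln: CTermAlignment) -> str:
    pad = max(len(i) for i in aln.ids) + 2
    return "\n".join(f"{i:<{pad}}{row}" for i, row in zip(aln.ids, aln.rows)) + "\n"
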