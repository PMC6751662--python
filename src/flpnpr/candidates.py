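"""Matrix-intersection inference of candidate in vivo ligands.

When heterologous receptors can functionally substitute a receptor in vivo,
the peptides that activate BOTH the native receptor and every substituting
(rescuing) receptor are the candidates for mediating the rescued behavior.
Non-rescuing receptors serve as specificity controls and can optionally be
used as an exclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .screen import GRADE_ORDER, InteractionMatrix


@dataclass(frozen=True)
class RescuePanel:
    """Outcome of a heterologous-rescue experiment for one target receptor."""

    target_receptor_id: str
    rescuing_receptor_ids: tuple[str, ...]
    non_rescuing_receptor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sets = [
            {self.target_receptor_id},
            set(self.rescuing_receptor_ids),
            set(self.non_rescuing_receptor_ids),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("target, rescuing and non-rescuing sets must be disjoint")


def infer_candidates(
    matrix: InteractionMatrix,
    panel: RescuePanel,
    min_grade: str = "i",
    exclude_non_rescuers: bool = False,
) -> list[str]:
    """Peptides active (grade >= ``min_grade``) at the target AND at every
    rescuing receptor, strongest first.

    Partial-agonist (asterisk) cells count by their grade: a flagged
    high-affinity partial agonist is a legitimate candidate. With
    ``exclude_non_rescuers`` peptides also active at every non-rescuing
    receptor are dropped (strict specificity mode).
    """
    if min_grade not in GRADE_ORDER or min_grade == "none":
        raise ValueError(f"min_grade must be one of i..v, got {min_grade!r}")
    if not panel.rescuing_receptor_ids:
        raise ValueError("rescuing receptor set is empty; inference undefined")
    required = (panel.target_receptor_id,) + tuple(panel.rescuing_receptor_ids)
    for receptor in required + tuple(panel.non_rescuing_receptor_ids):
        if receptor not in matrix.receptors:
            raise ValueError(f"receptor {receptor!r} absent from the matrix")

    threshold = GRADE_ORDER[min_grade]
    candidates: list[tuple[int, str]] = []
    for peptide in matrix.peptides:
        grades = [GRADE_ORDER[matrix.grade(peptide, r)] for r in required]
        if min(grades) < threshold:
            continue
        if exclude_non_rescuers and panel.non_rescuing_receptor_ids:
            non = [
                GRADE_ORDER[matrix.grade(peptide, r)]
                for r in panel.non_rescuing_receptor_ids
            ]
            if min(non) >= threshold:  # active at ALL specificity controls
                continue
        candidates.append((min(grades), peptide))
    # strongest minimum grade first; alphabetical tie-break for determinism
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [p for _, p in candidates]
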