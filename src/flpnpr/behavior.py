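"""Behavioral assay statistics: quadrant avoidance index, lawn bordering,
and the plate-level group comparisons used for rescue claims.

The statistical unit throughout is the plate: indices are computed per plate
and genotypes are compared on per-plate values (one-way ANOVA with Bonferroni
post-hoc against a reference genotype, or an unpaired t-test for two groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QuadrantCounts:
    """Worm counts from one four-quadrant avoidance plate."""

    plate_id: str
    genotype: str
    n_mesa: int
    n_eoh: int
    n_total: int

    def __post_init__(self) -> None:
        if min(self.n_mesa, self.n_eoh, self.n_total) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_mesa + self.n_eoh > self.n_total:
            raise ValueError("n_mesa + n_eoh cannot exceed n_total")


@dataclass(frozen=True)
class LawnCounts:
    """Worms within the 2 mm lawn-border zone vs. total on one plate."""

    plate_id: str
    genotype: str
    n_border: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_border < 0 or self.n_total < 0:
            raise ValueError("counts must be >= 0")
        if self.n_border > self.n_total:
            raise ValueError("n_border cannot exceed n_total")


SignConvention = Literal["as_printed", "avoidance_positive"]


def avoidance_index(
    counts: QuadrantCounts,
    sign_convention: SignConvention = "as_printed",
    include_unscored: bool = False,
) -> float:
    """Avoidance index of one plate.

    ``as_printed`` follows the assay definition literally: (worms on the
    methyl-salicylate sides - worms on the ethanol sides) / total, so avoiders
    score negative. ``avoidance_positive`` negates it so stronger avoidance is
    larger. By default the denominator is the scored worms (azide paralysis
    captures essentially all animals at endpoint); ``include_unscored`` uses
    the full plate total instead.
    """
    denom = counts.n_total if include_unscored else counts.n_mesa + counts.n_eoh
    if denom == 0:
        raise ValueError("no scored worms: total is zero")
    ai = (counts.n_mesa - counts.n_eoh) / denom
    return -ai if sign_convention == "avoidance_positive" else ai


def bordering_fraction(counts: LawnCounts) -> float:
    """Fraction of animals within the 2 mm border zone of the lawn."""
    if counts.n_total == 0:
        raise ValueError("n_total must be > 0")
    return counts.n_border / counts.n_total


@dataclass(frozen=True)
class GroupComparison:
    """Per-genotype summary plus adjusted comparisons against a reference."""

    genotypes: tuple[str, ...]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    ns: Mapping[str, int]
    reference: str
    test: str  # "anova_bonferroni" or "t_test"
    anova_p: float | None
    p_adjusted: Mapping[str, float]  # genotype -> p vs reference
    significant: Mapping[str, bool]
    stars: Mapping[str, str]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    values_by_genotype: Mapping[str, Sequence[float]],
    reference: str,
    method: Literal["auto", "anova_bonferroni", "t_test"] = "auto",
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare per-plate values of each genotype against a reference.

    With exactly two groups (or ``method="t_test"``) an unpaired two-sided
    Student t-test is used. Otherwise a one-way ANOVA is followed by pairwise
    t-tests against the reference with Bonferroni adjustment over the number
    of comparisons.
    """
    if reference not in values_by_genotype:
        raise ValueError(f"reference genotype {reference!r} not in data")
    if len(values_by_genotype) < 2:
        raise ValueError("need at least two genotypes to compare")
    for g, v in values_by_genotype.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 plates (no variance)")

    genotypes = tuple(sorted(values_by_genotype))
    arrays = {g: np.asarray(values_by_genotype[g], dtype=float) for g in genotypes}
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}
    ns = {g: int(a.size) for g, a in arrays.items()}

    others = [g for g in genotypes if g != reference]
    if method == "t_test" or (method == "auto" and len(genotypes) == 2):
        test = "t_test"
        anova_p = None
        p_adj = {}
        for g in others:
            _, p = stats.ttest_ind(arrays[g], arrays[reference], equal_var=True)
            p_adj[g] = float(min(1.0, p))
    else:
        test = "anova_bonferroni"
        _, anova_p = stats.f_oneway(*arrays.values())
        anova_p = float(anova_p)
        m = len(others)
        p_adj = {}
        for g in others:
            _, p = stats.ttest_ind(arrays[g], arrays[reference], equal_var=True)
            p_adj[g] = float(min(1.0, p * m))

    significant = {g: p_adj[g] < alpha for g in others}
    stars = {g: _stars(p_adj[g]) for g in others}
    return GroupComparison(
        genotypes=genotypes,
        means=means,
        sds=sds,
        ns=ns,
        reference=reference,
        test=test,
        anova_p=anova_p,
        p_adjusted=p_adj,
        significant=significant,
        stars=stars,
    )


def plate_indices(
    plates: Sequence[QuadrantCounts],
    sign_convention: SignConvention = "as_printed",
) -> dict[str, list[float]]:
    """Per-genotype lists of plate avoidance indices."""
    out: dict[str, list[float]] = {}
    for p in plates:
        out.setdefault(p.genotype, []).append(avoidance_index(p, sign_convention))
    return out


def plate_bordering(plates: Sequence[LawnCounts]) -> dict[str, list[float]]:
    """Per-genotype lists of plate bordering fractions."""
    out: dict[str, list[float]] = {}
    for p in plates:
        out.setdefault(p.genotype, []).append(bordering_fraction(p))
    return out
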