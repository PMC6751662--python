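"""Readers and writers for the pipeline's tabular and JSON artifacts.

Formats: long-format plate tables (TSV; columns receptor, pathway, peptide,
conc_M, experiment, replicate, signal), interaction matrices (long TSV with
grade tokens and an asterisk column, and a lossless JSON with full call
objects), dose-response fit tables, behavioral count tables, and group
comparisons. Concentrations are stored in molar, scientific notation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .behavior import GroupComparison, LawnCounts, QuadrantCounts
from .curves import DoseResponseFit
from .screen import ActivationCall, GRADES, InteractionMatrix
from .synth import PlateRecord

PLATE_COLUMNS = [
    "receptor",
    "pathway",
    "peptide",
    "conc_M",
    "experiment",
    "replicate",
    "signal",
]


def plate_records_to_df(records: Sequence[PlateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "receptor": [r.receptor_id for r in records],
            "pathway": [r.pathway for r in records],
            "peptide": [r.peptide_id for r in records],
            "conc_M": [r.concentration for r in records],
            "experiment": [r.experiment_id for r in records],
            "replicate": [r.replicate_id for r in records],
            "signal": [r.signal for r in records],
        }
    )


def write_plate_tsv(records: Sequence[PlateRecord], path: str | Path) -> None:
    df = plate_records_to_df(records)
    df["conc_M"] = df["conc_M"].map(lambda c: f"{c:.6e}")
    df["signal"] = df["signal"].map(lambda s: repr(float(s)))
    df.to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str | Path) -> list[PlateRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate-table column(s) {missing}")
    if df.empty:
        raise ValueError(f"{path}: plate table is empty")
    return [
        PlateRecord(
            receptor_id=str(row.receptor),
            pathway=str(row.pathway),
            peptide_id=str(row.peptide),
            concentration=float(row.conc_M),
            experiment_id=int(row.experiment),
            replicate_id=int(row.replicate),
            signal=float(row.signal),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# interaction matrix
# ---------------------------------------------------------------------------


def _call_to_dict(c: ActivationCall) -> dict:
    return {
        "receptor_id": c.receptor_id,
        "peptide_id": c.peptide_id,
        "pathway": c.pathway,
        "active_low": c.active_low,
        "active_high": c.active_high,
        "frac_low": None if math.isnan(c.frac_low) else c.frac_low,
        "frac_high": None if math.isnan(c.frac_high) else c.frac_high,
        "grade": c.grade,
        "partial_agonist": c.partial_agonist,
    }


def _call_from_dict(d: dict) -> ActivationCall:
    return ActivationCall(
        receptor_id=d["receptor_id"],
        peptide_id=d["peptide_id"],
        pathway=d["pathway"],
        active_low=bool(d["active_low"]),
        active_high=bool(d["active_high"]),
        frac_low=float("nan") if d["frac_low"] is None else float(d["frac_low"]),
        frac_high=float("nan") if d["frac_high"] is None else float(d["frac_high"]),
        grade=d["grade"],
        partial_agonist=bool(d["partial_agonist"]),
    )


def write_matrix_json(matrix: InteractionMatrix, path: str | Path) -> None:
    payload = {
        "peptides": list(matrix.peptides),
        "receptors": list(matrix.receptors),
        "calls": [_call_to_dict(matrix.calls[(p, r)])
                  for p in matrix.peptides for r in matrix.receptors],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_matrix_json(path: str | Path) -> InteractionMatrix:
    payload = json.loads(Path(path).read_text())
    calls = {}
    for d in payload["calls"]:
        c = _call_from_dict(d)
        calls[(c.peptide_id, c.receptor_id)] = c
    return InteractionMatrix(
        peptides=tuple(payload["peptides"]),
        receptors=tuple(payload["receptors"]),
        calls=calls,
    )


def write_matrix_tsv(matrix: InteractionMatrix, path: str | Path) -> None:
    """Long-format matrix: peptide, receptor, grade token (0 for none),
    asterisk flag."""
    rows = []
    for p in matrix.peptides:
        for r in matrix.receptors:
            c = matrix.calls[(p, r)]
            rows.append(
                {
                    "peptide": p,
                    "receptor": r,
                    "grade": "0" if c.grade == "none" else c.grade,
                    "asterisk": c.partial_agonist,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def matrix_to_grid(matrix: InteractionMatrix) -> pd.DataFrame:
    """Peptide x receptor grid of grade tokens, asterisk appended (e.g. iii*)."""
    grid = {}
    for r in matrix.receptors:
        col = []
        for p in matrix.peptides:
            c = matrix.calls[(p, r)]
            tok = "0" if c.grade == "none" else c.grade
            col.append(tok + ("*" if c.partial_agonist else ""))
        grid[r] = col
    return pd.DataFrame(grid, index=list(matrix.peptides))


# ---------------------------------------------------------------------------
# dose-response fits, behavioral tables, comparisons
# ---------------------------------------------------------------------------


def fits_to_df(fits: Sequence[DoseResponseFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "receptor": [f.receptor_id for f in fits],
            "peptide": [f.peptide_id for f in fits],
            "pathway": [f.pathway for f in fits],
            "ec50_M": [f.ec50 for f in fits],
            "log10_ec50_se": [f.log10_ec50_se for f in fits],
            "hill": [f.hill for f in fits],
            "hill_se": [f.hill_se for f in fits],
            "bottom": [f.bottom for f in fits],
            "top": [f.top for f in fits],
            "emax_pct_reference": [f.emax_pct_reference for f in fits],
            "reference_peptide": [f.reference_peptide_id for f in fits],
            "converged": [f.converged for f in fits],
        }
    )


def write_fits_tsv(fits: Sequence[DoseResponseFit], path: str | Path) -> None:
    fits_to_df(fits).to_csv(path, sep="\t", index=False)


def read_fits_tsv(path: str | Path) -> list[DoseResponseFit]:
    df = pd.read_csv(path, sep="\t")
    required = ["receptor", "peptide", "pathway", "ec50_M", "log10_ec50_se",
                "hill", "hill_se", "bottom", "top", "emax_pct_reference",
                "reference_peptide", "converged"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for r in df.itertuples():
        emax = None if pd.isna(r.emax_pct_reference) else float(r.emax_pct_reference)
        ref = None if pd.isna(r.reference_peptide) else str(r.reference_peptide)
        out.append(
            DoseResponseFit(
                receptor_id=str(r.receptor), peptide_id=str(r.peptide),
                pathway=str(r.pathway), ec50=float(r.ec50_M),
                log10_ec50_se=float(r.log10_ec50_se), hill=float(r.hill),
                hill_se=float(r.hill_se), bottom=float(r.bottom),
                top=float(r.top), converged=bool(r.converged),
                emax_pct_reference=emax, reference_peptide_id=ref,
            )
        )
    return out


def write_quadrant_tsv(plates: Sequence[QuadrantCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plate": [p.plate_id for p in plates],
            "genotype": [p.genotype for p in plates],
            "n_mesa": [p.n_mesa for p in plates],
            "n_eoh": [p.n_eoh for p in plates],
            "n_total": [p.n_total for p in plates],
        }
    ).to_csv(path, sep="\t", index=False)


def read_quadrant_tsv(path: str | Path) -> list[QuadrantCounts]:
    df = pd.read_csv(path, sep="\t")
    required = ["plate", "genotype", "n_mesa", "n_eoh", "n_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        QuadrantCounts(str(r.plate), str(r.genotype), int(r.n_mesa), int(r.n_eoh), int(r.n_total))
        for r in df.itertuples()
    ]


def write_lawn_tsv(plates: Sequence[LawnCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "plate": [p.plate_id for p in plates],
            "genotype": [p.genotype for p in plates],
            "n_border": [p.n_border for p in plates],
            "n_total": [p.n_total for p in plates],
        }
    ).to_csv(path, sep="\t", index=False)


def read_lawn_tsv(path: str | Path) -> list[LawnCounts]:
    df = pd.read_csv(path, sep="\t")
    required = ["plate", "genotype", "n_border", "n_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        LawnCounts(str(r.plate), str(r.genotype), int(r.n_border), int(r.n_total))
        for r in df.itertuples()
    ]


def comparison_to_dict(c: GroupComparison) -> dict:
    return {
        "genotypes": list(c.genotypes),
        "reference": c.reference,
        "test": c.test,
        "anova_p": c.anova_p,
        "means": dict(c.means),
        "sds": dict(c.sds),
        "ns": dict(c.ns),
        "p_adjusted": dict(c.p_adjusted),
        "significant": dict(c.significant),
        "stars": dict(c.stars),
    }


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
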