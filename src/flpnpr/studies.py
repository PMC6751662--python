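"""Simulation studies that validate the pipeline end to end.

Each study simulates data from a known ground truth and measures how well the
analysis recovers it: concentration-response parameter recovery, agreement of
the grading engine with an independently written brute-force grading table,
known-truth interaction-matrix recovery, empirical type-I error of the
statistical tests under null simulations, and equivalence of candidate
inference with brute-force set intersection. The oracles used here
(``oracle_grade``, ``bruteforce_candidates``) are deliberately written as
direct transliterations of the calling rules, independent of the pipeline
implementations they check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .behavior import compare_groups, plate_indices
from .candidates import RescuePanel, infer_candidates
from .config import PanelSpec, ReceptorSpec
from .curves import fit_4pl, normalize_emax
from .panels import demo_ground_truth, demo_panel_spec
from .screen import (
    ActivationCall,
    GRADE_ORDER,
    GRADES,
    InteractionMatrix,
    call_matrix,
    grade_pair,
    normalize,
    test_activation,
)
from .synth import (
    AvoidanceTruth,
    GroundTruthPharmacology,
    PharmEntry,
    ReceptorWindow,
    ScreenDesign,
    simulate_avoidance_plates,
    simulate_screen,
)

# ---------------------------------------------------------------------------
# concentration-response parameter recovery
# ---------------------------------------------------------------------------

#: (receptor, pathway, peptide, reference peptide, true EC50 [M], true Emax
#: [% of reference]) for the well-characterized pairs of the demo pharmacology
RECOVERY_TARGETS = [
    ("NPR-1", "Gio_cAMP_fsk", "FLP-21", "FLP-21", 1e-9, 100.0),
    ("NPR-1", "Gio_cAMP_fsk", "FLP-14", "FLP-21", 24e-9, 53.0),
    ("NPR-11", "Dqi4myr_IP", "FLP-34-1", "FLP-21", 19e-9, 100.0),
    ("NPR-11", "Dqi4myr_IP", "FLP-34-2", "FLP-21", 0.7e-9, 100.0),
    ("NPR-11", "Dqi4myr_IP", "PYY", "FLP-21", 24e-9, 86.0),
    ("NPR-11", "Dqi4myr_IP", "NPY", "FLP-21", 256e-9, 49.0),
]

#: eight-point curve spanning seven decades, bracketing every target EC50 by
#: at least two decades on each side
CURVE_CONCENTRATIONS = tuple(np.logspace(-11.5, -4.5, 8))


@dataclass(frozen=True)
class RecoveryResult:
    receptor_id: str
    peptide_id: str
    true_ec50: float
    true_emax_pct: float
    median_ec50: float
    median_emax_pct: float
    n_seeds: int

    @property
    def log10_ec50_error(self) -> float:
        return abs(math.log10(self.median_ec50) - math.log10(self.true_ec50))

    @property
    def emax_pct_error(self) -> float:
        return abs(self.median_emax_pct - self.true_emax_pct)


def recovery_study(n_seeds: int = 50, seed0: int = 0, noise_cv: float = 0.10) -> list[RecoveryResult]:
    """Simulate full curves from the demo pharmacology and re-fit them.

    For each seed: 8-point curves, 3 experiments x technical triplicates, the
    given per-well CV. EC50 and reference-normalized Emax are summarized as
    medians over seeds.
    """
    truth = demo_ground_truth()
    strata = {(r, pw) for r, pw, *_ in RECOVERY_TARGETS}
    peptides_by_stratum = {
        s: tuple(sorted({p for r, pw, p, ref, *_ in RECOVERY_TARGETS for p in (p, ref)
                         if (r, pw) == s}))
        for s in strata
    }
    estimates: dict[tuple[str, str], list[tuple[float, float]]] = {
        (r, p): [] for r, _pw, p, *_ in RECOVERY_TARGETS
    }

    for i in range(n_seeds):
        fits: dict[tuple[str, str], object] = {}
        for j, ((receptor, pathway), peps) in enumerate(sorted(peptides_by_stratum.items())):
            design = ScreenDesign(
                concentrations=CURVE_CONCENTRATIONS,
                noise_cv=noise_cv,
                seed=seed0 + 1000 * i + j,
                strata=((receptor, pathway),),
                peptides=peps,
            )
            records = simulate_screen(truth, design)
            responses = [r for r in normalize(records) if not r.is_control]
            for pep in peps:
                pts = [r for r in responses if r.peptide_id == pep]
                concs, folds = [], []
                for r in pts:
                    concs.extend([r.concentration] * len(r.well_folds))
                    folds.extend(r.well_folds)
                fits[(receptor, pep)] = fit_4pl(
                    concs, folds, receptor_id=receptor, peptide_id=pep, pathway=pathway
                )
        for receptor, _pw, pep, ref, *_ in RECOVERY_TARGETS:
            fit = fits[(receptor, pep)]
            ref_fit = fits[(receptor, ref)]
            if not fit.converged or not ref_fit.converged:
                continue
            emax = normalize_emax(fit, ref_fit)
            estimates[(receptor, pep)].append((fit.ec50, emax))

    results = []
    for receptor, _pw, pep, _ref, ec50, emax in RECOVERY_TARGETS:
        vals = estimates[(receptor, pep)]
        results.append(
            RecoveryResult(
                receptor_id=receptor,
                peptide_id=pep,
                true_ec50=ec50,
                true_emax_pct=emax,
                median_ec50=float(np.median([v[0] for v in vals])),
                median_emax_pct=float(np.median([v[1] for v in vals])),
                n_seeds=len(vals),
            )
        )
    return results


# ---------------------------------------------------------------------------
# grading-engine oracle equivalence
# ---------------------------------------------------------------------------


def oracle_grade(
    active_low: bool,
    active_high: bool,
    frac_low: float,
    frac_high: float,
    full: float = 0.8,
    mid: float = 0.35,
    delta: float = 0.10,
) -> tuple[str, bool]:
    """Brute-force transliteration of the verbal grading table.

    Kept independent of :func:`flpnpr.screen.grade_pair` on purpose: it is
    the oracle the engine is validated against.
    """
    if not active_low and not active_high:
        return "none", False
    asterisk = bool(
        active_low and active_high
        and abs(frac_high - frac_low) <= delta
        and frac_high < full
    )
    if active_low and frac_low >= full:
        return "v", asterisk
    if active_low and active_high and frac_high >= full:
        return "iv", asterisk
    if active_low and active_high and frac_high < full:
        return "iii", asterisk
    if not active_low and active_high and frac_high >= mid:
        return "ii", asterisk
    if not active_low and active_high and frac_high < mid:
        return "i", asterisk
    # active at the low concentration only: no explicit verbal slot; mid grade
    return "iii", asterisk


def grade_oracle_sweep(n: int = 10_000, seed: int = 0) -> dict:
    """Noise-free sweep of (EC50, Emax, window) triples: grade_pair vs oracle.

    Activity is pure thresholding (significance is moot without noise); the
    fraction of window uses the closed-form receptor maximum of a full
    agonist at the top concentration.
    """
    rng = np.random.default_rng(seed)
    c_low, c_high = 1e-7, 1e-5
    agree = 0
    for _ in range(n):
        ec50 = 10.0 ** rng.uniform(-10, -3)
        emax = rng.uniform(0.1, 1.0)
        window = rng.uniform(3.0, 30.0)

        def fold(c):
            occ = c / (c + ec50)
            return 1.0 + (window - 1.0) * emax * occ

        # receptor maximum: the full-agonist plateau of the window
        max_fold = window
        frac_low = (fold(c_low) - 1.0) / (max_fold - 1.0)
        frac_high = (fold(c_high) - 1.0) / (max_fold - 1.0)
        a_low = fold(c_low) >= 2.0
        a_high = fold(c_high) >= 2.0
        if grade_pair(a_low, a_high, frac_low, frac_high) == oracle_grade(
            a_low, a_high, frac_low, frac_high
        ):
            agree += 1
    return {"n": n, "agree": agree, "agreement": agree / n}


# ---------------------------------------------------------------------------
# known-truth matrix recovery
# ---------------------------------------------------------------------------

#: designed fixture: one peptide per grade plus an asterisk case and an inert
#: control, on a single stimulatory receptor (window 10x)
FIXTURE_EXPECTED = {
    "g_i": "i",
    "g_ii": "ii",
    "g_iii": "iii",
    "g_iv": "iv",
    "g_v": "v",
    "g_star": "iii",
    "inert": "none",
}
FIXTURE_ASTERISK = "g_star"


def fixture_truth() -> GroundTruthPharmacology:
    return GroundTruthPharmacology(
        entries={
            ("R1", "g_i", "Gs_cAMP"): PharmEntry(ec50=50e-6, emax=1.0),
            ("R1", "g_ii", "Gs_cAMP"): PharmEntry(ec50=8e-6, emax=1.0),
            ("R1", "g_iii", "Gs_cAMP"): PharmEntry(ec50=100e-9, emax=0.6),
            ("R1", "g_iv", "Gs_cAMP"): PharmEntry(ec50=500e-9, emax=1.0),
            ("R1", "g_v", "Gs_cAMP"): PharmEntry(ec50=10e-9, emax=1.0),
            ("R1", "g_star", "Gs_cAMP"): PharmEntry(ec50=5e-9, emax=0.5),
        },
        receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
    )


def fixture_panel() -> PanelSpec:
    return PanelSpec(
        receptors=[ReceptorSpec(id="R1", species="celegans", pathway="Gs_cAMP")],
        peptides=sorted(FIXTURE_EXPECTED),
    )


def matrix_recovery_study(n_seeds: int = 100, seed0: int = 0, noise_cv: float = 0.05) -> dict:
    """Simulate the per-grade fixture and measure exact grade recovery."""
    truth = fixture_truth()
    panel = fixture_panel()
    n_cells = 0
    n_correct = 0
    n_asterisk = 0
    for i in range(n_seeds):
        design = ScreenDesign(
            strata=(("R1", "Gs_cAMP"),),
            peptides=tuple(sorted(FIXTURE_EXPECTED)),
            noise_cv=noise_cv,
            seed=seed0 + i,
        )
        records = simulate_screen(truth, design)
        matrix = call_matrix(records, panel, seed=seed0 + i)
        for pep, expected in FIXTURE_EXPECTED.items():
            n_cells += 1
            if matrix.grade(pep, "R1") == expected:
                n_correct += 1
        if matrix.asterisk(FIXTURE_ASTERISK, "R1"):
            n_asterisk += 1
    return {
        "n_seeds": n_seeds,
        "n_cells": n_cells,
        "grade_agreement": n_correct / n_cells,
        "asterisk_recovery": n_asterisk / n_seeds,
    }


# ---------------------------------------------------------------------------
# statistical calibration under the null
# ---------------------------------------------------------------------------


def type1_activation(n_reps: int = 1000, seed0: int = 0) -> dict:
    """Family-wise type-I error of the activation test on inert strata."""
    truth = GroundTruthPharmacology(
        entries={},
        receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
    )
    false_pos = 0
    for i in range(n_reps):
        design = ScreenDesign(
            strata=(("R1", "Gs_cAMP"),),
            peptides=("pepA", "pepB"),
            noise_cv=0.10,
            seed=seed0 + i,
        )
        responses = normalize(simulate_screen(truth, design))
        sig = test_activation(responses, "R1", "Gs_cAMP", seed=seed0 + i)
        if any(s.significant for s in sig.values()):
            false_pos += 1
    return {"n": n_reps, "rate": false_pos / n_reps}


def type1_groups(n_reps: int = 1000, seed0: int = 0) -> dict:
    """Family-wise type-I error of the group comparison on identical truths."""
    false_pos = 0
    for i in range(n_reps):
        truths = [
            AvoidanceTruth(g, p_mesa=0.4, p_eoh=0.6, n_worms=100, n_plates=6)
            for g in ("mut", "rescue", "wt")
        ]
        plates = simulate_avoidance_plates(truths, seed=seed0 + i)
        cmp = compare_groups(plate_indices(plates), reference="mut")
        if any(cmp.significant.values()):
            false_pos += 1
    return {"n": n_reps, "rate": false_pos / n_reps}


# ---------------------------------------------------------------------------
# candidate inference vs brute force
# ---------------------------------------------------------------------------


def bruteforce_candidates(
    matrix: InteractionMatrix, target: str, rescuers: tuple[str, ...], min_grade: str
) -> set[str]:
    """Independent enumeration: intersection of per-receptor active sets."""
    sets = []
    for receptor in (target, *rescuers):
        sets.append(
            {
                p
                for p in matrix.peptides
                if GRADE_ORDER[matrix.grade(p, receptor)] >= GRADE_ORDER[min_grade]
            }
        )
    return set.intersection(*sets)


def _random_matrix(rng: np.random.Generator, peptides, receptors) -> InteractionMatrix:
    calls = {}
    for p in peptides:
        for r in receptors:
            g = GRADES[rng.integers(0, 6)]
            calls[(p, r)] = ActivationCall(
                receptor_id=r, peptide_id=p, pathway="Gio_cAMP_fsk",
                active_low=g in ("iii", "iv", "v"), active_high=g != "none",
                frac_low=0.5, frac_high=0.5, grade=g, partial_agonist=False,
            )
    return InteractionMatrix(tuple(peptides), tuple(receptors), calls)


def candidate_bruteforce_study(n_matrices: int = 1000, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    peptides = [f"p{i}" for i in range(20)]
    receptors = [f"r{i}" for i in range(8)]
    agree = 0
    for _ in range(n_matrices):
        m = _random_matrix(rng, peptides, receptors)
        k = int(rng.integers(1, 5))
        rescuers = tuple(receptors[1 : 1 + k])
        min_grade = GRADES[rng.integers(1, 6)]
        got = set(infer_candidates(m, RescuePanel(receptors[0], rescuers), min_grade))
        if got == bruteforce_candidates(m, receptors[0], rescuers, min_grade):
            agree += 1
    return {"n": n_matrices, "agree": agree, "agreement": agree / n_matrices}


#: heterologous receptors that substitute the native avoidance receptor in
#: vivo, versus those that do not, in the demo panel
DEMO_RESCUE_PANEL = RescuePanel(
    target_receptor_id="NPR-1",
    rescuing_receptor_ids=("Y2R", "Y4R", "Y5R", "NPFF1R", "NPFF2R"),
    non_rescuing_receptor_ids=("Y1R", "PrRPR"),
)

#: candidate set designed into the demo pharmacology: only these two peptides
#: activate the native receptor and every substituting receptor
DEMO_EXPECTED_CANDIDATES = {"FLP-14", "FLP-21"}


def demo_candidates(seed: int = 0) -> list[str]:
    """Simulate the full demo screen once and infer candidate ligands."""
    truth = demo_ground_truth()
    panel = demo_panel_spec()
    design = ScreenDesign(
        strata=tuple((r.id, r.pathway) for r in panel.receptors),
        peptides=tuple(panel.peptides),
        seed=seed,
    )
    records = simulate_screen(truth, design)
    matrix = call_matrix(records, panel, seed=seed)
    return infer_candidates(matrix, DEMO_RESCUE_PANEL)


# ---------------------------------------------------------------------------
# behavioral estimator convergence
# ---------------------------------------------------------------------------


def avoidance_convergence(
    p_mesa: float = 0.25, p_eoh: float = 0.75, n_worms: int = 100,
    n_plates: int = 2000, seed: int = 0,
) -> dict:
    """Plate-mean avoidance index vs the generating p_mesa - p_eoh.

    With p_mesa + p_eoh = 1 every worm is scored, so the index expectation is
    exactly p_mesa - p_eoh.
    """
    if abs(p_mesa + p_eoh - 1.0) > 1e-12:
        raise ValueError("convergence target requires p_mesa + p_eoh = 1")
    truth = AvoidanceTruth("g", p_mesa=p_mesa, p_eoh=p_eoh,
                           n_worms=n_worms, n_plates=n_plates)
    plates = simulate_avoidance_plates(truth, seed=seed)
    ai = np.array(plate_indices(plates)["g"])
    expected = p_mesa - p_eoh
    # per-plate index variance: 4 p (1-p) / n for a binomial split
    se = 2.0 * math.sqrt(p_mesa * (1 - p_mesa) / n_worms) / math.sqrt(n_plates)
    return {
        "n_plates": n_plates,
        "mean_index": float(ai.mean()),
        "expected": expected,
        "mc_se": se,
        "abs_error": abs(float(ai.mean()) - expected),
    }
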