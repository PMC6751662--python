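"""Normalization, thresholding, maximal-signal rules, grading, matrix
assembly, and coupling-preference calling, checked against closed-form
expectations and independent brute-force logic."""

import math

import numpy as np
import pytest

from flpnpr.config import GradeCutpoints, PanelSpec, ReceptorSpec, Thresholds
from flpnpr.io import read_matrix_json, write_matrix_json
from flpnpr.screen import (
    NormalizedResponse,
    above_threshold,
    build_matrix,
    call_matrix,
    compute_calls,
    coupling_profile,
    frac_of_window,
    grade_pair,
    normalize,
    receptor_max,
)
from flpnpr.screen import test_activation as activation_test
from flpnpr.synth import (
    GroundTruthPharmacology,
    PharmEntry,
    PlateRecord,
    ReceptorWindow,
    ScreenDesign,
    simulate_screen,
)


def _well(receptor, pathway, peptide, conc, exp, rep, signal):
    return PlateRecord(receptor, pathway, peptide, conc, exp, rep, signal)


def _resp(mean, pathway="Gs_cAMP", peptide="P", conc=1e-5):
    return NormalizedResponse(
        receptor_id="R", pathway=pathway, peptide_id=peptide, concentration=conc,
        fold_per_experiment=(mean,), well_folds=(mean,), mean=mean, sem=0.0, n=1,
    )


class TestNormalize:
    def test_fold_of_basal_arithmetic(self):
        records = [_well("R", "Gs_cAMP", "buffer", 0, 0, i, 100.0) for i in range(3)]
        records += [
            _well("R", "Gs_cAMP", "P", 1e-5, 0, i, s)
            for i, s in enumerate([240.0, 250.0, 260.0])
        ]
        resp = {r.peptide_id: r for r in normalize(records)}
        assert math.isclose(resp["P"].mean, 2.5)
        assert math.isclose(resp["buffer"].mean, 1.0)

    def test_fold_of_forskolin(self):
        records = [_well("R", "Gio_cAMP_fsk", "forskolin", 0, 0, i, 1000.0) for i in range(3)]
        records += [_well("R", "Gio_cAMP_fsk", "buffer", 0, 0, i, 50.0) for i in range(3)]
        records += [_well("R", "Gio_cAMP_fsk", "P", 1e-5, 0, i, 600.0) for i in range(3)]
        resp = {r.peptide_id: r for r in normalize(records)}
        assert math.isclose(resp["P"].mean, 0.6)  # 40% inhibition

    def test_wells_equal_buffer_give_unit_fold(self):
        records = [_well("R", "Gs_cAMP", "buffer", 0, 0, i, 100.0) for i in range(3)]
        records += [_well("R", "Gs_cAMP", "P", 1e-5, 0, i, 100.0) for i in range(3)]
        resp = {r.peptide_id: r for r in normalize(records)}
        assert math.isclose(resp["P"].mean, 1.0)

    def test_missing_control_names_stratum(self):
        records = [_well("R", "Gs_cAMP", "P", 1e-5, 0, 0, 100.0)]
        with pytest.raises(ValueError, match="R/Gs_cAMP"):
            normalize(records)


class TestThreshold:
    @pytest.mark.parametrize(
        "mean,pathway,expected",
        [
            (2.0, "Gs_cAMP", True),  # boundary inclusive
            (5.0, "Gs_cAMP", True),
            (1.99, "Gs_cAMP", False),
            (0.85, "Gio_cAMP_fsk", False),  # only 15% inhibition
            (0.8, "Gio_cAMP_fsk", True),  # boundary inclusive
            (0.5, "Gio_cAMP_fsk", True),
        ],
    )
    def test_boundaries(self, mean, pathway, expected):
        assert above_threshold(_resp(mean, pathway=pathway)) is expected


class TestReceptorMax:
    def _responses(self):
        return [
            _resp(9.2, peptide="A", conc=1e-5),
            _resp(6.0, peptide="AGO", conc=1e-5),
            _resp(3.0, peptide="AGO", conc=1e-7),
            _resp(7.5, peptide="B", conc=1e-5),
        ]

    def test_worm_rule_takes_overall_max(self):
        spec = PanelSpec(
            receptors=[ReceptorSpec(id="R", species="celegans", pathway="Gs_cAMP")],
            peptides=["A", "AGO", "B"],
        )
        assert receptor_max(self._responses(), "R", spec) == 9.2

    def test_human_rule_takes_endogenous_agonist(self):
        spec = PanelSpec(
            receptors=[
                ReceptorSpec(id="R", species="human", pathway="Gs_cAMP", endogenous_agonist="AGO")
            ],
            peptides=["A", "AGO", "B"],
        )
        # surrogate peptides reach 9.2 and 7.5 but the agonist defines the max
        assert receptor_max(self._responses(), "R", spec) == 6.0

    def test_human_without_agonist_rejected_at_spec_level(self):
        with pytest.raises(ValueError, match="endogenous"):
            ReceptorSpec(id="R", species="human", pathway="Gs_cAMP")

    def test_missing_agonist_responses_rejected(self):
        spec = PanelSpec(
            receptors=[
                ReceptorSpec(id="R", species="human", pathway="Gs_cAMP", endogenous_agonist="ZZZ")
            ],
            peptides=["A"],
        )
        with pytest.raises(ValueError, match="ZZZ"):
            receptor_max(self._responses(), "R", spec)


def closed_form_inputs(ec50, emax, window, threshold=2.0):
    """Noise-free two-point calling inputs for a full-window normalization."""

    def fold(c):
        occ = c / (c + ec50)
        return 1.0 + (window - 1.0) * emax * occ

    def frac(c):
        occ = c / (c + ec50)
        return emax * occ

    active_low = fold(1e-7) >= threshold
    active_high = fold(1e-5) >= threshold
    return active_low, active_high, frac(1e-7), frac(1e-5)


class TestGradePair:
    def test_potent_full_agonist_is_darkest(self):
        # EC50 10 nM, window 10x: frac at 100 nM = 100/110 = 0.909
        args = closed_form_inputs(10e-9, 1.0, 10.0)
        assert math.isclose(args[2], 100.0 / 110.0)
        assert grade_pair(*args) == ("v", False)

    def test_midrange_full_agonist_partial_then_full(self):
        # EC50 500 nM: frac 0.167 at 100 nM (active), 0.952 at 10 uM
        args = closed_form_inputs(500e-9, 1.0, 10.0)
        assert math.isclose(args[2], 1.0 / 6.0)
        assert math.isclose(args[3], 10000.0 / 10500.0)
        assert grade_pair(*args) == ("iv", False)

    def test_weak_full_agonist_is_lightest(self):
        # EC50 50 uM: inactive at 100 nM, frac 0.167 at 10 uM
        args = closed_form_inputs(50e-6, 1.0, 10.0)
        assert not args[0]
        assert math.isclose(args[3], 10.0 / 60.0)
        assert grade_pair(*args) == ("i", False)

    def test_high_affinity_partial_agonist_flagged(self):
        # Emax 0.5, EC50 10 nM: fracs 0.455 / 0.500, equal within delta
        args = closed_form_inputs(10e-9, 0.5, 10.0)
        assert math.isclose(args[2], 0.5 * 100.0 / 110.0)
        grade, asterisk = grade_pair(*args)
        assert (grade, asterisk) == ("iii", True)

    def test_inactive_pair_is_none_even_with_nan_fracs(self):
        assert grade_pair(False, False, float("nan"), float("nan")) == ("none", False)

    def test_out_of_range_frac_rejected(self):
        with pytest.raises(ValueError, match="normalization fault"):
            grade_pair(True, True, 0.5, 1.8)

    def test_grade_monotone_in_potency_for_full_agonists(self):
        order = {"none": 0, "i": 1, "ii": 2, "iii": 3, "iv": 4, "v": 5}
        last = 6
        for log_ec50 in np.linspace(-9, -3, 200):
            grade, _ = grade_pair(*closed_form_inputs(10**log_ec50, 1.0, 10.0))
            assert order[grade] <= last
            last = order[grade]


class TestPipeline:
    def test_noise_free_calls_equal_threshold_calls(self, single_receptor_truth, worm_panel):
        design = ScreenDesign(
            strata=(("R1", "Gs_cAMP"),), peptides=("AGO", "INERT"),
            noise_cv=0.0, experiment_cv=0.0, seed=0,
        )
        records = simulate_screen(single_receptor_truth, design)
        calls = {c.peptide_id: c for c in compute_calls(records, worm_panel)}
        assert calls["AGO"].grade == "v"
        assert calls["INERT"].grade == "none"
        assert not calls["INERT"].active_low and not calls["INERT"].active_high

    def test_all_inert_truth_grades_row_none(self, worm_panel):
        truth = GroundTruthPharmacology(
            entries={},
            receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
        )
        design = ScreenDesign(
            strata=(("R1", "Gs_cAMP"),), peptides=("AGO", "INERT"), seed=5
        )
        records = simulate_screen(truth, design)
        matrix = call_matrix(records, worm_panel, seed=5)
        assert all(c.grade == "none" for c in matrix.calls.values())

    def test_matrix_permutation_invariant_in_record_order(self, single_receptor_truth, worm_panel):
        design = ScreenDesign(strata=(("R1", "Gs_cAMP"),), peptides=("AGO", "INERT"), seed=2)
        records = simulate_screen(single_receptor_truth, design)
        m1 = call_matrix(records, worm_panel, seed=2)
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        m2 = call_matrix(shuffled, worm_panel, seed=2)
        assert set(m1.calls) == set(m2.calls)
        for key, c1 in m1.calls.items():
            c2 = m2.calls[key]
            assert (c1.grade, c1.partial_agonist, c1.active_low, c1.active_high) == (
                c2.grade, c2.partial_agonist, c2.active_low, c2.active_high
            )
            # summation order may shift fracs at machine precision
            assert math.isclose(c1.frac_low, c2.frac_low, rel_tol=1e-12)
            assert math.isclose(c1.frac_high, c2.frac_high, rel_tol=1e-12)

    def test_matrix_json_round_trip(self, single_receptor_truth, worm_panel, tmp_path):
        design = ScreenDesign(strata=(("R1", "Gs_cAMP"),), peptides=("AGO", "INERT"), seed=2)
        matrix = call_matrix(simulate_screen(single_receptor_truth, design), worm_panel, seed=2)
        path = tmp_path / "matrix.json"
        write_matrix_json(matrix, path)
        back = read_matrix_json(path)
        assert back.peptides == matrix.peptides
        assert back.receptors == matrix.receptors
        for k, c in matrix.calls.items():
            b = back.calls[k]
            assert (b.grade, b.partial_agonist, b.active_low, b.active_high) == (
                c.grade, c.partial_agonist, c.active_low, c.active_high
            )

    def test_missing_cell_rejected(self, worm_panel):
        with pytest.raises(ValueError, match="no activation call"):
            build_matrix([], worm_panel)


class TestActivationTest:
    def test_shifted_condition_detected(self, worm_panel):
        truth = GroundTruthPharmacology(
            entries={("R1", "AGO", "Gs_cAMP"): PharmEntry(ec50=1e-9, emax=1.0)},
            receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
        )
        design = ScreenDesign(strata=(("R1", "Gs_cAMP"),), peptides=("AGO",), seed=3)
        resp = normalize(simulate_screen(truth, design))
        sig = activation_test(resp, "R1", "Gs_cAMP", seed=3)
        assert sig[("AGO", 1e-5)].significant
        assert sig[("AGO", 1e-7)].significant

    def test_single_replicate_rejected(self):
        records = [
            _well("R", "Gs_cAMP", "buffer", 0, 0, 0, 100.0),
            _well("R", "Gs_cAMP", "P", 1e-5, 0, 0, 300.0),
        ]
        resp = normalize(records)
        with pytest.raises(ValueError, match="single replicate"):
            activation_test(resp, "R", "Gs_cAMP")

    def test_zero_variance_null_not_significant(self):
        records = [_well("R", "Gs_cAMP", "buffer", 0, 0, i, 100.0) for i in range(3)]
        records += [_well("R", "Gs_cAMP", "P", 1e-5, 0, i, 100.0) for i in range(3)]
        sig = activation_test(normalize(records), "R", "Gs_cAMP")
        assert not sig[("P", 1e-5)].significant


class TestCouplingProfile:
    def _gio_only_records(self):
        truth = GroundTruthPharmacology(
            entries={("R", "P", "Gio_cAMP_fsk"): PharmEntry(ec50=10e-9, emax=0.9)},
            receptor_windows={"R": ReceptorWindow(basal=100.0, window=5.0)},
        )
        design = ScreenDesign(
            strata=(("R", "Gio_cAMP_fsk"), ("R", "Gs_cAMP")), peptides=("P",), seed=8
        )
        return simulate_screen(truth, design)

    def test_gio_inhibition_only_primary(self):
        profile = coupling_profile(self._gio_only_records(), "R")
        assert profile.status["Gio_cAMP_fsk"] == "primary"
        assert profile.status["Gs_cAMP"] == "inactive"
        assert profile.primary == "Gio_cAMP_fsk"

    def test_gq_strong_gs_weak_both_active(self):
        # IP strongly elevated, cAMP modestly elevated: Gq primary, Gs secondary
        truth = GroundTruthPharmacology(
            entries={
                ("R", "P", "Gq_IP"): PharmEntry(ec50=10e-9, emax=1.0),
                ("R", "P", "Gs_cAMP"): PharmEntry(ec50=10e-9, emax=1.0),
            },
            receptor_windows={"R": ReceptorWindow(basal=100.0, window=12.0)},
        )
        records = simulate_screen(
            truth,
            ScreenDesign(strata=(("R", "Gq_IP"), ("R", "Gs_cAMP")), peptides=("P",), seed=9),
        )
        # shrink the cAMP window by damping those signals toward basal
        damped = []
        for r in records:
            if r.pathway == "Gs_cAMP" and r.peptide_id == "P":
                basal = 100.0
                damped.append(
                    PlateRecord(r.receptor_id, r.pathway, r.peptide_id, r.concentration,
                                r.experiment_id, r.replicate_id,
                                basal + 0.2 * (r.signal - basal))
                )
            else:
                damped.append(r)
        profile = coupling_profile(damped, "R")
        assert profile.status["Gq_IP"] == "primary"
        assert profile.status["Gs_cAMP"] == "secondary"

    def test_nothing_significant_all_inactive(self):
        truth = GroundTruthPharmacology(
            entries={},
            receptor_windows={"R": ReceptorWindow(basal=100.0, window=5.0)},
        )
        records = simulate_screen(
            truth,
            ScreenDesign(strata=(("R", "Gq_IP"), ("R", "Gs_cAMP")), peptides=("P",), seed=10),
        )
        profile = coupling_profile(records, "R")
        assert set(profile.status.values()) == {"inactive"}

    def test_no_records_rejected(self):
        with pytest.raises(ValueError):
            coupling_profile([], "R")


class TestFracOfWindow:
    def test_stimulatory_scale(self):
        assert math.isclose(frac_of_window(5.5, 10.0, "Gs_cAMP"), 0.5)

    def test_inhibitory_scale(self):
        # 40% inhibition against a 80%-inhibition window = half the window
        assert math.isclose(frac_of_window(0.6, 0.2, "Gio_cAMP_fsk"), 0.5)

    def test_degenerate_window_is_nan(self):
        assert math.isnan(frac_of_window(1.5, 1.0, "Gs_cAMP"))
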