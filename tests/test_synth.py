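"""The simulator must reproduce its closed-form readout model exactly at zero
noise, converge to it in mean under noise, and be bit-reproducible by seed."""

import math

import numpy as np
import pytest

from flpnpr.behavior import avoidance_index
from flpnpr.synth import (
    AvoidanceTruth,
    BorderingTruth,
    GroundTruthPharmacology,
    PharmEntry,
    PlateRecord,
    ReceptorWindow,
    ScreenDesign,
    simulate_avoidance_plates,
    simulate_bordering_plates,
    simulate_screen,
)


def _signals(records, peptide, conc):
    return [r.signal for r in records if r.peptide_id == peptide and r.concentration == conc]


class TestScreenReadoutModel:
    def test_inert_pair_equals_buffer_at_zero_noise(self, single_receptor_truth, single_receptor_design):
        records = simulate_screen(single_receptor_truth, single_receptor_design)
        buffer = _signals(records, "buffer", 0.0)
        inert = [r.signal for r in records if r.peptide_id == "INERT"]
        assert all(math.isclose(s, buffer[0], rel_tol=1e-12) for s in inert)

    def test_full_agonist_closed_form_at_100nM(self, single_receptor_truth, single_receptor_design):
        # window 10, EC50 10 nM, hill 1: fold at 100 nM = 1 + 9 * (100/110)
        records = simulate_screen(single_receptor_truth, single_receptor_design)
        expected = 100.0 * (1.0 + 9.0 * (100.0 / 110.0))
        for s in _signals(records, "AGO", 1e-7):
            assert math.isclose(s, expected, rel_tol=1e-12)
        assert math.isclose(expected, 918.18, rel_tol=1e-4)

    def test_gio_full_inhibition_closed_form(self):
        truth = GroundTruthPharmacology(
            entries={("R", "P", "Gio_cAMP_fsk"): PharmEntry(ec50=10e-9, emax=1.0)},
            receptor_windows={"R": ReceptorWindow(basal=50.0, window=5.0)},
            forskolin_fold=20.0,
        )
        design = ScreenDesign(
            strata=(("R", "Gio_cAMP_fsk"),), peptides=("P",),
            noise_cv=0.0, experiment_cv=0.0, seed=0,
        )
        records = simulate_screen(truth, design)
        fsk = _signals(records, "forskolin", 0.0)[0]
        at_10uM = _signals(records, "P", 1e-5)[0]
        # residual signal = 1 - 10000/10010 of the forskolin control
        assert math.isclose(at_10uM / fsk, 1.0 - 10000.0 / 10010.0, rel_tol=1e-9)
        assert at_10uM / fsk < 0.0011

    def test_forskolin_control_emitted_only_for_gio(self, single_receptor_truth, single_receptor_design):
        records = simulate_screen(single_receptor_truth, single_receptor_design)
        assert not any(r.peptide_id == "forskolin" for r in records)

    def test_monte_carlo_mean_converges(self):
        truth = GroundTruthPharmacology(
            entries={("R1", "AGO", "Gs_cAMP"): PharmEntry(ec50=10e-9, emax=1.0)},
            receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
        )
        cv = 0.10
        design = ScreenDesign(
            strata=(("R1", "Gs_cAMP"),), peptides=("AGO",),
            n_experiments=40, n_replicates=10, noise_cv=cv, experiment_cv=0.0, seed=3,
        )
        records = simulate_screen(truth, design)
        wells = np.array(_signals(records, "AGO", 1e-7))
        model_mean = truth.mean_signal("R1", "AGO", "Gs_cAMP", 1e-7)
        rel_err = abs(wells.mean() - model_mean) / model_mean
        assert rel_err < 3 * cv / math.sqrt(len(wells))

    def test_seed_determinism_and_divergence(self, single_receptor_truth):
        design = ScreenDesign(strata=(("R1", "Gs_cAMP"),), peptides=("AGO",), seed=11)
        a = simulate_screen(single_receptor_truth, design)
        b = simulate_screen(single_receptor_truth, design)
        assert [r.signal for r in a] == [r.signal for r in b]
        c = simulate_screen(
            single_receptor_truth,
            ScreenDesign(strata=(("R1", "Gs_cAMP"),), peptides=("AGO",), seed=12),
        )
        assert [r.signal for r in a] != [r.signal for r in c]


class TestScreenContracts:
    def test_unknown_pathway_rejected(self, single_receptor_truth):
        with pytest.raises(ValueError, match="pathway"):
            simulate_screen(
                single_receptor_truth,
                ScreenDesign(strata=(("R1", "Gx_bogus"),), peptides=("AGO",)),
            )

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ScreenDesign(concentrations=(0.0, 1e-5))

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            ScreenDesign(concentrations=(1e-5, 1e-7))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            PlateRecord("R", "Gs_cAMP", "P", 1e-7, 0, 0, -1.0)

    def test_invalid_pharm_entry(self):
        with pytest.raises(ValueError):
            PharmEntry(ec50=-1.0, emax=0.5)
        with pytest.raises(ValueError):
            PharmEntry(ec50=1e-9, emax=1.5)
        with pytest.raises(ValueError):
            PharmEntry(ec50=1e-9, emax=0.5, hill=0.0)


class TestBehaviorSimulators:
    def test_all_worms_avoid_when_p_mesa_one(self):
        plates = simulate_avoidance_plates(
            AvoidanceTruth("wt", p_mesa=1.0, p_eoh=0.0, n_worms=50, n_plates=3), seed=0
        )
        for p in plates:
            assert p.n_mesa == 50 and p.n_eoh == 0
            assert avoidance_index(p) == 1.0

    def test_symmetric_probabilities_give_near_zero_index(self):
        plates = simulate_avoidance_plates(
            AvoidanceTruth("wt", p_mesa=0.5, p_eoh=0.5, n_worms=10000, n_plates=1), seed=4
        )
        ai = avoidance_index(plates[0])
        se = 1.0 / math.sqrt(10000)  # binomial sampling scale of the index
        assert abs(ai) < 3 * se

    def test_avoidance_counts_sum_and_determinism(self):
        truth = AvoidanceTruth("g", p_mesa=0.4, p_eoh=0.5, n_worms=80, n_plates=5)
        a = simulate_avoidance_plates(truth, seed=9)
        b = simulate_avoidance_plates(truth, seed=9)
        assert a == b
        for p in a:
            assert p.n_mesa + p.n_eoh <= p.n_total == 80

    def test_bordering_degenerate_and_mean(self):
        none = simulate_bordering_plates(BorderingTruth("g", p_border=0.0), seed=0)
        assert all(p.n_border == 0 for p in none)
        many = simulate_bordering_plates(
            BorderingTruth("g", p_border=0.8, n_worms=120, n_plates=50), seed=1
        )
        fracs = np.array([p.n_border / p.n_total for p in many])
        se = math.sqrt(0.8 * 0.2 / 120) / math.sqrt(50)
        assert abs(fracs.mean() - 0.8) < 4 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            BorderingTruth("g", p_border=-0.1)
        with pytest.raises(ValueError):
            AvoidanceTruth("g", p_mesa=0.7, p_eoh=0.5)
        with pytest.raises(ValueError):
            AvoidanceTruth("g", p_mesa=0.5, p_eoh=0.4, n_worms=0)
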