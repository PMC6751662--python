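import pytest

from flpnpr.config import PanelSpec, ReceptorSpec
from flpnpr.synth import GroundTruthPharmacology, PharmEntry, ReceptorWindow, ScreenDesign


@pytest.fixture
def single_receptor_truth() -> GroundTruthPharmacology:
    """One stimulatory receptor, one full agonist, one inert peptide."""
    return GroundTruthPharmacology(
        entries={
            ("R1", "AGO", "Gs_cAMP"): PharmEntry(ec50=10e-9, emax=1.0, hill=1.0),
        },
        receptor_windows={"R1": ReceptorWindow(basal=100.0, window=10.0)},
    )


@pytest.fixture
def single_receptor_design() -> ScreenDesign:
    return ScreenDesign(
        strata=(("R1", "Gs_cAMP"),),
        peptides=("AGO", "INERT"),
        noise_cv=0.0,
        experiment_cv=0.0,
        seed=1,
    )


@pytest.fixture
def worm_panel() -> PanelSpec:
    return PanelSpec(
        receptors=[ReceptorSpec(id="R1", species="celegans", pathway="Gs_cAMP")],
        peptides=["AGO", "INERT"],
    )
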