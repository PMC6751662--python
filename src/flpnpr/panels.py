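"""Curated demonstration panel: receptors, peptides, and a synthetic ground
truth for the cross-species screen.

The receptor panel pairs six C. elegans neuropeptide receptors (NPRs, called
in their endogenous-coupling readout) with the human NPY-family and RFamide
receptors. Peptide sequences are included only where firmly established in
the literature (FLP-14 KHEYLRFa, FLP-21 GLGPRPLRFa, FLP-15-2 RGPSGPLRFa,
human NPY/PYY/PP, NPFF, and the eponymous FMRFamide); peptides that enter the
screen only as identifiers carry no sequence.

``demo_ground_truth`` is a synthetic pharmacology: potencies for the
well-characterized pairs use published values (e.g. FLP-21 at NPR-1, 1 nM;
FLP-14 at NPR-1, 24 nM at 53% relative efficacy; PYY and NPY at NPR-11), and
the remaining entries are plausible inventions chosen to reproduce the
qualitative cross-activation pattern: FLP-14 and FLP-21 activate the native
avoidance receptor NPR-1 and every human receptor capable of substituting it
in vivo, while the non-substituting receptors (Y1R, PrRPR) are not activated
by them.
"""

from __future__ import annotations

from .config import PanelSpec, ReceptorSpec
from .peptides import Peptide
from .synth import GroundTruthPharmacology, PharmEntry, ReceptorWindow

GIO = "Gio_cAMP_fsk"
CHIMERA = "Dqi4myr_IP"
GQ = "Gq_IP"

#: literature-established sequences (amidated); used by the motif and
#: alignment demonstrations, not by the screen itself
CURATED_PEPTIDES = [
    Peptide("FMRFa", "FMRF", amidated=True, species="mollusc"),
    Peptide("FLP-14", "KHEYLRF", amidated=True, species="celegans"),
    Peptide("FLP-21", "GLGPRPLRF", amidated=True, species="celegans"),
    Peptide("FLP-15-2", "RGPSGPLRF", amidated=True, species="celegans"),
    Peptide(
        "NPY",
        "YPSKPDNPGEDAPAEDMARYYSALRHYINLITRQRY",
        amidated=True,
        species="human",
    ),
    Peptide(
        "PYY",
        "YPIKPEAPGEDASPEELNRYYASLRHYLNLVTRQRY",
        amidated=True,
        species="human",
    ),
    Peptide(
        "PP",
        "APLEPVYPGDNATPEQMAQYAADLRRYINMLTRPRY",
        amidated=True,
        species="human",
    ),
    Peptide("NPFF", "FLFQPQRF", amidated=True, species="human"),
]

#: peptide ids entering the demo screen
SCREEN_PEPTIDES = [
    "FLP-14",
    "FLP-15-2",
    "FLP-18-5",
    "FLP-21",
    "FLP-27",
    "FLP-34-1",
    "FLP-34-2",
    "NPY",
    "PYY",
    "PP",
    "NPFF",
    "PrRP",
    "QRFP",
]


def demo_panel_spec() -> PanelSpec:
    """Receptor/peptide panel of the demonstration screen."""
    return PanelSpec(
        receptors=[
            ReceptorSpec(id="NPR-1", species="celegans", pathway=GIO),
            ReceptorSpec(id="NPR-11", species="celegans", pathway=CHIMERA),
            ReceptorSpec(id="Y1R", species="human", pathway=GIO, endogenous_agonist="NPY"),
            ReceptorSpec(id="Y2R", species="human", pathway=GIO, endogenous_agonist="NPY"),
            ReceptorSpec(id="Y4R", species="human", pathway=GIO, endogenous_agonist="PP"),
            ReceptorSpec(id="Y5R", species="human", pathway=GIO, endogenous_agonist="NPY"),
            ReceptorSpec(id="NPFF1R", species="human", pathway=GIO, endogenous_agonist="NPFF"),
            ReceptorSpec(id="NPFF2R", species="human", pathway=GIO, endogenous_agonist="NPFF"),
            ReceptorSpec(id="PrRPR", species="human", pathway=GQ, endogenous_agonist="PrRP"),
            ReceptorSpec(id="QRFPR", species="human", pathway=GQ, endogenous_agonist="QRFP"),
        ],
        peptides=list(SCREEN_PEPTIDES),
    )


def demo_ground_truth() -> GroundTruthPharmacology:
    """Synthetic screen pharmacology (see module docstring for provenance)."""
    nM = 1e-9
    uM = 1e-6
    windows = {
        "NPR-1": ReceptorWindow(basal=100.0, window=8.0),
        "NPR-11": ReceptorWindow(basal=120.0, window=10.0),
        "Y1R": ReceptorWindow(basal=100.0, window=8.0),
        "Y2R": ReceptorWindow(basal=100.0, window=8.0),
        "Y4R": ReceptorWindow(basal=100.0, window=8.0),
        "Y5R": ReceptorWindow(basal=100.0, window=8.0),
        "NPFF1R": ReceptorWindow(basal=100.0, window=8.0),
        "NPFF2R": ReceptorWindow(basal=100.0, window=8.0),
        "PrRPR": ReceptorWindow(basal=100.0, window=12.0),
        "QRFPR": ReceptorWindow(basal=100.0, window=12.0),
    }
    e: dict[tuple[str, str, str], PharmEntry] = {}

    def add(receptor: str, pathway: str, peptide: str, ec50: float, emax: float) -> None:
        e[(receptor, peptide, pathway)] = PharmEntry(ec50=ec50, emax=emax)

    # native avoidance receptor, Gi/o readout; published potencies where known
    add("NPR-1", GIO, "FLP-21", 1 * nM, 1.0)
    add("NPR-1", GIO, "FLP-14", 24 * nM, 0.53)  # high-affinity partial agonist
    add("NPR-1", GIO, "FLP-15-2", 60 * nM, 0.90)
    add("NPR-1", GIO, "FLP-18-5", 300 * nM, 0.85)

    # NPY-receptor-like NPR-11 via the chimeric G-protein IP readout
    add("NPR-11", CHIMERA, "FLP-34-1", 19 * nM, 1.0)
    add("NPR-11", CHIMERA, "FLP-34-2", 0.7 * nM, 1.0)
    add("NPR-11", CHIMERA, "PYY", 24 * nM, 0.86)
    add("NPR-11", CHIMERA, "NPY", 256 * nM, 0.49)
    add("NPR-11", CHIMERA, "FLP-21", 30 * nM, 1.0)
    add("NPR-11", CHIMERA, "FLP-15-2", 150 * nM, 0.85)
    add("NPR-11", CHIMERA, "FLP-27", 400 * nM, 0.70)
    add("NPR-11", CHIMERA, "FLP-14", 500 * nM, 0.75)

    # human receptors: endogenous agonists define the maximal signal
    for rec, agonist in [
        ("Y1R", "NPY"), ("Y2R", "NPY"), ("Y4R", "PP"), ("Y5R", "NPY"),
        ("NPFF1R", "NPFF"), ("NPFF2R", "NPFF"),
    ]:
        add(rec, GIO, agonist, 5 * nM, 1.0)
    add("PrRPR", GQ, "PrRP", 5 * nM, 1.0)
    add("QRFPR", GQ, "QRFP", 5 * nM, 1.0)

    # cross-species activation: FLP-14 and FLP-21 reach every receptor that
    # substitutes the native one in vivo (Y2R, Y4R, Y5R, NPFF1R, NPFF2R)
    for rec in ["Y2R", "Y4R", "Y5R", "NPFF1R", "NPFF2R"]:
        add(rec, GIO, "FLP-21", 80 * nM, 0.9)
        add(rec, GIO, "FLP-14", 150 * nM, 0.8)
    # broader FLP promiscuity at the NPFF receptors
    for rec in ["NPFF1R", "NPFF2R"]:
        add(rec, GIO, "FLP-15-2", 100 * nM, 0.9)
        add(rec, GIO, "FLP-18-5", 200 * nM, 0.8)
    # the NPY-like FLPs reach Y receptors
    add("Y2R", GIO, "FLP-27", 500 * nM, 0.7)
    add("Y2R", GIO, "FLP-34-1", 300 * nM, 0.8)
    add("Y2R", GIO, "FLP-34-2", 400 * nM, 0.8)
    add("Y1R", GIO, "FLP-27", 800 * nM, 0.6)
    add("Y1R", GIO, "FLP-34-1", 600 * nM, 0.7)
    # PrRPR and QRFPR respond to nothing but their own ligands (no entries)

    return GroundTruthPharmacology(entries=e, receptor_windows=windows)
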