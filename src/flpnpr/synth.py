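"""Synthetic second-messenger screening data and behavioral count data.

Simulates the raw material of a heterologous GPCR deorphanization screen:
plate-reader readouts (IP accumulation for Gq-family couplings, CRE-luciferase
cAMP for Gs, forskolin-stimulated cAMP inhibition for Gi/o) with the
replicate structure of independent experiments x technical replicates, plus
quadrant-assay and lawn-bordering worm counts. All signals derive from an
explicit ground truth (per receptor/peptide/pathway 4PL parameters), so every
downstream calling step can be validated against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .behavior import LawnCounts, QuadrantCounts

#: stimulatory readouts report accumulation over basal
STIMULATORY_PATHWAYS = frozenset({"Gs_cAMP", "Gq_IP", "G16_IP", "Dqi4myr_IP"})
#: inhibitory readout: suppression of forskolin-stimulated cAMP
INHIBITORY_PATHWAYS = frozenset({"Gio_cAMP_fsk"})
PATHWAYS = STIMULATORY_PATHWAYS | INHIBITORY_PATHWAYS

BUFFER = "buffer"
FORSKOLIN = "forskolin"


@dataclass(frozen=True)
class PharmEntry:
    """Ground-truth 4PL parameters for one receptor x peptide x pathway.

    ``emax`` is a fraction of the receptor's signal window (0 inert, 1 full
    agonist); for the Gi/o readout it is the maximal fractional inhibition of
    the forskolin-stimulated signal.
    """

    ec50: float  # molar
    emax: float  # fraction of window, 0..1
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError(f"emax must be in [0, 1], got {self.emax}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")

    def occupancy(self, conc: float) -> float:
        """Fractional response c^h / (c^h + EC50^h) at molar concentration."""
        if conc < 0:
            raise ValueError("concentration must be >= 0")
        if conc == 0:
            return 0.0
        # evaluate in log space for numerical safety at extreme ratios
        r = math.exp(self.hill * (math.log(conc) - math.log(self.ec50)))
        return r / (1.0 + r)


@dataclass(frozen=True)
class ReceptorWindow:
    """Basal signal (arbitrary units) and maximal fold-of-basal window."""

    basal: float
    window: float  # max fold of basal at full activation, > 1

    def __post_init__(self) -> None:
        if self.basal <= 0:
            raise ValueError("basal must be > 0")
        if self.window <= 1:
            raise ValueError("window must be > 1")


@dataclass
class GroundTruthPharmacology:
    """Complete ground truth for a screen.

    Pairs absent from ``entries`` are inert (emax = 0). ``forskolin_fold`` is
    the fold-over-basal of the forskolin positive control used by the Gi/o
    readout.
    """

    entries: dict[tuple[str, str, str], PharmEntry] = field(default_factory=dict)
    receptor_windows: dict[str, ReceptorWindow] = field(default_factory=dict)
    forskolin_fold: float = 20.0

    def __post_init__(self) -> None:
        if self.forskolin_fold <= 1:
            raise ValueError("forskolin_fold must be > 1")
        for (rec, _pep, pathway) in self.entries:
            if pathway not in PATHWAYS:
                raise ValueError(f"unknown pathway {pathway!r}")
            if rec not in self.receptor_windows:
                raise ValueError(f"receptor {rec!r} has no declared window")

    def entry(self, receptor: str, peptide: str, pathway: str) -> PharmEntry:
        inert = PharmEntry(ec50=1.0, emax=0.0)
        return self.entries.get((receptor, peptide, pathway), inert)

    def mean_signal(self, receptor: str, peptide: str, pathway: str, conc: float) -> float:
        """Noise-free plate-reader signal for one condition.

        Stimulatory: basal * (1 + (window - 1) * emax * occ(c)).
        Gi/o: basal * forskolin_fold * (1 - emax * occ(c)), i.e. inhibition of
        the forskolin-stimulated signal.
        """
        if pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {pathway!r}")
        win = self.receptor_windows[receptor]
        e = self.entry(receptor, peptide, pathway)
        occ = e.occupancy(conc)
        if pathway in STIMULATORY_PATHWAYS:
            return win.basal * (1.0 + (win.window - 1.0) * e.emax * occ)
        return win.basal * self.forskolin_fold * (1.0 - e.emax * occ)


@dataclass(frozen=True)
class ScreenDesign:
    """Replicate structure and noise of the two-concentration screen.

    Defaults follow the screening conditions: peptide concentrations 100 nM
    and 10 uM, at least three independent experiments in technical triplicate.
    ``noise_cv`` is the per-well coefficient of variation; ``experiment_cv``
    an optional between-experiment log-normal scale factor.
    """

    concentrations: tuple[float, ...] = (1e-7, 1e-5)
    n_experiments: int = 3
    n_replicates: int = 3
    noise_cv: float = 0.10
    experiment_cv: float = 0.05
    seed: int = 0
    strata: tuple[tuple[str, str], ...] | None = None  # (receptor, pathway)
    peptides: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if list(self.concentrations) != sorted(self.concentrations):
            raise ValueError("concentrations must be sorted ascending")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0 or self.experiment_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")


@dataclass(frozen=True)
class PlateRecord:
    """One raw well measurement. Control wells carry concentration 0."""

    receptor_id: str
    pathway: str
    peptide_id: str  # peptide id or control tag ("buffer" / "forskolin")
    concentration: float  # molar; 0 for controls
    experiment_id: int
    replicate_id: int
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError("signal must be >= 0")
        if self.peptide_id in (BUFFER, FORSKOLIN) and self.concentration != 0:
            raise ValueError("control records must have concentration 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-sigma2 / 2.0, sigma, size=size))


def _design_strata(truth: GroundTruthPharmacology, design: ScreenDesign) -> list[tuple[str, str]]:
    if design.strata is not None:
        for _rec, pathway in design.strata:
            if pathway not in PATHWAYS:
                raise ValueError(f"unknown pathway {pathway!r}")
        return list(design.strata)
    return sorted({(rec, pw) for (rec, _pep, pw) in truth.entries})


def _design_peptides(truth: GroundTruthPharmacology, design: ScreenDesign) -> list[str]:
    if design.peptides is not None:
        return list(design.peptides)
    return sorted({pep for (_rec, pep, _pw) in truth.entries})


def simulate_screen(truth: GroundTruthPharmacology, design: ScreenDesign) -> list[PlateRecord]:
    """Simulate raw plate records for every stratum of the design.

    Per receptor x pathway x experiment: buffer control wells, a forskolin
    control for the Gi/o readout, and one well set per peptide x
    concentration. Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    strata = _design_strata(truth, design)
    peptides = _design_peptides(truth, design)
    records: list[PlateRecord] = []

    for receptor, pathway in strata:
        win = truth.receptor_windows[receptor]
        for exp in range(design.n_experiments):
            offset = _lognormal_factor(rng, design.experiment_cv, 1)[0]

            def emit(peptide: str, conc: float, mean: float) -> None:
                noise = _lognormal_factor(rng, design.noise_cv, design.n_replicates)
                for rep in range(design.n_replicates):
                    records.append(
                        PlateRecord(
                            receptor_id=receptor,
                            pathway=pathway,
                            peptide_id=peptide,
                            concentration=conc,
                            experiment_id=exp,
                            replicate_id=rep,
                            signal=mean * offset * noise[rep],
                        )
                    )

            emit(BUFFER, 0.0, win.basal)
            if pathway in INHIBITORY_PATHWAYS:
                emit(FORSKOLIN, 0.0, win.basal * truth.forskolin_fold)
            for peptide in peptides:
                for conc in design.concentrations:
                    emit(peptide, conc, truth.mean_signal(receptor, peptide, pathway, conc))
    return records


# ---------------------------------------------------------------------------
# behavioral assays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AvoidanceTruth:
    """Generating probabilities for the four-quadrant chemical-avoidance assay.

    ``p_mesa``/``p_eoh`` are the per-worm probabilities of ending in the
    methyl-salicylate and ethanol-control quadrants; any remainder is worms
    lost to scoring. Plates carry 50-120 animals in the real assay.
    """

    genotype: str
    p_mesa: float
    p_eoh: float
    n_worms: int = 80
    n_plates: int = 6

    def __post_init__(self) -> None:
        for p in (self.p_mesa, self.p_eoh):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.p_mesa + self.p_eoh > 1.0 + 1e-12:
            raise ValueError("p_mesa + p_eoh must be <= 1")
        if self.n_worms <= 0 or self.n_plates <= 0:
            raise ValueError("counts must be positive integers")


@dataclass(frozen=True)
class BorderingTruth:
    """Generating probability for lawn-bordering counts (120 adults/plate)."""

    genotype: str
    p_border: float
    n_worms: int = 120
    n_plates: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_border <= 1.0:
            raise ValueError("p_border must be in [0, 1]")
        if self.n_worms <= 0 or self.n_plates <= 0:
            raise ValueError("counts must be positive integers")


def simulate_avoidance_plates(
    truths: Sequence[AvoidanceTruth] | AvoidanceTruth, seed: int = 0
) -> list[QuadrantCounts]:
    """Draw per-plate quadrant counts from a multinomial worm-destination model."""
    if isinstance(truths, AvoidanceTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    plates: list[QuadrantCounts] = []
    for truth in truths:
        p_lost = max(0.0, 1.0 - truth.p_mesa - truth.p_eoh)
        probs = np.array([truth.p_mesa, truth.p_eoh, p_lost])
        probs = probs / probs.sum()
        for i in range(truth.n_plates):
            n_mesa, n_eoh, _ = rng.multinomial(truth.n_worms, probs)
            plates.append(
                QuadrantCounts(
                    plate_id=f"{truth.genotype}-{i}",
                    genotype=truth.genotype,
                    n_mesa=int(n_mesa),
                    n_eoh=int(n_eoh),
                    n_total=truth.n_worms,
                )
            )
    return plates


def simulate_bordering_plates(
    truths: Sequence[BorderingTruth] | BorderingTruth, seed: int = 0
) -> list[LawnCounts]:
    """Draw per-plate bordering counts from a binomial model."""
    if isinstance(truths, BorderingTruth):
        truths = [truths]
    rng = np.random.default_rng(seed)
    plates: list[LawnCounts] = []
    for truth in truths:
        for i in range(truth.n_plates):
            n_border = int(rng.binomial(truth.n_worms, truth.p_border))
            plates.append(
                LawnCounts(
                    plate_id=f"{truth.genotype}-{i}",
                    genotype=truth.genotype,
                    n_border=n_border,
                    n_total=truth.n_worms,
                )
            )
    return plates
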