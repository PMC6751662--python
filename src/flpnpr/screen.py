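"""Activation calling, five-grade interaction-matrix construction, and
G-protein coupling-preference calling from raw plate records.

The calling pipeline mirrors the screening analysis conventions:

* per-experiment normalization to the buffer control ("fold of basal") or, for
  the Gi/o readout, to the forskolin control ("fold of forskolin");
* an activity call requires the response to clear a fixed threshold (2-fold
  over basal, or 20% inhibition of the forskolin signal) AND to differ
  significantly from the control (one-way ANOVA with Dunnett post-hoc,
  alpha = 0.05);
* responses are expressed as fractions of the receptor's maximal signal
  window — for the worm receptors the strongest response any peptide elicits,
  for the human receptors the response to the established endogenous agonist;
* each receptor x peptide pair is graded i-v from its activity at the two
  screening concentrations (0.1 and 10 uM), with an asterisk flag for
  high-affinity partial agonism (equal submaximal responses at both
  concentrations).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import GradeCutpoints, PanelSpec, Thresholds
from .synth import BUFFER, FORSKOLIN, INHIBITORY_PATHWAYS, PATHWAYS, PlateRecord

GRADES = ("none", "i", "ii", "iii", "iv", "v")
GRADE_ORDER = {g: i for i, g in enumerate(GRADES)}


@dataclass(frozen=True)
class NormalizedResponse:
    """Per-experiment normalized response of one condition.

    ``fold_per_experiment`` holds the per-experiment condition-mean folds;
    ``well_folds`` the per-well folds (each well divided by its experiment's
    control mean), used for the significance test.
    """

    receptor_id: str
    pathway: str
    peptide_id: str
    concentration: float
    fold_per_experiment: tuple[float, ...]
    well_folds: tuple[float, ...]
    mean: float
    sem: float
    n: int

    @property
    def is_control(self) -> bool:
        return self.peptide_id in (BUFFER, FORSKOLIN)


def _control_tag(pathway: str) -> str:
    return FORSKOLIN if pathway in INHIBITORY_PATHWAYS else BUFFER


def normalize(records: Sequence[PlateRecord]) -> list[NormalizedResponse]:
    """Normalize raw signals per experiment to the stratum's control.

    Stimulatory readouts divide by the buffer-control mean of the same
    receptor x pathway x experiment; the Gi/o readout divides by the
    forskolin-control mean. Raises if a stratum lacks its control.
    """
    if not records:
        raise ValueError("no plate records")
    df = pd.DataFrame(
        {
            "receptor": [r.receptor_id for r in records],
            "pathway": [r.pathway for r in records],
            "peptide": [r.peptide_id for r in records],
            "conc": [r.concentration for r in records],
            "experiment": [r.experiment_id for r in records],
            "signal": [r.signal for r in records],
        }
    )
    out: list[NormalizedResponse] = []
    for (receptor, pathway), stratum in df.groupby(["receptor", "pathway"], sort=True):
        ctrl = _control_tag(pathway)
        ctrl_means = (
            stratum[stratum.peptide == ctrl].groupby("experiment")["signal"].mean()
        )
        experiments = sorted(stratum.experiment.unique())
        missing = [e for e in experiments if e not in ctrl_means.index]
        if missing:
            raise ValueError(
                f"missing {ctrl} control for {receptor}/{pathway}, "
                f"experiment(s) {missing}"
            )
        for (peptide, conc), cond in stratum.groupby(["peptide", "conc"], sort=True):
            folds, wells = [], []
            for exp, grp in cond.groupby("experiment", sort=True):
                f = grp.signal.to_numpy() / ctrl_means[exp]
                wells.extend(f.tolist())
                folds.append(float(f.mean()))
            folds_arr = np.array(folds)
            sem = (
                float(folds_arr.std(ddof=1) / math.sqrt(len(folds_arr)))
                if len(folds_arr) > 1
                else 0.0
            )
            out.append(
                NormalizedResponse(
                    receptor_id=receptor,
                    pathway=pathway,
                    peptide_id=peptide,
                    concentration=float(conc),
                    fold_per_experiment=tuple(folds),
                    well_folds=tuple(wells),
                    mean=float(folds_arr.mean()),
                    sem=sem,
                    n=len(folds_arr),
                )
            )
    return out


@dataclass(frozen=True)
class SignificanceResult:
    p_adjusted: float
    significant: bool


def test_activation(
    responses: Sequence[NormalizedResponse],
    receptor: str,
    pathway: str,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, float], SignificanceResult]:
    """One-way ANOVA with Dunnett post-hoc versus the control condition.

    Operates on per-well normalized folds pooled across experiments within
    one receptor x pathway stratum. Returns Dunnett-adjusted p-values and
    significance flags at ``alpha`` for every non-control condition.
    """
    stratum = [
        r for r in responses if r.receptor_id == receptor and r.pathway == pathway
    ]
    if not stratum:
        raise ValueError(f"no responses for stratum {receptor}/{pathway}")
    ctrl_tag = _control_tag(pathway)
    control = next((r for r in stratum if r.peptide_id == ctrl_tag), None)
    if control is None:
        raise ValueError(f"stratum {receptor}/{pathway} lacks its {ctrl_tag} control")
    conditions = [r for r in stratum if not r.is_control]
    if not conditions:
        return {}
    for r in conditions + [control]:
        if len(r.well_folds) < 2:
            raise ValueError(
                f"condition {r.peptide_id}@{r.concentration} has a single "
                "replicate; no variance estimate"
            )

    samples = [np.asarray(r.well_folds) for r in conditions]
    ctrl_sample = np.asarray(control.well_folds)
    pooled = np.concatenate(samples + [ctrl_sample])
    if np.ptp(pooled) == 0 or all(np.ptp(s) == 0 for s in samples + [ctrl_sample]):
        # degenerate zero-variance input (noise-free simulation): a mean
        # difference is then exact, not sampled
        out = {}
        for r, s in zip(conditions, samples):
            diff = not math.isclose(float(s.mean()), float(ctrl_sample.mean()))
            out[(r.peptide_id, r.concentration)] = SignificanceResult(
                p_adjusted=0.0 if diff else 1.0, significant=diff
            )
        return out

    res = stats.dunnett(*samples, control=ctrl_sample, rng=seed)
    out = {}
    for r, p in zip(conditions, res.pvalue):
        out[(r.peptide_id, r.concentration)] = SignificanceResult(
            p_adjusted=float(p), significant=bool(p < alpha)
        )
    return out


def above_threshold(
    response: NormalizedResponse, thresholds: Thresholds | None = None
) -> bool:
    """Fixed-threshold activity: >= 2-fold of basal, or <= 0.8 of the
    forskolin signal (20% inhibition). Boundaries inclusive."""
    t = thresholds or Thresholds()
    if response.pathway in INHIBITORY_PATHWAYS:
        return response.mean <= t.fold_of_forskolin
    return response.mean >= t.fold_of_basal


def receptor_max(
    responses: Sequence[NormalizedResponse],
    receptor: str,
    panel_spec: PanelSpec,
) -> float:
    """Maximal-signal fold of a receptor in its designated pathway.

    Worm receptors: the strongest response elicited by any peptide at any
    concentration (lowest fold for the Gi/o readout). Human receptors: the
    response to the declared endogenous agonist at the top concentration.
    """
    spec = panel_spec.receptor(receptor)
    stratum = [
        r
        for r in responses
        if r.receptor_id == receptor and r.pathway == spec.pathway and not r.is_control
    ]
    if not stratum:
        raise ValueError(f"no peptide responses for {receptor}/{spec.pathway}")
    inhibitory = spec.pathway in INHIBITORY_PATHWAYS
    if spec.species == "celegans":
        means = [r.mean for r in stratum]
        return min(means) if inhibitory else max(means)
    agonist = spec.endogenous_agonist
    agonist_resp = [r for r in stratum if r.peptide_id == agonist]
    if not agonist_resp:
        raise ValueError(
            f"endogenous agonist {agonist!r} of {receptor} absent from responses"
        )
    top = max(agonist_resp, key=lambda r: r.concentration)
    return top.mean


def frac_of_window(mean_fold: float, max_fold: float, pathway: str) -> float:
    """Response as a fraction of the receptor window, on the fold scale.

    Stimulatory: (fold - 1) / (fold_max - 1); Gi/o: (1 - fold) /
    (1 - fold_min). NaN when the window is degenerate (no activation at all).
    """
    if pathway in INHIBITORY_PATHWAYS:
        denom = 1.0 - max_fold
    else:
        denom = max_fold - 1.0
    if denom <= 1e-9:
        return float("nan")
    if pathway in INHIBITORY_PATHWAYS:
        return (1.0 - mean_fold) / denom
    return (mean_fold - 1.0) / denom


@dataclass(frozen=True)
class ActivationCall:
    """Graded activity of one receptor x peptide pair in the screen."""

    receptor_id: str
    peptide_id: str
    pathway: str
    active_low: bool
    active_high: bool
    frac_low: float
    frac_high: float
    grade: str
    partial_agonist: bool  # the asterisk


def grade_pair(
    active_low: bool,
    active_high: bool,
    frac_low: float,
    frac_high: float,
    cutpoints: GradeCutpoints | None = None,
) -> tuple[str, bool]:
    """Map two-concentration activity to the five-shade grade and asterisk.

    Fractions are of the receptor's maximal window (0 = basal, 1 = maximal).
    Grades: i just-above-threshold and ii ~half-maximal at 10 uM only; iii
    active at 0.1 uM but submaximal at 10 uM; iv partial at 0.1 uM, full at
    10 uM; v full already at 0.1 uM. The asterisk marks equal submaximal
    responses at both concentrations (high-affinity partial agonism).
    """
    c = cutpoints or GradeCutpoints()
    for name, frac, used in (("frac_low", frac_low, active_low),
                             ("frac_high", frac_high, active_high)):
        if math.isfinite(frac) and not -0.2 <= frac <= 1.5:
            raise ValueError(f"{name}={frac:.3g} outside [-0.2, 1.5]: normalization fault")
        if used and not math.isfinite(frac):
            raise ValueError(f"{name} must be finite when the condition is active")

    if not active_low and not active_high:
        return "none", False

    asterisk = (
        active_low
        and active_high
        and abs(frac_high - frac_low) <= c.equality_delta
        and frac_high < c.full
    )
    if active_low and frac_low >= c.full:
        return "v", asterisk
    if active_low and active_high:
        return ("iv" if frac_high >= c.full else "iii"), asterisk
    if active_high:
        return ("ii" if frac_high >= c.mid else "i"), asterisk
    # active at 0.1 uM only: above-threshold at the low concentration but no
    # callable response at 10 uM — the verbal scheme has no slot; treated as
    # the mid grade (monotone agonism cannot produce it noise-free)
    return "iii", asterisk


def compute_calls(
    records: Sequence[PlateRecord],
    panel_spec: PanelSpec,
    thresholds: Thresholds | None = None,
    cutpoints: GradeCutpoints | None = None,
    seed: int = 0,
) -> list[ActivationCall]:
    """Full calling pipeline: normalize, test, threshold, window, grade.

    Each receptor is called in its designated (endogenous-coupling) pathway.
    A worm receptor with no active condition has an undefined window and its
    whole row is graded none.
    """
    t = thresholds or Thresholds()
    responses = normalize(records)
    concs = sorted(
        {r.concentration for r in responses if not r.is_control and r.concentration > 0}
    )
    if len(concs) < 2:
        raise ValueError("need at least two screening concentrations")
    c_low, c_high = concs[0], concs[-1]

    calls: list[ActivationCall] = []
    for rec_spec in panel_spec.receptors:
        receptor, pathway = rec_spec.id, rec_spec.pathway
        stratum = {
            (r.peptide_id, r.concentration): r
            for r in responses
            if r.receptor_id == receptor and r.pathway == pathway and not r.is_control
        }
        if not stratum:
            raise ValueError(f"no responses for panel receptor {receptor}/{pathway}")
        sig = test_activation(responses, receptor, pathway, alpha=t.alpha, seed=seed)
        active = {
            key: sig[key].significant and above_threshold(resp, t)
            for key, resp in stratum.items()
        }
        any_active = any(active.values())
        max_fold = receptor_max(responses, receptor, panel_spec) if any_active else None

        for peptide in panel_spec.peptides:
            lo = stratum.get((peptide, c_low))
            hi = stratum.get((peptide, c_high))
            if lo is None or hi is None:
                raise ValueError(
                    f"panel peptide {peptide!r} missing from {receptor} stratum"
                )
            if max_fold is None:
                calls.append(
                    ActivationCall(
                        receptor, peptide, pathway,
                        active_low=False, active_high=False,
                        frac_low=float("nan"), frac_high=float("nan"),
                        grade="none", partial_agonist=False,
                    )
                )
                continue
            frac_low = frac_of_window(lo.mean, max_fold, pathway)
            frac_high = frac_of_window(hi.mean, max_fold, pathway)
            a_low = active[(peptide, c_low)]
            a_high = active[(peptide, c_high)]
            grade, asterisk = grade_pair(a_low, a_high, frac_low, frac_high, cutpoints)
            calls.append(
                ActivationCall(
                    receptor, peptide, pathway,
                    active_low=a_low, active_high=a_high,
                    frac_low=frac_low, frac_high=frac_high,
                    grade=grade, partial_agonist=asterisk,
                )
            )
    return calls


@dataclass(frozen=True)
class InteractionMatrix:
    """Ordered peptide x receptor matrix of activation calls."""

    peptides: tuple[str, ...]
    receptors: tuple[str, ...]
    calls: Mapping[tuple[str, str], ActivationCall]  # (peptide, receptor) -> call

    def grade(self, peptide: str, receptor: str) -> str:
        return self.calls[(peptide, receptor)].grade

    def asterisk(self, peptide: str, receptor: str) -> bool:
        return self.calls[(peptide, receptor)].partial_agonist


def build_matrix(
    calls: Sequence[ActivationCall], panel_spec: PanelSpec
) -> InteractionMatrix:
    """Assemble a complete matrix over the declared panel; missing cells or
    undeclared receptors are errors."""
    by_key = {(c.peptide_id, c.receptor_id): c for c in calls}
    matrix_calls: dict[tuple[str, str], ActivationCall] = {}
    for rec in panel_spec.receptors:
        if not rec.pathway:
            raise ValueError(f"receptor {rec.id!r} lacks a designated pathway")
        for pep in panel_spec.peptides:
            key = (pep, rec.id)
            if key not in by_key:
                raise ValueError(f"matrix cell {key} has no activation call")
            matrix_calls[key] = by_key[key]
    return InteractionMatrix(
        peptides=tuple(panel_spec.peptides),
        receptors=tuple(r.id for r in panel_spec.receptors),
        calls=matrix_calls,
    )


def call_matrix(
    records: Sequence[PlateRecord],
    panel_spec: PanelSpec,
    thresholds: Thresholds | None = None,
    cutpoints: GradeCutpoints | None = None,
    seed: int = 0,
) -> InteractionMatrix:
    """records -> complete interaction matrix (convenience pipeline)."""
    calls = compute_calls(records, panel_spec, thresholds, cutpoints, seed=seed)
    return build_matrix(calls, panel_spec)


# ---------------------------------------------------------------------------
# coupling preference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingProfile:
    """Per-pathway coupling status of one receptor.

    A pathway is active when at least one peptide condition shifts the second
    messenger significantly (two-way ANOVA, pathway x stimulation, with
    Bonferroni post-hoc versus the pathway's control) and clears the activity
    threshold. Among active pathways the one with the strongest signal is
    primary, the rest secondary.
    """

    receptor_id: str
    status: Mapping[str, str]  # pathway -> inactive | secondary | primary
    strength: Mapping[str, float]  # comparable signal strength per pathway

    @property
    def primary(self) -> str | None:
        for p, s in self.status.items():
            if s == "primary":
                return p
        return None


def _pathway_strength(responses: Sequence[NormalizedResponse], pathway: str) -> float:
    """Cross-pathway comparable strength: max fold of basal for stimulatory
    readouts, fold-inhibition (1 / fold-of-forskolin) for Gi/o."""
    conds = [r for r in responses if r.pathway == pathway and not r.is_control]
    if not conds:
        return 0.0
    if pathway in INHIBITORY_PATHWAYS:
        return 1.0 / min(r.mean for r in conds)
    return max(r.mean for r in conds)


def coupling_profile(
    records: Sequence[PlateRecord],
    receptor: str,
    thresholds: Thresholds | None = None,
) -> CouplingProfile:
    """Call the G-protein coupling preference of one receptor.

    Builds a two-way layout (pathway x stimulation condition) of per-well
    normalized folds, fits the two-way ANOVA (type-II sums of squares), and
    compares every peptide condition against its pathway's control using the
    pooled residual variance with Bonferroni adjustment.
    """
    t = thresholds or Thresholds()
    responses = [r for r in normalize(records) if r.receptor_id == receptor]
    pathways = sorted({r.pathway for r in responses})
    if not pathways:
        raise ValueError(f"no pathways measured for receptor {receptor!r}")

    rows = []
    for r in responses:
        stim = "control" if r.is_control else f"{r.peptide_id}@{r.concentration:g}"
        for w in r.well_folds:
            rows.append({"pathway": r.pathway, "stim": stim, "fold": w})
    df = pd.DataFrame(rows)

    # two-way ANOVA; with a single pathway it degenerates to one-way
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = (
        "fold ~ C(pathway) * C(stim)" if len(pathways) > 1 else "fold ~ C(stim)"
    )
    cell_groups = df.groupby(["pathway", "stim"])["fold"]
    cell_means = cell_groups.mean()
    cell_ns = cell_groups.size()
    if df.groupby(["pathway", "stim"])["fold"].transform("mean").sub(df["fold"]).abs().max() < 1e-12:
        mse, df_resid = 0.0, 1.0  # noise-free degenerate case
    else:
        model = smf.ols(formula, data=df).fit()
        sm.stats.anova_lm(model, typ=2)  # validates the two-way decomposition
        mse = float(model.mse_resid)
        df_resid = float(model.df_resid)

    comparisons = [
        (pw, stim)
        for (pw, stim) in cell_means.index
        if stim != "control"
    ]
    m = len(comparisons)
    resp_by_key = {
        (r.pathway, f"{r.peptide_id}@{r.concentration:g}"): r
        for r in responses
        if not r.is_control
    }
    active_pathways: set[str] = set()
    for pw, stim in comparisons:
        diff = cell_means[(pw, stim)] - cell_means[(pw, "control")]
        if mse == 0.0:
            p_adj = 0.0 if abs(diff) > 1e-12 else 1.0
        else:
            se = math.sqrt(mse * (1.0 / cell_ns[(pw, stim)] + 1.0 / cell_ns[(pw, "control")]))
            t_stat = diff / se
            p = 2.0 * stats.t.sf(abs(t_stat), df_resid)
            p_adj = min(1.0, p * m)
        resp = resp_by_key[(pw, stim)]
        if p_adj < t.alpha and above_threshold(resp, t):
            active_pathways.add(pw)

    strength = {pw: _pathway_strength(responses, pw) for pw in pathways}
    status = {pw: "inactive" for pw in pathways}
    if active_pathways:
        primary = max(active_pathways, key=lambda pw: strength[pw])
        for pw in active_pathways:
            status[pw] = "primary" if pw == primary else "secondary"
    return CouplingProfile(receptor_id=receptor, status=status, strength=strength)
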