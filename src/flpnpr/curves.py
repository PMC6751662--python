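"""Concentration-response curve fitting.

Fits the four-parameter logistic (4PL) model

    response = bottom + (top - bottom) * c^h / (c^h + EC50^h)

by nonlinear least squares on log10 concentration, with multi-start
initialization, and expresses a ligand's maximal effect as a percentage of a
reference agonist's fitted window (the convention used to report, e.g., an
Emax of 53% of the reference-induced response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters with Jacobian-based standard errors."""

    receptor_id: str
    peptide_id: str
    pathway: str
    ec50: float  # molar
    log10_ec50_se: float
    hill: float
    hill_se: float
    bottom: float
    top: float
    converged: bool
    emax_pct_reference: float | None = None
    reference_peptide_id: str | None = None

    @property
    def window(self) -> float:
        return self.top - self.bottom


def _model(logc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_4pl(
    concentrations: Sequence[float],
    responses: Sequence[float],
    receptor_id: str = "",
    peptide_id: str = "",
    pathway: str = "",
    fix_hill: float | None = None,
) -> DoseResponseFit:
    """Fit a 4PL curve to concentration/response pairs.

    Multi-start: bottom/top seeded from the data extremes, log10 EC50 swept
    over the observed concentration range, Hill slope started at 0.5/1/2 (or
    fixed via ``fix_hill``). The best-residual solution is kept. Flat data or
    failure of every start returns ``converged=False`` with the estimates
    flagged unusable.
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses differ in length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    logc = np.log10(conc)

    span = float(resp.max() - resp.min())
    scale = max(abs(float(resp.mean())), 1e-12)
    if span < 1e-9 * scale:
        # flat data: EC50 unidentifiable
        return DoseResponseFit(
            receptor_id, peptide_id, pathway,
            ec50=float("nan"), log10_ec50_se=float("nan"),
            hill=float("nan"), hill_se=float("nan"),
            bottom=float(resp.mean()), top=float(resp.mean()),
            converged=False,
        )

    b0, t0 = float(resp.min()), float(resp.max())
    ec50_grid = np.linspace(logc.min(), logc.max(), 5)
    hill_grid = (fix_hill,) if fix_hill is not None else (0.5, 1.0, 2.0)

    best = None
    best_cost = math.inf
    for le in ec50_grid:
        for h in hill_grid:
            if fix_hill is not None:

                def f(x, bottom, top, log_ec50, _h=h):
                    return _model(x, bottom, top, log_ec50, _h)

                p0 = [b0, t0, le]
            else:
                f = _model
                p0 = [b0, t0, le, h]
            try:
                popt, pcov = curve_fit(f, logc, resp, p0=p0, maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            residual = float(np.sum((f(logc, *popt) - resp) ** 2))
            if residual < best_cost:
                best_cost = residual
                best = (popt, pcov)

    if best is None:
        return DoseResponseFit(
            receptor_id, peptide_id, pathway,
            ec50=float("nan"), log10_ec50_se=float("nan"),
            hill=float("nan"), hill_se=float("nan"),
            bottom=float("nan"), top=float("nan"),
            converged=False,
        )

    popt, pcov = best
    se = np.sqrt(np.abs(np.diag(pcov)))
    if fix_hill is not None:
        bottom, top, log_ec50 = popt
        hill, hill_se = float(fix_hill), 0.0
        log_ec50_se = float(se[2])
    else:
        bottom, top, log_ec50, hill = popt
        log_ec50_se = float(se[2])
        hill_se = float(se[3])

    # identifiability guards: EC50 far outside the tested range, a negative
    # Hill slope, or a collapsed window mean the sigmoid is not determined;
    # inhibition curves legitimately run downward (top < bottom)
    converged = (
        logc.min() - 2.0 <= log_ec50 <= logc.max() + 2.0
        and hill > 0
        and abs(top - bottom) > 1e-6 * scale
    )
    return DoseResponseFit(
        receptor_id, peptide_id, pathway,
        ec50=float(10.0 ** log_ec50), log10_ec50_se=log_ec50_se,
        hill=float(hill), hill_se=hill_se,
        bottom=float(bottom), top=float(top),
        converged=converged,
    )


def normalize_emax(fit: DoseResponseFit, reference_fit: DoseResponseFit) -> float:
    """Ligand window as a percentage of the reference agonist's window."""
    if (fit.receptor_id, fit.pathway) != (
        reference_fit.receptor_id,
        reference_fit.pathway,
    ):
        raise ValueError("fit and reference must share receptor and pathway")
    if not reference_fit.converged:
        raise ValueError("reference fit did not converge")
    ref_window = reference_fit.window
    if ref_window == 0:
        raise ValueError("reference window must be non-zero")
    pct = 100.0 * fit.window / ref_window
    if pct < 0:
        raise ValueError(
            "fit and reference windows have opposite signs; responses are not comparable"
        )
    return pct


def with_reference(fit: DoseResponseFit, reference_fit: DoseResponseFit) -> DoseResponseFit:
    """Return a copy carrying the reference-normalized Emax."""
    pct = normalize_emax(fit, reference_fit)
    return replace(
        fit, emax_pct_reference=pct, reference_peptide_id=reference_fit.peptide_id
    )


#: grade -> plausible EC50 band (molar) for noise-free full agonists; the
#: lightest shades correspond to estimated EC50 of 10-100 uM, the mid shade
#: ~1 uM, the second darkest ~0.1 uM, and the darkest < 100 nM
GRADE_EC50_BANDS: dict[str, tuple[float, float]] = {
    "i": (1e-5, 1e-4),
    "ii": (1e-5, 1e-4),
    "iii": (0.3e-6, 3e-6),
    "iv": (30e-9, 300e-9),
    "v": (0.0, 100e-9),
}


@dataclass(frozen=True)
class GradeBandReport:
    grade: str
    ec50: float
    band: tuple[float, float] | None
    status: str  # "consistent" | "inconsistent" | "not_applicable"


def grade_band_check(fit: DoseResponseFit, grade: str, partial_agonist: bool = False) -> GradeBandReport:
    """Check a fitted EC50 against the band its two-point grade implies.

    The bands assume full agonism and normal curve steepness, so partial
    agonists (and ungraded pairs or failed fits) report not-applicable.
    """
    if partial_agonist or grade == "none" or not fit.converged:
        return GradeBandReport(grade, fit.ec50, None, "not_applicable")
    lo, hi = GRADE_EC50_BANDS[grade]
    ok = lo <= fit.ec50 <= hi if lo > 0 else fit.ec50 <= hi
    return GradeBandReport(
        grade, fit.ec50, (lo, hi), "consistent" if ok else "inconsistent"
    )
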