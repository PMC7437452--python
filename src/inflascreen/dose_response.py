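"""Four-parameter logistic dose-response fitting and IC50 estimation.

The confirmation screen measures percent inhibition over a dose grid
(default: five half-log doses, 0.1-10 uM) with replicate wells per dose.
The response model is the Hill / four-parameter logistic curve

    r(d) = bottom + (top - bottom) / (1 + (ic50 / d)^hill)

which rises from ``bottom`` at low dose to ``top`` at saturating dose and
crosses the half-way point at d = ic50. Fitting is least squares in
log10-dose space on all replicate points, with a monotone-interpolation
fallback for the 50% crossing when the optimizer fails. Selectivity at each
dose (the counter-screen logic) is assessed by comparing the mean IL-1beta
and IL-6 inhibition: a dose is called "predominant" for IL-1beta when the
difference exceeds a margin and the IL-1beta inhibition itself clears a
floor (both default 30 percentage points, both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import AlignmentError, InsufficientDosesError

FLAT_RANGE = 10.0  # percentage points; below this the curve carries no signal


def hill_curve(dose, bottom, top, ic50, hill):
    """Increasing 4PL response at ``dose`` (uM)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / dose) ** hill)


def _log_hill(logd, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logd)))


@dataclass
class DoseResponseFit:
    compound_id: str
    analyte: str
    doses: np.ndarray
    responses: np.ndarray  # one response per (dose, replicate) point
    ic50: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    converged: bool
    method: str  # "model_fit" or "interpolation"
    flat: bool = False

    def to_row(self) -> dict:
        return {"compound_id": self.compound_id, "analyte": self.analyte,
                "ic50_uM": self.ic50, "hill": self.hill,
                "top": self.top, "bottom": self.bottom,
                "converged": self.converged, "method": self.method, "flat": self.flat}


def _mean_by_dose(doses, responses):
    grid = np.unique(doses)
    means = np.array([np.mean(responses[doses == d]) for d in grid])
    return grid, means


def _interpolate_ic50(grid, means):
    """First 50% crossing of the mean curve, linear in log10-dose; None if none."""
    logd = np.log10(grid)
    for i in range(len(grid) - 1):
        lo, hi = means[i], means[i + 1]
        if (lo - 50.0) * (hi - 50.0) <= 0 and lo != hi:
            x = logd[i] + (50.0 - lo) * (logd[i + 1] - logd[i]) / (hi - lo)
            return float(10.0 ** x)
    return None


def fit_4pl(doses, responses, compound_id: str = "", analyte: str = "",
            fix_hill: float | None = None) -> DoseResponseFit:
    """Fit the 4PL to replicate (dose, response) points.

    Initialization: bottom/top from the extreme mean responses, ic50 at the
    dose whose mean response is nearest half-maximal, hill = 1. Bounds keep
    ic50 within [min dose / 10, max dose x 10] and hill within [0.1, 10].
    A mean-response range under 10 percentage points is flagged flat (no
    IC50). If the optimizer fails, the 50% crossing of the mean curve,
    interpolated in log-dose, is reported instead (``method`` records which
    route produced the IC50).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align point-for-point")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (uM)")
    grid, means = _mean_by_dose(doses, responses)
    if grid.size < 3:
        raise InsufficientDosesError(f"need >= 3 distinct doses, got {grid.size}")

    base = dict(compound_id=compound_id, analyte=analyte, doses=doses, responses=responses)
    if means.max() - means.min() < FLAT_RANGE:
        return DoseResponseFit(**base, ic50=None, hill=None, top=None, bottom=None,
                               converged=False, method="model_fit", flat=True)

    lo_ic, hi_ic = grid.min() / 10.0, grid.max() * 10.0
    half = (means.min() + means.max()) / 2.0
    p0 = [means.min(), means.max(), np.log10(grid[np.argmin(np.abs(means - half))]),
          1.0 if fix_hill is None else fix_hill]
    logd = np.log10(doses)
    try:
        if fix_hill is None:
            popt, _ = curve_fit(
                _log_hill, logd, responses, p0=p0, maxfev=10000,
                bounds=([-1000, -1000, np.log10(lo_ic), 0.1],
                        [1000, 1000, np.log10(hi_ic), 10.0]))
            bottom, top, log_ic50, hill = popt
        else:
            def fixed(ld, bottom, top, log_ic50):
                return _log_hill(ld, bottom, top, log_ic50, fix_hill)
            popt, _ = curve_fit(
                fixed, logd, responses, p0=p0[:3], maxfev=10000,
                bounds=([-1000, -1000, np.log10(lo_ic)], [1000, 1000, np.log10(hi_ic)]))
            bottom, top, log_ic50 = popt
            hill = fix_hill
        # a solution pinned to the ic50 bound is degenerate (the plateau was
        # never reached inside the dose range); report the model-free crossing
        eps = 1e-6
        if log_ic50 - np.log10(lo_ic) > eps and np.log10(hi_ic) - log_ic50 > eps:
            return DoseResponseFit(**base, ic50=float(10.0 ** log_ic50), hill=float(hill),
                                   top=float(max(top, bottom)), bottom=float(min(top, bottom)),
                                   converged=True, method="model_fit")
        ic50 = _interpolate_ic50(grid, means)
        return DoseResponseFit(**base, ic50=ic50, hill=None,
                               top=float(means.max()), bottom=float(means.min()),
                               converged=False, method="interpolation")
    except RuntimeError:
        ic50 = _interpolate_ic50(grid, means)
        return DoseResponseFit(**base, ic50=ic50, hill=None,
                               top=float(means.max()), bottom=float(means.min()),
                               converged=False, method="interpolation")


def interpolated_ic50(doses, responses) -> float | None:
    """Model-free 50% crossing of the mean response curve (log-dose linear)."""
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    grid, means = _mean_by_dose(doses, responses)
    return _interpolate_ic50(grid, means)


@dataclass(frozen=True)
class PredominanceCall:
    """Per-dose selectivity call: does IL-1beta inhibition dominate IL-6?"""

    compound_id: str
    dose: float
    il1b_inhibition: float
    il6_inhibition: float
    predominant: bool


def assess_predominance(il1b_doses, il1b_responses, il6_doses, il6_responses,
                        compound_id: str = "", margin: float = 30.0,
                        floor: float = 30.0) -> list[PredominanceCall]:
    """Call per-dose IL-1beta predominance from paired response arrays.

    Both analytes must have been measured on the same dose grid (an
    :class:`AlignmentError` otherwise); replicates are averaged per dose
    before comparison. A dose is predominant for IL-1beta when
    (IL-1b% - IL-6%) >= margin and IL-1b% >= floor.
    """
    g1, m1 = _mean_by_dose(np.asarray(il1b_doses, dtype=float),
                           np.asarray(il1b_responses, dtype=float))
    g6, m6 = _mean_by_dose(np.asarray(il6_doses, dtype=float),
                           np.asarray(il6_responses, dtype=float))
    if g1.shape != g6.shape or not np.allclose(g1, g6):
        raise AlignmentError("IL-1beta and IL-6 dose grids do not match")
    calls = []
    for d, a, b in zip(g1, m1, m6):
        calls.append(PredominanceCall(
            compound_id=compound_id, dose=float(d),
            il1b_inhibition=float(a), il6_inhibition=float(b),
            predominant=bool((a - b) >= margin and a >= floor)))
    return calls


def count_predominant(calls: list[PredominanceCall]) -> int:
    return sum(c.predominant for c in calls)
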