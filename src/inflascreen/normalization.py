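"""HTRF ratios and control-anchored percent inhibition.

The assay signal is the HTRF ratio, 10000 x Em665/Em620: the acceptor/donor
emission ratio of a time-resolved FRET immunoassay, scaled by 1e4 as plate
readers report it. Each plate carries 16 stimulated DMSO wells (high
controls, maximal cytokine signal) and 16 unstimulated DMSO wells (low
controls, background). A compound well's percent inhibition is anchored to
the same-plate, same-analyte control means:

    inhibition% = 100 * (mu_hc - x) / (mu_hc - mu_lc)

so the high control sits at 0% and the low control at 100%; enhancement of
secretion comes out negative. Control means for normalization use a single
mean +/- 3 SD outlier pass; the Z'/S-B quality metrics deliberately use the
uncleaned statistics (see :mod:`inflascreen.qc`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateWindowError,
    InsufficientControlsError,
    UndefinedRatioError,
    ValidationError,
)
from .plate_io import PlateMap

logger = logging.getLogger(__name__)

ACTIVITY_COLUMNS = ["compound_id", "plate_id", "analyte", "concentration_uM",
                    "htrf_ratio", "percent_inhibition"]


def compute_htrf_ratio(em665, em620):
    """HTRF ratio 10000 x Em665/Em620. Scalar or array.

    Raises :class:`UndefinedRatioError` if any donor-channel count is zero
    (callers that want to drop such wells filter before calling).
    """
    em665 = np.asarray(em665, dtype=float)
    em620 = np.asarray(em620, dtype=float)
    if np.any(em620 <= 0):
        raise UndefinedRatioError("em620 (donor channel) must be > 0")
    ratio = 10000.0 * em665 / em620
    return float(ratio) if ratio.ndim == 0 else ratio


@dataclass(frozen=True)
class ControlStats:
    """Mean/SD of one control group (one plate, analyte and role)."""

    mean: float
    sd: float  # n-1 denominator
    n: int
    outlier_wells: tuple[str, ...] = ()
    cleaned: bool = False


def summarize_controls(values, wells=None, exclude_outliers: bool = True) -> ControlStats:
    """Summarize one plate's control group, optionally excluding outliers.

    The outlier rule is a single pass: mean and SD (n-1 denominator) are
    computed on all values, values outside mean +/- 3 SD are removed, and
    the statistics are recomputed once on the remainder. With
    ``exclude_outliers=False`` the plain statistics on all values are
    returned (the Z'/S-B path).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientControlsError(f"need >= 2 control values, got {values.size}")
    if wells is None:
        wells = [str(i) for i in range(values.size)]
    wells = list(wells)

    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if not exclude_outliers:
        return ControlStats(mean=mu, sd=sd, n=values.size, cleaned=False)

    keep = np.abs(values - mu) <= 3.0 * sd
    if keep.all():
        return ControlStats(mean=mu, sd=sd, n=values.size, cleaned=True)
    kept = values[keep]
    if kept.size < 2:
        raise InsufficientControlsError("outlier exclusion left fewer than 2 controls")
    excluded = tuple(w for w, k in zip(wells, keep) if not k)
    return ControlStats(mean=float(np.mean(kept)), sd=float(np.std(kept, ddof=1)),
                        n=int(kept.size), outlier_wells=excluded, cleaned=True)


@dataclass
class ControlSummary:
    """Paired high/low control statistics for one plate and analyte."""

    plate_id: str
    analyte: str
    hc: ControlStats
    lc: ControlStats
    cleaned: bool

    @property
    def mu_hc(self) -> float:
        return self.hc.mean

    @property
    def mu_lc(self) -> float:
        return self.lc.mean

    @property
    def sigma_hc(self) -> float:
        return self.hc.sd

    @property
    def sigma_lc(self) -> float:
        return self.lc.sd

    @property
    def window_valid(self) -> bool:
        """A stimulated assay needs mu_hc > mu_lc; otherwise the plate is flagged."""
        return self.mu_hc > self.mu_lc

    def to_row(self) -> dict:
        return {
            "plate_id": self.plate_id, "analyte": self.analyte,
            "mu_hc": self.mu_hc, "sigma_hc": self.sigma_hc, "n_hc": self.hc.n,
            "mu_lc": self.mu_lc, "sigma_lc": self.sigma_lc, "n_lc": self.lc.n,
            "outlier_wells": ";".join(self.hc.outlier_wells + self.lc.outlier_wells),
            "cleaned": self.cleaned, "window_valid": self.window_valid,
        }


def percent_inhibition(x, mu_hc: float, mu_lc: float):
    """Control-anchored percent inhibition; 0% at mu_hc, 100% at mu_lc."""
    if mu_hc == mu_lc:
        raise DegenerateWindowError("mu_hc equals mu_lc; percent inhibition undefined")
    x = np.asarray(x, dtype=float)
    pct = 100.0 * (mu_hc - x) / (mu_hc - mu_lc)
    return float(pct) if pct.ndim == 0 else pct


def summarize_plate_controls(measurements: pd.DataFrame, exclude_outliers: bool = True
                             ) -> ControlSummary:
    """Build a :class:`ControlSummary` from one plate+analyte's control rows.

    ``measurements`` must hold exactly one plate_id and analyte, with an
    ``htrf_ratio`` column (see :func:`attach_ratios`).
    """
    plate_id = str(measurements["plate_id"].iloc[0])
    analyte = str(measurements["analyte"].iloc[0])
    groups = {}
    for role in ("high_control", "low_control"):
        sel = measurements[measurements["role"] == role]
        if len(sel) < 2:
            raise InsufficientControlsError(
                f"plate {plate_id}/{analyte}: {len(sel)} {role} wells (need >= 2)")
        groups[role] = summarize_controls(sel["htrf_ratio"].to_numpy(),
                                          wells=sel["well"].tolist(),
                                          exclude_outliers=exclude_outliers)
    summary = ControlSummary(plate_id=plate_id, analyte=analyte,
                             hc=groups["high_control"], lc=groups["low_control"],
                             cleaned=exclude_outliers)
    if not summary.window_valid:
        logger.warning("plate %s/%s: mu_hc <= mu_lc — assay window flagged invalid",
                       plate_id, analyte)
    return summary


def attach_ratios(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add an ``htrf_ratio`` column; split off wells with a zero donor channel.

    Returns ``(with_ratio, dropped)``; dropped wells are logged.
    """
    ok = measurements["em620"] > 0
    dropped = measurements[~ok]
    for _, r in dropped.iterrows():
        logger.warning("plate %s well %s (%s): em620=0, HTRF ratio undefined — well dropped",
                       r["plate_id"], r["well"], r["analyte"])
    kept = measurements[ok].copy()
    kept["htrf_ratio"] = compute_htrf_ratio(kept["em665"].to_numpy(),
                                            kept["em620"].to_numpy())
    return kept, dropped


def normalize_plate(measurements: pd.DataFrame, plate_map: PlateMap | None = None
                    ) -> tuple[pd.DataFrame, ControlSummary, ControlSummary]:
    """Normalize one plate+analyte: ratios -> cleaned controls -> activities.

    Returns ``(activities, summary_cleaned, summary_raw)``. Every compound
    well with a defined ratio yields one activity row normalized against the
    outlier-cleaned control summary of its own plate and analyte; control
    and empty wells yield none. The raw (uncleaned) summary is returned for
    the Z'/S-B quality-control path. When a :class:`PlateMap` is given it
    is authoritative for well roles (a measurement in an unmapped well is an
    error); otherwise the measurement table's own role column is used.
    """
    if plate_map is not None:
        unmapped = [w for w in measurements["well"] if w not in plate_map.assignments]
        if unmapped:
            raise ValidationError(
                f"plate {plate_map.plate_id}: measured well(s) not in plate map: "
                f"{', '.join(sorted(set(unmapped))[:5])}")
        measurements = measurements.assign(
            role=measurements["well"].map(lambda w: plate_map.assignments[w][0]))
    kept, _ = attach_ratios(measurements)
    summary_cleaned = summarize_plate_controls(kept, exclude_outliers=True)
    summary_raw = summarize_plate_controls(kept, exclude_outliers=False)
    if summary_cleaned.mu_hc == summary_cleaned.mu_lc:
        raise DegenerateWindowError(
            f"plate {summary_cleaned.plate_id}/{summary_cleaned.analyte}: "
            "control means coincide")

    cmp_rows = kept[kept["role"] == "compound"]
    activities = pd.DataFrame({
        "compound_id": cmp_rows["compound_id"].to_numpy(),
        "plate_id": cmp_rows["plate_id"].to_numpy(),
        "analyte": cmp_rows["analyte"].to_numpy(),
        "concentration_uM": cmp_rows["concentration_uM"].to_numpy(),
        "htrf_ratio": cmp_rows["htrf_ratio"].to_numpy(),
        "percent_inhibition": percent_inhibition(
            cmp_rows["htrf_ratio"].to_numpy(),
            summary_cleaned.mu_hc, summary_cleaned.mu_lc)
        if len(cmp_rows) else np.array([], dtype=float),
    }, columns=ACTIVITY_COLUMNS)
    return activities, summary_cleaned, summary_raw


def normalize_screen(measurements: pd.DataFrame, plate_maps: dict[str, PlateMap]
                     ) -> tuple[pd.DataFrame, list[ControlSummary], list[ControlSummary]]:
    """Run :func:`normalize_plate` over every (plate, analyte) in a screen.

    Returns the concatenated activity table plus the cleaned and raw control
    summaries, in (plate, analyte) iteration order.
    """
    activities, cleaned, raw = [], [], []
    for (plate_id, analyte), grp in measurements.groupby(["plate_id", "analyte"], sort=False):
        act, cs, rs = normalize_plate(grp, plate_maps.get(str(plate_id)))
        activities.append(act)
        cleaned.append(cs)
        raw.append(rs)
    table = (pd.concat(activities, ignore_index=True)
             if activities else pd.DataFrame(columns=ACTIVITY_COLUMNS))
    return table, cleaned, raw


def summaries_to_frame(summaries: list[ControlSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])
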