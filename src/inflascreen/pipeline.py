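"""End-to-end orchestration: ratios -> QC -> activities -> triage -> confirmation.

This is the library surface the CLI wraps. Each runner takes in-memory
tables, applies the analysis stages in the published order, and returns a
dict of result DataFrames ready for :func:`inflascreen.plate_io.write_results`.
The analysis path contains no randomness: identical inputs and config give
byte-identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import dose_response as dr
from .errors import IncompletePairError
from .hit_calling import ScreenConfig, confirm_hits, triage_primary
from .normalization import normalize_screen, summaries_to_frame
from .plate_io import PlateMap
from .qc import qc_plate

logger = logging.getLogger(__name__)


def run_screen(wells: pd.DataFrame, plate_maps: dict[str, PlateMap],
               annotations: pd.DataFrame | None = None,
               config: ScreenConfig | None = None) -> dict:
    """Primary-screen analysis on raw well measurements.

    Returns a dict with keys ``activity``, ``control_summaries``, ``qc``,
    ``triage``, ``counts``, ``scatter`` (display copy of the per-compound
    percent inhibitions, clipped to [-100, 100]; triage always uses the
    unclipped values). With ``config.exclude_failing_plates`` compounds on
    plates failing the Z' gate (either analyte) are dropped before triage.
    """
    config = config or ScreenConfig()
    activity, cleaned, raw = normalize_screen(wells, plate_maps)
    qc_records = [qc_plate(s, threshold=config.zprime_threshold) for s in raw]
    qc_table = pd.DataFrame([q.to_row() for q in qc_records])

    triage_input = activity
    if config.exclude_failing_plates:
        failing = {(q.plate_id, q.analyte) for q in qc_records if not q.passed}
        bad_plates = {p for p, _ in failing}
        if bad_plates:
            logger.warning("excluding %d plate(s) failing Z' > %.2f: %s",
                           len(bad_plates), config.zprime_threshold,
                           ", ".join(sorted(bad_plates)))
            triage_input = activity[~activity["plate_id"].isin(bad_plates)]

    triage, counts = triage_primary(triage_input, annotations, config)
    scatter = triage[["compound_id", "il1b_percent", "il6_percent"]].copy()
    scatter[["il1b_percent", "il6_percent"]] = scatter[
        ["il1b_percent", "il6_percent"]].clip(-100.0, 100.0)
    for stage, n in counts.items():
        if n:
            logger.info("triage %-32s %6d", stage, n)
    return {
        "activity": activity,
        "control_summaries": summaries_to_frame(cleaned),
        "qc": qc_table,
        "triage": triage,
        "counts": pd.DataFrame(sorted(counts.items()), columns=["stage", "count"]),
        "scatter": scatter,
    }


def run_confirm(responses: pd.DataFrame, config: ScreenConfig | None = None) -> dict:
    """Confirmation-screen analysis on a long dose-response table.

    ``responses`` columns: compound_id, analyte, concentration_uM,
    percent_inhibition (replicate column optional). Fits the 4PL per
    compound and analyte, calls per-dose IL-1beta predominance, and applies
    the confirmation rules. Returns ``fits``, ``predominance``, ``confirmation``.
    """
    config = config or ScreenConfig()
    fit_rows, call_rows, confirm_rows = [], [], []
    for cid, grp in responses.groupby("compound_id", sort=True):
        per_analyte = {}
        ic50_il1b = None
        for analyte, sub in grp.groupby("analyte"):
            fit = dr.fit_4pl(sub["concentration_uM"].to_numpy(),
                             sub["percent_inhibition"].to_numpy(),
                             compound_id=str(cid), analyte=str(analyte))
            per_analyte[analyte] = sub
            fit_rows.append(fit.to_row())
            if analyte == "IL1B":
                ic50_il1b = fit.ic50
        if set(per_analyte) != {"IL1B", "IL6"}:
            raise IncompletePairError("dose-response data missing an analyte", [str(cid)])
        calls = dr.assess_predominance(
            per_analyte["IL1B"]["concentration_uM"].to_numpy(),
            per_analyte["IL1B"]["percent_inhibition"].to_numpy(),
            per_analyte["IL6"]["concentration_uM"].to_numpy(),
            per_analyte["IL6"]["percent_inhibition"].to_numpy(),
            compound_id=str(cid),
            margin=config.predominance_margin, floor=config.predominance_floor)
        call_rows.extend(vars(c) for c in calls)
        confirm_rows.append({"compound_id": str(cid), "ic50_il1b": ic50_il1b,
                             "n_predominant_doses": dr.count_predominant(calls)})

    confirmation = confirm_hits(pd.DataFrame(confirm_rows), config)
    return {
        "fits": pd.DataFrame(fit_rows),
        "predominance": pd.DataFrame(call_rows),
        "confirmation": confirmation,
    }


def mean_plate_stats(qc_table: pd.DataFrame) -> pd.DataFrame:
    """Across-plate mean and SE of Z' and S/B per analyte (the headline QC)."""
    out = []
    for analyte, grp in qc_table.groupby("analyte"):
        n = len(grp)
        out.append({
            "analyte": analyte, "n_plates": n,
            "mean_zprime": grp["z_prime"].mean(),
            "se_zprime": grp["z_prime"].std(ddof=1) / np.sqrt(n),
            "mean_sb": grp["sb_ratio"].mean(),
            "se_sb": grp["sb_ratio"].std(ddof=1) / np.sqrt(n),
        })
    return pd.DataFrame(out)
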