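"""Staged hit triage: primary-screen cascade and confirmation rules.

The primary screen measures every compound once at 1 uM against both
cytokines. Triage applies, in order:

1. keep compounds whose IL-1beta inhibition exceeds a threshold
   (default: strictly more than 30%);
2. exclude compounds that nonspecifically inhibit *or enhance* IL-6
   (|IL-6%| above a band, default 50% — deliberately more relaxed than the
   IL-1beta cut because the IL-6 assay window is narrower);
3. exclude known steroids (broad anti-inflammatories, from annotations);
4. collapse duplicate-compound groups to the strongest IL-1beta inhibitor.

Survivors are ``primary_selected`` and go to dose-response confirmation,
where a compound is confirmed when its IL-1beta IC50 is strictly below a
cutoff (default 10 uM) and IL-1beta inhibition predominates over IL-6 at a
minimum number of doses (default 2). Every compound ends in exactly one
terminal category; the stage counts read as the screen's cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import IncompletePairError

OUTCOMES = (
    "primary_selected",
    "excluded_below_il1b_threshold",
    "excluded_il6_nonspecific",
    "excluded_duplicate",
    "excluded_steroid",
    "confirmation_tested",
    "confirmed_hit",
    "rejected_ic50",
    "rejected_predominance",
)

TRIAGE_COLUMNS = ["compound_id", "il1b_percent", "il6_percent", "outcome"]


@dataclass
class ScreenConfig:
    """All decision thresholds of the screen, echoed into every manifest."""

    il1b_threshold: float = 30.0        # %, strict >
    il6_exclusion_band: float = 50.0    # %, exclude if |IL-6%| > band
    ic50_cutoff: float = 10.0           # uM, strict <
    min_predominant_doses: int = 2
    predominance_margin: float = 30.0   # % points, IL-1b% - IL-6%
    predominance_floor: float = 30.0    # % points, minimum IL-1b%
    zprime_threshold: float = 0.5
    exclude_failing_plates: bool = False
    dose_grid: tuple[float, ...] = (0.1, 0.3, 1.0, 3.0, 10.0)
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def pair_activities(activities: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-analyte activities into one row per compound.

    Expects columns compound_id, analyte, percent_inhibition; raises
    :class:`IncompletePairError` for compounds missing either analyte.
    """
    wide = (activities.pivot_table(index="compound_id", columns="analyte",
                                   values="percent_inhibition", aggfunc="mean")
            .rename(columns={"IL1B": "il1b_percent", "IL6": "il6_percent"}))
    for col in ("il1b_percent", "il6_percent"):
        if col not in wide.columns:
            wide[col] = float("nan")
    incomplete = wide.index[wide[["il1b_percent", "il6_percent"]].isna().any(axis=1)]
    if len(incomplete):
        raise IncompletePairError("compounds missing one analyte", sorted(map(str, incomplete)))
    return wide.reset_index()[["compound_id", "il1b_percent", "il6_percent"]]


def triage_primary(activities: pd.DataFrame, annotations: pd.DataFrame | None,
                   config: ScreenConfig | None = None
                   ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the primary-screen cascade; return outcomes and stage counts.

    ``activities`` is the long per-analyte table (or a pre-paired one with
    il1b_percent/il6_percent columns). Compounds absent from ``annotations``
    are treated as non-steroid singletons (logged by the caller's manifest).
    """
    config = config or ScreenConfig()
    if "il1b_percent" in activities.columns:
        paired = activities[["compound_id", "il1b_percent", "il6_percent"]].copy()
    else:
        paired = pair_activities(activities)

    ann = annotations if annotations is not None else pd.DataFrame(
        columns=["compound_id", "duplicate_group", "is_steroid"])
    paired = paired.merge(
        ann[["compound_id", "duplicate_group", "is_steroid"]]
        if len(ann) else ann, on="compound_id", how="left")
    if "is_steroid" not in paired.columns:
        paired["is_steroid"] = False
        paired["duplicate_group"] = None
    paired["is_steroid"] = paired["is_steroid"].map(
        lambda v: bool(v) if pd.notna(v) else False)

    outcome = pd.Series("primary_selected", index=paired.index)
    below = ~(paired["il1b_percent"] > config.il1b_threshold)
    outcome[below] = "excluded_below_il1b_threshold"
    nonspec = (~below) & (paired["il6_percent"].abs() > config.il6_exclusion_band)
    outcome[nonspec] = "excluded_il6_nonspecific"
    steroid = (outcome == "primary_selected") & paired["is_steroid"]
    outcome[steroid] = "excluded_steroid"

    # duplicate collapse: keep the strongest IL-1beta inhibitor per group
    surv = paired[(outcome == "primary_selected") & paired["duplicate_group"].notna()]
    for _, grp in surv.groupby("duplicate_group"):
        if len(grp) > 1:
            keep = grp["il1b_percent"].idxmax()
            outcome[grp.index.difference([keep])] = "excluded_duplicate"

    result = paired[["compound_id", "il1b_percent", "il6_percent"]].copy()
    result["outcome"] = outcome.to_numpy()
    counts = summarize_cascade(result)
    return result, counts


def confirm_hits(confirmation: pd.DataFrame, config: ScreenConfig | None = None
                 ) -> pd.DataFrame:
    """Apply the confirmation rules to fitted dose-response results.

    ``confirmation`` needs columns compound_id, ic50_il1b (uM or NaN) and
    n_predominant_doses. A compound is confirmed when ic50 < cutoff AND
    predominant doses >= minimum; otherwise the first failing rule is
    recorded (rejected_ic50 before rejected_predominance).
    """
    config = config or ScreenConfig()
    required = {"compound_id", "ic50_il1b", "n_predominant_doses"}
    missing = required - set(confirmation.columns)
    if missing:
        raise IncompletePairError(f"confirmation table missing columns {sorted(missing)}")
    out = confirmation.copy()
    ic50_ok = out["ic50_il1b"].notna() & (out["ic50_il1b"] < config.ic50_cutoff)
    pred_ok = out["n_predominant_doses"] >= config.min_predominant_doses
    out["outcome"] = "confirmed_hit"
    out.loc[~pred_ok, "outcome"] = "rejected_predominance"
    out.loc[~ic50_ok, "outcome"] = "rejected_ic50"  # first failing rule wins
    return out


def summarize_cascade(outcomes: pd.DataFrame) -> dict[str, int]:
    """Terminal-category counts; values sum to the number of compounds."""
    counts = {cat: 0 for cat in OUTCOMES}
    if len(outcomes):
        counts.update(outcomes["outcome"].value_counts().to_dict())
    return counts
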