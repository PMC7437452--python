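"""Seeded synthetic-screen generator with known ground truth.

Emulates a 16-plate, 384-well dual-cytokine screen: each plate carries 16
stimulated (high) and 16 unstimulated (low) DMSO control wells; compound
wells are dosed at 1 uM. Per well and analyte the generator draws a target
HTRF ratio

    ratio = mu_lc + (1 - f) * (mu_hc - mu_lc) + Normal(0, sigma)

where f is the compound's true fractional inhibition at the screening dose
(f = 0 for high controls, f = 1 for low controls) and sigma is the matching
control SD (sigma_hc for stimulated wells — high controls and compound
wells — sigma_lc for low controls). The two raw emission channels are then
emitted so the ratio survives the round trip exactly: em620 is drawn from a
truncated normal and em665 = ratio * em620 / 10000.

The default control-distribution calibration is chosen so the closed-form
plate statistics match an excellent IL-1beta window (population Z' 0.771,
S/B 8.98) and a narrower IL-6 window (Z' 0.471, S/B 4.29).

Compound effects come in five classes: inactive; selective IL-1beta
inhibitor (the planted hits — IC50 drawn log-uniformly, IL-6 untouched);
nonspecific inhibitor (same inhibition of both cytokines); enhancer
(increases both, f = -0.5); cytotoxic (apparent inhibition of both,
f = 0.9). Everything is driven by one numpy Generator seeded from the
config, and the ground truth is returned as a table for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_io import (
    ANNOTATION_COLUMNS,
    PLATE_MAP_COLUMNS,
    WELL_TABLE_COLUMNS,
    PlateMap,
    format_well,
)

EFFECT_CLASSES = ("inactive", "selective_inhibitor", "nonspecific_inhibitor",
                  "enhancer", "cytotoxic")

TRUTH_COLUMNS = ["compound_id", "effect_class", "true_ic50_il1b", "true_ic50_il6",
                 "true_inhibition_il1b_1uM", "true_inhibition_il6_1uM"]


@dataclass(frozen=True)
class AnalyteParams:
    """Control HTRF-ratio distribution for one cytokine readout."""

    mu_hc: float
    mu_lc: float
    sigma_hc: float
    sigma_lc: float

    def population_zprime(self) -> float:
        return 1.0 - 3.0 * (self.sigma_hc + self.sigma_lc) / (self.mu_hc - self.mu_lc)

    def population_sb(self) -> float:
        return self.mu_hc / self.mu_lc


@dataclass
class SimulationConfig:
    n_plates: int = 16
    wells_per_plate: int = 384
    controls_per_plate: int = 16      # per role: 16 high + 16 low
    n_compounds: int = 4825
    screening_dose_uM: float = 1.0
    analyte_params: dict[str, AnalyteParams] = field(default_factory=lambda: {
        "IL1B": AnalyteParams(mu_hc=8980.0, mu_lc=1000.0, sigma_hc=450.0, sigma_lc=160.0),
        "IL6": AnalyteParams(mu_hc=4290.0, mu_lc=1000.0, sigma_hc=430.0, sigma_lc=150.0),
    })
    effect_mix: dict[str, float] = field(default_factory=lambda: {
        "inactive": 0.94, "selective_inhibitor": 0.01, "nonspecific_inhibitor": 0.02,
        "enhancer": 0.01, "cytotoxic": 0.02,
    })
    # log-uniform IC50 range (uM) for actives; the upper end keeps true
    # inhibition at the 1 uM screening dose above ~62% (hill = 1)
    potency_range_uM: tuple[float, float] = (0.05, 0.6)
    response_noise_sd: float = 10.0   # % points, dose-response simulation
    # log-normal plate-to-plate drift: each plate/analyte's ratios are scaled
    # by exp(Normal(0, plate_effect_sigma)); 0 disables (the default — the
    # per-plate normalization makes the analysis invariant to it)
    plate_effect_sigma: float = 0.0
    em620_mean: float = 20000.0
    em620_sd: float = 1000.0
    deterministic_classes: bool = False
    seed: int = 0

    @property
    def compound_wells_per_plate(self) -> int:
        return self.wells_per_plate - 2 * self.controls_per_plate

    def validate(self) -> None:
        total = sum(self.effect_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"effect_mix proportions sum to {total}, not 1")
        unknown = set(self.effect_mix) - set(EFFECT_CLASSES)
        if unknown:
            raise ValidationError(f"unknown effect class(es) {sorted(unknown)}")
        for analyte, p in self.analyte_params.items():
            if p.sigma_hc < 0 or p.sigma_lc < 0:
                raise ValidationError(f"{analyte}: negative control SD")
        cap = self.n_plates * self.compound_wells_per_plate
        if self.n_compounds > cap:
            raise ValidationError(
                f"n_compounds={self.n_compounds} exceeds plate capacity {cap} "
                f"({self.n_plates} plates x {self.compound_wells_per_plate} compound wells)")
        lo, hi = self.potency_range_uM
        if not (0 < lo <= hi):
            raise ValidationError("potency_range_uM must be positive and ordered")

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["analyte_params"] = {k: vars(v) for k, v in self.analyte_params.items()}
        d["potency_range_uM"] = list(self.potency_range_uM)
        return d


def default_calibration(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-scale configuration (16 plates, 4,825 compounds).

    The IL-1beta calibration (mu_hc=8980, mu_lc=1000, sigma_hc=450,
    sigma_lc=160) has population Z' = 1 - 3*610/7980 = 0.7707 and
    S/B = 8.98; the IL-6 calibration (4290/1000/430/150) has
    Z' = 1 - 3*580/3290 = 0.4711 and S/B = 4.29.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.validate()
    return cfg


def planted_screen_config(n_selective: int = 50, seed: int = 0, **overrides
                          ) -> SimulationConfig:
    """Spike-in design for recovery tests: exactly ``n_selective`` selective
    IL-1beta inhibitors planted among otherwise-inactive compounds.

    Uses the default calibration and noise; deterministic class counts. The
    default potency range keeps the planted hits' true IL-1beta inhibition
    at 1 uM above ~62%.
    """
    cfg = SimulationConfig(seed=seed, deterministic_classes=True, **overrides)
    frac = n_selective / cfg.n_compounds
    cfg.effect_mix = {"inactive": 1.0 - frac, "selective_inhibitor": frac}
    cfg.validate()
    return cfg


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    classes = [c for c in EFFECT_CLASSES if cfg.effect_mix.get(c, 0) > 0]
    probs = np.array([cfg.effect_mix[c] for c in classes])
    if cfg.deterministic_classes:
        # exact counts by largest remainder, then a seeded shuffle
        raw = probs * cfg.n_compounds
        counts = np.floor(raw).astype(int)
        rem = cfg.n_compounds - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        labels = np.repeat(classes, counts)
        rng.shuffle(labels)
        return labels
    return rng.choice(classes, size=cfg.n_compounds, p=probs / probs.sum())


def _fraction_at(dose_uM: float, ic50_uM: float) -> float:
    """Hill (slope 1) fractional inhibition at a dose."""
    return 1.0 / (1.0 + ic50_uM / dose_uM)


def simulate_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-compound effect classes, potencies, and true 1 uM inhibitions."""
    classes = _assign_classes(cfg, rng)
    lo, hi = cfg.potency_range_uM
    n = cfg.n_compounds
    ic50 = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    d = cfg.screening_dose_uM

    rows = []
    for i, cls in enumerate(classes):
        cid = f"CPD{i + 1:05d}"
        ic1 = ic6 = None
        if cls == "inactive":
            f1 = f6 = 0.0
        elif cls == "selective_inhibitor":
            ic1 = float(ic50[i])
            f1, f6 = _fraction_at(d, ic1), 0.0
        elif cls == "nonspecific_inhibitor":
            ic1 = ic6 = float(ic50[i])
            f1 = f6 = _fraction_at(d, ic1)
        elif cls == "enhancer":
            f1 = f6 = -0.5
        else:  # cytotoxic
            f1 = f6 = 0.9
        rows.append((cid, cls, ic1, ic6, 100.0 * f1, 100.0 * f6))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _plate_layout(cfg: SimulationConfig, plate_index: int, compound_ids: list[str]
                  ) -> pd.DataFrame:
    """Plate-map rows for one plate: compounds fill columns 1-22 row-major,
    high controls column 23, low controls column 24; unfilled wells empty."""
    plate_id = f"P{plate_index + 1:02d}"
    rows = []
    n_cmp_cols = (cfg.wells_per_plate - 2 * cfg.controls_per_plate) // 16
    k = 0
    for r in range(16):
        for c in range(n_cmp_cols):
            well = format_well(r, c)
            if k < len(compound_ids):
                rows.append((plate_id, well, "compound", compound_ids[k],
                             cfg.screening_dose_uM))
                k += 1
            else:
                rows.append((plate_id, well, "empty", None, None))
    for r in range(cfg.controls_per_plate):
        rows.append((plate_id, format_well(r, n_cmp_cols), "high_control", None, None))
        rows.append((plate_id, format_well(r, n_cmp_cols + 1), "low_control", None, None))
    frame = pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)
    return frame.astype({"compound_id": object, "concentration_uM": float})


@dataclass
class ScreenData:
    """Everything one simulated screen produces."""

    wells: pd.DataFrame       # raw two-channel measurements (well-table schema)
    plate_map: pd.DataFrame   # plate-map schema, all plates
    truth: pd.DataFrame       # ground truth per compound
    annotations: pd.DataFrame  # all non-steroid singletons by default
    config: SimulationConfig

    def plate_maps(self) -> dict[str, PlateMap]:
        maps: dict[str, PlateMap] = {}
        for plate_id, grp in self.plate_map.groupby("plate_id", sort=False):
            pm = PlateMap(plate_id=str(plate_id))
            for _, r in grp.iterrows():
                cid = r["compound_id"] if pd.notna(r["compound_id"]) else None
                conc = float(r["concentration_uM"]) if pd.notna(r["concentration_uM"]) else None
                pm.assignments[r["well"]] = (r["role"], cid, conc)
            maps[str(plate_id)] = pm
        return maps


def simulate_screen(cfg: SimulationConfig | None = None,
                    noise: bool = True) -> ScreenData:
    """Generate one full screen: raw wells, plate maps, truth, annotations.

    Deterministic under a fixed ``cfg.seed``. ``noise=False`` zeroes the
    well-level ratio noise (the emission channels are still randomized) for
    exact-recovery tests.
    """
    cfg = cfg or default_calibration()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    truth = simulate_truth(cfg, rng)
    frac = {"IL1B": truth["true_inhibition_il1b_1uM"].to_numpy() / 100.0,
            "IL6": truth["true_inhibition_il6_1uM"].to_numpy() / 100.0}
    cid_index = {cid: i for i, cid in enumerate(truth["compound_id"])}

    cids = truth["compound_id"].tolist()
    per = cfg.compound_wells_per_plate
    map_frames = [
        _plate_layout(cfg, p, cids[p * per:(p + 1) * per]) for p in range(cfg.n_plates)
    ]
    plate_map = pd.concat(map_frames, ignore_index=True)

    well_rows = []
    used = plate_map[plate_map["role"] != "empty"]
    for analyte, params in cfg.analyte_params.items():
        window = params.mu_hc - params.mu_lc
        role = used["role"].to_numpy()
        f = np.zeros(len(used))
        is_cmp = role == "compound"
        cmp_idx = np.array([cid_index[c] for c in used["compound_id"][is_cmp]])
        f[is_cmp] = frac[analyte][cmp_idx]
        f[role == "low_control"] = 1.0
        sigma = np.where(role == "low_control", params.sigma_lc, params.sigma_hc)
        target = params.mu_lc + (1.0 - f) * window
        if noise:
            target = target + rng.normal(0.0, 1.0, size=len(used)) * sigma
        if cfg.plate_effect_sigma > 0:
            drift = np.exp(rng.normal(0.0, cfg.plate_effect_sigma, size=cfg.n_plates))
            plate_idx = used["plate_id"].str.slice(1).astype(int).to_numpy() - 1
            target = target * drift[plate_idx]
        # fluorescence counts cannot be negative: floor the ratio at zero
        # (only reachable for near-total inhibition plus a deep noise draw)
        target = np.maximum(target, 0.0)
        em620 = np.maximum(rng.normal(cfg.em620_mean, cfg.em620_sd, size=len(used)), 1.0)
        em665 = target * em620 / 10000.0
        frame = used[PLATE_MAP_COLUMNS].copy()
        frame["analyte"] = analyte
        frame["em620"] = em620
        frame["em665"] = em665
        well_rows.append(frame)
    wells = pd.concat(well_rows, ignore_index=True)[WELL_TABLE_COLUMNS]

    annotations = pd.DataFrame({
        "compound_id": truth["compound_id"],
        "library": "synthetic",
        "duplicate_group": None,
        "is_steroid": False,
    }, columns=ANNOTATION_COLUMNS)
    return ScreenData(wells=wells, plate_map=plate_map, truth=truth,
                      annotations=annotations, config=cfg)


def simulate_dose_response(truth: pd.DataFrame, dose_grid=(0.1, 0.3, 1.0, 3.0, 10.0),
                           replicates: int = 4, noise_sd: float = 10.0,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate confirmation-screen responses from the truth table.

    For compounds with a true IC50 the response follows the Hill curve
    (slope 1); enhancers and cytotoxics keep their flat class effect;
    inactives respond at 0. Gaussian noise (``noise_sd`` percentage points)
    is added per replicate well. Returns a long table with columns
    compound_id, analyte, concentration_uM, replicate, percent_inhibition.
    """
    dose_grid = np.asarray(dose_grid, dtype=float)
    if np.any(dose_grid <= 0) or replicates < 1:
        raise ValidationError("dose grid must be positive and replicates >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for _, t in truth.iterrows():
        for analyte, ic_col, f_col in (("IL1B", "true_ic50_il1b", "true_inhibition_il1b_1uM"),
                                       ("IL6", "true_ic50_il6", "true_inhibition_il6_1uM")):
            ic50 = t[ic_col]
            if ic50 is not None and pd.notna(ic50):
                mean = 100.0 / (1.0 + float(ic50) / dose_grid)
            else:
                # flat class effect at every dose (0 for inactive)
                mean = np.full_like(dose_grid, float(t[f_col]))
            for rep in range(replicates):
                resp = mean + (rng.normal(0.0, noise_sd, size=dose_grid.size)
                               if noise_sd > 0 else 0.0)
                for d, r in zip(dose_grid, resp):
                    rows.append((t["compound_id"], analyte, float(d), rep + 1, float(r)))
    return pd.DataFrame(rows, columns=["compound_id", "analyte", "concentration_uM",
                                       "replicate", "percent_inhibition"])
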