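"""Data model and delimited-text I/O for 384-well screening data.

The on-disk formats are plain delimited text (comma or tab, auto-detected):

well table
    plate_id, well, role, compound_id, concentration_uM, analyte, em620, em665
plate map
    plate_id, well, role, compound_id, concentration_uM
annotations
    compound_id, library, duplicate_group, is_steroid

Wells are labelled row letter A-P plus column 1-24 as printed on plates
("A1"); zero-padded labels ("A01") are accepted on input but never written.
Roles are ``high_control`` / ``low_control`` (DMSO wells with and without
stimulation), ``compound`` and ``empty``. The two cytokine readouts, IL1B
and IL6, are stored as separate measurement rows keyed by
(plate_id, well, analyte) because one supernatant is assayed twice.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError, WellLabelError

logger = logging.getLogger(__name__)

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLS = 24

ROLES = ("high_control", "low_control", "compound", "empty")
ANALYTES = ("IL1B", "IL6")

WELL_TABLE_COLUMNS = [
    "plate_id", "well", "role", "compound_id", "concentration_uM",
    "analyte", "em620", "em665",
]
PLATE_MAP_COLUMNS = ["plate_id", "well", "role", "compound_id", "concentration_uM"]
ANNOTATION_COLUMNS = ["compound_id", "library", "duplicate_group", "is_steroid"]


def parse_well(label: str) -> tuple[int, int]:
    """Parse a well label like ``"A1"`` or ``"A01"`` to 0-based (row, col).

    Raises :class:`WellLabelError` for anything outside A1..P24.
    """
    label = str(label).strip().upper()
    if len(label) < 2 or label[0] not in ROW_LETTERS:
        raise WellLabelError(f"unparsable well label {label!r}")
    try:
        col = int(label[1:])
    except ValueError:
        raise WellLabelError(f"unparsable well label {label!r}") from None
    if not 1 <= col <= N_COLS:
        raise WellLabelError(f"well column out of range in {label!r}")
    return ROW_LETTERS.index(label[0]), col - 1


def format_well(row: int, col: int) -> str:
    """0-based (row, col) -> unpadded label, inverse of :func:`parse_well`."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise WellLabelError(f"well coordinate ({row}, {col}) outside a 384-well plate")
    return f"{ROW_LETTERS[row]}{col + 1}"


@dataclass(frozen=True)
class WellMeasurement:
    """One raw two-channel HTRF reading for one well and one analyte."""

    plate_id: str
    well: str
    role: str
    analyte: str
    em620: float
    em665: float
    compound_id: str | None = None
    concentration_uM: float | None = None

    def __post_init__(self):
        parse_well(self.well)  # raises on bad label
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.em620 < 0 or self.em665 < 0:
            raise ValidationError("emission counts must be >= 0")
        if self.role == "compound" and not self.compound_id:
            raise ValidationError("compound wells require a compound_id")
        if self.role in ("high_control", "low_control") and self.compound_id:
            raise ValidationError("control wells are DMSO; compound_id must be absent")
        if self.concentration_uM is not None and not self.concentration_uM > 0:
            raise ValidationError("concentration must be > 0 when present")


@dataclass(frozen=True)
class CompoundAnnotation:
    """Library provenance, duplicate grouping and steroid flag for one compound."""

    compound_id: str
    library: str = ""
    duplicate_group: str | None = None
    is_steroid: bool = False


@dataclass
class PlateMap:
    """Role/compound/concentration assignment of every used well on one plate.

    ``assignments`` maps well label -> (role, compound_id, concentration_uM).
    Control-well geometry is entirely map-driven; nothing is hard-coded.
    """

    plate_id: str
    assignments: dict[str, tuple[str, str | None, float | None]] = field(default_factory=dict)

    def validate(self, controls_per_plate: int = 16) -> None:
        for well, (role, cid, conc) in self.assignments.items():
            parse_well(well)
            if role not in ROLES:
                raise ValidationError(f"plate {self.plate_id}: unknown role {role!r} at {well}")
            if role == "compound" and not cid:
                raise ValidationError(f"plate {self.plate_id}: compound well {well} lacks compound_id")
            if role in ("high_control", "low_control") and cid:
                raise ValidationError(f"plate {self.plate_id}: control well {well} carries a compound_id")
            if conc is not None and not conc > 0:
                raise ValidationError(f"plate {self.plate_id}: non-positive concentration at {well}")
        n_hc = len(self.wells_with_role("high_control"))
        n_lc = len(self.wells_with_role("low_control"))
        if n_hc != controls_per_plate or n_lc != controls_per_plate:
            raise ValidationError(
                f"plate {self.plate_id}: expected {controls_per_plate} high and "
                f"{controls_per_plate} low controls, found {n_hc} high / {n_lc} low"
            )

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, (r, _, _) in self.assignments.items() if r == role]

    def role_of(self, well: str) -> str:
        return self.assignments[well][0]


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    if not header:
        raise FormatError(f"{path}: empty file, no header")
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in header else ","


def _read_delimited(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"plate_id": str, "well": str, "compound_id": str,
                                           "duplicate_group": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _canonical_wells(labels: pd.Series) -> tuple[pd.Series, list[int]]:
    """Canonicalize well labels; return (labels, 1-based data-row numbers of bad ones)."""
    out, bad = [], []
    for i, lab in enumerate(labels):
        try:
            out.append(format_well(*parse_well(lab)))
        except WellLabelError:
            out.append(None)
            bad.append(i + 1)
    return pd.Series(out, index=labels.index), bad


def read_well_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a raw well-measurement table.

    Returns a DataFrame with the canonical :data:`WELL_TABLE_COLUMNS`.
    Any invalid row aborts the read with a :class:`ValidationError` naming
    the 1-based data-row numbers. A header-only file yields an empty frame
    (with a logged warning).
    """
    df = _read_delimited(path, WELL_TABLE_COLUMNS)
    if df.empty:
        logger.warning("%s: well table contains a header but no rows", path)
        return df.reindex(columns=WELL_TABLE_COLUMNS)

    df = df.copy()
    df["well"], bad_wells = _canonical_wells(df["well"])
    bad = set(bad_wells)
    bad |= {i + 1 for i, r in enumerate(df["role"]) if r not in ROLES}
    bad |= {i + 1 for i, a in enumerate(df["analyte"]) if a not in ANALYTES}
    em = df[["em620", "em665"]].apply(pd.to_numeric, errors="coerce")
    bad |= {i + 1 for i, ok in enumerate((em >= 0).all(axis=1) & em.notna().all(axis=1)) if not ok}
    has_cid = df["compound_id"].notna() & (df["compound_id"].astype(str).str.len() > 0)
    bad |= {i + 1 for i, (role, h) in enumerate(zip(df["role"], has_cid))
            if (role == "compound") != h and role in ("compound", "high_control", "low_control")}
    conc = pd.to_numeric(df["concentration_uM"], errors="coerce")
    bad |= {i + 1 for i, (c, raw) in enumerate(zip(conc, df["concentration_uM"]))
            if pd.notna(raw) and not (pd.notna(c) and c > 0)}
    if bad:
        raise ValidationError(f"{path}: invalid well-table rows", sorted(bad))

    df["em620"] = em["em620"].astype(float)
    df["em665"] = em["em665"].astype(float)
    df["concentration_uM"] = conc
    df.loc[~has_cid, "compound_id"] = None
    return df[WELL_TABLE_COLUMNS]


def read_plate_maps(path: str | Path, controls_per_plate: int = 16) -> dict[str, PlateMap]:
    """Read a plate-map file (one or many plates) into validated PlateMaps.

    Duplicate well assignments within a plate and control counts differing
    from ``controls_per_plate`` (16 high + 16 low by default) are errors.
    """
    df = _read_delimited(path, PLATE_MAP_COLUMNS)
    df = df.copy()
    df["well"], bad_wells = _canonical_wells(df["well"])
    if bad_wells:
        raise ValidationError(f"{path}: unparsable well labels", bad_wells)
    maps: dict[str, PlateMap] = {}
    for plate_id, grp in df.groupby("plate_id", sort=False):
        dup = grp["well"][grp["well"].duplicated()].unique()
        if len(dup):
            raise ValidationError(
                f"{path}: plate {plate_id} assigns well(s) {', '.join(dup)} more than once")
        pm = PlateMap(plate_id=str(plate_id))
        for _, r in grp.iterrows():
            cid = r["compound_id"] if pd.notna(r["compound_id"]) else None
            conc = float(r["concentration_uM"]) if pd.notna(r["concentration_uM"]) else None
            pm.assignments[r["well"]] = (r["role"], cid, conc)
        pm.validate(controls_per_plate=controls_per_plate)
        maps[str(plate_id)] = pm
    return maps


def read_plate_map(path: str | Path, plate_id: str | None = None,
                   controls_per_plate: int = 16) -> PlateMap:
    """Read a single PlateMap; ``plate_id`` selects among several in one file."""
    maps = read_plate_maps(path, controls_per_plate=controls_per_plate)
    if plate_id is not None:
        if plate_id not in maps:
            raise ValidationError(f"{path}: no plate {plate_id!r} in map file")
        return maps[plate_id]
    if len(maps) != 1:
        raise ValidationError(
            f"{path}: file holds {len(maps)} plates; pass plate_id to choose one")
    return next(iter(maps.values()))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the compound annotation table (library, duplicate group, steroid flag)."""
    df = _read_delimited(path, ANNOTATION_COLUMNS).copy()
    if df["compound_id"].duplicated().any():
        dups = df["compound_id"][df["compound_id"].duplicated()].unique()
        raise ValidationError(f"{path}: duplicated compound_id(s): {', '.join(map(str, dups[:5]))}")
    df["is_steroid"] = df["is_steroid"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes"))
    sizes = df["duplicate_group"].dropna().value_counts()
    lonely = sizes[sizes < 2]
    if len(lonely):
        raise ValidationError(
            f"{path}: duplicate_group(s) with a single member: {', '.join(lonely.index[:5])}")
    return df[ANNOTATION_COLUMNS]


# Header aliases for the supplementary per-compound workbook, whose exact
# column names vary; matching is case/punctuation-insensitive.
_WORKBOOK_ALIASES = {
    "compound_id": ("compoundid", "compound", "id", "compoundname", "name", "sampleid"),
    "il1b_percent": ("il1b", "il1bpercent", "il1binhibition", "il1bpercentinhibition",
                     "percentinhibitionil1b", "il1"),
    "il6_percent": ("il6", "il6percent", "il6inhibition", "il6percentinhibition",
                    "percentinhibitionil6"),
}


def read_supplementary_workbook(path: str | Path) -> pd.DataFrame:
    """Read a per-compound screen-result spreadsheet into the activity schema.

    Tolerates renamed headers (e.g. "IL-1b % inhibition"); returns a frame
    with columns compound_id, il1b_percent, il6_percent — one row per
    compound, percent inhibition at the screening dose.
    """
    raw = pd.read_excel(path)
    norm = {c: "".join(ch for ch in str(c).lower() if ch.isalnum()) for c in raw.columns}
    mapping = {}
    for target, aliases in _WORKBOOK_ALIASES.items():
        for col, n in norm.items():
            if n in aliases or any(n.startswith(a) and len(a) > 2 for a in aliases):
                mapping[target] = col
                break
    missing = [t for t in _WORKBOOK_ALIASES if t not in mapping]
    if missing:
        raise FormatError(f"{path}: could not locate column(s) {missing} in workbook "
                          f"headers {list(raw.columns)}")
    out = pd.DataFrame({
        "compound_id": raw[mapping["compound_id"]].astype(str),
        "il1b_percent": pd.to_numeric(raw[mapping["il1b_percent"]], errors="coerce"),
        "il6_percent": pd.to_numeric(raw[mapping["il6_percent"]], errors="coerce"),
    })
    return out.dropna(subset=["il1b_percent", "il6_percent"]).reset_index(drop=True)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  sep: str = ",") -> pd.DataFrame:
    """Write result tables as delimited text and return a file manifest.

    ``tables`` maps a short name ("qc", "activity", ...) to a DataFrame.
    Column order is preserved as given (deterministic). The manifest lists
    every written file with its row count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in tables.items():
        fname = f"{name}.csv" if sep == "," else f"{name}.tsv"
        fpath = out_dir / fname
        df.to_csv(fpath, sep=sep, index=False)
        rows.append({"name": name, "path": str(fpath), "rows": len(df)})
    return pd.DataFrame(rows, columns=["name", "path", "rows"])
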