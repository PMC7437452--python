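"""Per-plate assay-quality metrics: Z'-factor, signal-to-background, CV.

Z' = 1 - (3*sigma_hc + 3*sigma_lc) / (mu_hc - mu_lc) is the screening-window
coefficient; a value above 0.5 marks an excellent assay (it can never exceed
1 and is negative when the control bands overlap). S/B = mu_hc / mu_lc.
Both are computed from the *uncleaned* control statistics — the outlier
exclusion used for normalization is deliberately not applied here, so the
quality metrics reflect the plate as measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateWindowError
from .normalization import ControlSummary


def compute_zprime(mu_hc: float, mu_lc: float, sigma_hc: float, sigma_lc: float) -> float:
    if mu_hc == mu_lc:
        raise DegenerateWindowError("Z' undefined: mu_hc equals mu_lc")
    return 1.0 - (3.0 * sigma_hc + 3.0 * sigma_lc) / (mu_hc - mu_lc)


def compute_sb(mu_hc: float, mu_lc: float) -> float:
    if mu_lc == 0:
        raise DegenerateWindowError("S/B undefined: mu_lc is zero")
    return mu_hc / mu_lc


def compute_cv(values) -> float:
    """Coefficient of variation of replicate measurements, in percent."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"CV needs >= 2 values, got {values.size}")
    mean = float(np.mean(values))
    if mean == 0:
        raise ZeroDivisionError("CV undefined: mean is zero")
    return 100.0 * float(np.std(values, ddof=1)) / mean


@dataclass
class PlateQC:
    plate_id: str
    analyte: str
    z_prime: float  # NaN when the window is degenerate
    sb_ratio: float
    n_hc: int
    n_lc: int
    passed: bool
    error: str | None = None

    def to_row(self) -> dict:
        return {"plate_id": self.plate_id, "analyte": self.analyte,
                "z_prime": self.z_prime, "sb_ratio": self.sb_ratio,
                "n_hc": self.n_hc, "n_lc": self.n_lc,
                "pass": self.passed, "error": self.error or ""}


def qc_plate(summary_raw: ControlSummary, threshold: float = 0.5) -> PlateQC:
    """Score one plate/analyte from its uncleaned control summary.

    ``passed`` is strict: Z' must exceed the threshold (default 0.5).
    A degenerate window yields a flagged, failing record rather than an
    exception — failing plates are reported, never silently dropped;
    whether to exclude them is a pipeline-level choice.
    """
    if summary_raw.cleaned:
        raise ValueError("qc_plate requires the uncleaned control summary")
    try:
        z = compute_zprime(summary_raw.mu_hc, summary_raw.mu_lc,
                           summary_raw.sigma_hc, summary_raw.sigma_lc)
        sb = compute_sb(summary_raw.mu_hc, summary_raw.mu_lc)
        err = None
    except DegenerateWindowError as exc:
        z, sb, err = math.nan, math.nan, str(exc)
    return PlateQC(plate_id=summary_raw.plate_id, analyte=summary_raw.analyte,
                   z_prime=z, sb_ratio=sb,
                   n_hc=summary_raw.hc.n, n_lc=summary_raw.lc.n,
                   passed=(err is None and z > threshold), error=err)
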