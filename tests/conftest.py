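import numpy as np
import pandas as pd
import pytest

from inflascreen.synthetic import (
    AnalyteParams,
    SimulationConfig,
    default_calibration,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A 2-plate, 120-compound screen with the default calibration."""
    cfg = default_calibration(seed=123, n_plates=2, n_compounds=120)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def full_screen():
    """The full study-scale screen (16 plates, 4,825 compounds)."""
    return simulate_screen(default_calibration(seed=2024))


def noiseless_config(seed=0, **overrides):
    """All-control-noise-free configuration for exactness tests."""
    params = {
        "IL1B": AnalyteParams(mu_hc=8980.0, mu_lc=1000.0, sigma_hc=0.0, sigma_lc=0.0),
        "IL6": AnalyteParams(mu_hc=4290.0, mu_lc=1000.0, sigma_hc=0.0, sigma_lc=0.0),
    }
    base = dict(seed=seed, n_plates=1, n_compounds=40, analyte_params=params,
                effect_mix={"inactive": 1.0})
    base.update(overrides)
    cfg = SimulationConfig(**base)
    cfg.validate()
    return cfg


@pytest.fixture
def single_plate_measurements():
    """Hand-built one-plate/one-analyte table: sigma-0 controls plus one
    compound well at the window midpoint-ish ratio 4500 (8000/1000 window)."""
    rows = []
    for i in range(16):
        rows.append(("P1", f"A{i + 1}", "high_control", None, None, "IL1B", 10000.0, 8000.0))
        rows.append(("P1", f"B{i + 1}", "low_control", None, None, "IL1B", 10000.0, 1000.0))
    rows.append(("P1", "C1", "compound", "CPDX", 1.0, "IL1B", 10000.0, 4500.0))
    return pd.DataFrame(rows, columns=[
        "plate_id", "well", "role", "compound_id", "concentration_uM",
        "analyte", "em620", "em665"])
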