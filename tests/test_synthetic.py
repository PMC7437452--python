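import numpy as np
import pandas as pd
import pytest

from inflascreen import synthetic as syn
from inflascreen.errors import ValidationError
from inflascreen.hit_calling import triage_primary
from inflascreen.normalization import compute_htrf_ratio, normalize_screen
from conftest import noiseless_config


class TestDefaultCalibration:
    def test_il1b_closed_form_statistics(self):
        p = syn.default_calibration().analyte_params["IL1B"]
        assert p.population_zprime() == pytest.approx(0.7707, abs=5e-4)
        assert p.population_sb() == pytest.approx(8.98)

    def test_il6_closed_form_statistics(self):
        p = syn.default_calibration().analyte_params["IL6"]
        assert p.population_zprime() == pytest.approx(0.4711, abs=5e-4)
        assert p.population_sb() == pytest.approx(4.29)

    def test_study_scale_defaults(self):
        cfg = syn.default_calibration()
        assert (cfg.n_plates, cfg.wells_per_plate, cfg.controls_per_plate,
                cfg.n_compounds) == (16, 384, 16, 4825)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        cfg = syn.SimulationConfig(effect_mix={"inactive": 0.8, "cytotoxic": 0.4})
        with pytest.raises(ValidationError, match="sum"):
            cfg.validate()

    def test_capacity_bound(self):
        cfg = syn.SimulationConfig(n_plates=1, n_compounds=400)
        with pytest.raises(ValidationError, match="capacity"):
            cfg.validate()


class TestSimulateScreen:
    def test_same_seed_is_bit_identical(self):
        cfg = syn.default_calibration(seed=9, n_plates=2, n_compounds=100)
        a = syn.simulate_screen(cfg)
        b = syn.simulate_screen(syn.default_calibration(seed=9, n_plates=2,
                                                        n_compounds=100))
        pd.testing.assert_frame_equal(a.wells, b.wells)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_table_conservation(self, small_screen):
        assert len(small_screen.truth) == small_screen.config.n_compounds
        assert small_screen.truth["compound_id"].is_unique

    def test_channel_round_trip_recovers_target_ratio(self):
        """With zero ratio noise every compound well's ratio is exactly mu_hc."""
        data = syn.simulate_screen(noiseless_config(seed=3))
        cmp_rows = data.wells[(data.wells["role"] == "compound")
                              & (data.wells["analyte"] == "IL1B")]
        ratios = compute_htrf_ratio(cmp_rows["em665"].to_numpy(),
                                    cmp_rows["em620"].to_numpy())
        np.testing.assert_allclose(ratios, 8980.0, rtol=1e-12)

    def test_all_inactive_zero_noise_gives_exactly_zero_inhibition(self):
        data = syn.simulate_screen(noiseless_config(seed=4))
        activities, *_ = normalize_screen(data.wells, data.plate_maps())
        np.testing.assert_allclose(activities["percent_inhibition"], 0.0, atol=1e-9)

    def test_planted_full_inhibitors_recovered_exactly(self):
        """10 planted near-complete selective inhibitors, zero noise: triage
        selects exactly those 10."""
        cfg = noiseless_config(
            seed=5, n_compounds=100, deterministic_classes=True,
            effect_mix={"inactive": 0.9, "selective_inhibitor": 0.1},
            potency_range_uM=(1e-6, 1e-6))  # f ~ 1 at 1 uM
        data = syn.simulate_screen(cfg)
        activities, *_ = normalize_screen(data.wells, data.plate_maps())
        out, counts = triage_primary(activities, data.annotations)
        planted = set(data.truth.loc[
            data.truth["effect_class"] == "selective_inhibitor", "compound_id"])
        selected = set(out.loc[out["outcome"] == "primary_selected", "compound_id"])
        assert selected == planted and counts["primary_selected"] == 10

    def test_deterministic_class_counts_are_exact(self):
        cfg = syn.default_calibration(seed=6, n_plates=2, n_compounds=200,
                                      deterministic_classes=True)
        truth = syn.simulate_screen(cfg).truth
        counts = truth["effect_class"].value_counts()
        assert counts["inactive"] == 188  # 0.94 * 200
        assert counts["nonspecific_inhibitor"] == 4
        assert counts["cytotoxic"] == 4

    def test_plate_drift_cancels_in_normalization(self):
        """Per-plate log-normal drift leaves percent inhibition unchanged,
        because normalization is anchored to same-plate controls."""
        base = syn.simulate_screen(noiseless_config(seed=12, n_plates=2,
                                                    n_compounds=80))
        drifted = syn.simulate_screen(noiseless_config(seed=12, n_plates=2,
                                                       n_compounds=80,
                                                       plate_effect_sigma=0.3))
        a0, *_ = normalize_screen(base.wells, base.plate_maps())
        a1, *_ = normalize_screen(drifted.wells, drifted.plate_maps())
        np.testing.assert_allclose(a1["percent_inhibition"],
                                   a0["percent_inhibition"], atol=1e-8)

    def test_trailing_wells_are_empty(self, small_screen):
        pm = small_screen.plate_map
        # 120 compounds over 2 plates: second plate holds 120-352 < 352, so empties exist
        assert (pm["role"] == "empty").sum() == 2 * 352 - 120
        assert small_screen.wells["role"].isin(["high_control", "low_control",
                                                "compound"]).all()


class TestPlantedScreenConfig:
    def test_exact_spike_in_counts(self):
        cfg = syn.planted_screen_config(n_selective=50, seed=1)
        truth = syn.simulate_screen(cfg).truth
        assert (truth["effect_class"] == "selective_inhibitor").sum() == 50
        planted = truth[truth["effect_class"] == "selective_inhibitor"]
        assert (planted["true_inhibition_il1b_1uM"] >= 60.0).all()
        assert (planted["true_inhibition_il6_1uM"] == 0.0).all()


class TestSimulateDoseResponse:
    def _truth_row(self, ic50=2.0):
        return pd.DataFrame([{
            "compound_id": "C1", "effect_class": "selective_inhibitor",
            "true_ic50_il1b": ic50, "true_ic50_il6": None,
            "true_inhibition_il1b_1uM": 100 / (1 + ic50),
            "true_inhibition_il6_1uM": 0.0}])

    def test_hill_midpoint_is_fifty_percent(self):
        table = syn.simulate_dose_response(self._truth_row(2.0), dose_grid=[2.0],
                                           replicates=1, noise_sd=0.0)
        il1b = table[table["analyte"] == "IL1B"]
        assert il1b["percent_inhibition"].iloc[0] == pytest.approx(50.0)

    def test_row_conservation(self):
        table = syn.simulate_dose_response(self._truth_row(), replicates=4)
        for analyte in ("IL1B", "IL6"):
            assert len(table[table["analyte"] == analyte]) == 5 * 4

    def test_inactive_compound_pure_noise(self):
        truth = self._truth_row().assign(effect_class="inactive",
                                         true_ic50_il1b=None,
                                         true_inhibition_il1b_1uM=0.0)
        table = syn.simulate_dose_response(truth, replicates=2, noise_sd=0.0)
        np.testing.assert_allclose(table["percent_inhibition"], 0.0)
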