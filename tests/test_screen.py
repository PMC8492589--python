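"""Well normalization, prescreen testing, classification, ABT comparisons."""

import numpy as np
import pytest

from scmetox.imaging import FieldSummary
from scmetox.screen import (
    HIGH_UM,
    LOW_UM,
    PARAMETERS,
    abt_effect,
    classify_prescreen,
    frame_to_wells,
    run_prescreen,
    summarize_well,
    wells_to_frame,
)
from scmetox.simulate import PlateSimConfig, simulate_plate


def _field(count=10, area=100.0, nuc_int=5e4, mito=2e4, cal=1.5e4, mem=8e3,
           qc=True):
    return FieldSummary(
        region_count=count,
        mean_region_area=area,
        total_nuclei_intensity=nuc_int,
        channel_totals={"mito": mito, "calcium": cal, "membrane": mem},
        qc_pass=qc,
    )


class TestSummarizeWell:
    def test_constant_fields_give_their_count(self):
        well = summarize_well([_field(10)] * 6, well_id="B2")
        assert well.parameters["cell_count"] == 10

    def test_count_normalized_to_passing_fields(self):
        fields = [_field(10)] * 5 + [_field(37, qc=False)]
        well = summarize_well(fields, well_id="B2")
        assert well.parameters["cell_count"] == 10  # 50 regions / 5 fields

    def test_mito_parameter_is_linear_in_channel_total(self):
        full = summarize_well([_field(mito=2e4)] * 6, well_id="a")
        half = summarize_well([_field(mito=1e4)] * 6, well_id="b")
        assert half.parameters["mito_potential"] == pytest.approx(
            full.parameters["mito_potential"] / 2
        )

    def test_intensity_parameters_normalized_to_cell_count(self):
        sparse = summarize_well([_field(count=10)] * 6, well_id="a")
        dense = summarize_well([_field(count=20)] * 6, well_id="b")
        assert dense.parameters["mito_potential"] == pytest.approx(
            sparse.parameters["mito_potential"] / 2
        )

    def test_scaling_all_intensities_scales_intensity_parameters_only(self):
        k = 3.7
        base = summarize_well([_field()] * 6, well_id="a")
        scaled = summarize_well(
            [_field(nuc_int=5e4 * k, mito=2e4 * k, cal=1.5e4 * k, mem=8e3 * k)] * 6,
            well_id="b",
        )
        assert scaled.parameters["cell_count"] == base.parameters["cell_count"]
        for p in ("nuclear_intensity", "mito_potential", "calcium",
                  "membrane_integrity"):
            assert scaled.parameters[p] == pytest.approx(k * base.parameters[p])

    def test_no_passing_fields_excludes_well_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            assert summarize_well([_field(qc=False)] * 6, well_id="bad") is None

    def test_no_detected_nuclei_excludes_well_with_warning(self):
        with pytest.warns(UserWarning, match="no nuclei"):
            assert summarize_well([_field(count=0)] * 6, well_id="empty") is None


class TestClassificationRule:
    def _flags(self, low=(), high=()):
        return (
            {p: p in low for p in PARAMETERS},
            {p: p in high for p in PARAMETERS},
        )

    @pytest.mark.parametrize(
        "low,high,verdict",
        [
            # >=2 parameters hit at the low concentration -> strong
            (("mito_potential", "calcium"), (), "strong"),
            (("mito_potential", "calcium", "cell_count"),
             ("mito_potential",), "strong"),
            # one low + one further high -> moderate
            (("mito_potential",), ("cell_count",), "moderate"),
            (("mito_potential",), ("mito_potential", "cell_count"), "moderate"),
            # effects only at the high concentration -> negative
            ((), ("cell_count", "calcium"), "negative"),
            # a single affected parameter is not enough for moderate
            (("mito_potential",), (), "negative"),
            ((), (), "negative"),
        ],
    )
    def test_verdict_follows_decision_rule(self, low, high, verdict):
        sig_low, sig_high = self._flags(low, high)
        result = classify_prescreen(sig_low, sig_high, compound="X")
        assert result.verdict == verdict

    def test_reported_study_patterns_reproduce_published_verdicts(self):
        # JWH-200 / A-796260: several parameters already hit at 7.81 uM
        sig_low, sig_high = self._flags(
            ("mito_potential", "calcium"), ("cell_count", "mito_potential")
        )
        assert classify_prescreen(sig_low, sig_high, "JWH-200").verdict == "strong"
        sig_low, sig_high = self._flags(
            ("mito_potential", "nuclear_intensity"), ("mito_potential",)
        )
        assert classify_prescreen(sig_low, sig_high, "A-796260").verdict == "strong"
        # 5F-EMB-PINACA: one parameter at 7.81 uM, another only at 125 uM
        sig_low, sig_high = self._flags(("cell_count",), ("mito_potential",))
        assert classify_prescreen(sig_low, sig_high, "5F-EMB-PINACA").verdict == "moderate"

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            classify_prescreen({}, {p: False for p in PARAMETERS})

    def test_report_notes_moderate_rule_reading(self):
        sig_low, sig_high = self._flags(("mito_potential",), ("cell_count",))
        assert "ambiguous" in classify_prescreen(sig_low, sig_high).note


class TestRunPrescreen:
    def test_strong_preset_plate_classified_strong(self):
        wells = simulate_plate(PlateSimConfig(preset="strong", seed=0))
        report = run_prescreen(wells)
        assert report.classification.verdict == "strong"
        assert "mito_potential" in report.classification.significant_low

    def test_flat_plate_classified_negative(self):
        wells = simulate_plate(PlateSimConfig(seed=1))  # no effects at all
        report = run_prescreen(wells, pvalues=False)
        assert report.classification.verdict == "negative"

    def test_missing_concentration_level_rejected(self):
        wells = simulate_plate(
            PlateSimConfig(seed=0, concentrations=(0.0, LOW_UM))
        )
        with pytest.raises(ValueError, match="125"):
            run_prescreen(wells)

    def test_abt_blank_effect_reported(self):
        config = PlateSimConfig(
            preset="negative", seed=3, abt_effects={"mito_potential": -0.4}
        )
        report = run_prescreen(simulate_plate(config), pvalues=False)
        flagged = [r.label for r in report.abt_comparisons if r.significant]
        assert any("mito_potential" in lab and "blank" in lab for lab in flagged)

    def test_summary_text_states_verdict(self):
        wells = simulate_plate(PlateSimConfig(preset="moderate", seed=4))
        text = run_prescreen(wells, pvalues=False).summary()
        assert "verdict: moderate" in text


class TestAbtEffect:
    def _arms(self, seed=0, abt_effects=None):
        config = PlateSimConfig(
            preset="negative", seed=seed, abt_effects=abt_effects or {}
        )
        wells = simulate_plate(config)
        return ([w for w in wells if w.abt], [w for w in wells if not w.abt])

    def test_identical_arms_show_no_differences(self):
        with_abt, without_abt = self._arms(seed=8)
        results = abt_effect(with_abt, without_abt)
        assert sum(r.significant for r in results) <= 1  # chance level

    def test_planted_membrane_effect_is_flagged(self):
        with_abt, without_abt = self._arms(
            seed=9, abt_effects={"membrane_integrity": 0.8}
        )
        results = abt_effect(with_abt, without_abt)
        flagged = {r.label for r in results if r.significant}
        assert any("membrane_integrity" in lab for lab in flagged)
        assert not any("nuclear_size" in lab for lab in flagged)

    def test_empty_arm_rejected(self):
        _, without_abt = self._arms()
        with pytest.raises(ValueError):
            abt_effect([], without_abt)

    def test_unmatched_treatments_rejected(self):
        with_abt, without_abt = self._arms()
        trimmed = [w for w in without_abt if w.concentration != HIGH_UM]
        with pytest.raises(ValueError, match="unmatched"):
            abt_effect(with_abt, trimmed)


class TestTabularInterchange:
    def test_well_table_round_trips(self):
        wells = simulate_plate(PlateSimConfig(preset="strong", seed=2))
        frame = wells_to_frame(wells)
        back = frame_to_wells(frame)
        assert len(back) == len(wells)
        for a, b in zip(wells, back):
            assert (a.well_id, a.compound, a.concentration, a.abt,
                    a.control_type, a.replicate) == (
                b.well_id, b.compound, b.concentration, b.abt,
                b.control_type, b.replicate)
            for p in PARAMETERS:
                assert b.parameters[p] == pytest.approx(a.parameters[p])
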