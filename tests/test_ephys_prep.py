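"""Ephys record filtering, condition normalization, summarization, and the
derived single-cell features."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import genephys as gp
from genephys.synthetic_data import LabEffect, REFERENCE_TEMP_C


def _rec(prop="Vrest", value=-65.0, **kw):
    defaults = dict(
        article_id="a1", cell_type_label="T1", property=prop, value=value,
        species="mouse", preparation="acute_slice", electrode="patch",
        jxn_status="unreported", age_lo_days=14.0, age_hi_days=14.0,
        rec_temp_C=33.0,
    )
    defaults.update(kw)
    return gp.EphysMeasurement(**defaults)


class TestPreprocess:
    def test_age_range_collapses_to_geometric_mean(self, rc):
        (out,) = gp.preprocess_measurements(
            [_rec(age_lo_days=14, age_hi_days=20)], rc
        )
        assert out.age_lo_days == pytest.approx(np.sqrt(14 * 20))  # ~16.73
        assert out.age_hi_days == out.age_lo_days

    def test_non_slice_and_wrong_species_and_young_removed(self, rc):
        records = [
            _rec(article_id="keep"),
            _rec(article_id="vivo", preparation="in_vivo"),
            _rec(article_id="other", species="other"),
            _rec(article_id="young", age_lo_days=1.5, age_hi_days=1.5),
        ]
        out = gp.preprocess_measurements(records, rc)
        assert [r.article_id for r in out] == ["keep"]

    def test_missing_temperature_imputed_with_median(self, rc):
        records = [
            _rec(article_id=a, rec_temp_C=t)
            for a, t in [("a", 32.0), ("b", 34.0), ("c", 36.0), ("d", None)]
        ]
        out = gp.preprocess_measurements(records, rc)
        assert out[-1].rec_temp_C == 34.0

    def test_missing_age_imputed_with_median(self, rc):
        records = [
            _rec(article_id=a, age_lo_days=v, age_hi_days=v)
            for a, v in [("a", 10.0), ("b", 20.0), ("c", 40.0), ("d", None)]
        ]
        out = gp.preprocess_measurements(records, rc)
        assert out[-1].age_lo_days == 20.0

    def test_configured_exclusions_removed(self):
        cfg = gp.RunConfig(seed=0, exclusions=(("G42 P15", "APthr"),))
        records = [
            _rec(prop="APthr", value=-40, cell_type_label="G42 P15"),
            _rec(prop="APthr", value=-40, cell_type_label="CA1 Pyr"),
        ]
        out = gp.preprocess_measurements(records, cfg)
        assert [r.cell_type_label for r in out] == ["CA1 Pyr"]

    def test_ljp_correction_reverted_on_absolute_voltages_only(self, rc):
        records = [
            _rec(prop="Vrest", value=-70.0, jxn_status="corrected", jxn_offset_mV=10.0),
            _rec(prop="APamp", value=80.0, jxn_status="corrected", jxn_offset_mV=10.0),
            _rec(prop="Vrest", value=-70.0, jxn_status="corrected", jxn_offset_mV=None),
        ]
        out = gp.preprocess_measurements(records, rc)
        assert out[0].value == -60.0 and out[0].jxn_status == "post_corrected"
        assert out[1].value == 80.0 and out[1].jxn_status == "corrected"
        assert out[2].value == -70.0 and out[2].jxn_status == "corrected"


class TestDerivedFeatures:
    @pytest.mark.parametrize(
        "isis, expected",
        [([20, 20, 20], 1.0), ([10, 20, 30], 0.5), ([15], 1.0)],
    )
    def test_sfa_is_first_over_mean_interval(self, isis, expected):
        assert gp.compute_sfa(isis) == pytest.approx(expected)

    def test_sfa_rejects_empty_or_nonpositive_trains(self):
        with pytest.raises(ValueError):
            gp.compute_sfa([])
        with pytest.raises(ValueError):
            gp.compute_sfa([10, 0, 5])

    @pytest.mark.parametrize(
        "tau, rin, pf", [(20.0, 200.0, 100.0), (10.0, 100.0, 100.0)]
    )
    def test_capacitance_unit_arithmetic(self, tau, rin, pf):
        assert gp.derive_capacitance(tau, rin) == pytest.approx(pf)

    def test_capacitance_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            gp.derive_capacitance(20.0, 0.0)

    def test_max_rate_sweep_argmax_and_rate(self):
        assert gp.select_max_rate_sweep([2, 10, 7], 1.0) == (2, 10.0)
        assert gp.select_max_rate_sweep([4], 0.5) == (1, 8.0)

    def test_max_rate_tie_keeps_first_sweep(self, caplog):
        with caplog.at_level("INFO", logger="genephys.ephys_prep"):
            assert gp.select_max_rate_sweep([5, 5], 1.0) == (1, 5.0)
        assert any("tie" in r.message for r in caplog.records)

    def test_no_spikes_flags_zero_rate(self, caplog):
        with caplog.at_level("WARNING", logger="genephys.ephys_prep"):
            idx, fr = gp.select_max_rate_sweep([0, 0], 1.0)
        assert fr == 0.0
        assert any("no spikes" in r.message for r in caplog.records)


class TestSummarize:
    def test_article_mean_then_median_across_articles(self):
        records = [
            _rec(article_id="a1", value=-60.0),
            _rec(article_id="a1", value=-62.0),  # article mean -61
            _rec(article_id="a2", value=-65.0),
            _rec(article_id="a3", value=-70.0),
        ]
        out = gp.summarize_ephys_by_cell_type(records)
        assert out.loc["T1", "Vrest"] == -65.0

    def test_order_invariance_and_missingness(self):
        records = [
            _rec(article_id="a1", value=-60.0),
            _rec(article_id="a2", value=-70.0),
            _rec(article_id="a3", prop="Rin", value=150.0, cell_type_label="T2"),
        ]
        fwd = gp.summarize_ephys_by_cell_type(records)
        rev = gp.summarize_ephys_by_cell_type(records[::-1])
        pd.testing.assert_frame_equal(fwd, rev)
        assert np.isnan(fwd.loc["T2", "Vrest"])
        assert np.isnan(fwd.loc["T1", "Rin"])


def _synthetic_temp_records(seed, n_types=30):
    cfg = gp.SyntheticConfig(seed=seed, n_cell_types=n_types, n_genes=20)
    truth = gp.GroundTruth(
        planted_effects=[],
        lab_effects=[LabEffect("Vrest", "temp", 0.5)],
        null_genes=set(cfg.gene_ids()),
    )
    _, recs, truth = gp.generate_discovery_dataset(cfg, truth)
    rc = gp.RunConfig(seed=seed)
    pre = [r for r in gp.preprocess_measurements(recs, rc) if r.property == "Vrest"]
    return pre, truth, rc


class TestConditionModel:
    def test_planted_temperature_slope_mostly_removed(self):
        pre, truth, rc = _synthetic_temp_records(0)
        model = gp.fit_condition_model(pre, "Vrest", rc)
        adjusted = gp.adjust_measurements(model, pre)
        lat = truth.latent_ephys["Vrest"]
        temps = np.array([r.rec_temp_C for r in pre])
        resid = np.array([r.value - lat[r.cell_type_label] for r in adjusted])
        slope = np.polyfit(temps, resid, 1)[0]
        assert abs(slope) <= 0.2 * 0.5

    def test_zero_metadata_variation_reduces_to_cell_type_means(self, rc):
        rng = np.random.default_rng(1)
        records = [
            _rec(article_id=f"a{i}", cell_type_label=f"T{i % 5}",
                 value=float(rng.normal(-65, 5)))
            for i in range(20)
        ]
        model = gp.fit_condition_model(records, "Vrest", rc)
        adjusted = gp.adjust_measurements(model, records)
        for before, after in zip(records, adjusted):
            assert after.value == pytest.approx(before.value, abs=1e-6)

    def test_duplicated_dataset_gives_identical_coefficients(self):
        pre, _, rc = _synthetic_temp_records(2, n_types=12)
        m1 = gp.fit_condition_model(pre, "Vrest", rc)
        m2 = gp.fit_condition_model(pre + pre, "Vrest", rc)
        for k, v in m1.coefficients.items():
            assert m2.coefficients[k] == pytest.approx(v, abs=1e-8)

    def test_record_at_reference_conditions_is_unchanged(self):
        pre, _, rc = _synthetic_temp_records(3, n_types=10)
        model = gp.fit_condition_model(pre, "Vrest", rc)
        ref = model.reference_conditions
        probe = _rec(
            article_id="probe", cell_type_label=pre[0].cell_type_label,
            value=-61.5, species=ref["species"], electrode=ref["electrode"],
            jxn_status=ref["jxn_status"], rec_temp_C=ref["rec_temp_C"],
        )
        age = 10 ** ref["log10_age_by_type"][pre[0].cell_type_label]
        probe = dataclasses.replace(probe, age_lo_days=age, age_hi_days=age)
        (out,) = gp.adjust_measurements(model, [probe])
        assert out.value == pytest.approx(-61.5, abs=1e-9)

    def test_unseen_categorical_level_left_unadjusted(self):
        pre, _, rc = _synthetic_temp_records(4, n_types=10)
        model = gp.fit_condition_model(pre, "Vrest", rc)
        odd = dataclasses.replace(pre[0], electrode="perforated_patch", value=-50.0)
        out = gp.adjust_measurements(model, [odd])
        assert out[0].value == -50.0

    def test_nonpositive_value_for_log10_property_is_an_error(self, rc):
        records = [
            _rec(prop="Rin", article_id=f"a{i}", cell_type_label=f"T{i % 3}",
                 value=100.0)
            for i in range(10)
        ]
        records[3] = dataclasses.replace(records[3], value=-5.0)
        with pytest.raises(ValueError, match="non-positive"):
            gp.fit_condition_model(records, "Rin", rc)

    def test_adjustment_preserves_cell_type_rank_order_on_additive_data(self):
        pre, truth, rc = _synthetic_temp_records(5)
        model = gp.fit_condition_model(pre, "Vrest", rc)
        adjusted = gp.adjust_measurements(model, pre)
        before = gp.summarize_ephys_by_cell_type(pre)["Vrest"]
        after = gp.summarize_ephys_by_cell_type(adjusted)["Vrest"]
        lat = truth.latent_ephys["Vrest"][before.index]
        # adjusted medians should track the latent ordering at least as
        # well as unadjusted ones
        from scipy.stats import spearmanr
        assert spearmanr(after, lat)[0] >= spearmanr(before, lat)[0] - 0.05

    def test_log10_property_normalization_keeps_summaries_positive(self):
        cfg = gp.SyntheticConfig(seed=6, n_cell_types=15, n_genes=20)
        truth = gp.GroundTruth(
            planted_effects=[], lab_effects=[LabEffect("Rin", "age", -0.4)],
            null_genes=set(cfg.gene_ids()),
        )
        _, recs, _ = gp.generate_discovery_dataset(cfg, truth)
        rc = gp.RunConfig(seed=6)
        pre = [r for r in gp.preprocess_measurements(recs, rc) if r.property == "Rin"]
        model = gp.fit_condition_model(pre, "Rin", rc)
        assert model.transform == "log10"
        adjusted = gp.adjust_measurements(model, pre)
        summary = gp.summarize_ephys_by_cell_type(adjusted)["Rin"]
        assert (summary.dropna() > 0).all()

    def test_model_serialization_round_trip_reproduces_adjustment(self, tmp_path):
        pre, _, rc = _synthetic_temp_records(7, n_types=10)
        model = gp.fit_condition_model(pre, "Vrest", rc)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = gp.ConditionModel.from_file(path)
        a1 = gp.adjust_measurements(model, pre)
        a2 = gp.adjust_measurements(back, pre)
        np.testing.assert_allclose(
            [r.value for r in a1], [r.value for r in a2], atol=1e-12
        )

    def test_too_few_records_or_types_rejected(self, rc):
        few = [_rec(article_id=f"a{i}") for i in range(9)]
        with pytest.raises(ValueError, match=">= 2 distinct cell types"):
            gp.fit_condition_model(few, "Vrest", rc)
        two_types = [
            _rec(article_id=f"a{i}", cell_type_label=f"T{i % 2}") for i in range(9)
        ]
        with pytest.raises(ValueError, match=">= 10 records"):
            gp.fit_condition_model(two_types, "Vrest", rc)
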