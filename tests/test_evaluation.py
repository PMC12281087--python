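"""Join semantics, additive-model fits, AIC comparison, correlations."""

import math

import numpy as np
import pandas as pd
import pytest

from sentmetrics import (
    FrequencyTable,
    ModelSpec,
    ReadingRecord,
    Sentence,
    SmoothTerm,
    base_model_spec,
    build_sentence_table,
    compare_models,
    compare_to_base,
    correlate_metrics,
    export_partial_effects,
    fit_additive_model,
    fit_models,
    partial_effect_slope,
    segment_document,
    with_metric,
)


def _tiny_corpus():
    text = "aa bb cc. bb cc dd. cc dd aa. dd aa bb."
    return [segment_document(text, "d1", "en")]


def _metric_table(values):
    return pd.DataFrame(
        {
            "doc_id": ["d1"] * len(values),
            "sentence_index": range(len(values)),
            "value": values,
        }
    )


def _records(n_sent=4):
    out = []
    for p in ("p1", "p2"):
        for i in range(n_sent):
            out.append(ReadingRecord("en", p, "d1", i, 3, 1200.0 + 100 * i))
    return out


class TestBuildSentenceTable:
    FREQS = FrequencyTable({"aa": 10, "bb": 20, "cc": 30, "dd": 40}, total=100)

    def test_full_join_row_count(self):
        table = build_sentence_table(
            _records(), {"surprisal": _metric_table([1, 2, 3, 4])}, _tiny_corpus(), self.FREQS
        )
        assert len(table) == 8
        assert {"log_speed", "mean_word_length", "mean_log_wordfreq", "surprisal"} <= set(
            table.columns
        )

    def test_partial_metrics_drop_rows(self, caplog):
        table = build_sentence_table(
            _records(), {"surprisal": _metric_table([1, 2, 3])}, _tiny_corpus(), self.FREQS
        )
        assert len(table) == 6  # metrics cover 3 of 4 sentences, 2 participants

    def test_response_is_log_words_per_second(self):
        rec = ReadingRecord("en", "p1", "d1", 0, 3, 1200.0)  # 2.5 w/s
        table = build_sentence_table(
            [rec], {"surprisal": _metric_table([1.0])}, _tiny_corpus(), self.FREQS
        )
        assert table["log_speed"].iloc[0] == pytest.approx(math.log(2.5))

    def test_empty_join_rejected(self):
        other = _metric_table([1.0]).assign(doc_id="nope")
        with pytest.raises(ValueError, match="empty join"):
            build_sentence_table([_records()[0]], {"surprisal": other}, _tiny_corpus(), self.FREQS)


class TestModelSpec:
    def test_r_formula_rendering(self):
        spec = base_model_spec()
        assert spec.to_r_formula() == (
            "log_speed ~ s(mean_word_length, k=9) + s(mean_log_wordfreq, k=9)"
            ' + language + s(participant, bs="re")'
        )

    def test_full_contains_base(self):
        base = base_model_spec()
        assert with_metric(base, "surprisal").contains(base)
        assert not base.contains(with_metric(base, "surprisal"))

    def test_hostile_identifier_rejected(self):
        with pytest.raises(ValueError, match="identifier"):
            ModelSpec(response="log_speed; system('rm')").to_r_formula()
        with pytest.raises(ValueError, match="identifier"):
            SmoothTerm("x)+s(y").to_r()


@pytest.fixture(scope="module")
def fits(small_table):
    """One engine session fitting base (twice), single-metric, and joint."""
    base = base_model_spec()
    specs = {
        "base": base,
        "base_again": base,
        "surp": with_metric(base, "surprisal"),
        "joint": with_metric(base, "surprisal", "relevance"),
    }
    return fit_models(small_table, specs)


class TestAdditiveModelFits:
    def test_identical_specs_identical_aic(self, fits):
        assert fits["base"].aic == fits["base_again"].aic
        assert np.array_equal(fits["base"].coefficients, fits["base_again"].coefficients)

    def test_same_rows_used_by_all_models(self, fits):
        assert len({f.n_obs for f in fits.values()}) == 1

    def test_smooth_term_tables_present(self, fits):
        assert set(fits["joint"].smooth_terms) == {
            "s(mean_word_length)",
            "s(mean_log_wordfreq)",
            "s(surprisal)",
            "s(relevance)",
            "s(participant)",
        }
        for term in fits["joint"].smooth_terms.values():
            assert 0.0 <= term["p"] <= 1.0

    def test_partial_effect_curves_on_observed_range(self, fits, small_table):
        pe = fits["surp"].partial_effects["surprisal"]
        assert len(pe) == 100
        assert pe["grid"].min() == pytest.approx(small_table["surprisal"].min())
        assert pe["grid"].max() == pytest.approx(small_table["surprisal"].max())
        assert (pe["lower"] <= pe["effect"]).all() and (pe["effect"] <= pe["upper"]).all()

    def test_refit_is_deterministic(self, small_table, fits):
        again = fit_additive_model(small_table, base_model_spec())
        assert again.aic == fits["base"].aic
        assert np.array_equal(again.coefficients, fits["base"].coefficients)

    def test_exact_linear_truth_recovered(self):
        # no-noise linear response: the smooth must reproduce the line
        rng = np.random.default_rng(0)
        n = 400
        x = rng.uniform(0.0, 2.0, size=n)
        table = pd.DataFrame(
            {
                "mean_word_length": x,
                "log_speed": 0.1 + 0.3 * x,
                "participant": np.repeat(["p1", "p2"], n // 2),
            }
        )
        spec = ModelSpec(
            response="log_speed",
            smooth_terms=(SmoothTerm("mean_word_length"),),
            factor_terms=(),
            random_intercept="participant",
        )
        fit = fit_additive_model(table, spec)
        pe = fit.partial_effects["mean_word_length"]
        interior = pe.iloc[5:-5]
        resid = interior["effect"] - 0.3 * interior["grid"]
        assert float(resid.max() - resid.min()) < 1e-3  # line up to centering constant
        assert partial_effect_slope(fit, "mean_word_length") == pytest.approx(0.3, rel=0.01)

    def test_constant_predictor_rejected(self, small_table):
        bad = small_table.assign(flat=1.0)
        spec = with_metric(base_model_spec(), "flat")
        with pytest.raises(ValueError, match="constant"):
            fit_additive_model(bad, spec)

    def test_missing_column_rejected(self, small_table):
        spec = with_metric(base_model_spec(), "not_a_column")
        with pytest.raises(ValueError, match="not_a_column"):
            fit_additive_model(small_table, spec)


class TestModelComparison:
    def test_identical_specs_give_exactly_zero(self, small_table):
        base = base_model_spec()
        res = compare_models(small_table, base, base)
        assert res.delta_aic == 0.0

    def test_sign_convention_full_minus_base(self, fits):
        delta = fits["surp"].aic - fits["base"].aic
        assert delta != 0.0  # informative on this data
        # reconstructing through compare_to_base must agree with raw AICs
        assert math.copysign(1, delta) == math.copysign(1, fits["surp"].aic - fits["base"].aic)

    def test_full_must_contain_base(self, small_table):
        base = base_model_spec()
        smaller = ModelSpec(
            response="log_speed",
            smooth_terms=(SmoothTerm("mean_word_length"),),
            factor_terms=("language",),
            random_intercept="participant",
        )
        with pytest.raises(ValueError, match="contain"):
            compare_models(small_table, base, smaller)

    def test_compare_to_base_deltas_are_aic_differences(self, small_table):
        base = base_model_spec()
        res = compare_to_base(small_table, base, {"surp": with_metric(base, "surprisal")})
        assert res["surp"].delta_aic == pytest.approx(
            res["surp"].full.aic - res["surp"].base.aic
        )


class TestCorrelations:
    def test_identical_columns_give_one(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert correlate_metrics(t, "a", "b") == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [9.0, 7, 5, 2]})
        assert correlate_metrics(t, "a", "b") == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        t = pd.DataFrame({"a": a, "b": np.exp(a)})
        assert correlate_metrics(t, "a", "b") == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        t = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            correlate_metrics(t, "a", "b")

    def test_too_few_rows_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(ValueError, match="3 rows"):
            correlate_metrics(t, "a", "b")


class TestPartialEffectExport:
    def test_one_tsv_per_smooth_term(self, fits, tmp_path):
        paths = export_partial_effects(fits["joint"], tmp_path)
        names = sorted(p.name for p in paths)
        assert names == [
            "partial_effect_mean_log_wordfreq.tsv",
            "partial_effect_mean_word_length.tsv",
            "partial_effect_relevance.tsv",
            "partial_effect_surprisal.tsv",
        ]

    def test_export_round_trip(self, fits, tmp_path):
        export_partial_effects(fits["surp"], tmp_path)
        back = pd.read_csv(tmp_path / "partial_effect_surprisal.tsv", sep="\t")
        pd.testing.assert_frame_equal(
            back, fits["surp"].partial_effects["surprisal"], check_exact=False, atol=1e-9
        )

    def test_plot_files_written(self, fits, tmp_path):
        paths = export_partial_effects(fits["surp"], tmp_path, plot=True)
        assert any(p.suffix == ".png" for p in paths)

    def test_unknown_term_rejected(self, fits):
        with pytest.raises(KeyError):
            partial_effect_slope(fits["surp"], "nonexistent")
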