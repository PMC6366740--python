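import numpy as np
import pytest

from upscreen import (ICMetric, ModelRecord, NestedPair, ParameterEstimate,
                      ScreenConfig, rank_models, screen_model_set, screen_pair)
from upscreen.screen import (signal1_close_ic, signal2_ranked_below,
                             signal3_similar_loglik, signal4_null_estimate)

from conftest import random_model_set
from naive_oracle import naive_screen


def _pair(simple, complex_, extra, d=1):
    return NestedPair(simple_id=simple, complex_id=complex_,
                      extra_terms=frozenset(extra), d=d)


@pytest.fixture
def warbler_ranked(warblers):
    return rank_models(warblers, ICMetric("AIC"))


class TestSignal1:
    def test_warbler_pair_1_2_within_two(self, warbler_ranked):
        assert signal1_close_ic(_pair("1", "2", {"%LCCb"}), warbler_ranked)

    def test_warbler_pair_3_4_within_two(self, warbler_ranked):
        # |569.26 - 568.36| = 0.90
        assert signal1_close_ic(_pair("3", "4", {"%LCCb"}), warbler_ranked)

    def test_large_gap_fails(self):
        ms = [ModelRecord("s", {"a"}, 2, -10.0), ModelRecord("c", {"a", "b"}, 3, -14.0)]
        ranked = rank_models(ms)
        assert not signal1_close_ic(_pair("s", "c", {"b"}), ranked)

    def test_missing_member_errors(self, warbler_ranked):
        with pytest.raises(KeyError):
            signal1_close_ic(_pair("1", "nope", {"x"}), warbler_ranked)

    def test_exact_penalty_mode_widens_cutoff_under_aicc(self):
        """At small n two identical-fit models sit more than 2 AICc apart;
        the exact-penalty cutoff still counts them as signal-1 close."""
        ms = [ModelRecord("s", {"a"}, 2, -10.0), ModelRecord("c", {"a", "b"}, 3, -10.0)]
        metric = ICMetric("AICc", n=30)
        ranked = rank_models(ms, metric)
        gap = ranked["c"].ic_value - ranked["s"].ic_value
        assert gap > 2.0
        cfg = ScreenConfig(ic_cutoff_mode="exact_penalty")
        assert signal1_close_ic(_pair("s", "c", {"b"}), ranked, cfg)


class TestSignal2:
    def test_complex_ranked_below(self, warbler_ranked):
        assert signal2_ranked_below(_pair("1", "2", {"%LCCb"}), warbler_ranked)

    def test_complex_ranked_above_fails(self, warbler_ranked):
        # model 3 (complex) outranks model 5 (simple): 4.08 < 5.62
        assert not signal2_ranked_below(_pair("5", "3", {"dMWT"}), warbler_ranked)

    def test_exact_tie_is_false(self):
        ms = [ModelRecord("s", {"a"}, 2, -10.0), ModelRecord("c", {"a", "b"}, 2, -10.0)]
        ranked = rank_models(ms)
        assert not signal2_ranked_below(_pair("s", "c", {"b"}), ranked)


class TestSignal3:
    def test_identical_loglik(self, warblers):
        by_id = {m.model_id: m for m in warblers}
        assert signal3_similar_loglik(_pair("1", "2", {"%LCCb"}), by_id)

    def test_small_gain_passes(self, warblers):
        by_id = {m.model_id: m for m in warblers}
        # -277.63 - (-278.18) = 0.55 <= 1.0
        assert signal3_similar_loglik(_pair("3", "4", {"%LCCb"}), by_id)

    def test_large_gain_fails(self):
        by_id = {"s": ModelRecord("s", {"a"}, 2, -10.0),
                 "c": ModelRecord("c", {"a", "b"}, 3, -6.8)}
        assert not signal3_similar_loglik(_pair("s", "c", {"b"}), by_id)

    def test_negative_gain_warns_but_evaluates(self):
        by_id = {"s": ModelRecord("s", {"a"}, 2, -10.0),
                 "c": ModelRecord("c", {"a", "b"}, 3, -10.5)}
        with pytest.warns(UserWarning, match="lower log-likelihood"):
            assert signal3_similar_loglik(_pair("s", "c", {"b"}), by_id)


class TestSignal4:
    def test_ci_overlapping_zero(self):
        assert signal4_null_estimate([ParameterEstimate(0.00, -0.05, 0.05)]) is True

    def test_ci_excluding_zero(self):
        assert signal4_null_estimate([ParameterEstimate(-2.54, -4.64, -0.46)]) is False

    def test_no_estimates_unassessable(self):
        assert signal4_null_estimate([]) == "unassessable"

    def test_any_nonzero_level_fails(self):
        ests = [ParameterEstimate(0.0, -0.1, 0.1), ParameterEstimate(1.0, 0.5, 1.5)]
        assert signal4_null_estimate(ests) is False


class TestScreenPair:
    def test_uninformative_verdict(self, warblers, warbler_ranked):
        res = screen_pair(_pair("1", "2", {"%LCCb"}), warbler_ranked, warblers)
        assert res.verdict == "uninformative"
        assert res.signal1 and res.signal2 and res.signal3 and res.signal4 is True

    def test_short_circuit_leaves_later_signals_unasserted(self, warblers, warbler_ranked):
        res = screen_pair(_pair("5", "3", {"dMWT"}), warbler_ranked, warblers)
        assert res.verdict == "not_uninformative"
        assert res.signal2 is False and res.signal3 is None and res.signal4 is None

    def test_florican_weather_is_uninformative(self, floricans):
        ranked = rank_models(floricans, ICMetric("reported"))
        res = screen_pair(_pair("time", "time_weather", {"weather"}), ranked, floricans)
        assert res.verdict == "uninformative"
        assert res.ic_diff == pytest.approx(1.54)
        assert res.loglik_gain == pytest.approx(0.69)

    def test_interaction_retention(self):
        """An extra main effect that participates in an interaction kept by
        the complex model is exempt from flagging."""
        ms = [
            ModelRecord("s", {"a"}, 2, -10.0),
            ModelRecord("c", {"a", "b", "a:b"}, 4, -10.0,
                        estimates={"b": ParameterEstimate(0.0, -0.1, 0.1)}),
        ]
        ranked = rank_models(ms)
        res = screen_pair(_pair("s", "c", {"b", "a:b"}, d=2), ranked, ms)
        assert res.verdict == "not_applicable"

    def test_diagnostic_ratio_reported(self, warblers, warbler_ranked):
        res = screen_pair(_pair("3", "4", {"%LCCb"}), warbler_ranked, warblers)
        assert res.term_diagnostics["%LCCb"] == pytest.approx(0.03 / 0.045, abs=1e-9)


class TestScreenModelSet:
    def test_warbler_flags(self, warblers):
        """The full screen flags the buffer land-cover covariate in exactly
        the three models that carry it."""
        report = screen_model_set(warblers, ICMetric("AIC"))
        assert {m: set(t) for m, t in report.flagged.items()} == {
            "2": {"%LCCb"}, "4": {"%LCCb"}, "6": {"%LCCb"},
        }
        assert report.set_verdict == "has_UP"

    def test_non_nested_set_has_no_up(self):
        ms = [ModelRecord(mid, {t}, 2, -10.0) for mid, t in
              zip("abcd", ["w", "x", "y", "z"])]
        report = screen_model_set(ms)
        assert report.flagged == {} and report.set_verdict == "no_UP"

    def test_missing_estimates_degrade_to_very_likely(self, warblers):
        from dataclasses import replace
        stripped = [replace(m, estimates={}) for m in warblers]
        report = screen_model_set(stripped, ICMetric("AIC"))
        assert report.flagged == {}
        assert report.set_verdict == "very_likely_UP"
        very_likely = {(r.pair.simple_id, r.pair.complex_id)
                       for r in report.pair_results if r.verdict == "very_likely"}
        assert ("1", "2") in very_likely

    def test_determinism(self, warblers):
        r1 = screen_model_set(warblers, ICMetric("AIC"))
        r2 = screen_model_set(warblers, ICMetric("AIC"))
        assert r1 == r2

    def test_exclude_null_pairs_switch(self):
        ms = [ModelRecord("null", frozenset(), 1, -12.0),
              ModelRecord("x", {"x"}, 2, -11.9,
                          estimates={"x": ParameterEstimate(0.0, -0.3, 0.3)})]
        with_null = screen_model_set(ms)
        without = screen_model_set(ms, config=ScreenConfig(include_null_pairs=False))
        assert len(with_null.pair_results) == 1
        assert len(without.pair_results) == 0 and without.set_verdict == "no_UP"

    def test_flagged_set_monotone_in_loglik_tol(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            models = random_model_set(rng)
            if not models:
                continue
            flagged_sets = []
            for tol in (0.25, 0.5, 1.0, 2.0, 4.0):
                rep = screen_model_set(models, config=ScreenConfig(loglik_tol=tol))
                flagged_sets.append({(m, t) for m, ts in rep.flagged.items() for t in ts})
            for small, big in zip(flagged_sets, flagged_sets[1:]):
                assert small <= big

    def test_pair_locality_under_model_removal(self):
        """Dropping a flagged complex model never changes the verdicts of the
        remaining pairs."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            models = random_model_set(rng)
            rep = screen_model_set(models)
            if not rep.flagged:
                continue
            drop = next(iter(rep.flagged))
            remaining = [m for m in models if m.model_id != drop]
            rep2 = screen_model_set(remaining)
            before = {(r.pair.simple_id, r.pair.complex_id): r.verdict
                      for r in rep.pair_results if drop not in
                      (r.pair.simple_id, r.pair.complex_id)}
            after = {(r.pair.simple_id, r.pair.complex_id): r.verdict
                     for r in rep2.pair_results}
            assert before == after

    def test_matches_naive_oracle_on_random_sets(self):
        """Sequential short-circuit screening equals the naive no-short-circuit
        enumeration on random model sets."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            models = random_model_set(rng)
            if not models:
                continue
            rep = screen_model_set(models, ICMetric("AIC"))
            verdicts = {(r.pair.simple_id, r.pair.complex_id): r.verdict
                        for r in rep.pair_results}
            naive_verdicts, naive_flagged, naive_set = naive_screen(models)
            assert verdicts == naive_verdicts
            assert {m: set(t) for m, t in rep.flagged.items()} == naive_flagged
            assert rep.set_verdict == naive_set
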