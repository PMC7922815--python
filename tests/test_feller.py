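"""Feller independence model and the interaction verdict."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrasense import (
    DataError,
    DesignError,
    DetectionCurve,
    DoseSeries,
    MixturePair,
    StudyConfig,
    classify_interaction,
    feller_predict,
    simulate_mixture_experiment,
    threshold_ratio,
)
from pyrasense.feller import (
    _poolwise_exact_tails,
    estimate_component_a_detection,
)

LADDER = (0.039, 0.077, 0.154, 0.307, 0.614, 1.228, 2.456, 4.912, 9.824)

probs = st.floats(0.0, 1.0)


class TestFellerPredict:
    @pytest.mark.parametrize(
        "pa,pb,expected", [(0.5, 0.5, 0.75), (0.0, 0.37, 0.37), (0.3, 0.4, 0.58)]
    )
    def test_values(self, pa, pb, expected):
        assert feller_predict(pa, pb) == pytest.approx(expected)

    @given(probs, probs)
    @settings(max_examples=200, deadline=None)
    def test_commutative_and_complement_product(self, pa, pb):
        assert feller_predict(pa, pb) == pytest.approx(feller_predict(pb, pa))
        assert 1 - feller_predict(pa, pb) == pytest.approx((1 - pa) * (1 - pb))

    @given(probs, probs)
    @settings(max_examples=200, deadline=None)
    def test_never_below_either_component(self, pa, pb):
        p = feller_predict(pa, pb)
        assert p >= max(pa, pb) - 1e-12
        if pb == 0:
            assert p == pytest.approx(pa)

    def test_domain_checked(self):
        with pytest.raises(DataError):
            feller_predict(-0.1, 0.5)


class TestThresholdRatio:
    @pytest.mark.parametrize(
        "ref,test,expected", [(0.456, 0.143, 3.2), (0.292, 0.143, 2.0), (1.7, 1.7, 1.0)]
    )
    def test_printed_factors(self, ref, test, expected):
        assert threshold_ratio(ref, test) == expected

    def test_positive_inputs_required(self):
        with pytest.raises(DataError):
            threshold_ratio(0.0, 1.0)


class TestComponentA:
    def test_pooled_abbott_estimate(self):
        a = DetectionCurve((1.0,), (20,), (12,))
        assert estimate_component_a_detection(a) == pytest.approx(
            (12 / 20 - 1 / 3) / (2 / 3)
        )

    def test_below_chance_clips_to_zero(self):
        a = DetectionCurve((1.0,), (20,), (5,))
        assert estimate_component_a_detection(a) == 0.0

    def test_missing_curve_means_inert(self):
        assert estimate_component_a_detection(None) == 0.0


class TestExactConvolutionTails:
    def test_matches_direct_enumeration(self):
        # oracle: enumerate the joint pmf of two small binomials
        from math import comb

        ns, ps = [4, 5], [0.3, 0.6]
        pmf = {}
        for k1 in range(5):
            for k2 in range(6):
                pr = (
                    comb(4, k1) * 0.3**k1 * 0.7 ** (4 - k1)
                    * comb(5, k2) * 0.6**k2 * 0.4 ** (5 - k2)
                )
                pmf[k1 + k2] = pmf.get(k1 + k2, 0.0) + pr
        for ks in ([2, 3], [0, 0], [4, 5]):
            hi, lo = _poolwise_exact_tails(ns, ks, ps)
            t = sum(ks)
            assert hi == pytest.approx(sum(v for s, v in pmf.items() if s >= t))
            assert lo == pytest.approx(sum(v for s, v in pmf.items() if s <= t))


class TestClassifyInteraction:
    def test_dose_axis_mismatch_rejected(self):
        b = DetectionCurve((0.1, 0.2, 0.4), (20,) * 3, (5, 10, 15))
        ab = DetectionCurve((0.1, 0.2, 0.8), (20,) * 3, (5, 10, 15))
        with pytest.raises(DesignError):
            MixturePair(component_b=b, mixture_observed=ab)

    def test_observed_equals_predicted_is_additive(self):
        # exact independence: mixture counts generated at the Feller value
        cfg = StudyConfig(seed=3, interaction_factor=1.0)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(42)
        pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
        v = classify_interaction(pair, random_state=0)
        assert v.call == "additive"
        assert v.p_value > 0.05 or v.ratio == pytest.approx(1.0, abs=0.5)

    def test_strong_synergy_detected(self):
        cfg = StudyConfig(seed=3, interaction_factor=4.0)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(10)
        calls = []
        for i in range(20):
            pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
            calls.append(classify_interaction(pair, random_state=i).call)
        assert calls.count("synergy") > 10
        assert "suppression" not in calls

    def test_strong_suppression_detected(self):
        cfg = StudyConfig(seed=3, interaction_factor=0.25)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(11)
        calls = []
        for i in range(20):
            pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
            calls.append(classify_interaction(pair, random_state=i).call)
        assert calls.count("suppression") > 10
        assert "synergy" not in calls

    def test_inert_component_a_reduces_to_component_b(self):
        cfg = StudyConfig(seed=6, p_a=0.0, interaction_factor=1.0)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(12)
        pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
        v = classify_interaction(pair, p_a=0.0, random_state=0)
        assert v.call == "additive"
        assert v.predicted_detection == pytest.approx(tuple(np.clip(
            (np.array([k for k in pair.component_b.k]) / 20 - 1 / 3) / (2 / 3), 0, 1
        )), abs=0.35)  # prediction is the smoothed B curve itself

    def test_p_a_required_when_component_a_missing(self):
        b = DetectionCurve(LADDER, (20,) * 9, (5, 6, 7, 9, 12, 15, 18, 19, 20))
        ab = DetectionCurve(LADDER, (20,) * 9, (6, 7, 8, 10, 13, 16, 18, 20, 20))
        pair = MixturePair(component_b=b, mixture_observed=ab)
        with pytest.raises(DesignError):
            classify_interaction(pair)
        v = classify_interaction(pair, p_a=0.0, random_state=0)
        assert v.call in {"additive", "synergy", "suppression"}

    def test_verdict_reproducible_from_random_state(self):
        cfg = StudyConfig(seed=9, interaction_factor=1.0)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(13)
        pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
        v1 = classify_interaction(pair, random_state=5)
        v2 = classify_interaction(pair, random_state=5)
        assert v1.p_value == v2.p_value and v1.call == v2.call

    def test_predicted_threshold_tracks_observed_under_independence(self):
        # with a large panel the predicted and observed thresholds agree
        cfg = StudyConfig(seed=3, n_panelists=200, interaction_factor=1.0)
        series = DoseSeries(LADDER, factor=2)
        rng = np.random.default_rng(21)
        diffs = []
        for i in range(20):
            pair = simulate_mixture_experiment(series, cfg, 0.456, rng=rng)
            v = classify_interaction(pair, random_state=i, n_boot=500)
            assert not v.censored
            diffs.append(abs(np.log2(v.threshold_predicted.value / v.threshold_observed.value)))
        assert float(np.median(diffs)) < 0.5  # within half a dilution step
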