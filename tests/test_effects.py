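import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointeffects.composition import CommunityKey
from jointeffects.effects import (
    EffectEstimate,
    FilterConfig,
    WellRecord,
    baseline_normalize,
    bootstrap_se,
    classify_sign,
    effect_estimate,
    estimate_effects,
    filter_autofluorescence,
    filter_replicates,
    summarize_distribution,
)


class TestBaselineNormalize:
    @pytest.mark.parametrize(
        "readings,expected,flagged",
        [
            ({0.0: 100, 24.0: 600}, {0.0: 0, 24.0: 500}, False),
            ({0.0: 100, 24.0: 80}, {0.0: 0, 24.0: -20}, True),
            ({0.0: 0, 24.0: 300}, {0.0: 0, 24.0: 300}, False),
        ],
    )
    def test_t0_subtraction(self, readings, expected, flagged):
        growth, flag = baseline_normalize(readings)
        assert growth == pytest.approx(expected)
        assert flag is flagged

    def test_missing_t0_rejected(self):
        with pytest.raises(ValueError):
            baseline_normalize({24.0: 500})


class TestReplicateFilter:
    def test_under_threshold_dropped_with_log(self):
        ab = CommunityKey("F", frozenset("AB"))
        ac = CommunityKey("F", frozenset("AC"))
        kept, dropped = filter_replicates({ab: [1, 2], ac: list(range(7))})
        assert set(kept) == {ac}
        assert dropped[0][0] == ab

    def test_min_one_retains_all(self):
        ab = CommunityKey("F", frozenset("AB"))
        kept, dropped = filter_replicates({ab: [1]}, FilterConfig(min_replicates=1))
        assert set(kept) == {ab} and not dropped

    def test_empty_input(self):
        assert filter_replicates({}) == ({}, [])


class TestAutofluorescenceFilter:
    @pytest.mark.parametrize(
        "mono,autofluor,keep",
        [(1000, 150, True), (1000, 250, False), (1000, 200, True)],  # boundary inclusive
    )
    def test_five_fold_rule(self, mono, autofluor, keep):
        assert filter_autofluorescence(mono, autofluor) is keep

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            filter_autofluorescence(-1, 100)


class TestEffectEstimate:
    def test_log_ratio_of_medians(self):
        est = effect_estimate([400, 600, 500], [800, 1000, 1200])
        assert est.effect == pytest.approx(np.log(0.5))
        assert not est.censored

    def test_equal_medians_give_zero(self):
        assert effect_estimate([5, 5, 5], [5, 5, 5]).effect == 0.0

    def test_e_fold_reduction(self):
        est = effect_estimate([1000 / np.e] * 3, [1000] * 3)
        assert est.effect == pytest.approx(-1.0)

    def test_censoring_clamps_at_floor(self):
        est = effect_estimate([50, 60, 55], [1000] * 3, detection_floor=200.0)
        assert est.censored
        assert est.effect == pytest.approx(np.log(200 / 1000))

    def test_failed_monoculture_rejected(self):
        with pytest.raises(ValueError):
            effect_estimate([100] * 3, [0, 0, 0])

    def test_scale_invariance(self, rng):
        co = rng.lognormal(6, 0.4, 12)
        mono = rng.lognormal(6.5, 0.4, 15)
        base = effect_estimate(co, mono).effect
        assert effect_estimate(co * 37.5, mono * 37.5).effect == pytest.approx(base)

    def test_antisymmetry_under_group_swap(self, rng):
        co = rng.lognormal(6, 0.4, 9)
        mono = rng.lognormal(6.5, 0.4, 9)
        assert effect_estimate(co, mono).effect == pytest.approx(
            -effect_estimate(mono, co).effect
        )


def _bootstrap_se_oracle(co, mono, b, seed):
    """Plain-loop Monte-Carlo reference, independent of the implementation."""
    rng = np.random.default_rng(seed)
    co, mono = np.asarray(co, float), np.asarray(mono, float)
    effects = np.empty(b)
    for i in range(b):
        effects[i] = np.log(
            np.median(rng.choice(co, co.size)) / np.median(rng.choice(mono, mono.size))
        )
    return effects.std()


class TestBootstrapSE:
    def test_degenerate_groups_have_zero_se(self):
        assert bootstrap_se([500] * 6, [800] * 6, rng=0) == 0.0

    def test_matches_large_b_monte_carlo_oracle(self):
        co = [100, 1000, 100, 1000] * 5
        mono = [500] * 5
        got = bootstrap_se(co, mono, b=1000, rng=7)
        oracle = _bootstrap_se_oracle(co, mono, 100_000, seed=123)
        assert got == pytest.approx(oracle, rel=0.20)

    def test_se_increases_with_spread(self):
        base = np.array([800.0, 900, 1000, 1100, 1200])
        mono = [1000.0] * 8
        ses = []
        for scale in (1.0, 2.0, 4.0):
            co = 1000 + (base - 1000) * scale
            ses.append(bootstrap_se(co, mono, b=400, rng=5))
        assert ses[0] < ses[1] < ses[2]

    def test_seed_reproducible(self):
        co, mono = [1, 2, 3, 4.0], [2, 3, 4.0]
        assert bootstrap_se(co, mono, rng=9) == bootstrap_se(co, mono, rng=9)


class TestClassifySign:
    @pytest.mark.parametrize(
        "effect,se,expected",
        [(-0.5, 0.6, "neutral"), (-0.5, 0.2, "negative"), (0.9, 0.1, "positive")],
    )
    def test_neutral_when_se_exceeds_magnitude(self, effect, se, expected):
        assert classify_sign(effect, se) == expected

    @given(st.floats(-5, 5), st.floats(0, 5))
    @settings(max_examples=100, deadline=None)
    def test_classification_consistency(self, effect, se):
        sign = classify_sign(effect, se)
        if se > abs(effect):
            assert sign == "neutral"
        else:
            assert sign == ("negative" if effect < 0 else "positive")


class TestSummarizeDistribution:
    def test_type7_quantiles(self):
        s = summarize_distribution([-1.0, 0.0, 1.0])
        assert s["median"] == 0.0 and s["iqr"] == 1.0

    def test_single_element(self):
        s = summarize_distribution([0.7])
        assert s["median"] == pytest.approx(0.7) and s["iqr"] == 0.0

    def test_all_negative_classification(self):
        ests = [
            EffectEstimate(CommunityKey("F", frozenset([c])), -1.0, 0.1, 5, "negative")
            for c in "ABC"
        ]
        s = summarize_distribution(ests)
        assert s["frac_negative"] == 1.0
        assert s["frac_positive"] + s["frac_negative"] + s["frac_neutral"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([])


class TestEstimateEffects:
    def _growth(self):
        mono = CommunityKey("F", frozenset())
        a = CommunityKey("F", frozenset("A"))
        b = CommunityKey("F", frozenset("B"))
        return {
            mono: np.array([1000.0, 1100, 900, 1000]),
            a: np.array([400.0, 500, 600]),
            b: np.array([1000.0, 1050]),  # only 2 replicates
        }

    def test_replicate_filter_and_point_estimates(self):
        ests, dropped = estimate_effects(self._growth(), {}, seed=1)
        assert [e.community for e in ests] == [CommunityKey("F", frozenset("A"))]
        assert ests[0].effect == pytest.approx(np.log(0.5))
        assert dropped and "replicates" in dropped[0][1]

    def test_autofluorescence_drop(self):
        ests, dropped = estimate_effects(self._growth(), {"A": 300.0}, seed=1)
        assert not ests
        assert any("autofluorescence" in reason for _, reason in dropped)

    def test_deterministic_given_seed(self):
        a, _ = estimate_effects(self._growth(), {}, seed=3)
        b, _ = estimate_effects(self._growth(), {}, seed=3)
        assert a == b

    def test_censoring_floor_bounds_measured_effect(self):
        # coculture signal at the autofluorescence bound: a species that
        # just passes the 5x filter cannot show an effect below ln(1/5)
        mono = np.array([1000.0] * 5)
        co = np.array([10.0, 12, 11])
        growth = {
            CommunityKey("F", frozenset()): mono,
            CommunityKey("F", frozenset("A")): co,
        }
        ests, _ = estimate_effects(growth, {"A": 200.0}, seed=0)
        assert ests[0].censored
        assert ests[0].effect == pytest.approx(np.log(1 / 5))
        assert ests[0].effect >= np.log(1 / 5) - 1e-12
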