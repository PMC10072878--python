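import numpy as np
import pytest

from jointeffects.composition import CommunityKey
from jointeffects.effects import FilterConfig
from jointeffects.evaluation import (
    EvalConfig,
    bootstrap_nrmse,
    error_distribution,
    model_ranking,
    nrmse,
    stratify_by_sign,
)
from jointeffects.models import ModelPrediction


def _nrmse_oracle(pred, obs):
    """Direct-formula recomputation, independent of the implementation."""
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    rmse = np.sqrt(((pred - obs) ** 2).sum() / obs.size)
    iqr = np.percentile(obs, 75) - np.percentile(obs, 25)
    return rmse / iqr


class TestNrmse:
    def test_perfect_predictions(self):
        obs = [0.1, -0.4, 0.9]
        assert nrmse(obs, obs) == 0.0

    def test_constant_offset_equals_offset_over_iqr(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])  # IQR 1.5
        assert nrmse(obs + 1.5, obs) == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(100):
            obs = rng.normal(0, 1, 20)
            pred = obs + rng.normal(0, 0.5, 20)
            assert nrmse(pred, obs) == pytest.approx(_nrmse_oracle(pred, obs), abs=1e-12)

    def test_shift_invariance(self, rng):
        obs = rng.normal(0, 1, 15)
        pred = obs + rng.normal(0, 0.3, 15)
        assert nrmse(pred + 2.5, obs + 2.5) == pytest.approx(nrmse(pred, obs))

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nrmse([1.0, 2.0], [0.5, 0.5])


class TestStratifyBySign:
    def test_sign_combinations(self):
        singles = {
            CommunityKey("F", frozenset([s])): v
            for s, v in [("A", -2.0), ("B", -0.1), ("C", 0.1), ("D", 0.3)]
        }
        pairs = [CommunityKey("F", frozenset(p)) for p in ("AB", "AC", "CD")]
        strata, excluded = stratify_by_sign(pairs, singles)
        assert strata[pairs[0]] == "neg-neg"
        assert strata[pairs[1]] == "neg-pos"
        assert strata[pairs[2]] == "pos-pos"
        assert not excluded

    def test_zero_counts_positive(self):
        singles = {
            CommunityKey("F", frozenset([s])): v for s, v in [("A", 0.0), ("B", 0.2)]
        }
        strata, _ = stratify_by_sign([CommunityKey("F", frozenset("AB"))], singles)
        assert list(strata.values()) == ["pos-pos"]

    def test_missing_single_excluded(self):
        singles = {CommunityKey("F", frozenset("A")): -1.0}
        strata, excluded = stratify_by_sign([CommunityKey("F", frozenset("AX"))], singles)
        assert not strata and excluded


def _toy_growth(effects, mono_level=1000.0, n_rep=5):
    """Exact (noise-free) growth table realizing the given log effects."""
    growth = {CommunityKey("F", frozenset()): np.full(n_rep, mono_level)}
    for members, eff in effects.items():
        key = CommunityKey("F", frozenset(members))
        growth[key] = np.full(n_rep, mono_level * np.exp(eff))
    return growth


class TestBootstrapNrmse:
    def _growth(self):
        singles = {"A": -1.0, "B": -0.4, "C": 0.3, "D": 0.8}
        pairs = {}
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1:]:
                strongest = max(singles[a], singles[b], key=abs)
                pairs[a + b] = strongest  # truth follows the strongest rule
        return _toy_growth({**singles, **pairs})

    def test_identity_resample_equals_plain_nrmse(self):
        growth = self._growth()
        summaries = bootstrap_nrmse(
            growth,
            ("additive", "mean", "strongest"),
            EvalConfig(n_bootstrap=1, seed=0),
            resample=False,
        )
        # recompute by hand from point estimates
        mono = np.median(growth[CommunityKey("F", frozenset())])
        eff = {
            k: np.log(np.median(v) / mono)
            for k, v in growth.items()
            if not k.is_monoculture
        }
        pairs = sorted(k for k in eff if k.order == 2)
        obs = np.array([eff[p] for p in pairs])
        for s in summaries:
            if s.model == "additive":
                pred = np.array([
                    sum(eff[CommunityKey("F", frozenset([m]))] for m in p.affecting_set)
                    for p in pairs
                ])
                assert s.nrmse_median == pytest.approx(_nrmse_oracle(pred, obs), abs=1e-12)
            if s.model == "strongest":
                assert s.nrmse_median == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_strongest_truth_only_strongest_is_exact(self):
        summaries = bootstrap_nrmse(
            self._growth(),
            ("additive", "mean", "strongest"),
            EvalConfig(n_bootstrap=20, seed=1),
        )
        by_model = {s.model: s for s in summaries}
        assert by_model["strongest"].nrmse_median == pytest.approx(0.0, abs=1e-12)
        assert by_model["additive"].nrmse_median > 0
        assert by_model["mean"].nrmse_median > 0

    def test_fixed_seed_is_bit_identical(self, noise_free_growth):
        cfg = EvalConfig(n_bootstrap=25, seed=7)
        fc = FilterConfig(min_replicates=1)
        a = bootstrap_nrmse(noise_free_growth, cfg=cfg, filter_cfg=fc)
        b = bootstrap_nrmse(noise_free_growth, cfg=cfg, filter_cfg=fc)
        assert a == b

    def test_single_well_groups_degenerate_to_point_estimate(self):
        growth = {k: v[:1] for k, v in self._growth().items()}
        summaries = bootstrap_nrmse(
            growth,
            ("additive",),
            EvalConfig(n_bootstrap=200, seed=0),
            filter_cfg=FilterConfig(min_replicates=1),
        )
        assert summaries[0].nrmse_iqr == 0.0

    def test_stratified_summaries_use_stratum_iqr(self):
        summaries = bootstrap_nrmse(
            self._growth(),
            ("strongest",),
            EvalConfig(n_bootstrap=10, seed=0, stratify=True),
        )
        strata = {s.stratum for s in summaries}
        assert "all" in strata and len(strata) > 1
        assert all(s.nrmse_median == pytest.approx(0.0, abs=1e-12) for s in summaries)

    def test_too_few_communities_rejected(self):
        growth = _toy_growth({"A": -1.0, "AB": -1.0})
        with pytest.raises(ValueError):
            bootstrap_nrmse(growth, filter_cfg=FilterConfig(min_replicates=1))


class TestErrorDistribution:
    def _pred(self, members, model, value):
        return ModelPrediction(
            CommunityKey("F", frozenset(members)), model, "singles", value
        )

    def test_perfect_predictions_zero_errors(self):
        obs = {CommunityKey("F", frozenset(p)): -1.0 for p in ("AB", "AC")}
        preds = [self._pred(p, "mean", -1.0) for p in ("AB", "AC")]
        out = error_distribution(preds, obs)
        assert np.all(out["mean"]["errors"] == 0.0)

    def test_sign_convention(self):
        # additive on (-1,-1) vs observed -1: prediction -2, error -1
        # (overestimates the magnitude of a negative effect)
        obs = {CommunityKey("F", frozenset("AB")): -1.0}
        out = error_distribution([self._pred("AB", "additive", -2.0)], obs)
        assert out["additive"]["errors"][0] == pytest.approx(-1.0)
        # mean on (-2, 0) vs observed -2: prediction -1, error +1
        obs2 = {CommunityKey("F", frozenset("AB")): -2.0}
        out2 = error_distribution([self._pred("AB", "mean", -1.0)], obs2)
        assert out2["mean"]["errors"][0] == pytest.approx(1.0)

    def test_stratum_restriction(self):
        obs = {CommunityKey("F", frozenset(p)): -1.0 for p in ("AB", "AC")}
        preds = [self._pred(p, "mean", 0.0) for p in ("AB", "AC")]
        out = error_distribution(preds, obs, [CommunityKey("F", frozenset("AB"))])
        assert out["mean"]["n"] == 1


class TestModelRanking:
    def _summary(self, model, med):
        from jointeffects.evaluation import EvaluationSummary

        return EvaluationSummary("all", model, "singles", med, 0.1, 10, 100)

    def test_ascending_order(self):
        s = [self._summary(m, v) for m, v in [("additive", 0.6), ("mean", 0.3), ("strongest", 0.2)]]
        out = model_ranking(s)
        assert out["all"]["ranking"] == ["strongest", "mean", "additive"]
        assert not out["all"]["tie"]

    def test_singleton_and_tie(self):
        assert model_ranking([self._summary("mean", 0.4)])["all"]["ranking"] == ["mean"]
        tied = [self._summary("mean", 0.4), self._summary("additive", 0.4)]
        assert model_ranking(tied)["all"]["tie"]
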