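"""Model fitting, AICc arithmetic, profile intervals and %social."""

import numpy as np
import pandas as pd
import pytest

from multinbda import (
    AssociationNetwork,
    DiffusionData,
    ModelSpec,
    NetworkStack,
    SimConfig,
    aicc,
    akaike_weights,
    build_candidate_specs,
    classify_spec,
    evaluate_at,
    fit_model,
    fit_model_set,
    likelihood_interval,
    model_average,
    percent_social,
    profile_ci,
    random_species_stack,
    simulate_diffusions,
)
from multinbda.fitting import ModelSetResult, FitResult


class TestAicc:
    def test_hand_value(self):
        assert aicc(-50.0, 2, 10) == pytest.approx(100 + 4 + 12 / 7, rel=1e-12)

    def test_zero_params_is_minus_two_loglik(self):
        assert aicc(-50.0, 0, 10) == pytest.approx(100.0)

    def test_correction_always_positive(self):
        for k, n in [(1, 5), (3, 20), (5, 100)]:
            assert aicc(-10.0, k, n) > -2 * -10.0 + 2 * k

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_equal_aiccs_split_evenly(self):
        assert np.allclose(akaike_weights([100.0, 100.0]), [0.5, 0.5])

    def test_delta_two(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), rel=1e-12)
        assert w[1] == pytest.approx(np.exp(-1.0) / (1 + np.exp(-1.0)), rel=1e-12)

    def test_sum_to_one_even_with_huge_deltas(self):
        w = akaike_weights([0.0, 1e4, 3.0, 1e5])
        assert w.sum() == pytest.approx(1.0, rel=1e-12)

    def test_non_finite_models_get_zero_weight(self):
        with pytest.warns(UserWarning):
            w = akaike_weights([100.0, np.inf])
        assert w[1] == 0.0 and w[0] == 1.0


class TestModelAverage:
    def _fake_set(self, weights, estimates):
        fits = [
            FitResult(spec=ModelSpec(layer_constraint="asocial"), estimates=e,
                      loglik=0.0, aicc=0.0, n_params=1, n_events=10, converged=True)
            for e in estimates
        ]
        return ModelSetResult(fits=fits, weights=np.asarray(weights),
                              table=pd.DataFrame(), hypothesis_support={})

    def test_conditional_and_full_variants(self):
        res = self._fake_set([0.6, 0.4], [{"s": 10.0}, {}])
        cond, full = model_average(res, "s")
        assert cond == pytest.approx(10.0)
        assert full == pytest.approx(6.0)

    def test_identical_everywhere(self):
        res = self._fake_set([0.3, 0.7], [{"s": 4.0}, {"s": 4.0}])
        cond, full = model_average(res, "s")
        assert cond == pytest.approx(4.0) and full == pytest.approx(4.0)

    def test_concentrated_weight_returns_best_model_value(self):
        res = self._fake_set([1.0, 0.0], [{"s": 2.5}, {"s": 99.0}])
        cond, full = model_average(res, "s")
        assert cond == pytest.approx(2.5) and full == pytest.approx(2.5)

    def test_absent_everywhere_raises(self):
        res = self._fake_set([0.5, 0.5], [{}, {}])
        with pytest.raises(KeyError):
            model_average(res, "s")


class TestLikelihoodInterval:
    def test_quadratic_loglik_hand_solution(self):
        # ell(theta) = -(theta - 2)^2 drops 1.9207 at 2 +/- sqrt(1.9207)
        ci = likelihood_interval(lambda th: -((th - 2.0) ** 2), 2.0, 0.0)
        root = np.sqrt(1.9207293)
        assert ci.lower == pytest.approx(2.0 - root, abs=1e-4)
        assert ci.upper == pytest.approx(2.0 + root, abs=1e-4)

    def test_flat_maximum_at_zero_clips_to_boundary(self):
        ci = likelihood_interval(lambda th: 0.0 if th < 1 else -5.0 * (th - 1.0),
                                 0.0, 0.0, lower_domain=0.0)
        assert ci.lower == 0.0 and ci.lower_at_boundary

    def test_interval_contains_the_mle(self):
        ci = likelihood_interval(lambda th: -abs(th - 3.0) ** 1.5, 3.0, 0.0,
                                 lower_domain=0.0)
        assert ci.lower <= 3.0 <= ci.upper


def _sim_dataset(seed, s=(22.2, 12.5), lam0=4.5e-7, n_nodes=30, n_diffusions=8):
    stack, cov_df = random_species_stack(
        n_nodes, {"blue": n_nodes // 2, "great": n_nodes - n_nodes // 2},
        seed=seed + 100,
    )
    cfg = SimConfig(stack=stack, lambda0=lam0,
                    s={"intra": s[0], "inter": s[1]},
                    n_diffusions=n_diffusions, seed=seed)
    return simulate_diffusions(cfg), {"site1": stack}


class TestFitModel:
    def test_recovers_generative_rates_at_generous_event_counts(self):
        # mean MLE over replicates approaches the generative rates
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        si, se = [], []
        for seed in range(4):
            diffs, stacks = _sim_dataset(seed)
            fit = fit_model(diffs, stacks, None, spec, seed=seed, n_starts=3)
            assert fit.converged
            si.append(fit.estimates["s_intra"])
            se.append(fit.estimates["s_inter"])
        assert np.mean(si) == pytest.approx(22.2, rel=0.5)
        assert np.mean(se) == pytest.approx(12.5, rel=0.5)

    def test_asocial_data_yields_small_social_estimates(self):
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        est = []
        for seed in range(3):
            diffs, stacks = _sim_dataset(seed + 30, s=(0.0, 0.0), lam0=3e-6,
                                         n_diffusions=30)
            fit = fit_model(diffs, stacks, None, spec, seed=seed, n_starts=3)
            est.append(max(fit.estimates["s_intra"], fit.estimates["s_inter"]))
        assert np.median(est) < 0.5

    def test_duplicated_layers_sum_matches_single_layer_fit(self, tiny_stack):
        ids = tiny_stack.node_ids
        w = tiny_stack.layers[0].weights + tiny_stack.layers[1].weights
        twin = NetworkStack(
            [AssociationNetwork(ids, w.copy()), AssociationNetwork(ids, w.copy())],
            ["a", "b"],
        )
        single = NetworkStack([AssociationNetwork(ids, w.copy())], ["a"])
        diffs = [
            DiffusionData("t1", "s1", 900.0, {"A": 50.0, "B": 200.0, "C": 400.0}),
            DiffusionData("t2", "s1", 900.0, {"D": 100.0, "E": 300.0, "A": 600.0}),
        ]
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        f2 = fit_model(diffs, {"s1": twin}, None, spec, seed=0)
        f1 = fit_model(diffs, {"s1": single}, None, spec, seed=0)
        assert f2.estimates["s_a"] + f2.estimates["s_b"] == pytest.approx(
            f1.estimates["s_a"], abs=1e-3
        )
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-6)

    def test_invariant_to_relabelling_and_reordering(self):
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        diffs, stacks = _sim_dataset(5, n_nodes=20, n_diffusions=4)
        fit = fit_model(diffs, stacks, None, spec, seed=1)
        stack = stacks["site1"]
        perm = np.random.default_rng(9).permutation(stack.n_nodes)
        ids = [stack.node_ids[p] for p in perm]
        stack2 = NetworkStack(
            [AssociationNetwork(ids, l.weights[np.ix_(perm, perm)])
             for l in stack.layers],
            list(stack.layer_names),
        )
        fit2 = fit_model(diffs[::-1], {"site1": stack2}, None, spec, seed=1)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)


class TestProfileCI:
    def test_ci_brackets_mle_and_tightens_with_level(self):
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        diffs, stacks = _sim_dataset(0)
        fit = fit_model(diffs, stacks, None, spec, seed=0)
        ci95 = profile_ci(diffs, stacks, None, spec, "s_intra", fit=fit)
        ci80 = profile_ci(diffs, stacks, None, spec, "s_intra", level=0.80, fit=fit)
        assert ci95.lower <= fit.estimates["s_intra"] <= ci95.upper
        assert ci95.lower <= ci80.lower and ci80.upper <= ci95.upper

    def test_difference_of_rates_profile(self):
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        diffs, stacks = _sim_dataset(0)
        fit = fit_model(diffs, stacks, None, spec, seed=0)
        ci = profile_ci(diffs, stacks, None, spec, "s_intra-s_inter", fit=fit)
        d_mle = fit.estimates["s_intra"] - fit.estimates["s_inter"]
        assert ci.lower <= d_mle <= ci.upper
        assert ci.upper - ci.lower > 0


class TestPercentSocial:
    def test_zero_social_rate_gives_zero_percent(self, tiny_stack):
        diffs = [DiffusionData("t", "s1", 900.0, {"A": 100.0, "D": 500.0})]
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        fit = evaluate_at(diffs, {"s1": tiny_stack}, None, spec,
                          {"lambda0": 1e-3, "s_intra": 0.0, "s_inter": 0.0})
        assert percent_social(fit).overall == 0.0

    def test_innovator_event_is_asocial_by_construction(self, tiny_stack):
        diffs = [DiffusionData("t", "s1", 900.0, {"A": 100.0})]
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        fit = evaluate_at(diffs, {"s1": tiny_stack}, None, spec,
                          {"lambda0": 1e-3, "s_intra": 50.0, "s_inter": 50.0})
        ps = percent_social(fit)
        assert ps.overall == 0.0 and ps.n_events == 1

    def test_near_pure_transmission(self):
        stack, _ = random_species_stack(20, {"blue": 10, "great": 10}, seed=7)
        seed_id = stack.node_ids[0]
        cfg = SimConfig(stack=stack, lambda0=1e-9, s={"intra": 5e4, "inter": 5e4},
                        n_diffusions=4, seed=3, seed_informed=(seed_id,))
        diffs = [d for d in simulate_diffusions(cfg) if d.n_events > 0]
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        fit = evaluate_at(diffs, {"site1": stack}, None, spec,
                          {"lambda0": 1e-9, "s_intra": 5e4, "s_inter": 5e4})
        ps = percent_social(fit)
        assert (ps.per_event["p_social"] > 0.95).all()

    def test_probabilities_bounded_and_layers_sum_below_one(self):
        diffs, stacks = _sim_dataset(2)
        spec = ModelSpec(layer_constraint="free", use_ties=False)
        fit = fit_model(diffs, stacks, None, spec, seed=2, n_starts=2)
        ps = percent_social(fit)
        pe = ps.per_event
        assert ((pe["p_social"] >= 0) & (pe["p_social"] <= 1)).all()
        assert ((pe["p_intra"] + pe["p_inter"]) <= 1 + 1e-12).all()

    def test_tie_masking_zeroes_and_restores_social_share(self):
        ids = ["A", "B"]
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        stack = NetworkStack([AssociationNetwork(ids, w)], ["intra"])
        spec = ModelSpec(layer_constraint="free", use_ties=True)
        vals = {"lambda0": 1e-4, "s_intra": 10.0}
        five_min = [DiffusionData("t", "s1", 3600.0, {"A": 100.0, "B": 400.0})]
        eleven_min = [DiffusionData("t", "s1", 3600.0, {"A": 100.0, "B": 760.0})]
        ps5 = percent_social(evaluate_at(five_min, {"s1": stack}, None, spec, vals))
        ps11 = percent_social(evaluate_at(eleven_min, {"s1": stack}, None, spec, vals))
        assert ps5.per_event["p_social"].iloc[1] == 0.0
        assert ps11.per_event["p_social"].iloc[1] > 0.5


class TestModelSet:
    def test_social_data_buries_the_asocial_model(self):
        diffs, stacks = _sim_dataset(0)
        specs = [ModelSpec(layer_constraint="asocial", use_ties=False),
                 ModelSpec(layer_constraint="shared", use_ties=False)]
        res = fit_model_set(diffs, stacks, None, specs, seed=0, n_starts=3)
        assert res.hypothesis_support["asocial"] < 0.01
        assert res.hypothesis_support["same_rate"] > 0.99

    def test_duplicated_spec_splits_weight_evenly(self, tiny_stack):
        diffs = [DiffusionData("t1", "s1", 900.0, {"A": 50.0, "B": 200.0, "C": 400.0}),
                 DiffusionData("t2", "s1", 900.0, {"D": 100.0, "E": 300.0})]
        spec = ModelSpec(layer_constraint="shared", use_ties=False)
        res = fit_model_set(diffs, {"s1": tiny_stack}, None, [spec, spec], seed=0,
                            n_starts=2)
        assert res.weights == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_hypothesis_support_partitions_unit_mass(self):
        diffs, stacks = _sim_dataset(1, n_nodes=20, n_diffusions=4)
        specs = build_candidate_specs(baselines=("constant",), use_ties=False)
        res = fit_model_set(diffs, stacks, None, specs, seed=1, n_starts=2)
        assert sum(res.hypothesis_support.values()) == pytest.approx(1.0, abs=1e-12)
        classes = {classify_spec(s, ("intra", "inter")) for s in specs}
        assert classes == {"asocial", "homogeneous", "same_rate", "different_rate",
                           "intra_only", "inter_only"}

    def test_candidate_grid_shape(self):
        specs = build_candidate_specs(
            ilv_subsets=((), ("species",), ("n_obs",)),
            always_ilv=("site",),
        )
        # per (baseline, subset): 5 social x 2 modes + 1 asocial = 11
        assert len(specs) == 2 * 3 * 11
        names = [s.name for s in specs]
        assert len(set(names)) == len(names)
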