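import numpy as np
import pytest

import plantclock as pc
from plantclock.cost import CostEvaluator, total_cost
from plantclock.synth import Design, NoiseModel, default_designs, generate_dataset


@pytest.fixture(scope="module")
def small_designs():
    """Four fast courses: wild type only, short LD protocol."""
    t = np.arange(12.0, 48.0, 3.0)
    return [
        Design("ld_L_m1", "wt", "ld:2", "LHY_m", t, scale_group="g1"),
        Design("ld_T_m1", "wt", "ld:2", "TOC1_m", t, scale_group="g1"),
        Design("ld_G_m1", "wt", "ld:2", "GI_m", t),
        Design("ld_P9_m1", "wt", "ld:2", "PRR9_m", t),
    ]


def gen(network, params, designs, **noise_kw):
    noise = NoiseModel(**noise_kw)
    return generate_dataset(network, params, designs, noise,
                            entrain_max_days=12, entrain_tol=1e-4)


class TestGenerateDataset:
    def test_seeded_determinism(self, canonical_network, reference_params,
                                small_designs):
        d1, t1 = gen(canonical_network, reference_params, small_designs,
                     multiplicative_sd=0.2, rng_seed=4)
        d2, t2 = gen(canonical_network, reference_params, small_designs,
                     multiplicative_sd=0.2, rng_seed=4)
        for cid in d1.courses:
            np.testing.assert_array_equal(d1.courses[cid].values,
                                          d2.courses[cid].values)
        assert t1["hidden_factors"] == t2["hidden_factors"]

    def test_zero_noise_self_consistency(self, canonical_network,
                                         reference_params, small_designs):
        # sigma = 0, unit scale factors: the generating parameters score ~0
        ds, _ = gen(canonical_network, reference_params, small_designs,
                    multiplicative_sd=0.0, scale_jitter_sd=0.0, rng_seed=0)
        bd = total_cost(ds, canonical_network, reference_params,
                        entrain_max_days=12, entrain_tol=1e-4)
        assert bd.total < 1e-6

    def test_hidden_factors_invisible_to_profile_cost(self, canonical_network,
                                                      reference_params,
                                                      small_designs):
        # random per-course factors, no groups: mean-normalization removes
        # them, so the profile cost stays ~0; grouped courses with
        # different factors pay a scaling cost instead
        designs = [Design(d.id, d.genotype, d.protocol, d.species, d.times)
                   for d in small_designs]  # strip groups
        ds, truth = gen(canonical_network, reference_params, designs,
                        multiplicative_sd=0.0, scale_jitter_sd=1.0, rng_seed=8)
        bd = total_cost(ds, canonical_network, reference_params,
                        entrain_max_days=12, entrain_tol=1e-4)
        assert bd.total < 1e-6

        ds2, truth2 = gen(canonical_network, reference_params, small_designs,
                          multiplicative_sd=0.0, scale_jitter_sd=1.0, rng_seed=8)
        bd2 = total_cost(ds2, canonical_network, reference_params,
                         entrain_max_days=12, entrain_tol=1e-4)
        # both grouped courses share one hidden factor here -> no penalty;
        # force distinct factors to see the cost appear
        f = truth2["hidden_factors"]
        assert bd2.total < 1e-6
        course = ds2.courses["ld_T_m1"]
        object.__setattr__(course, "values", course.values * 3.0)
        bd3 = total_cost(ds2, canonical_network, reference_params,
                         entrain_max_days=12, entrain_tol=1e-4)
        # two members, ratios r and 3r: deviations +/- log(3)/2
        assert bd3.per_group_scaling["g1"] == pytest.approx(np.log(3.0) ** 2 / 4,
                                                            rel=1e-3)

    def test_noise_floor_matches_analytic_value(self, canonical_network,
                                                reference_params, small_designs):
        # with lognormal noise exp(N(0, s^2)), the expected profile cost at
        # the generating parameters approaches 2 s^2 for small s (variance
        # of the normalized ratio, twice: data normalized by a noisy mean)
        s = 0.15
        costs = []
        for seed in range(12):
            ds, _ = gen(canonical_network, reference_params, small_designs[:2],
                        multiplicative_sd=s, scale_jitter_sd=0.0, rng_seed=seed)
            bd = total_cost(ds, canonical_network, reference_params,
                            entrain_max_days=12, entrain_tol=1e-4)
            costs.append(np.mean(list(bd.per_course_profile.values())))
        mean_cost = float(np.mean(costs))
        # generous Monte-Carlo band around the s^2..2s^2 analytic scale
        assert 0.5 * s ** 2 < mean_cost < 4.0 * s ** 2

    def test_cost_nondecreasing_in_noise(self, canonical_network,
                                         reference_params, small_designs):
        means = []
        for s in (0.05, 0.15, 0.4):
            per = []
            for seed in range(4):
                ds, _ = gen(canonical_network, reference_params,
                            small_designs[:2], multiplicative_sd=s,
                            scale_jitter_sd=0.0, rng_seed=seed)
                bd = total_cost(ds, canonical_network, reference_params,
                                entrain_max_days=12, entrain_tol=1e-4)
                per.append(sum(bd.per_course_profile.values()))
            means.append(np.mean(per))
        assert means[0] < means[1] < means[2]

    def test_default_designs_structure(self):
        designs = default_designs()
        assert len(designs) == 12
        genotypes = {d.genotype for d in designs}
        assert genotypes == {"wt", "cca1;lhy", "rve4;rve6;rve8"}
        grouped = [d for d in designs if d.scale_group == "g1"]
        assert len(grouped) == 3
        dt = np.diff(designs[0].times)
        assert np.allclose(dt, 3.0)


class TestCostEvaluatorIntegration:
    def test_alpha_zero_drops_scaling_term(self, canonical_network,
                                           reference_params, small_designs):
        ds, _ = gen(canonical_network, reference_params, small_designs,
                    multiplicative_sd=0.1, scale_jitter_sd=0.4, rng_seed=1)
        course = ds.courses["ld_T_m1"]
        object.__setattr__(course, "values", course.values * 2.5)
        ev0 = CostEvaluator(canonical_network, ds, alpha=0.0,
                            entrain_max_days=12, entrain_tol=1e-4)
        ev1 = CostEvaluator(canonical_network, ds, alpha=1.0,
                            entrain_max_days=12, entrain_tol=1e-4)
        b0 = ev0.breakdown(reference_params)
        b1 = ev1.breakdown(reference_params)
        assert b0.total == pytest.approx(
            sum(ds.courses[c].weight * v for c, v in b0.per_course_profile.items()))
        assert b1.total > b0.total  # the scaling term is positive here

    def test_doubling_weight_doubles_contribution(self, canonical_network,
                                                  reference_params,
                                                  small_designs):
        ds, _ = gen(canonical_network, reference_params, small_designs,
                    multiplicative_sd=0.2, scale_jitter_sd=0.0, rng_seed=2)
        ev = CostEvaluator(canonical_network, ds, alpha=0.0,
                           entrain_max_days=12, entrain_tol=1e-4)
        b1 = ev.breakdown(reference_params)
        c = ds.courses["ld_G_m1"]
        object.__setattr__(c, "weight", 2.0)
        b2 = ev.breakdown(reference_params)
        delta = b2.total - b1.total
        assert delta == pytest.approx(b1.per_course_profile["ld_G_m1"], rel=1e-9)

    def test_simulation_failure_gives_infinite_cost(self, canonical_network,
                                                    small_designs,
                                                    reference_params,
                                                    monkeypatch):
        solo = Design("ld_G_m2", "wt", "ld:2", "GI_m",
                      np.arange(12.0, 48.0, 3.0))
        ds, _ = gen(canonical_network, reference_params, [solo],
                    multiplicative_sd=0.0, rng_seed=0)
        ev = CostEvaluator(canonical_network, ds, entrain_max_days=3,
                           entrain_tol=1e-4)
        from plantclock import cost as cost_mod
        from plantclock.simulate import IntegrationError

        def boom(*a, **k):
            raise IntegrationError("synthetic failure")

        monkeypatch.setattr(cost_mod, "simulate", boom)
        bd = ev.breakdown(reference_params)
        assert bd.total == float("inf")
        assert any("failed" in d for d in bd.diagnostics)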