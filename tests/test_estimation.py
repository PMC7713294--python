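import numpy as np
import pytest

from carokin import (
    AssaySpec,
    FitConfig,
    KineticParameters,
    TimeCourse,
    build_network,
    derive_constants,
    fit_pso,
    objective,
    profile_identifiability,
    simulate,
)
from carokin.estimate import default_bounds, parameter_names


@pytest.fixture
def experiment(network4, params4, dense_assay):
    tc = simulate(network4, params4, dense_assay)
    return (dense_assay, tc)


class TestFitConfig:
    def test_defaults_match_stated_bounds(self):
        config = FitConfig()
        assert config.bounds["k_f"] == (0.1, 1.0)
        assert config.bounds["k_r"] == (1.0, 10.0)
        assert config.bounds["k_cat"] == (1e-5, 0.1)
        assert config.iterations == 2000
        assert config.swarm_size == 50

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(bounds={"k_f": (1.0, 0.1)})

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(iterations=0)
        with pytest.raises(ValueError):
            FitConfig(swarm_size=1)

    def test_dict_round_trip(self):
        config = FitConfig(iterations=100, swarm_size=10, seed=7)
        assert FitConfig.from_dict(config.to_dict()) == config


class TestObjective:
    def test_self_consistency_noise_free(self, network4, params4, experiment):
        val = objective(params4, [experiment], network4)
        assert val == pytest.approx(0.0, abs=1e-8)

    def test_single_point_formula(self, network4):
        """obs = 2, sim = 3 at one point -> w = 1/4, objective = 0.25."""
        assay = AssaySpec(10.0, 0.0, (0.0, 10.0))
        # enzyme_total = 0 keeps phytoene at 10 exactly; craft obs so that
        # only phytoene contributes, with a single informative point.
        obs = TimeCourse(
            np.array([0.0, 10.0]), {"phytoene": np.array([10.0, 2.0])}
        )
        # sim is [10, 10]; residuals (0, 8) -> w = 1/mean([100,4]) = 1/52
        val = objective(
            KineticParameters([0.5] * 5, [5.0] * 5, [0.05] * 4),
            [(assay, obs)],
            build_network(4),
        )
        assert val == pytest.approx(64.0 / 52.0, rel=1e-6)

    def test_single_species_single_time_weight(self, network4):
        """Directly check w = 1/mean(obs^2) with obs 2 vs sim 3."""
        from carokin.estimate import _WEIGHTINGS

        obs = np.array([2.0])
        w = _WEIGHTINGS["mean_square"](obs)
        assert w == pytest.approx(0.25)
        assert w * (3.0 - 2.0) ** 2 == pytest.approx(0.25)

    def test_scale_invariance_of_weighting(self, network4, params4, dense_assay):
        tc = simulate(network4, params4, dense_assay)
        perturbed = KineticParameters(
            params4.k_f, params4.k_r, params4.k_cat * 1.3
        )
        base = objective(perturbed, [(dense_assay, tc)], network4)
        # doubling observations AND simulations of one species leaves its
        # weighted contribution unchanged: emulate by scaling a species'
        # observations and comparing contribution ratios analytically
        name = "phytofluene"
        scaled_totals = {
            k: (v * 2.0 if k == name else v) for k, v in tc.totals.items()
        }
        # contribution of species s is w_s * sse_s with w_s ~ 1/mean(obs^2):
        # scaling obs and sim by c multiplies sse by c^2 and w by 1/c^2.
        from carokin.estimate import _WEIGHTINGS

        w = _WEIGHTINGS["mean_square"]
        sim = simulate(network4, perturbed, dense_assay)
        contrib = w(tc.totals[name]) * np.sum(
            (sim.totals[name] - tc.totals[name]) ** 2
        )
        contrib_scaled = w(tc.totals[name] * 2) * np.sum(
            (2 * sim.totals[name] - 2 * tc.totals[name]) ** 2
        )
        assert contrib_scaled == pytest.approx(contrib, rel=1e-12)
        assert base >= 0

    def test_all_zero_species_skipped(self, network4, params4, dense_assay):
        tc = simulate(network4, params4, dense_assay)
        totals = dict(tc.totals)
        totals["lycopene"] = np.zeros_like(tc.times)
        censored = TimeCourse(tc.times, totals)
        val = objective(params4, [(dense_assay, censored)], network4)
        assert np.isfinite(val)

    def test_empty_experiments_rejected(self, network4, params4):
        with pytest.raises(ValueError):
            objective(params4, [], network4)

    def test_mismatched_times_rejected(self, network4, params4, dense_assay):
        tc = TimeCourse(np.array([0.0, 5.0]), {"phytoene": np.array([10.0, 9.0])})
        with pytest.raises(ValueError, match="match"):
            objective(params4, [(dense_assay, tc)], network4)

    def test_unknown_weighting_rejected(self, network4, params4, experiment):
        with pytest.raises(ValueError, match="weighting"):
            objective(params4, [experiment], network4, weighting="bogus")


class TestDeriveConstants:
    def test_kd_upper_bound_corner(self):
        p = KineticParameters([0.1, 0.1], [10.0, 10.0], [0.01])
        table = derive_constants(p)
        assert table["K_d_uM"].iloc[0] == pytest.approx(100.0)

    def test_kd_lower_bound_corner(self):
        p = KineticParameters([1.0, 1.0], [1.0, 1.0], [0.01])
        table = derive_constants(p)
        assert table["K_d_uM"].iloc[0] == pytest.approx(1.0)

    def test_km_equals_kd_when_kcat_zero(self):
        p = KineticParameters([0.5, 0.5], [5.0, 5.0], [0.0])
        table = derive_constants(p)
        assert table["K_m_uM"].iloc[0] == pytest.approx(table["K_d_uM"].iloc[0])

    def test_terminal_step_has_no_km_or_kcat(self, params4):
        table = derive_constants(params4)
        assert np.isnan(table["K_m_uM"].iloc[-1])
        assert np.isnan(table["k_cat_per_s"].iloc[-1])

    def test_zero_kf_rejected(self):
        p = KineticParameters([0.0, 0.5], [5.0, 5.0], [0.01])
        with pytest.raises(ZeroDivisionError):
            derive_constants(p)


class TestFitPso:
    def test_seeded_determinism(self, network4, experiment):
        config = FitConfig(iterations=5, swarm_size=5, seed=42, polish=False)
        a = fit_pso(network4, [experiment], config)
        b = fit_pso(network4, [experiment], config)
        assert np.array_equal(a.best_params.to_vector(), b.best_params.to_vector())
        assert np.array_equal(a.trace, b.trace)
        assert a.objective_value == b.objective_value

    def test_trace_monotone_and_bounds_respected(self, network4, experiment):
        config = FitConfig(iterations=15, swarm_size=8, seed=3, polish=False)
        res = fit_pso(network4, [experiment], config)
        assert np.all(np.diff(res.trace) <= 0)
        lo, hi = default_bounds(network4, config.bounds)
        vec = res.best_params.to_vector()
        assert np.all(vec >= lo - 1e-12)
        assert np.all(vec <= hi + 1e-12)

    def test_derived_table_consistent(self, network4, experiment):
        res = fit_pso(network4, [experiment], FitConfig(iterations=5, swarm_size=5, polish=False))
        kd = res.best_params.k_r / res.best_params.k_f
        assert res.derived_constants["K_d_uM"].to_numpy() == pytest.approx(kd)

    def test_warm_start_at_truth_is_immediately_optimal(
        self, network4, params4, experiment
    ):
        config = FitConfig(iterations=3, swarm_size=5, seed=0, polish=False)
        res = fit_pso(
            network4, [experiment], config, initial_guess=params4
        )
        assert res.objective_value < 1e-8

    def test_empty_experiments_rejected(self, network4):
        with pytest.raises(ValueError):
            fit_pso(network4, [], FitConfig(iterations=2, swarm_size=3, polish=False))

    def test_fixed_parameter_is_held(self, network4, experiment):
        config = FitConfig(iterations=5, swarm_size=5, seed=1, polish=False)
        res = fit_pso(network4, [experiment], config, fixed={"k_cat[0]": 0.02})
        assert res.best_params.k_cat[0] == pytest.approx(0.02)

    def test_unknown_fixed_parameter_rejected(self, network4, experiment):
        with pytest.raises(KeyError):
            fit_pso(
                network4, [experiment],
                FitConfig(iterations=2, swarm_size=3, polish=False),
                fixed={"k_cat[9]": 0.02},
            )

    def test_result_json_round_trip(self, network4, experiment, tmp_path):
        from carokin.estimate import FitResult

        res = fit_pso(network4, [experiment], FitConfig(iterations=4, swarm_size=4, polish=False))
        path = tmp_path / "fit.json"
        res.to_json(path)
        back = FitResult.from_json(path)
        assert np.array_equal(back.best_params.to_vector(),
                              res.best_params.to_vector())
        assert back.objective_value == res.objective_value
        assert back.config == res.config


class TestProfileIdentifiability:
    def test_single_point_equals_constrained_fit(self, network4, experiment):
        config = FitConfig(iterations=4, swarm_size=4, seed=5, polish=False)
        profile = profile_identifiability(
            network4, [experiment], config, "k_cat[0]", [0.05]
        )
        direct = fit_pso(
            network4, [experiment], config, fixed={"k_cat[0]": 0.05}
        )
        assert len(profile) == 1
        assert profile["objective"].iloc[0] == pytest.approx(direct.objective_value)

    def test_unknown_parameter_rejected(self, network4, experiment):
        with pytest.raises(KeyError):
            profile_identifiability(
                network4, [experiment], FitConfig(iterations=2, swarm_size=3, polish=False),
                "k_oops[0]", [0.1],
            )

    def test_ignored_parameter_gives_flat_profile(self, network4, params4):
        """Terminal k_r is irrelevant when the terminal product never forms."""
        zero_cat = KineticParameters(
            params4.k_f, params4.k_r, np.zeros(4)
        )
        assay = AssaySpec(10.0, 0.83, (0.0, 10.0, 30.0))
        tc = simulate(network4, zero_cat, assay)
        config = FitConfig(iterations=3, swarm_size=4, seed=9, polish=False)
        profile = profile_identifiability(
            network4, [(assay, tc)], config, "k_r[4]", [1.0, 5.0, 10.0]
        )
        # all re-fits see the same information: objectives within noise of
        # the swarm, far below any identifiable signal
        assert profile["objective"].max() < 1e-3


def test_parameter_names_order(network4):
    names = parameter_names(network4)
    assert names[0] == "k_f[0]"
    assert names[5] == "k_r[0]"
    assert names[-1] == "k_cat[3]"
    assert len(names) == 14
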