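import numpy as np
import pytest
from scipy import stats

from daphnia_ifd.ibm import (
    InvalidMoveError,
    SimulationConfig,
    SimulationState,
    equilibrium_check,
    perceived_fitness,
    run_replicates,
    run_simulation,
    step,
)


class TestPerceivedFitness:
    def test_non_adjacent_candidate_rejected(self, environments, params):
        st_ = SimulationState.initial(5, 4, 10)
        with pytest.raises(InvalidMoveError):
            perceived_fitness(4, 6, st_, environments["none"], params)

    def test_zero_thresholds_see_true_conditions(self, environments, sharp_params):
        # in the food treatment the upper neighbor is truly richer, so an
        # omniscient singleton always ranks it above staying
        st_ = SimulationState.initial(1, 4, 10)
        up = perceived_fitness(4, 3, st_, environments["food"], sharp_params)
        stay = perceived_fitness(4, 4, st_, environments["food"], sharp_params)
        assert up > stay

    def test_sub_threshold_food_difference_invisible(self, column, params):
        # 10% food step is below the juvenile 19% detection threshold:
        # both candidate sectors are perceived as equal to staying
        from daphnia_ifd.column import build_environment

        food = 0.8 * 1.1 ** np.arange(10)[::-1]
        env = build_environment(column, food, np.full(10, 10.0))
        st_ = SimulationState.initial(1, 4, 10)
        stay = perceived_fitness(4, 4, st_, env, params, "juvenile")
        up = perceived_fitness(4, 3, st_, env, params, "juvenile")
        assert up == pytest.approx(stay)

    def test_mover_counts_itself_in_candidate_density(self, environments, params):
        # moving next to an equally occupied sector must look worse than
        # staying (the mover raises the target's density by 1/volume)
        env = environments["none"]
        st_ = SimulationState.initial(10, 4, 10)
        st_.agent_sectors[:5] = 5
        st_.occupancy[:] = 0
        st_.occupancy[4] = 5
        st_.occupancy[5] = 5
        stay = perceived_fitness(4, 4, st_, env, params)
        move = perceived_fitness(4, 5, st_, env, params)
        assert move < stay


class TestStep:
    def test_conservation_and_single_sector_moves(self, environments, params):
        rng = np.random.default_rng(5)
        st_ = SimulationState.initial(60, 4, 10)
        for _ in range(50):
            before = st_.agent_sectors.copy()
            step(st_, environments["both"], params, rng)
            assert st_.occupancy.sum() == 60
            assert np.array_equal(
                st_.occupancy, np.bincount(st_.agent_sectors, minlength=10)
            )
            assert np.max(np.abs(st_.agent_sectors - before)) <= 1

    def test_greedy_ascent_on_monotone_landscape(self, environments, sharp_params):
        # a lone omniscient animal climbs a strict food gradient to the top
        # sector within at most n_sectors - 1 sweeps
        rng = np.random.default_rng(0)
        st_ = SimulationState.initial(1, 4, 10)
        for _ in range(9):
            step(st_, environments["food"], sharp_params, rng)
        assert st_.agent_sectors[0] == 0

    def test_uniform_environment_is_unbiased_lazy_walk(self, environments, params):
        rng = np.random.default_rng(11)
        st_ = SimulationState.initial(1, 4, 10)
        ups = downs = 0
        prev = 4
        for _ in range(10_000):
            step(st_, environments["none"], params, rng)
            cur = int(st_.agent_sectors[0])
            if 0 < prev < 9:  # interior: up and down both available
                ups += cur == prev - 1
                downs += cur == prev + 1
            prev = cur
        p = stats.binomtest(ups, ups + downs, 0.5).pvalue
        assert p > 0.01

    def test_identical_seed_identical_trajectory(self, environments, params):
        cfg = SimulationConfig(n_individuals=40, treatment="both", seed=9,
                               n_replicates=2)
        a = run_simulation(cfg, environments["both"], params, record_trajectory=True)
        b = run_simulation(cfg, environments["both"], params, record_trajectory=True)
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_python_and_compiled_backends_agree(self, environments, params):
        cfg = SimulationConfig(n_individuals=30, treatment="risk", seed=3,
                               n_replicates=2, n_steps=60, burn_in=30)
        fast = run_simulation(cfg, environments["risk"], params,
                              record_trajectory=True, backend="fast")
        slow = run_simulation(cfg, environments["risk"], params,
                              record_trajectory=True, backend="python")
        assert np.array_equal(fast.trajectory, slow.trajectory)


class TestReplicates:
    def test_single_replicate_matches_run_simulation(self, environments, params):
        cfg = SimulationConfig(n_individuals=20, treatment="food", seed=21,
                               n_replicates=1)
        one = run_replicates(cfg, environments["food"], params)
        direct = run_simulation(cfg, environments["food"], params, replicate=0)
        assert np.allclose(one.mean_distribution, direct.mean_distribution)
        assert one.grand_mean_depth == pytest.approx(direct.grand_mean_depth)

    def test_grand_mean_is_mean_of_replicates(self, environments, params):
        cfg = SimulationConfig(n_individuals=20, treatment="both", seed=2,
                               n_replicates=8)
        res = run_replicates(cfg, environments["both"], params)
        assert res.grand_mean_depth == pytest.approx(
            res.per_replicate_mean_depth.mean()
        )
        assert res.mean_distribution.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_gradient_distribution_uniform(self, environments, params):
        # chi-square goodness of fit on the pooled final-step occupancy
        cfg = SimulationConfig(n_individuals=60, treatment="none", seed=17,
                               n_replicates=100)
        res = run_replicates(cfg, environments["none"], params,
                             keep_final_states=True)
        counts = np.sum([s.occupancy for s in res.final_states], axis=0)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01
        assert abs(res.grand_mean_depth - 0.5) < 0.05

    def test_risk_gradient_pushes_deeper_than_none(self, params):
        depths = {}
        for tr in ("none", "risk"):
            cfg = SimulationConfig(n_individuals=60, treatment=tr, seed=31,
                                   n_replicates=10)
            depths[tr] = run_replicates(cfg, params=params).per_replicate_mean_depth
        assert np.all(depths["risk"] > depths["none"])


class TestEquilibrium:
    def test_lone_agent_at_global_optimum(self, environments, sharp_params):
        st_ = SimulationState.initial(1, 0, 10)  # top = food optimum
        gain = equilibrium_check(st_, environments["food"], sharp_params)
        assert gain <= 0

    def test_flat_landscape_without_interference_is_all_ties(self, column,
                                                             sharp_params):
        from daphnia_ifd.column import build_environment
        from daphnia_ifd.ibm import AgeClassParams, ModelParams
        from daphnia_ifd.rates import GrowthParams

        juv = sharp_params.juvenile
        no_interf = AgeClassParams(
            GrowthParams(b=0.0), juv.rd, juv.perception, juv.gamma
        )
        p = ModelParams(juvenile=no_interf, adult=sharp_params.adult,
                        mortality=sharp_params.mortality,
                        handling=sharp_params.handling,
                        n_exponent=sharp_params.n_exponent)
        env = build_environment(column, np.full(10, 0.8), np.full(10, 10.0))
        rng = np.random.default_rng(1)
        st_ = SimulationState.initial(12, 4, 10)
        for _ in range(20):
            step(st_, env, p, rng)
        assert equilibrium_check(st_, env, p) == pytest.approx(0.0, abs=1e-12)
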