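import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import zeta

from levyswarm import (
    NEVER,
    KernelSpec,
    LevyStepSampler,
    SimConfig,
    apply_boundary,
    choose_move_mode,
    generate_environment,
    init_state,
    run,
    sample_levy_component,
    step,
)


class TestLevySampler:
    def test_sign_symmetry(self):
        rng = np.random.default_rng(0)
        draws = LevyStepSampler(mu=1.0, cutoff=1000).sample(100_000, rng)
        assert np.all(draws != 0)
        p_pos = np.mean(draws > 0)
        assert abs(p_pos - 0.5) < 3 * 0.5 / np.sqrt(draws.size)

    def test_mu_one_unit_step_mass(self):
        # P(l = +1) -> 1 / (2 zeta(2)) = 3 / pi^2 as the cutoff grows
        rng = np.random.default_rng(1)
        draws = LevyStepSampler(mu=1.0, cutoff=10_000_000).sample(200_000, rng)
        p = np.mean(draws == 1)
        expect = 3 / np.pi**2
        assert abs(p - expect) < 3 * np.sqrt(expect * (1 - expect) / draws.size)

    def test_mu_two_magnitude_one_mass(self):
        # P(|l| = 1) -> 1 / zeta(3)
        rng = np.random.default_rng(2)
        draws = LevyStepSampler(mu=2.0, cutoff=10_000_000).sample(200_000, rng)
        p = np.mean(np.abs(draws) == 1)
        expect = 1 / zeta(3)
        assert abs(p - expect) < 3 * np.sqrt(expect * (1 - expect) / draws.size)

    def test_magnitudes_respect_cutoff(self):
        rng = np.random.default_rng(3)
        draws = LevyStepSampler(mu=0.0, cutoff=7).sample(10_000, rng)
        assert np.abs(draws).max() <= 7

    def test_scalar_wrapper(self, rng):
        val = sample_levy_component(1.0, 10, rng)
        assert isinstance(val, int) and 1 <= abs(val) <= 10


class TestBoundary:
    @pytest.mark.parametrize(
        "x,L,mode,expected",
        [
            (12, 10, "reflective", 7),
            (-1, 10, "reflective", 0),
            (3, 10, "reflective", 3),
            (3, 10, "periodic", 3),
            (12, 10, "periodic", 2),
            (-1, 10, "periodic", 9),
            (10, 10, "reflective", 9),
            (-10, 10, "reflective", 9),
        ],
    )
    def test_fold_examples(self, x, L, mode, expected):
        assert apply_boundary(x, L, mode) == expected

    @settings(deadline=None)
    @given(x=st.integers(-1000, 1000), L=st.integers(2, 50),
           mode=st.sampled_from(["reflective", "periodic"]))
    def test_in_range_and_idempotent(self, x, L, mode):
        y = apply_boundary(x, L, mode)
        assert 0 <= y < L
        assert apply_boundary(y, L, mode) == y

    def test_vectorized(self):
        out = apply_boundary(np.array([-1, 3, 12]), 10, "reflective")
        np.testing.assert_array_equal(out, [0, 3, 7])


class TestChooseMoveMode:
    def test_no_memory_always_random(self, rng):
        for _ in range(50):
            assert choose_move_mode(False, 0.0, q=0.0, rho=0.7, rng=rng) == "random_step"

    def test_full_self_memory(self, rng):
        for _ in range(50):
            assert choose_move_mode(False, 0.0, q=1.0, rho=0.0, rng=rng) == "self_memory"

    def test_feeding_frequency(self):
        rng = np.random.default_rng(4)
        n = 100_000
        stays = sum(
            choose_move_mode(True, 0.9, q=0.25, rho=0.5, rng=rng) == "stay_feeding"
            for _ in range(n)
        )
        assert abs(stays / n - 0.9) < 3 * np.sqrt(0.9 * 0.1 / n)

    def test_off_target_partition(self):
        rng = np.random.default_rng(5)
        n = 60_000
        modes = [choose_move_mode(False, 0.0, q=0.4, rho=0.25, rng=rng) for _ in range(n)]
        freqs = {m: modes.count(m) / n for m in set(modes)}
        for mode, p in [("self_memory", 0.3), ("peer_memory", 0.1), ("random_step", 0.6)]:
            assert abs(freqs[mode] - p) < 4 * np.sqrt(p * (1 - p) / n)


@pytest.fixture
def small_env():
    return generate_environment(20, 0.01, 0.9, seed=42)


class TestStepAndRun:
    def test_pure_memory_walker_frozen_at_origin(self, small_env):
        """q=1, rho=0: the only history entry is X0, so the walker never moves."""
        cfg = SimConfig(N=4, q=1.0, rho=0.0, T=200, kernel=KernelSpec(beta=0.7),
                        seed=1, obs_every=50)
        res = run(small_env, cfg, record_trajectory=True)
        sites = res.trajectory.sites
        assert np.all(sites == sites[0])

    def test_positions_stay_on_lattice(self, small_env):
        cfg = SimConfig(N=10, q=0.3, rho=0.5, mu=0.5, T=500, seed=3, obs_every=100)
        res = run(small_env, cfg, record_trajectory=True)
        assert res.trajectory.sites.min() >= 0
        assert res.trajectory.sites.max() < small_env.L**2

    def test_identical_seeds_bitwise_identical(self, small_env):
        cfg = SimConfig(N=8, q=0.25, rho=0.5, T=300, kernel=KernelSpec(beta=1.0), seed=9)
        a = run(small_env, cfg, record_trajectory=True)
        b = run(small_env, cfg, record_trajectory=True)
        np.testing.assert_array_equal(a.trajectory.sites, b.trajectory.sites)
        np.testing.assert_array_equal(a.n_r, b.n_r)
        np.testing.assert_array_equal(a.first_visit_best, b.first_visit_best)

    def test_different_seed_differs(self, small_env):
        from dataclasses import replace

        cfg = SimConfig(N=8, q=0.25, rho=0.5, T=300, seed=9)
        a = run(small_env, cfg, record_trajectory=True)
        b = run(small_env, replace(cfg, seed=10), record_trajectory=True)
        assert not np.array_equal(a.trajectory.sites, b.trajectory.sites)

    def test_single_walker_zero_mean_displacement(self):
        """Independent unbiased walks: ensemble-mean displacement ~ 0 by symmetry."""
        env = generate_environment(101, 0.0005, 0.9, seed=2)  # 5 targets, sparse
        cfg = SimConfig(N=60, q=0.0, rho=0.0, mu=1.0, T=300, boundary="periodic",
                        seed=6, obs_every=100)
        res = run(env, cfg, record_trajectory=True)
        x0 = res.trajectory.coordinates(0)
        xT = res.trajectory.coordinates(300)
        # net displacement on the torus, folded to [-L/2, L/2)
        d = (xT - x0 + env.L // 2) % env.L - env.L // 2
        assert abs(d.mean()) < 4 * d.std() / np.sqrt(d.size)

    def test_mean_feeding_duration_matches_reward(self):
        """Simulated sojourns on a target average 1/(1-gamma) steps per visit."""
        env = generate_environment(10, 0.01, 0.9, seed=1)
        gamma = env.targets[0].gamma
        site = env.best_site_flat()
        cfg = SimConfig(N=60, q=0.0, rho=0.0, mu=0.5, T=4000, seed=7,
                        boundary="periodic", obs_every=1000)
        res = run(env, cfg, record_trajectory=True)
        on = res.trajectory.sites == site  # (T+1, N)
        lengths = []
        for l in range(cfg.N):
            col = on[:, l].astype(np.int8)
            edges = np.diff(np.concatenate([[0], col, [0]]))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            for s, e in zip(starts, ends):
                if e <= cfg.T:  # drop the sojourn truncated by the horizon
                    lengths.append(e - s)
        lengths = np.array(lengths)
        assert lengths.size > 300
        mean, se = lengths.mean(), lengths.std() / np.sqrt(lengths.size)
        assert abs(mean - 1 / (1 - gamma)) < 4 * se

    def test_first_visit_recorded(self, small_env):
        cfg = SimConfig(N=30, q=0.1, rho=0.5, mu=0.5, T=2000, seed=11, obs_every=500)
        res = run(small_env, cfg, record_trajectory=True)
        best = small_env.best_site_flat()
        for l in range(30):
            visits = np.flatnonzero(res.trajectory.sites[:, l] == best)
            fv = res.first_visit_best[l]
            if visits.size:
                assert fv == visits[0]
            else:
                assert fv == NEVER

    def test_single_walker_with_rho_warns_and_runs(self, small_env):
        cfg = SimConfig(N=1, q=0.5, rho=0.5, T=50, seed=1, obs_every=25)
        with pytest.warns(UserWarning, match="peer"):
            res = run(small_env, cfg)
        assert res.final_sites.shape == (1,)

    def test_step_advances_one_walker_synchronously(self, small_env):
        cfg = SimConfig(N=5, q=0.5, rho=0.5, T=10, seed=2)
        rng = np.random.default_rng(cfg.seed)
        state = init_state(small_env, cfg, rng)
        before = state.history[0].copy()
        step(state, small_env, cfg, rng)
        assert state.t == 1
        np.testing.assert_array_equal(state.history[0], before)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=0),
            dict(q=1.2),
            dict(rho=-0.1),
            dict(movement="walk"),
            dict(mu=3.0),
            dict(T=0),
            dict(boundary="absorbing"),
            dict(obs_every=0),
            dict(levy_cutoff=0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
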