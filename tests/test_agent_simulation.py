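"""Access probabilities, lifetime simulation, and the fitness surface."""

import itertools

import numpy as np
import pytest

import dualproc as dp
from dualproc.energy_model import consumption_to_reach


def enumerate_access(R, pc, mean_auto_share, w_auto):
    """Brute-force expectation over every contest configuration.

    Enumerates (contested?, opponent mode, winner) outcomes one by one and
    sums path probabilities — an independent path to the closed form.
    """
    win = {  # (focal_mode, opp_mode) -> probability the focal actor wins
        ("auto", "auto"): 0.5,
        ("auto", "ctrl"): w_auto,
        ("ctrl", "auto"): 1.0 - w_auto,
        ("ctrl", "ctrl"): 0.5,
    }
    out = {}
    for focal in ("auto", "ctrl"):
        total = 0.0
        for contested, opp in itertools.product((False, True), ("auto", "ctrl")):
            p_branch = (pc if contested else 1.0 - pc) * (
                mean_auto_share if opp == "auto" else 1.0 - mean_auto_share
            )
            p_win = win[(focal, opp)] if contested else 1.0
            total += p_branch * p_win
        out[focal] = R * total
    return out["auto"], out["ctrl"]


class TestAccessProbabilities:
    def test_alone_means_no_competition(self):
        acc = dp.access_probabilities(0.1, 1, 1.0, dp.CompetitionModel())
        assert acc.p_auto == acc.p_ctrl == pytest.approx(0.1)

    def test_full_contest_all_automatic(self):
        # every encounter contested by an automatic opponent: automatic
        # actors split randomly, controlled actors get nothing (w_auto=1)
        comp = dp.CompetitionModel(kappa=1.0, w_auto=1.0)
        assert comp.contest_probability(11, 0.1) == 1.0
        acc = dp.access_probabilities(0.1, 11, 1.0, comp)
        assert acc.p_auto == pytest.approx(0.05)
        assert acc.p_ctrl == pytest.approx(0.0)

    def test_full_contest_all_controlled(self):
        comp = dp.CompetitionModel(kappa=1.0, w_auto=1.0)
        acc = dp.access_probabilities(0.1, 11, 0.0, comp)
        assert acc.p_ctrl == pytest.approx(0.05)

    @pytest.mark.parametrize("w_auto", [0.6, 1.0])
    def test_closed_form_matches_enumeration(self, w_auto):
        comp = dp.CompetitionModel(kappa=0.05, w_auto=w_auto)
        for N in (1, 5, 50, 200):
            pc = comp.contest_probability(N, 0.2)
            for mas in (0.0, 0.3, 1.0):
                acc = dp.access_probabilities(0.2, N, mas, comp)
                exp_auto, exp_ctrl = enumerate_access(0.2, pc, mas, w_auto)
                assert acc.p_auto == pytest.approx(exp_auto, abs=1e-12)
                assert acc.p_ctrl == pytest.approx(exp_ctrl, abs=1e-12)
                assert acc.p_ctrl <= acc.p_auto + 1e-12

    def test_contest_win_probabilities_conserve_total(self):
        for w in (0.6, 0.8, 1.0):
            assert w + (1.0 - w) == pytest.approx(1.0)  # mixed pairing
            assert 0.5 + 0.5 == pytest.approx(1.0)  # same-mode pairing

    def test_invalid_inputs(self):
        comp = dp.CompetitionModel()
        with pytest.raises(ValueError):
            dp.access_probabilities(0.1, 0, 0.5, comp)
        with pytest.raises(ValueError):
            dp.CompetitionModel(w_auto=0.4)

    def test_saturating_form_monotone_and_bounded(self):
        comp = dp.CompetitionModel(kappa=0.05, saturating=True)
        probs = [comp.contest_probability(N, 0.2) for N in (1, 10, 100, 1000)]
        assert probs[0] == 0.0
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[-1] <= 1.0
        # contests also intensify with richness at fixed N
        assert comp.contest_probability(100, 0.4) > comp.contest_probability(100, 0.1)


class TestLifetimeSimulation:
    def test_no_access_starves(self, env, policy_set):
        acc = dp.AccessProbabilities(p_auto=0.0, p_ctrl=0.0)
        mean_E = dp.simulate_lifetime(0.0, acc, env, policy_set, 200, 0)
        assert mean_E == 0.0

    def test_guaranteed_access_saturates(self, env, policy_set):
        acc = dp.AccessProbabilities(p_auto=1.0, p_ctrl=1.0)
        mean_E = dp.simulate_lifetime(0.0, acc, env, policy_set, 1000, 0)
        assert mean_E > env.E_max - 10.0 * env.drain

    def test_controlled_beats_automatic_when_scarce(self, env, policy_set):
        """Flexible consumption yields higher, steadier energy at matched
        access — the core advantage of controlled processing in isolation."""
        n, steps, p = 100, 1000, 0.02
        rng = np.random.default_rng(3)
        mean_E, var_E = dp.simulate_lifetimes_batch(
            np.repeat([0.0, 1.0], n), p, p, env, policy_set, steps, rng
        )
        auto_m, ctrl_m = mean_E[:n], mean_E[n:]
        gap = ctrl_m.mean() - auto_m.mean()
        se = np.sqrt(auto_m.var() / n + ctrl_m.var() / n)
        assert gap > 3.0 * se
        assert var_E[n:].mean() < var_E[:n].mean()

    def test_determinism_given_seed(self, env, policy_set):
        acc = dp.AccessProbabilities(p_auto=0.02, p_ctrl=0.01)
        a = dp.simulate_lifetime(0.5, acc, env, policy_set, 300, 42)
        b = dp.simulate_lifetime(0.5, acc, env, policy_set, 300, 42)
        assert a == b


class TestFitnessTable:
    def test_empty_axes_rejected(self, env, policy_set):
        with pytest.raises(ValueError):
            dp.build_fitness_table(env, policy_set, c_levels=[], n_sims=10, steps=10)

    def test_starvation_cell_and_access_monotonicity(self, env, policy_set):
        table = dp.build_fitness_table(
            env, policy_set,
            c_levels=[0.0, 1.0],
            p_levels=[0.0, 0.02, 0.125],
            n_sims=3600, steps=400, seed=9,
        )
        assert table.values[0, 0, 0] == 0.0  # no access, no energy
        # more automatic access never hurts an automatic agent
        auto_slice = table.values[0, :, 0]
        assert np.all(np.diff(auto_slice) >= -1.0)  # slack for MC noise
        assert auto_slice[-1] > auto_slice[0]

    def test_lookup_exact_at_nodes(self, fitness_table):
        t = fitness_table
        for ic, ia, ip in [(0, 0, 0), (3, 2, 1), (10, 7, 7)]:
            got = dp.lookup_fitness(
                t, t.c_levels[ic], t.p_auto_levels[ia], t.p_ctrl_levels[ip]
            )
            assert got == pytest.approx(t.values[ic, ia, ip], rel=1e-12)

    def test_lookup_midpoint_is_average_along_one_axis(self, fitness_table):
        t = fitness_table
        mid_c = 0.5 * (t.c_levels[2] + t.c_levels[3])
        got = dp.lookup_fitness(t, mid_c, t.p_auto_levels[4], t.p_ctrl_levels[4])
        expected = 0.5 * (t.values[2, 4, 4] + t.values[3, 4, 4])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_interpolation_bounded_by_cell_corners(self, fitness_table):
        t = fitness_table
        rng = np.random.default_rng(0)
        for _ in range(100):
            ic = rng.integers(0, t.c_levels.size - 1)
            ia = rng.integers(0, t.p_auto_levels.size - 1)
            ip = rng.integers(0, t.p_ctrl_levels.size - 1)
            q = [
                rng.uniform(t.c_levels[ic], t.c_levels[ic + 1]),
                rng.uniform(t.p_auto_levels[ia], t.p_auto_levels[ia + 1]),
                rng.uniform(t.p_ctrl_levels[ip], t.p_ctrl_levels[ip + 1]),
            ]
            corners = t.values[ic : ic + 2, ia : ia + 2, ip : ip + 2]
            got = dp.lookup_fitness(t, *q)
            assert corners.min() - 1e-9 <= got <= corners.max() + 1e-9

    def test_query_outside_unit_cube_rejected(self, fitness_table):
        with pytest.raises(ValueError):
            dp.lookup_fitness(fitness_table, 1.2, 0.1, 0.1)
        with pytest.raises(ValueError):
            dp.lookup_fitness(fitness_table, 0.5, -0.1, 0.1)

    def test_csv_round_trip(self, env, policy_set, tmp_path):
        table = dp.build_fitness_table(
            env, policy_set,
            c_levels=[0.0, 0.5, 1.0], p_levels=[0.0, 0.05],
            n_sims=60, steps=50, seed=1,
        )
        path = tmp_path / "table.csv"
        dp.agent_simulation.table_to_csv(table, path)
        back = dp.agent_simulation.table_from_csv(path)
        np.testing.assert_allclose(back.values, table.values)
        np.testing.assert_allclose(back.c_levels, table.c_levels)


class TestEvolvableAutomaticTarget:
    def test_required_consumption_inverts_utility(self, env):
        for E, T in [(0.0, 50.0), (30.0, 60.0)]:
            x = consumption_to_reach(E, T, env)
            assert dp.consume(E, x, env) == pytest.approx(T, rel=1e-10)

    def test_target_already_met_stores_everything(self, env):
        assert consumption_to_reach(80.0, 60.0, env) == 0.0

    def test_ceiling_target_with_pure_automatic_reduces_to_default(
        self, env, policy_set
    ):
        """A C=0 agent whose target is the ceiling consumes everything it
        finds and its store stays empty — the default automatic rule."""
        p = 0.05
        base, _ = dp.simulate_lifetimes_batch(
            np.zeros(50), p, p, env, policy_set, 400,
            np.random.default_rng(8),
        )
        variant, _ = dp.simulate_lifetimes_batch(
            np.zeros(50), p, p, env, policy_set, 400,
            np.random.default_rng(8), target_E=np.full(50, env.E_max),
        )
        np.testing.assert_allclose(variant, base)

    def test_low_target_keeps_energy_near_target(self, env, policy_set):
        """An abundant environment plus a modest target pins energy there."""
        target = 40.0
        _, _, trace = dp.simulate_lifetimes_batch(
            np.zeros(10), 0.9, 0.9, env, policy_set, 500,
            np.random.default_rng(2), target_E=np.full(10, target),
            record=True,
        )
        tail = trace[200:]
        assert abs(tail.mean() - target) < 3.0

    def test_wrapper_dispatch(self, env, policy_set):
        acc = dp.AccessProbabilities(p_auto=0.05, p_ctrl=0.05)
        full = dp.simulate_lifetime_evolvable_auto(
            0.0, dp.AutomaticPolicy(), acc, env, policy_set, 200, 4
        )
        assert full == dp.simulate_lifetime(0.0, acc, env, policy_set, 200, 4)

    def test_target_table_lookup(self, env, policy_set):
        table = dp.build_target_fitness_table(
            env, policy_set,
            target_levels=[0.0, env.E_max],
            c_levels=[0.0, 1.0], p_levels=[0.0, 0.05],
            n_sims=160, steps=100, seed=3,
        )
        got = table.lookup(env.E_max, 0.0, 0.05, 0.05)
        assert got == pytest.approx(table.values[1, 0, 1, 1], rel=1e-12)
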