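import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edlama.atsa import (
    AtsaConfig,
    TabuList,
    init_solution,
    metropolis_accept,
    optimize,
    propose_neighbor,
    random_search,
    tabu_key,
    update_temperature,
)
from edlama.space import ParamSpec, SearchSpace, Solution


# --- initial solution -------------------------------------------------------


def test_init_uniform_over_integer_grid():
    space = SearchSpace((ParamSpec("k", "integer", 1, 50),))
    rng = np.random.default_rng(0)
    draws = [init_solution(space, rng)["k"] for _ in range(2000)]
    assert all(1 <= v <= 50 and v == int(v) for v in draws)
    assert len(set(draws)) > 40  # covers most of the grid


def test_init_uniform_binary_frequency():
    space = SearchSpace((ParamSpec("k", "integer", 1, 2),))
    rng = np.random.default_rng(1)
    n = 10_000
    draws = np.array([init_solution(space, rng)["k"] for _ in range(n)])
    freq = (draws == 1).mean()
    sigma = math.sqrt(0.25 / n)
    assert abs(freq - 0.5) <= 3 * sigma


def test_init_uniform_float_mean():
    space = SearchSpace((ParamSpec("x", "float", 0.0, 1.0, positive=True),))
    rng = np.random.default_rng(2)
    n = 10_000
    draws = np.array([init_solution(space, rng)["x"] for _ in range(n)])
    assert (draws > 0).all() and (draws <= 1).all()
    sigma = 1 / math.sqrt(12 * n)
    assert abs(draws.mean() - 0.5) <= 3 * sigma


# --- neighborhood moves -----------------------------------------------------


def test_zero_step_returns_same_point(float_axis):
    cfg = AtsaConfig(step_scale=0.0)
    rng = np.random.default_rng(0)
    sol = Solution({"x": 4.2})
    for _ in range(5):
        assert propose_neighbor(sol, float_axis, cfg, rng)["x"] == 4.2


def test_clipping_at_upper_bound(float_axis):
    cfg = AtsaConfig(step_scale=10.0)  # huge steps
    rng = np.random.default_rng(3)
    sol = Solution({"x": 10.0})
    out = [propose_neighbor(sol, float_axis, cfg, rng)["x"] for _ in range(200)]
    assert max(out) <= 10.0 and min(out) >= 0.0
    assert 10.0 in out  # positive draws pinned at the bound


def test_neighbor_moments_match_scaled_normal():
    # wide axis, center far from bounds -> clipping negligible
    space = SearchSpace((ParamSpec("x", "float", 0.0, 100.0),))
    cfg = AtsaConfig(step_scale=0.1)  # step sd = 10
    rng = np.random.default_rng(4)
    sol = Solution({"x": 50.0})
    n = 10_000
    disp = np.array(
        [propose_neighbor(sol, space, cfg, rng)["x"] - 50.0 for _ in range(n)]
    )
    assert abs(disp.mean()) <= 3 * 10 / math.sqrt(n)
    assert abs(disp.std() - 10.0) / 10.0 <= 0.05


def test_integer_axis_neighbors_stay_on_grid(two_int_axes):
    cfg = AtsaConfig(step_scale=0.3)
    rng = np.random.default_rng(5)
    sol = Solution({"a": 3, "b": 1})
    for _ in range(300):
        nb = propose_neighbor(sol, two_int_axes, cfg, rng)
        two_int_axes.validate(nb)


# --- metropolis rule --------------------------------------------------------


def test_accepts_all_improvements_and_zero_delta():
    rng = np.random.default_rng(0)
    assert all(metropolis_accept(0.0, t, rng) for t in (0.01, 1, 100))
    assert all(metropolis_accept(5.0, t, rng) for t in (0.01, 1, 100))


def test_nonpositive_temperature_rejected():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        metropolis_accept(-1.0, 0.0, rng)


def test_acceptance_rate_monotone_in_delta_and_temperature():
    rng = np.random.default_rng(6)
    n = 4000

    def rate(delta, T):
        r = np.random.default_rng(123)
        return np.mean([metropolis_accept(delta, T, r) for _ in range(n)])

    rates_delta = [rate(d, 2.0) for d in (-0.5, -2.0, -8.0)]
    assert rates_delta[0] > rates_delta[1] > rates_delta[2]
    rates_T = [rate(-2.0, T) for T in (0.5, 2.0, 8.0)]
    assert rates_T[0] < rates_T[1] < rates_T[2]


# --- adaptive temperature control -------------------------------------------


def test_cooling_on_improvement():
    cfg = AtsaConfig(alpha=0.9, t_min=2.0, t_init=100.0)
    T, stall = update_temperature(10.0, 5, True, cfg)
    assert T == pytest.approx(9.0)
    assert stall == 0


def test_floor_clamp_at_t_min():
    cfg = AtsaConfig(alpha=0.9, t_min=2.0)
    T, stall = update_temperature(2.0, 0, False, cfg)
    assert T == 2.0
    assert stall == 1


def test_reheat_after_stall_threshold():
    cfg = AtsaConfig(beta=2.0, stall_reheat=10, t_init=100.0)
    T, stall = update_temperature(4.0, 9, False, cfg)
    assert T == 8.0
    assert stall == 0


def test_reheat_capped_at_t_init():
    cfg = AtsaConfig(beta=2.0, stall_reheat=10, t_init=100.0)
    T, _ = update_temperature(80.0, 9, False, cfg)
    assert T == 100.0


# --- tabu list + keys -------------------------------------------------------


def test_tabu_key_quantization(float_axis):
    a = Solution({"x": 5.0})
    b = Solution({"x": 5.0 + 0.004})  # < half of a 0.01 grid step
    c = Solution({"x": 5.01})
    assert tabu_key(a, float_axis) == tabu_key(a, float_axis)
    assert tabu_key(a, float_axis) == tabu_key(b, float_axis)
    assert tabu_key(a, float_axis) != tabu_key(c, float_axis)


def test_tabu_key_integer_exact(two_int_axes):
    assert tabu_key(Solution({"a": 2, "b": 3}), two_int_axes) != tabu_key(
        Solution({"a": 2, "b": 4}), two_int_axes
    )


@given(st.lists(st.integers(0, 30), min_size=1, max_size=200))
def test_tabu_fifo_eviction(keys):
    tabu = TabuList(capacity=5)
    pushed = []
    for k in keys:
        tabu.push(k)
        pushed.append(k)
        assert len(tabu) <= 5
        assert tabu.entries == tuple(pushed[-5:])


# --- full optimizer ---------------------------------------------------------


def _table5_config(seed, **overrides):
    base = dict(
        t_min=2.0, t_init=100.0, beta=2.0, alpha=0.95, tabu_length=20,
        n_iterations=300, n_moves=8, stall_reheat=10, step_scale=0.1, seed=seed,
    )
    base.update(overrides)
    return AtsaConfig(**base)


def test_constant_objective(float_axis):
    res = optimize(lambda s: 7.5, float_axis, _table5_config(0, n_iterations=20))
    assert res.best_value == 7.5


def test_trace_monotone_and_temperature_bounds(float_axis):
    res = optimize(lambda s: -((s["x"] - 3) ** 2), float_axis, _table5_config(1))
    best = res.best_values
    assert (np.diff(best) >= 0).all()
    temps = np.array([r.temperature for r in res.trace])
    assert (temps >= 2.0 - 1e-12).all()
    assert (temps <= 100.0 + 1e-12).all()
    assert res.tabu_max_len <= 20


def test_determinism(float_axis):
    cfg = _table5_config(7, n_iterations=50)
    r1 = optimize(lambda s: math.sin(s["x"]), float_axis, cfg)
    r2 = optimize(lambda s: math.sin(s["x"]), float_axis, cfg)
    assert r1.best.values == r2.best.values
    assert r1.trace == r2.trace


def test_objective_errors_annotated(float_axis):
    from edlama.atsa import ObjectiveError

    def bad(sol):
        raise RuntimeError("boom")

    with pytest.raises(ObjectiveError) as err:
        optimize(bad, float_axis, _table5_config(0, n_iterations=2))
    assert isinstance(err.value.solution, Solution)


def test_hill_climbing_limit_accepts_no_worsening_moves(float_axis):
    """As T -> 0+ the Metropolis rule degenerates to hill climbing."""
    cfg = _table5_config(3, t_min=1e-12, t_init=1e-12, n_iterations=100)
    res = optimize(lambda s: math.sin(3 * s["x"]) + 0.1 * s["x"], float_axis, cfg)
    prev_current = res.trace[0].current_value
    worse_accepted = 0
    for rec in res.trace[1:]:
        if rec.accepted and rec.candidate_value < prev_current:
            worse_accepted += 1
        prev_current = rec.current_value
    assert worse_accepted == 0


def test_beats_or_matches_random_search_on_multimodal(float_axis):
    def f(sol):
        x = sol["x"]
        return math.sin(5 * x) - 0.1 * (x - 6) ** 2

    res = optimize(f, float_axis, _table5_config(11))
    _, rs_val = random_search(f, float_axis, n=res.n_evaluations, seed=11)
    assert res.best_value >= rs_val - 0.05
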