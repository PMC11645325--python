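"""Adaptive tabu simulated annealing over mixed integer/float bounded spaces.

The optimizer maximizes an arbitrary black-box objective.  It combines three
strategies: Metropolis acceptance of worsening moves (probability
``exp(delta/T)``), an adaptive temperature schedule that geometrically cools
after each level but *reheats* (multiplies T by ``beta``, capped at the initial
temperature) after a run of non-improving levels, and a fixed-capacity FIFO
tabu list of recently evaluated solutions that the search refuses to revisit.

The search runs ``n_iterations`` temperature levels; at each level up to
``n_moves`` candidate neighbors of the current solution are generated by
Gaussian perturbation, evaluated, recorded in the tabu list, and accepted or
rejected by the Metropolis rule.  The best solution ever evaluated is tracked
separately from the current one and only replaced on strict improvement.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .space import ParamSpec, SearchSpace, Solution

__all__ = [
    "AtsaConfig",
    "AtsaResult",
    "TabuList",
    "TraceRecord",
    "ObjectiveError",
    "init_solution",
    "propose_neighbor",
    "metropolis_accept",
    "update_temperature",
    "tabu_key",
    "optimize",
    "random_search",
    "trace_to_csv",
]


@dataclass(frozen=True)
class AtsaConfig:
    """Annealer settings.

    ``t_min=2``, ``beta=2``, ``tabu_length=20``, ``n_iterations=300`` and
    ``n_moves=8`` are the published experimental settings; the cooling factor
    ``alpha``, initial temperature ``t_init``, reheat stall threshold and the
    per-axis step scale are this package's documented gap-fills (see
    docs/methods.md).
    """

    t_min: float = 2.0
    t_init: float = 100.0
    beta: float = 2.0
    alpha: float = 0.95
    tabu_length: int = 20
    n_iterations: int = 300
    n_moves: int = 8
    stall_reheat: int = 10
    step_scale: float = 0.1
    seed: int = 0
    tabu_retries: int = 5
    quantize: int = 1000

    def __post_init__(self) -> None:
        if self.t_min <= 0 or self.t_init <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_init < self.t_min:
            raise ValueError("t_init must be >= t_min")
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("tabu_length", "n_iterations", "n_moves", "stall_reheat"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def to_dict(self) -> dict:
        return {
            "t_min": self.t_min,
            "t_init": self.t_init,
            "beta": self.beta,
            "alpha": self.alpha,
            "tabu_length": self.tabu_length,
            "n_iterations": self.n_iterations,
            "n_moves": self.n_moves,
            "stall_reheat": self.stall_reheat,
            "step_scale": self.step_scale,
            "seed": self.seed,
        }


class TabuList:
    """Fixed-capacity FIFO memory of solution keys.

    When full, each push evicts exactly the oldest entry (insertion order).
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._entries: deque = deque()

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key) -> bool:
        return key in self._entries

    @property
    def entries(self) -> tuple:
        return tuple(self._entries)

    def push(self, key) -> None:
        if len(self._entries) >= self.capacity:
            self._entries.popleft()
        self._entries.append(key)


class ObjectiveError(RuntimeError):
    """Raised when the black-box objective fails; carries the offending solution."""

    def __init__(self, solution: Solution, cause: BaseException):
        super().__init__(f"objective failed at {solution}: {cause}")
        self.solution = solution
        self.cause = cause


def init_solution(space: SearchSpace, rng: np.random.Generator) -> Solution:
    """Draw a starting point uniformly over every axis.

    Integer axes are drawn uniformly over their integer grid; float axes
    uniformly over their interval (kept strictly above an open lower bound).
    """
    values = {}
    for s in space:
        if s.kind == "integer":
            values[s.name] = float(rng.integers(int(s.lower), int(s.upper) + 1))
        else:
            values[s.name] = s.clip(float(rng.uniform(s.lower, s.upper)))
    return Solution(values)


def propose_neighbor(
    sol: Solution, space: SearchSpace, config: AtsaConfig, rng: np.random.Generator
) -> Solution:
    """Perturb every axis by a standard-normal draw scaled to the axis range.

    The raw move is ``N(0, 1) * step_scale * (upper - lower)``; results are
    clipped to bounds and integer axes rounded half-away-from-zero.  Setting
    ``step_scale = 1/range`` on an axis-by-axis basis recovers the literal
    unit-variance rule.
    """
    values = {}
    for s in space:
        step = float(rng.normal()) * config.step_scale * s.width
        values[s.name] = s.clip(sol[s.name] + step)
    return Solution(values)


def metropolis_accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept a candidate whose objective differs from the current by ``delta``.

    Improvements (``delta >= 0``, maximization) are always accepted; worsening
    moves are accepted with probability ``exp(delta / temperature)``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta >= 0:
        return True
    return float(rng.random()) < math.exp(delta / temperature)


def update_temperature(
    temperature: float, stall_count: int, improved: bool, config: AtsaConfig
) -> tuple[float, int]:
    """Adaptive cool-or-reheat step; returns ``(new_temperature, new_stall_count)``.

    A level that produced a new best cools geometrically and resets the stall
    counter.  After ``stall_reheat`` consecutive non-improving levels the
    temperature is reheated by ``beta`` (capped at ``t_init``); otherwise it
    cools geometrically with a floor at ``t_min``.
    """
    if improved:
        return max(config.alpha * temperature, config.t_min), 0
    if stall_count + 1 >= config.stall_reheat:
        return min(config.beta * temperature, config.t_init), 0
    return max(config.alpha * temperature, config.t_min), stall_count + 1


def tabu_key(sol: Solution, space: SearchSpace, quantize: int = 1000) -> tuple:
    """Deterministic hashable key identifying a solution for tabu membership.

    Integer axes compare exactly; float axes are quantized to ``1/quantize`` of
    their range so that near-identical continuous points collide (exact float
    equality would make the tabu list vacuous).
    """
    key = []
    for s in space:
        v = sol[s.name]
        if s.kind == "integer":
            key.append(int(v))
        else:
            key.append(int(round((v - s.lower) / s.width * quantize)))
    return tuple(key)


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    temperature: float
    candidate_value: float
    best_value: float
    accepted: bool
    current_value: float


@dataclass
class AtsaResult:
    best: Solution
    best_value: float
    trace: list[TraceRecord] = field(default_factory=list)
    n_evaluations: int = 0
    tabu_max_len: int = 0
    final_temperature: float = float("nan")

    @property
    def best_values(self) -> np.ndarray:
        return np.array([r.best_value for r in self.trace])


def optimize(
    objective: Callable[[Solution], float],
    space: SearchSpace,
    config: AtsaConfig,
    callback: Optional[Callable[[int, AtsaResult], None]] = None,
) -> AtsaResult:
    """Run the annealer; fully reproducible for a fixed ``config.seed``.

    The initial solution is evaluated first and seeds both the current and the
    best solution.  At each temperature level up to ``n_moves`` neighbors are
    proposed; a tabu candidate is regenerated up to ``tabu_retries`` times and
    the move skipped if all regenerations are tabu (the refused key is still
    recorded, aging the list).  Every evaluated candidate is pushed onto the
    tabu list.  The best solution is replaced only on strict improvement, so
    ties keep the earlier solution.
    """
    rng = np.random.default_rng(config.seed)
    tabu = TabuList(config.tabu_length)

    def _eval(sol: Solution) -> float:
        try:
            return float(objective(sol))
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise ObjectiveError(sol, exc) from exc

    current = init_solution(space, rng)
    current_value = _eval(current)
    best, best_value = current, current_value
    tabu.push(tabu_key(current, space, config.quantize))

    result = AtsaResult(best=best, best_value=best_value)
    result.n_evaluations = 1
    result.tabu_max_len = len(tabu)
    temperature = config.t_init
    stall = 0

    result.trace.append(
        TraceRecord(0, temperature, current_value, best_value, True, current_value)
    )

    for it in range(1, config.n_iterations + 1):
        improved = False
        for _ in range(config.n_moves):
            cand = propose_neighbor(current, space, config, rng)
            key = tabu_key(cand, space, config.quantize)
            retries = 0
            while key in tabu and retries < config.tabu_retries:
                cand = propose_neighbor(current, space, config, rng)
                key = tabu_key(cand, space, config.quantize)
                retries += 1
            if key in tabu:
                # Skip the move, but still note the refused proposal so the
                # FIFO ages: on spaces smaller than the tabu capacity the
                # search would otherwise freeze once every reachable neighbor
                # is remembered, with no evaluation left to evict anything.
                tabu.push(key)
                continue
            value = _eval(cand)
            result.n_evaluations += 1
            tabu.push(key)
            result.tabu_max_len = max(result.tabu_max_len, len(tabu))
            if value > best_value:
                best, best_value = cand, value
                improved = True
            accepted = metropolis_accept(value - current_value, temperature, rng)
            if accepted:
                current, current_value = cand, value
            result.trace.append(
                TraceRecord(it, temperature, value, best_value, accepted, current_value)
            )
        temperature, stall = update_temperature(temperature, stall, improved, config)
        result.best, result.best_value = best, best_value
        if callback is not None:
            callback(it, result)

    result.best, result.best_value = best, best_value
    result.final_temperature = temperature
    return result


def random_search(
    objective: Callable[[Solution], float],
    space: SearchSpace,
    n: int,
    seed: int = 0,
) -> tuple[Solution, float]:
    """Uniform random-search baseline used for comparison in tests."""
    rng = np.random.default_rng(seed)
    best: Optional[Solution] = None
    best_value = -math.inf
    for _ in range(n):
        sol = init_solution(space, rng)
        value = float(objective(sol))
        if value > best_value:
            best, best_value = sol, value
    assert best is not None
    return best, best_value


def trace_to_csv(trace: Sequence[TraceRecord], path) -> None:
    """Write a convergence trace (iteration, temperature, candidate, best)."""
    import pandas as pd

    pd.DataFrame(
        {
            "iteration": [r.iteration for r in trace],
            "temperature": [r.temperature for r in trace],
            "candidate_value": [r.candidate_value for r in trace],
            "best_value": [r.best_value for r in trace],
            "accepted": [r.accepted for r in trace],
            "current_value": [r.current_value for r in trace],
        }
    ).to_csv(path, index=False)
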