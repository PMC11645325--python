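"""Typed bounded hyperparameter axes and solutions.

A :class:`SearchSpace` is an ordered collection of :class:`ParamSpec` axes, each
either integer- or float-valued with inclusive bounds.  Float axes may be
declared *positive*, meaning the interval is open at the lower end (e.g. a
learning rate on ``(0, 1]``); sampling and clipping then stay a hair above the
lower bound.  A :class:`Solution` is one point in the space — the unit the
annealer moves, the tabu list remembers, and the objective scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = ["ParamSpec", "SearchSpace", "Solution", "default_xgb_space"]

# Relative margin kept above an open lower bound.
_OPEN_EPS = 1e-9


@dataclass(frozen=True)
class ParamSpec:
    """One bounded hyperparameter axis.

    Parameters
    ----------
    name : str
        Unique identifier of the axis.
    kind : {"integer", "float"}
        Value type.  Integer axes live on the integer grid of ``[lower, upper]``.
    lower, upper : float
        Bounds. ``lower < upper``; integer axes must have integral bounds.
    positive : bool
        For float axes only: the interval is open at ``lower`` (values are kept
        strictly above it), closed at ``upper``.
    """

    name: str
    kind: str
    lower: float
    upper: float
    positive: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "float"):
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: need lower < upper, got [{self.lower}, {self.upper}]")
        if self.kind == "integer":
            if self.lower != int(self.lower) or self.upper != int(self.upper):
                raise ValueError(f"{self.name}: integer axis needs integer bounds")
            if self.positive:
                raise ValueError(f"{self.name}: 'positive' applies to float axes only")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        if self.kind == "integer":
            return value == int(value) and self.lower <= value <= self.upper
        if self.positive:
            return self.lower < value <= self.upper
        return self.lower <= value <= self.upper

    def clip(self, value: float) -> float:
        """Clip ``value`` into the axis; integer axes also round.

        Rounding is half-away-from-zero so that perturbations are not biased
        toward even integers (banker's rounding) and stay deterministic.
        """
        if self.kind == "integer":
            import math

            rounded = math.floor(abs(value) + 0.5)
            value = float(rounded if value >= 0 else -rounded)
            return float(min(max(value, self.lower), self.upper))
        lo = self.lower + _OPEN_EPS * self.width if self.positive else self.lower
        return float(min(max(value, lo), self.upper))

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "lower": self.lower, "upper": self.upper}
        if self.positive:
            d["positive"] = True
        return d


@dataclass(frozen=True)
class SearchSpace:
    """Ordered, uniquely named collection of axes."""

    specs: tuple[ParamSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("search space must contain at least one axis")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("axis names must be unique")
        object.__setattr__(self, "specs", tuple(self.specs))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def __iter__(self) -> Iterator[ParamSpec]:
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def spec(self, name: str) -> ParamSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def validate(self, solution: "Solution") -> None:
        """Raise ``ValueError`` if ``solution`` does not satisfy the space."""
        if set(solution.values) != set(self.names):
            raise ValueError(
                f"solution axes {sorted(solution.values)} != space axes {sorted(self.names)}"
            )
        for s in self.specs:
            v = solution.values[s.name]
            if not s.contains(v):
                raise ValueError(f"{s.name}={v} outside {s.kind} axis [{s.lower}, {s.upper}]")

    def to_dict(self) -> dict:
        return {"axes": [s.to_dict() for s in self.specs]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SearchSpace":
        return cls(tuple(ParamSpec(**a) for a in d["axes"]))


@dataclass(frozen=True)
class Solution:
    """A point in a search space: one value per axis."""

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **updates: float) -> "Solution":
        new = dict(self.values)
        new.update(updates)
        return Solution(new)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v:g}" for k, v in self.values.items())
        return f"Solution({inner})"


def default_xgb_space() -> SearchSpace:
    """The eight tuned XGBoost axes with their experimental ranges.

    Four integer axes on [1, 50] (number of boosting rounds, maximum tree
    depth, maximum delta step, number of parallel trees per round) and four
    float axes: learning rate, L1 and L2 regularization on (0, 1], and the
    minimum-split-loss gamma on (0, 50].
    """
    return SearchSpace(
        (
            ParamSpec("n_estimators", "integer", 1, 50),
            ParamSpec("max_depth", "integer", 1, 50),
            ParamSpec("max_delta_step", "integer", 1, 50),
            ParamSpec("num_parallel_tree", "integer", 1, 50),
            ParamSpec("learning_rate", "float", 0.0, 1.0, positive=True),
            ParamSpec("reg_alpha", "float", 0.0, 1.0, positive=True),
            ParamSpec("reg_lambda", "float", 0.0, 1.0, positive=True),
            ParamSpec("gamma", "float", 0.0, 50.0, positive=True),
        )
    )
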