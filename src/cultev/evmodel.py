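"""Expected-value arithmetic for cultivation bets.

The central quantity is the expectation of a single cultivation attempt,

    EV = i * cP - e * (1 - cP)

where ``i`` is the (monetary) value of the isolate sought, ``cP`` its
cultivation probability, and ``e`` the cost of the experiment.  A project
recovering ``x`` isolates amortizes its cost across them: each isolate is
charged ``e / x``, and the project expectation is the sum of the per-isolate
expectations.  Break-even solvers invert these formulas for the cost (or
isolate value) at which the expectation crosses zero.

Costs are stored as positive magnitudes and applied with a negative sign
inside the expectation; currency is an abstract nonnegative real.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import EmptyProjectError, UnboundedBreakEvenError, ValidationError

__all__ = [
    "CultivationProbability",
    "IsolateCategory",
    "ProjectScenario",
    "EVResult",
    "as_cp",
    "ev_single",
    "ev_project",
    "breakeven_cost",
    "breakeven_value",
    "breakeven_project_cost",
    "largest_positive_thousand",
    "round_to_hundred",
    "classify_ev",
]


def _require_finite_nonneg(x: float, name: str) -> float:
    x = float(x)
    if not math.isfinite(x) or x < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {x!r}")
    return x


@dataclass(frozen=True)
class CultivationProbability:
    """A per-taxon cultivation probability with its estimation provenance.

    ``value`` is the probability that one expected occurrence of the taxon in
    a culture well yields a recovered isolate.  When estimated from data,
    ``n_isolates`` and ``expected_occurrences`` record the ratio it came from;
    ``clamped`` flags estimates whose raw ratio exceeded 1.
    """

    value: float
    n_isolates: int | None = None
    expected_occurrences: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        v = float(self.value)
        if not math.isfinite(v) or not (0.0 <= v <= 1.0):
            raise ValidationError(f"cultivation probability must lie in [0, 1], got {v!r}")
        object.__setattr__(self, "value", v)


def as_cp(cp: CultivationProbability | float) -> CultivationProbability:
    """Coerce a bare float into a :class:`CultivationProbability`."""
    if isinstance(cp, CultivationProbability):
        return cp
    return CultivationProbability(float(cp))


@dataclass(frozen=True)
class IsolateCategory:
    """A group of isolates sharing a value ``i`` and cultivation probability."""

    label: str
    value: float
    cp: CultivationProbability | float
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _require_finite_nonneg(self.value, "isolate value"))
        object.__setattr__(self, "cp", as_cp(self.cp))
        if int(self.count) != self.count or self.count < 0:
            raise ValidationError(f"category count must be a nonnegative integer, got {self.count!r}")
        object.__setattr__(self, "count", int(self.count))


@dataclass(frozen=True)
class ProjectScenario:
    """A set of isolate categories plus a total project cost."""

    categories: tuple[IsolateCategory, ...]
    cost: float

    def __init__(self, categories: Iterable[IsolateCategory], cost: float) -> None:
        object.__setattr__(self, "categories", tuple(categories))
        object.__setattr__(self, "cost", _require_finite_nonneg(cost, "project cost"))

    @property
    def total_isolates(self) -> int:
        return sum(c.count for c in self.categories)


@dataclass(frozen=True)
class EVResult:
    """An expectation decomposed into its reward and amortized-cost terms.

    ``value = reward_term - cost_term``; ``per_category`` carries the
    category-summed expectations for project evaluations.
    """

    value: float
    reward_term: float
    cost_term: float
    per_category: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    @property
    def sign(self) -> str:
        return classify_ev(self.value)


def classify_ev(ev: float) -> str:
    """Classify an expectation as ``positive`` or ``non-positive`` (strict at 0)."""
    return "positive" if ev > 0 else "non-positive"


def ev_single(i: float, cp: CultivationProbability | float, e: float) -> EVResult:
    """Expectation of a single cultivation attempt: ``i*cP - e*(1-cP)``."""
    i = _require_finite_nonneg(i, "isolate value")
    e = _require_finite_nonneg(e, "experiment cost")
    p = as_cp(cp).value
    reward = i * p
    cost = e * (1.0 - p)
    return EVResult(value=reward - cost, reward_term=reward, cost_term=cost)


def breakeven_cost(i: float, cp: CultivationProbability | float) -> float:
    """The cost ``e* = i*cP / (1-cP)`` at which the single-attempt EV is zero.

    Raises :class:`UnboundedBreakEvenError` when ``cP = 1`` (the expectation is
    positive at any cost, so no finite break-even exists).
    """
    i = _require_finite_nonneg(i, "isolate value")
    p = as_cp(cp).value
    if p >= 1.0:
        raise UnboundedBreakEvenError("cP = 1: expectation is positive at any cost (no break-even)")
    return i * p / (1.0 - p)


def breakeven_value(e: float, cp: CultivationProbability | float) -> float:
    """The isolate value ``i* = e*(1-cP)/cP`` at which the single-attempt EV is zero."""
    e = _require_finite_nonneg(e, "experiment cost")
    p = as_cp(cp).value
    if p <= 0.0:
        raise UnboundedBreakEvenError("cP = 0: no finite isolate value yields a non-negative expectation")
    return e * (1.0 - p) / p


def ev_project(scenario: ProjectScenario) -> EVResult:
    """Project expectation with the cost amortized across all isolates.

    Each of the ``x`` isolates is charged ``e/x``, so its expectation is
    ``i*cP - (e/x)*(1-cP)`` and the project expectation is the sum over
    isolates.  Categories aggregate isolates sharing ``(i, cP)``.
    """
    x = scenario.total_isolates
    if x < 1:
        raise EmptyProjectError("project expectation is undefined for zero isolates")
    share = scenario.cost / x
    reward = 0.0
    cost = 0.0
    per_cat: list[tuple[str, float]] = []
    for cat in scenario.categories:
        p = cat.cp.value
        r = cat.count * cat.value * p
        c = cat.count * share * (1.0 - p)
        reward += r
        cost += c
        per_cat.append((cat.label, r - c))
    return EVResult(value=reward - cost, reward_term=reward, cost_term=cost, per_category=tuple(per_cat))


def breakeven_project_cost(categories: Sequence[IsolateCategory]) -> float:
    """Project cost ``e* = x * Σ(i*cP) / Σ(1-cP)`` at which the project EV is zero.

    Sums run over individual isolates (categories expanded by count).  Raises
    :class:`UnboundedBreakEvenError` when every isolate has ``cP = 1``.
    """
    cats = [c if isinstance(c, IsolateCategory) else IsolateCategory(*c) for c in categories]
    x = sum(c.count for c in cats)
    if x < 1:
        raise EmptyProjectError("break-even undefined for zero isolates")
    reward = sum(c.count * c.value * c.cp.value for c in cats)
    deficit = sum(c.count * (1.0 - c.cp.value) for c in cats)
    if deficit <= 0.0:
        raise UnboundedBreakEvenError("all cP = 1: project expectation is positive at any cost")
    return x * reward / deficit


def largest_positive_thousand(categories: Sequence[IsolateCategory]) -> int | None:
    """Largest whole-thousand cost strictly below the project break-even.

    Because the project EV is strictly decreasing in cost (when not all
    cP = 1), every cost below the break-even gives a positive expectation.
    Returns ``None`` when no nonnegative whole-thousand lies strictly below it.
    """
    e_star = breakeven_project_cost(categories)
    k = math.floor(e_star / 1000.0)
    if k * 1000.0 >= e_star:
        k -= 1
    return k * 1000 if k >= 0 else None


def round_to_hundred(x: float) -> int:
    """Round to the nearest 100 currency units (half away from zero)."""
    return int(math.floor(x / 100.0 + 0.5)) * 100
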