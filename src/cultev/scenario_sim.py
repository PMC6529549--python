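"""Project-portfolio scenario enumeration.

Holds a grid of isolate categories — each a (value, cultivation probability)
pair — and a fixed project cost, then sweeps isolate-count combinations
across the categories, computing the amortized project expectation for each
and classifying its sign.  The summary bins the positive fraction by total
isolate count and by the ratio of low-value to high-value isolates, the two
axes on which portfolio composition drives the expectation.

The default nine-category grid is a 3x3 cross of isolate values
{10,000; 500,000; 10,000,000} and cultivation probabilities
{0.282; 0.0146; 0.001}, anchored so the highest-value category pairs with
the lowest cP (a $10M isolate at 0.1%), with the project cost fixed at
$100,000.  Only that top category and the cost are canonical; the rest of
the grid is a documented default and fully configurable.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evmodel import IsolateCategory, ProjectScenario, classify_ev, ev_project

__all__ = [
    "CategoryGrid",
    "ScenarioResult",
    "default_grid",
    "enumerate_scenarios",
    "ratio_low_high",
    "summarize_scenarios",
    "results_table",
]

DEFAULT_VALUES = (10_000.0, 500_000.0, 10_000_000.0)
DEFAULT_CPS = (0.282, 0.0146, 0.001)
DEFAULT_COST = 100_000.0
DEFAULT_COUNT_LEVELS = (0, 1, 10, 100)
EXHAUSTIVE_CAP = 10**6


@dataclass(frozen=True)
class CategoryGrid:
    """Isolate categories, allowed counts per category, and the project cost."""

    categories: tuple[tuple[str, float, float], ...]
    count_levels: tuple[int, ...] = DEFAULT_COUNT_LEVELS
    cost: float = DEFAULT_COST
    low_labels: tuple[str, ...] = ()
    high_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError("category grid must contain at least one category")
        if not self.count_levels or any(l < 0 for l in self.count_levels):
            raise ValidationError("count_levels must be nonempty and nonnegative")
        object.__setattr__(self, "count_levels", tuple(sorted(set(int(l) for l in self.count_levels))))
        if set(self.low_labels) & set(self.high_labels):
            raise ValidationError("low_labels and high_labels must be disjoint")
        labels = {c[0] for c in self.categories}
        for lab in (*self.low_labels, *self.high_labels):
            if lab not in labels:
                raise ValidationError(f"unknown category label {lab!r} in ratio axis")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.categories)


def default_grid(
    values: Sequence[float] = DEFAULT_VALUES,
    cps: Sequence[float] = DEFAULT_CPS,
    cost: float = DEFAULT_COST,
    count_levels: Sequence[int] = DEFAULT_COUNT_LEVELS,
) -> CategoryGrid:
    """The default 3x3 value-by-probability grid (nine categories).

    Low/high label sets for the ratio axis default to the minimum-value and
    maximum-value tiers respectively.
    """
    cats = []
    for i in sorted(values):
        for p in sorted(cps, reverse=True):
            cats.append((f"i{int(i)}_cp{p:g}", float(i), float(p)))
    low = tuple(lab for lab, i, _ in cats if i == min(values))
    high = tuple(lab for lab, i, _ in cats if i == max(values))
    return CategoryGrid(
        categories=tuple(cats),
        count_levels=tuple(count_levels),
        cost=float(cost),
        low_labels=low,
        high_labels=high,
    )


@dataclass(frozen=True)
class ScenarioResult:
    """One isolate-count combination with its project expectation and sign."""

    counts: Mapping[str, int]
    total_isolates: int
    low_high_ratio: float | None
    ev: float | None
    sign: str
    undefined: bool = False


def ratio_low_high(counts: Mapping[str, int], grid: CategoryGrid) -> float | None:
    """Ratio of low-value to high-value isolate counts; None when high = 0."""
    labels = set(grid.labels)
    for lab in counts:
        if lab not in labels:
            raise ValidationError(f"unknown category label {lab!r}")
    low = sum(counts.get(lab, 0) for lab in grid.low_labels)
    high = sum(counts.get(lab, 0) for lab in grid.high_labels)
    if high == 0:
        return None
    return low / high


def _evaluate(grid: CategoryGrid, combo: Sequence[int]) -> ScenarioResult:
    counts = dict(zip(grid.labels, (int(c) for c in combo)))
    total = sum(counts.values())
    ratio = ratio_low_high(counts, grid)
    if total == 0:
        return ScenarioResult(
            counts=counts, total_isolates=0, low_high_ratio=ratio,
            ev=None, sign="non-positive", undefined=True,
        )
    cats = [
        IsolateCategory(label=lab, value=i, cp=p, count=counts[lab])
        for (lab, i, p) in grid.categories
        if counts[lab] > 0
    ]
    ev = ev_project(ProjectScenario(cats, grid.cost)).value
    return ScenarioResult(
        counts=counts, total_isolates=total, low_high_ratio=ratio,
        ev=ev, sign=classify_ev(ev),
    )


def enumerate_scenarios(
    grid: CategoryGrid,
    strategy: str = "exhaustive",
    n_samples: int = 10_000,
    seed: int = 0,
    cap: int = EXHAUSTIVE_CAP,
) -> list[ScenarioResult]:
    """Sweep isolate-count combinations and evaluate each project expectation.

    ``exhaustive`` walks the full Cartesian product of count levels across
    categories (refused above ``cap`` combinations); ``sampled`` draws
    ``n_samples`` combinations uniformly from that product with the given
    seed.  Zero-isolate combinations are emitted flagged undefined rather
    than dropped, so enumeration counts stay exact.
    """
    k = len(grid.categories)
    levels = grid.count_levels
    if strategy == "exhaustive":
        n_combos = len(levels) ** k
        if n_combos > cap:
            raise ValidationError(
                f"exhaustive enumeration would evaluate {n_combos} combinations "
                f"(cap {cap}); use strategy='sampled' with n_samples"
            )
        combos: Iterable[Sequence[int]] = itertools.product(levels, repeat=k)
    elif strategy == "sampled":
        if n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(levels), size=(n_samples, k))
        level_arr = np.asarray(levels)
        combos = level_arr[idx]
    else:
        raise ValidationError(f"unknown strategy {strategy!r}; expected exhaustive or sampled")
    return [_evaluate(grid, combo) for combo in combos]


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregate view over enumerated scenarios."""

    n_scenarios: int
    n_positive: int
    fraction_positive: float
    min_ev: float
    max_ev: float
    by_total: pd.DataFrame = field(repr=False)
    by_ratio: pd.DataFrame = field(repr=False)


def results_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """One row per scenario: per-category counts, total, ratio, ev, sign.

    This is the table a scatter of expectation sign against portfolio
    composition is plotted from.
    """
    if not results:
        raise ValidationError("no scenarios to tabulate")
    rows = []
    for r in results:
        row = dict(r.counts)
        row.update(
            total_isolates=r.total_isolates,
            low_high_ratio=math.nan if r.low_high_ratio is None else r.low_high_ratio,
            ev=math.nan if r.ev is None else r.ev,
            sign=r.sign,
            undefined=r.undefined,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_scenarios(
    results: Sequence[ScenarioResult],
    total_bins: Sequence[int] = (1, 10, 100, 1000),
    ratio_bins: Sequence[float] = (0.0, 1.0, 10.0, 100.0),
) -> ScenarioSummary:
    """Fraction of positive expectations, overall and binned by composition."""
    if not results:
        raise ValidationError("no scenarios to summarize")
    table = results_table(results)
    defined = table[~table["undefined"]]
    positive = defined["sign"] == "positive"
    by_total = (
        defined.assign(bin=pd.cut(defined["total_isolates"], [0, *total_bins, np.inf]))
        .groupby("bin", observed=True)["sign"]
        .apply(lambda s: (s == "positive").mean())
        .rename("fraction_positive")
        .reset_index()
    )
    with_ratio = defined[defined["low_high_ratio"].notna()]
    by_ratio = (
        with_ratio.assign(bin=pd.cut(with_ratio["low_high_ratio"], [-0.001, *ratio_bins, np.inf]))
        .groupby("bin", observed=True)["sign"]
        .apply(lambda s: (s == "positive").mean())
        .rename("fraction_positive")
        .reset_index()
    )
    evs = defined["ev"]
    return ScenarioSummary(
        n_scenarios=len(results),
        n_positive=int(positive.sum()),
        fraction_positive=float(positive.sum()) / len(results),
        min_ev=float(evs.min()) if len(evs) else math.nan,
        max_ev=float(evs.max()) if len(evs) else math.nan,
        by_total=by_total,
        by_ratio=by_ratio,
    )
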