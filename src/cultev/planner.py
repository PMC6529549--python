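"""Forward planning for dilution-to-extinction campaigns.

Given a community profile, per-taxon cultivation probabilities, and a plate
design (well count, cells per well), these helpers answer the practical
questions: how many isolates of a taxon should this design yield, how many
wells (or repeat experiments) are needed to hit a target, what does each
isolate cost, and is the design's expectation positive at a given budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cpestimate import TaxonProfile, expected_occurrences
from .errors import (
    EmptyProjectError,
    InfeasibleDesignError,
    UnknownTaxonError,
    ValidationError,
)
from .evmodel import (
    CultivationProbability,
    EVResult,
    IsolateCategory,
    ProjectScenario,
    as_cp,
    ev_project,
)

__all__ = [
    "ExperimentDesign",
    "CostSummary",
    "FeasibilityReport",
    "expected_isolates",
    "wells_needed",
    "experiments_needed",
    "per_isolate_cost",
    "design_feasibility",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """A plate layout plus the community it is inoculated from.

    ``cells_per_well`` is the dilution target (the Poisson mean under
    stochastic loading); ``growth_probs`` maps taxon ids to their cultivation
    probabilities.
    """

    n_wells: int
    cells_per_well: float
    community: tuple[TaxonProfile, ...]
    growth_probs: dict[str, CultivationProbability] = field(default_factory=dict)

    def __init__(
        self,
        n_wells: int,
        cells_per_well: float,
        community,
        growth_probs=None,
    ) -> None:
        if n_wells < 1 or int(n_wells) != n_wells:
            raise ValidationError(f"n_wells must be a positive integer, got {n_wells!r}")
        if not (cells_per_well > 0 and math.isfinite(cells_per_well)):
            raise ValidationError(f"cells_per_well must be > 0, got {cells_per_well!r}")
        community = tuple(community)
        total = sum(t.relative_abundance for t in community)
        if total > 1.0 + 1e-6:
            raise ValidationError(f"community abundances sum to {total:.6f} > 1")
        object.__setattr__(self, "n_wells", int(n_wells))
        object.__setattr__(self, "cells_per_well", float(cells_per_well))
        object.__setattr__(self, "community", community)
        object.__setattr__(
            self, "growth_probs", {t: as_cp(p) for t, p in (growth_probs or {}).items()}
        )

    def abundance_of(self, taxon_id: str) -> float:
        for t in self.community:
            if t.taxon_id == taxon_id:
                return t.relative_abundance
        raise UnknownTaxonError(f"taxon {taxon_id!r} not in community profile")

    def cp_of(self, taxon_id: str) -> CultivationProbability:
        try:
            return self.growth_probs[taxon_id]
        except KeyError:
            raise UnknownTaxonError(f"no cultivation probability for taxon {taxon_id!r}") from None


@dataclass(frozen=True)
class CostSummary:
    """A budget amortized over the isolates it produced."""

    budget: float
    n_isolates: int
    per_isolate: float

    @property
    def per_isolate_rounded(self) -> int:
        return int(math.floor(self.per_isolate / 100.0 + 0.5)) * 100


def expected_isolates(
    design: ExperimentDesign, taxon_id: str, mode: str = "nominal"
) -> float:
    """Expected isolate count for one taxon: expected occurrences x cP."""
    occ = expected_occurrences(
        design.n_wells, design.abundance_of(taxon_id), design.cells_per_well, mode
    )
    return occ * design.cp_of(taxon_id).value


def wells_needed(
    target_expected: float,
    abundance: float,
    cp: CultivationProbability | float,
    cells_per_well: float = 1.0,
    mode: str = "nominal",
) -> int:
    """Smallest well count whose expected isolate yield reaches the target."""
    if target_expected <= 0:
        raise ValidationError(f"target_expected must be > 0, got {target_expected!r}")
    p = as_cp(cp).value
    if abundance <= 0 or p <= 0:
        raise InfeasibleDesignError(
            "expected yield per well is zero (abundance or cP is 0); no well count suffices"
        )
    if mode == "nominal":
        per_well = abundance * cells_per_well * p
    elif mode == "poisson":
        per_well = -math.expm1(-cells_per_well * abundance) * p
    else:
        raise ValidationError(f"unknown occupancy mode {mode!r}")
    n = math.ceil(target_expected / per_well)
    # guard against float edge cases around the ceiling boundary
    while n * per_well < target_expected:
        n += 1
    while n > 1 and (n - 1) * per_well >= target_expected:
        n -= 1
    return n


def experiments_needed(per_experiment_expected: float, success_prob: float = 0.99) -> int:
    """Experiments needed for >= success_prob chance of at least one isolate.

    Total isolate count across ``k`` experiments is modeled as Poisson with
    mean ``k * mu``, so the requirement is ``1 - exp(-k*mu) >= success_prob``.
    This makes the informal "run several to hedge" rule quantitative.
    """
    if not (per_experiment_expected > 0):
        raise ValidationError("per_experiment_expected must be > 0")
    if not (0.0 < success_prob < 1.0):
        raise ValidationError(f"success_prob must lie in (0, 1), got {success_prob!r}")
    k = math.ceil(-math.log(1.0 - success_prob) / per_experiment_expected)
    return max(1, k)


def per_isolate_cost(budget: float, n_isolates: int) -> CostSummary:
    """Amortize a project budget across its isolates."""
    if budget < 0 or not math.isfinite(budget):
        raise ValidationError(f"budget must be finite and >= 0, got {budget!r}")
    if n_isolates < 1 or int(n_isolates) != n_isolates:
        raise EmptyProjectError("per-isolate cost undefined for zero isolates")
    return CostSummary(budget=float(budget), n_isolates=int(n_isolates), per_isolate=budget / n_isolates)


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of a design-level expectation check.

    ``ev`` is the project expectation over the taxa the design is expected to
    actually recover (expected counts rounded to nearest integer; taxa
    rounding to zero are listed in ``excluded`` and carry no expectation).
    """

    ev: EVResult
    scenario: ProjectScenario
    excluded: tuple[str, ...]
    fractional: bool = False


def design_feasibility(
    design: ExperimentDesign,
    values: dict[str, float],
    e: float,
    mode: str = "nominal",
    fractional: bool = False,
) -> FeasibilityReport:
    """Evaluate whether a design's expectation is positive at budget ``e``.

    Builds a project scenario whose per-taxon isolate counts are the rounded
    expected yields of the design, then amortizes ``e`` across them.  With
    ``fractional=True`` the unrounded expected counts enter the sums directly
    (no taxon is excluded unless its expectation is exactly zero).
    """
    yields: list[tuple[str, float]] = []
    excluded: list[str] = []
    for taxon in design.community:
        tid = taxon.taxon_id
        if tid not in values:
            continue
        mu = expected_isolates(design, tid, mode)
        n = mu if fractional else round(mu)
        if n <= 0:
            excluded.append(tid)
        else:
            yields.append((tid, n))
    if not yields:
        raise EmptyProjectError(
            "no taxon has an expected isolate count above zero under this design; "
            f"excluded: {', '.join(excluded) or '(none valued)'}"
        )
    if fractional:
        x = sum(n for _, n in yields)
        share = e / x
        reward = cost = 0.0
        per_cat = []
        for tid, n in yields:
            p = design.cp_of(tid).value
            r = n * values[tid] * p
            c = n * share * (1.0 - p)
            reward += r
            cost += c
            per_cat.append((tid, r - c))
        ev = EVResult(value=reward - cost, reward_term=reward, cost_term=cost, per_category=tuple(per_cat))
        cats = [
            IsolateCategory(label=tid, value=values[tid], cp=design.cp_of(tid), count=max(1, round(n)))
            for tid, n in yields
        ]
        scenario = ProjectScenario(cats, e)
    else:
        cats = [
            IsolateCategory(label=tid, value=values[tid], cp=design.cp_of(tid), count=int(n))
            for tid, n in yields
        ]
        scenario = ProjectScenario(cats, e)
        ev = ev_project(scenario)
    return FeasibilityReport(ev=ev, scenario=scenario, excluded=tuple(excluded), fractional=fractional)
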