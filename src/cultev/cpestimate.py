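"""Cultivation-probability estimation from campaign outcomes.

A taxon's cultivation probability cP is estimated by comparing how often it
was actually isolated with how often it is expected to have occurred in the
culture wells, given its relative abundance in the source community:

    cP = n_isolates / expected_occurrences

Expected occurrences come from an occupancy model.  The ``nominal`` model is
plain proportional arithmetic (wells x abundance x cells-per-well), matching
the back-of-envelope planning style this framework formalizes; the
``poisson`` model instead counts wells expected to contain at least one cell
of the taxon under Poisson loading, ``n_wells * (1 - exp(-lambda * a))``,
which corrects for multiple cells landing in one well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateDenominatorError, ValidationError
from .evmodel import CultivationProbability

__all__ = [
    "TaxonProfile",
    "CultivationRecord",
    "estimate_cp",
    "expected_occurrences",
    "cp_interval",
    "pool_records",
    "OCCUPANCY_MODES",
]

OCCUPANCY_MODES = ("nominal", "poisson")


@dataclass(frozen=True)
class TaxonProfile:
    """A taxon and its relative abundance in the source community."""

    taxon_id: str
    relative_abundance: float

    def __post_init__(self) -> None:
        a = float(self.relative_abundance)
        if not math.isfinite(a) or not (0.0 <= a <= 1.0):
            raise ValidationError(
                f"relative abundance of {self.taxon_id!r} must lie in [0, 1], got {a!r}"
            )
        object.__setattr__(self, "relative_abundance", a)


@dataclass(frozen=True)
class CultivationRecord:
    """Observed isolate count versus expected well occurrences for one taxon."""

    taxon_id: str
    n_isolates: int
    expected_occurrences: float

    def __post_init__(self) -> None:
        if int(self.n_isolates) != self.n_isolates or self.n_isolates < 0:
            raise ValidationError(f"n_isolates must be a nonnegative integer, got {self.n_isolates!r}")
        object.__setattr__(self, "n_isolates", int(self.n_isolates))
        occ = float(self.expected_occurrences)
        if not math.isfinite(occ) or occ <= 0:
            raise ValidationError(f"expected_occurrences must be > 0, got {occ!r}")
        object.__setattr__(self, "expected_occurrences", occ)


def estimate_cp(record: CultivationRecord) -> CultivationProbability:
    """Point estimate cP = n_isolates / expected_occurrences, clamped to 1.

    Raw ratios above 1 can occur when the taxon's abundance (hence its
    expected occurrences) is underestimated; they are clamped to 1 with the
    ``clamped`` flag set rather than silently.
    """
    raw = record.n_isolates / record.expected_occurrences
    clamped = raw > 1.0
    return CultivationProbability(
        value=min(raw, 1.0),
        n_isolates=record.n_isolates,
        expected_occurrences=record.expected_occurrences,
        clamped=clamped,
    )


def expected_occurrences(
    n_wells: int,
    abundance: float,
    cells_per_well: float = 1.0,
    mode: str = "nominal",
) -> float:
    """Expected number of wells holding the taxon for a given inoculation.

    ``nominal``: ``n_wells * abundance * cells_per_well``.
    ``poisson``: ``n_wells * (1 - exp(-cells_per_well * abundance))``, the
    expected count of wells with at least one cell of the taxon when total
    cell counts per well are Poisson(cells_per_well).
    """
    if n_wells < 1 or int(n_wells) != n_wells:
        raise ValidationError(f"n_wells must be a positive integer, got {n_wells!r}")
    if not (0.0 <= abundance <= 1.0):
        raise ValidationError(f"abundance must lie in [0, 1], got {abundance!r}")
    if not (cells_per_well > 0 and math.isfinite(cells_per_well)):
        raise ValidationError(f"cells_per_well must be > 0, got {cells_per_well!r}")
    if mode == "nominal":
        return n_wells * abundance * cells_per_well
    if mode == "poisson":
        return n_wells * -math.expm1(-cells_per_well * abundance)
    raise ValidationError(f"unknown occupancy mode {mode!r}; expected one of {OCCUPANCY_MODES}")


def cp_interval(record: CultivationRecord, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for cP at the given confidence level.

    Treats ``n_isolates`` as binomial successes out of
    ``round(expected_occurrences)`` trials; the interval is intersected with
    [0, 1].
    """
    if not (0.0 < confidence < 1.0):
        raise ValidationError(f"confidence must lie in (0, 1), got {confidence!r}")
    trials = round(record.expected_occurrences)
    if trials < max(1, record.n_isolates):
        raise DegenerateDenominatorError(
            f"rounded expected occurrences ({trials}) below isolate count "
            f"({record.n_isolates}) for {record.taxon_id!r}"
        )
    lo, hi = proportion_confint(record.n_isolates, trials, alpha=1.0 - confidence, method="wilson")
    lo = 0.0 if record.n_isolates == 0 else max(0.0, float(lo))
    hi = 1.0 if record.n_isolates == trials else min(1.0, float(hi))
    return (lo, hi)


def pool_records(records: list[CultivationRecord]) -> list[CultivationRecord]:
    """Sum records by taxon id, pooling isolate counts and expected occurrences.

    This is how multi-experiment campaigns aggregate before estimation: the
    pooled ratio weights every experiment by its expected occurrences.
    """
    isolates: dict[str, int] = {}
    occurrences: dict[str, float] = {}
    for rec in records:
        isolates[rec.taxon_id] = isolates.get(rec.taxon_id, 0) + rec.n_isolates
        occurrences[rec.taxon_id] = occurrences.get(rec.taxon_id, 0.0) + rec.expected_occurrences
    return [
        CultivationRecord(taxon_id=t, n_isolates=isolates[t], expected_occurrences=occurrences[t])
        for t in isolates
    ]
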