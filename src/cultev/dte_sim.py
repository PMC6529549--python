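"""Stochastic simulator of dilution-to-extinction cultivation campaigns.

Each well of a microtiter plate receives either exactly one cell
(``exact_one`` loading) or a Poisson-distributed number of cells with mean
``cells_per_well`` (``poisson`` loading).  Every cell's taxon is drawn
independently from the community's relative abundances; community mass not
covered by the profile is simulated as an inert "other" taxon that never
grows.  Growth is a black-box Bernoulli trial per distinct taxon per well
with that taxon's cultivation probability cP:

* ``simple`` mode — every successful growth trial yields an isolate.  This
  matches the bookkeeping behind cP estimation (isolates per expected
  occurrence), ignoring well purity.
* ``axenic`` mode — a well yields an isolate only when exactly one taxon's
  trial succeeds there, modeling the requirement that the culture be pure.
  Under exact-one loading the two modes coincide.

The module also hosts the synthetic fixture generator (Dirichlet community
profiles with log-uniform cultivation probabilities) and a parameter-recovery
harness that validates the cP estimator against simulated campaigns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cpestimate import CultivationRecord, TaxonProfile, estimate_cp, expected_occurrences
from .errors import InfeasibleDesignError, ValidationError
from .evmodel import CultivationProbability
from .planner import ExperimentDesign

__all__ = [
    "ExperimentOutcome",
    "simulate_experiment",
    "run_campaign",
    "pool_outcomes",
    "generate_fixture_community",
    "assign_growth_probs",
    "recovery_check",
    "RecoveryReport",
]

OTHER_TAXON = "__other__"


@dataclass(frozen=True)
class ExperimentOutcome:
    """Per-taxon isolate counts and well occupancy from one campaign run."""

    per_taxon_isolates: dict[str, int]
    per_taxon_occupied_wells: dict[str, int]
    n_wells_occupied: int
    n_wells_total: int
    seed: int
    mode: str
    loading: str

    @property
    def total_isolates(self) -> int:
        return sum(self.per_taxon_isolates.values())


def _community_arrays(design: ExperimentDesign):
    """Taxon ids, abundance vector (with residual 'other'), and cP vector."""
    ids = [t.taxon_id for t in design.community]
    abund = np.array([t.relative_abundance for t in design.community], dtype=float)
    residual = 1.0 - abund.sum()
    if residual < -1e-6:
        raise ValidationError(f"community abundances sum to {abund.sum():.6f} > 1")
    ids.append(OTHER_TAXON)
    abund = np.append(abund, max(residual, 0.0))
    abund = abund / abund.sum()
    cps = np.array(
        [design.growth_probs.get(t, CultivationProbability(0.0)).value for t in ids[:-1]] + [0.0]
    )
    return ids, abund, cps


def simulate_experiment(
    design: ExperimentDesign,
    mode: str = "simple",
    loading: str = "exact_one",
    seed: int = 0,
) -> ExperimentOutcome:
    """Simulate one dilution-to-extinction experiment.

    Identical seeds give identical outcomes; the random stream is a
    numpy ``default_rng(seed)``.
    """
    if mode not in ("simple", "axenic"):
        raise ValidationError(f"unknown mode {mode!r}; expected simple or axenic")
    if loading not in ("exact_one", "poisson"):
        raise ValidationError(f"unknown loading {loading!r}; expected exact_one or poisson")
    ids, abund, cps = _community_arrays(design)
    n_taxa = len(ids)
    rng = np.random.default_rng(seed)
    n_wells = design.n_wells

    if loading == "exact_one":
        cell_counts = np.ones(n_wells, dtype=np.int64)
    else:
        cell_counts = rng.poisson(design.cells_per_well, size=n_wells)

    # presence[w, t]: does well w contain >= 1 cell of taxon t
    presence = np.zeros((n_wells, n_taxa), dtype=bool)
    occupied = cell_counts > 0
    max_cells = int(cell_counts.max(initial=0))
    for c in range(1, max_cells + 1):
        wells_c = np.flatnonzero(cell_counts == c)
        if wells_c.size == 0:
            continue
        draws = rng.choice(n_taxa, size=(wells_c.size, c), p=abund)
        presence[np.repeat(wells_c, c), draws.ravel()] = True

    occupied_per_taxon = presence.sum(axis=0).astype(int)

    # one growth trial per distinct taxon per well
    successes = presence & (rng.random((n_wells, n_taxa)) < cps[None, :])
    if mode == "simple":
        isolates_per_taxon = successes.sum(axis=0).astype(int)
    else:
        pure = successes.sum(axis=1) == 1
        isolates_per_taxon = (successes & pure[:, None]).sum(axis=0).astype(int)

    per_isolates = {t: int(isolates_per_taxon[i]) for i, t in enumerate(ids) if t != OTHER_TAXON}
    per_occupied = {t: int(occupied_per_taxon[i]) for i, t in enumerate(ids) if t != OTHER_TAXON}
    return ExperimentOutcome(
        per_taxon_isolates=per_isolates,
        per_taxon_occupied_wells=per_occupied,
        n_wells_occupied=int(occupied.sum()),
        n_wells_total=n_wells,
        seed=seed,
        mode=mode,
        loading=loading,
    )


def _subseed(master_seed: int, index: int) -> int:
    """Deterministic per-experiment seed: child of SeedSequence(master_seed)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_campaign(
    design: ExperimentDesign,
    n_experiments: int,
    mode: str = "simple",
    loading: str = "exact_one",
    seed: int = 0,
) -> list[ExperimentOutcome]:
    """Run independent experiments with sub-seeds derived from a master seed."""
    if n_experiments < 1:
        raise ValidationError(f"n_experiments must be >= 1, got {n_experiments!r}")
    return [
        simulate_experiment(design, mode=mode, loading=loading, seed=_subseed(seed, k))
        for k in range(n_experiments)
    ]


def pool_outcomes(outcomes: list[ExperimentOutcome]) -> ExperimentOutcome:
    """Sum isolate counts and occupied wells by taxon across experiments."""
    if not outcomes:
        raise ValidationError("no outcomes to pool")
    isolates: dict[str, int] = {}
    occupied: dict[str, int] = {}
    for o in outcomes:
        for t, n in o.per_taxon_isolates.items():
            isolates[t] = isolates.get(t, 0) + n
        for t, n in o.per_taxon_occupied_wells.items():
            occupied[t] = occupied.get(t, 0) + n
    return ExperimentOutcome(
        per_taxon_isolates=isolates,
        per_taxon_occupied_wells=occupied,
        n_wells_occupied=sum(o.n_wells_occupied for o in outcomes),
        n_wells_total=sum(o.n_wells_total for o in outcomes),
        seed=outcomes[0].seed,
        mode=outcomes[0].mode,
        loading=outcomes[0].loading,
    )


def generate_fixture_community(
    n_taxa: int, concentration: float = 0.5, seed: int = 0
) -> list[TaxonProfile]:
    """Draw a synthetic community from a symmetric Dirichlet, sorted descending.

    Low concentration values produce the steep rank-abundance curves typical
    of natural communities (a few dominant taxa, a long rare tail).
    """
    if n_taxa < 1:
        raise ValidationError(f"n_taxa must be >= 1, got {n_taxa!r}")
    if not (concentration > 0):
        raise ValidationError(f"concentration must be > 0, got {concentration!r}")
    rng = np.random.default_rng(seed)
    abund = np.sort(rng.dirichlet(np.full(n_taxa, concentration)))[::-1]
    return [
        TaxonProfile(taxon_id=f"taxon{k:04d}", relative_abundance=float(a))
        for k, a in enumerate(abund, start=1)
    ]


def assign_growth_probs(
    community: list[TaxonProfile],
    cp_range: tuple[float, float] = (0.001, 0.6),
    seed: int = 0,
) -> dict[str, CultivationProbability]:
    """Assign each taxon a cultivation probability, log-uniform on cp_range."""
    lo, hi = cp_range
    if not (0 < lo <= hi <= 1):
        raise ValidationError(f"cp_range must satisfy 0 < lo <= hi <= 1, got {cp_range!r}")
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(community)))
    return {
        t.taxon_id: CultivationProbability(float(p)) for t, p in zip(community, draws)
    }


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery check of the cP estimator on simulated campaigns."""

    generating_cp: float
    mean_estimate: float
    std_error: float
    n_replicates: int
    recovered: bool
    estimates: tuple[float, ...] = field(repr=False, default=())


def recovery_check(
    generating_cp: float,
    design: ExperimentDesign,
    n_replicates: int = 200,
    seed: int = 0,
    taxon_id: str | None = None,
) -> RecoveryReport:
    """Does the cP estimator recover the generating probability?

    Runs ``n_replicates`` simple-mode exact-one campaigns of the design with
    the target taxon's cP set to ``generating_cp``, estimates cP from each
    with nominal expected occurrences, and checks the mean estimate lies
    within 3 Monte-Carlo standard errors of the truth.
    """
    if n_replicates < 2:
        raise ValidationError(f"n_replicates must be >= 2, got {n_replicates!r}")
    if taxon_id is None:
        taxon_id = design.community[0].taxon_id
    abundance = design.abundance_of(taxon_id)
    expected = expected_occurrences(design.n_wells, abundance, design.cells_per_well, "nominal")
    if expected <= 0:
        raise InfeasibleDesignError("design gives zero expected occurrences for the target taxon")
    probs = dict(design.growth_probs)
    probs[taxon_id] = CultivationProbability(float(generating_cp))
    design = ExperimentDesign(design.n_wells, design.cells_per_well, design.community, probs)
    estimates = []
    for k in range(n_replicates):
        out = simulate_experiment(design, mode="simple", loading="exact_one", seed=_subseed(seed, k))
        rec = CultivationRecord(
            taxon_id=taxon_id,
            n_isolates=out.per_taxon_isolates[taxon_id],
            expected_occurrences=expected,
        )
        estimates.append(estimate_cp(rec).value)
    est = np.asarray(estimates)
    mean = float(est.mean())
    se = float(est.std(ddof=1) / math.sqrt(n_replicates))
    recovered = abs(mean - generating_cp) <= 3.0 * se if se > 0 else mean == generating_cp
    return RecoveryReport(
        generating_cp=float(generating_cp),
        mean_estimate=mean,
        std_error=se,
        n_replicates=n_replicates,
        recovered=bool(recovered),
        estimates=tuple(estimates),
    )
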