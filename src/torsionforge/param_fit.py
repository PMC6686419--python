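"""Fitting torsion barrier heights to reference potential-energy profiles.

Two strategies are provided, matching common force-field parameterization
practice:

* **systematic** — exhaustive scan of one quadruple's free components on a
  regular value grid (default step 0.1 kcal/mol within [-15, 15]); suited
  to cases where a single quadruple carries the whole torsion profile.
* **genetic algorithm** — joint optimization of all free components across
  several reference profiles with the summed per-profile RMSD as fitness;
  suited to families of related molecules that share quadruples, where the
  redundancy constrains the shared parameters.

The merit function is the RMSD between the force-field profile and the
reference profile, both shifted so their grid minimum is zero (profiles are
relative energies; absolute offsets carry no information).  By default the
force-field profile is the rigid torsion-term-only sum of the cosine series
over the quadruples present on the scanned bond; a relaxed-scan profile
through a pluggable energy engine can be substituted via
``FitSpec.profile_fn``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .param_model import EnergyProfile, torsion_energy

__all__ = [
    "QuadrupleSpec",
    "ReferencePES",
    "FitSpec",
    "FitResult",
    "merit_rmsd",
    "cis_trans_gap",
    "model_profile",
    "systematic_fit",
    "ga_fit",
]

_COMPONENTS = ("V1", "V2", "V3")


@dataclass(frozen=True)
class QuadrupleSpec:
    """One atom quadruple contributing to a scanned bond.

    ``key`` identifies the quadruple (shared keys across references share
    fitted values); ``base`` holds the fixed (V1, V2, V3) starting triple;
    ``phase_deg`` shifts the dihedral seen by this quadruple relative to the
    scanned reference dihedral (two quadruples across the same bond may be
    offset by a constant angle).
    """

    key: tuple
    base: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_deg: float = 0.0


@dataclass
class ReferencePES:
    """A reference torsion profile plus the quadruples present on the bond."""

    molecule: str
    profile: EnergyProfile
    quadruples: tuple[QuadrupleSpec, ...]

    def __post_init__(self):
        if len(self.profile.angles) < 2:
            raise ValueError("reference profile needs at least two grid points")
        prof = self.profile.to_unit("kcal/mol").relative()
        self.profile = prof
        self.quadruples = tuple(self.quadruples)


@dataclass
class FitSpec:
    """Free components, bounds and optimizer settings for a fit."""

    free: dict[tuple, tuple[str, ...]]  # quadruple key -> subset of ("V1","V2","V3")
    bounds: tuple[float, float] = (-15.0, 15.0)
    step: float = 0.1
    population: int = 60
    generations: int = 300
    crossover_rate: float = 0.7
    mutation_sigma: float = 0.25
    mutation_rate: float = 0.3
    tournament_k: int = 3
    elites: int = 2
    seed: int | None = None
    profile_fn: Callable | None = None  # (ReferencePES, params) -> EnergyProfile

    def __post_init__(self):
        if not self.free or not any(self.free.values()):
            raise ValueError("at least one free component is required")
        for comps in self.free.values():
            for c in comps:
                if c not in _COMPONENTS:
                    raise ValueError(f"unknown component {c!r}")
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be finite with lower < upper")
        if self.step <= 0:
            raise ValueError("grid step must be positive")

    def genes(self) -> list[tuple[tuple, str]]:
        """Flattened (quadruple key, component) list defining the genome order."""
        return [(key, c) for key, comps in sorted(self.free.items(), key=lambda kv: repr(kv[0]))
                for c in comps]


@dataclass
class FitResult:
    triples: dict[tuple, tuple[float, float, float]]
    merit: float
    mode: str  # {"systematic", "ga"}
    evaluations: int
    seed: int | None = None
    history: tuple[float, ...] = ()  # best fitness per generation (GA only)


# ---------------------------------------------------------------------------
# merit and profile model
# ---------------------------------------------------------------------------

def merit_rmsd(ff_profile: EnergyProfile, ref_profile: EnergyProfile) -> float:
    """RMSD between two relative profiles on an identical angle grid (kcal/mol)."""
    if ff_profile.unit != ref_profile.unit:
        raise ValueError("profiles must share an energy unit")
    if len(ff_profile.angles) != len(ref_profile.angles) or any(
        abs(a - b) > 1e-9 for a, b in zip(ff_profile.angles, ref_profile.angles)
    ):
        raise ValueError("profiles must share an identical angle grid")
    a = np.asarray(ff_profile.energies, float)
    b = np.asarray(ref_profile.energies, float)
    a = a - a.min()
    b = b - b.min()
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cis_trans_gap(profile: EnergyProfile) -> float:
    """E(0 deg) - E(180 deg); decides whether V1 must be freed in a fit."""
    angles = profile.angles

    def value_at(target: float) -> float:
        for ang, e in zip(angles, profile.energies):
            if abs(ang - target) < 1e-6:
                return e
        raise ValueError(f"profile grid does not contain {target} degrees")

    return value_at(0.0) - value_at(180.0)


def _triples_for(
    ref: ReferencePES, params: dict[tuple[tuple, str], float]
) -> list[tuple[tuple[float, float, float], float]]:
    out = []
    for quad in ref.quadruples:
        triple = list(quad.base)
        for ci, comp in enumerate(_COMPONENTS):
            if (quad.key, comp) in params:
                triple[ci] = params[(quad.key, comp)]
        out.append((tuple(triple), quad.phase_deg))
    return out


def model_profile(ref: ReferencePES, params: dict[tuple[tuple, str], float]) -> EnergyProfile:
    """Rigid torsion-term-only profile of a reference's quadruples on its grid."""
    triples = _triples_for(ref, params)
    energies = [
        sum(torsion_energy(v1, v2, v3, ang + phase) for (v1, v2, v3), phase in triples)
        for ang in ref.profile.angles
    ]
    return EnergyProfile(list(ref.profile.angles), energies)


def _evaluate(refs: Sequence[ReferencePES], spec: FitSpec,
              params: dict[tuple[tuple, str], float]) -> float:
    profile_fn = spec.profile_fn or model_profile
    return sum(merit_rmsd(profile_fn(ref, params), ref.profile) for ref in refs)


def _params_from_vector(genes: Sequence[tuple[tuple, str]], vec: Sequence[float]):
    return {g: float(v) for g, v in zip(genes, vec)}


def _result_triples(refs, spec, params):
    triples = {}
    for ref in refs:
        for quad in ref.quadruples:
            triple = list(quad.base)
            for ci, comp in enumerate(_COMPONENTS):
                if (quad.key, comp) in params:
                    triple[ci] = params[(quad.key, comp)]
            triples[quad.key] = tuple(triple)
    return triples


# ---------------------------------------------------------------------------
# systematic grid search
# ---------------------------------------------------------------------------

def systematic_fit(ref: ReferencePES, spec: FitSpec) -> FitResult:
    """Exhaustive grid search over one quadruple's free components.

    Candidate values lie on the regular ``spec.step`` grid within the
    bounds; ties in merit break toward smaller summed |V|, then
    lexicographically.
    """
    if len(spec.free) != 1:
        raise ValueError("systematic mode fits exactly one quadruple")
    genes = spec.genes()
    lo, hi = spec.bounds
    n_lo = math.ceil(round(lo / spec.step, 9))
    n_hi = math.floor(round(hi / spec.step, 9))
    grid = [round(n * spec.step, 10) for n in range(n_lo, n_hi + 1)]
    best_vec = None
    best_merit = math.inf
    evaluations = 0
    for vec in itertools.product(grid, repeat=len(genes)):
        merit = _evaluate([ref], spec, _params_from_vector(genes, vec))
        evaluations += 1
        if merit < best_merit - 1e-12:
            best_merit, best_vec = merit, vec
        elif abs(merit - best_merit) <= 1e-12 and best_vec is not None:
            key_new = (sum(abs(v) for v in vec), vec)
            key_old = (sum(abs(v) for v in best_vec), best_vec)
            if key_new < key_old:
                best_vec = vec
    params = _params_from_vector(genes, best_vec)
    return FitResult(_result_triples([ref], spec, params), best_merit,
                     "systematic", evaluations)


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def ga_fit(refs: Sequence[ReferencePES], spec: FitSpec) -> FitResult:
    """Elitist genetic algorithm minimizing the summed per-reference RMSD.

    Quadruples shared between references share genes, so redundancy across
    the reference set constrains the fit.  Deterministic for a fixed seed.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("at least one reference profile is required")
    if spec.seed is None:
        raise ValueError("ga_fit requires an explicit seed")
    genes = spec.genes()
    n_genes = len(genes)
    lo, hi = spec.bounds
    rng = np.random.default_rng(spec.seed)

    pop = rng.uniform(lo, hi, size=(spec.population, n_genes))
    fitness = np.array([
        _evaluate(refs, spec, _params_from_vector(genes, ind)) for ind in pop
    ])
    evaluations = spec.population
    history = [float(fitness.min())]

    for _ in range(spec.generations):
        order = np.argsort(fitness, kind="stable")
        elites = pop[order[: spec.elites]].copy()
        children = []
        while len(children) < spec.population - spec.elites:
            idx_a = order[min(rng.integers(0, spec.population, spec.tournament_k))]
            idx_b = order[min(rng.integers(0, spec.population, spec.tournament_k))]
            pa = pop[idx_a].copy()
            pb = pop[idx_b].copy()
            if rng.random() < spec.crossover_rate:
                mask = rng.random(n_genes) < 0.5
                pa[mask], pb[mask] = pb[mask], pa[mask].copy()
            for child in (pa, pb):
                mut = rng.random(n_genes) < spec.mutation_rate
                child[mut] += rng.normal(0.0, spec.mutation_sigma, mut.sum())
                np.clip(child, lo, hi, out=child)
                children.append(child)
        pop = np.vstack([elites, np.array(children[: spec.population - spec.elites])])
        fitness = np.array([
            _evaluate(refs, spec, _params_from_vector(genes, ind)) for ind in pop
        ])
        evaluations += spec.population
        history.append(float(fitness.min()))

    best = pop[int(np.argmin(fitness))]
    params = _params_from_vector(genes, best)
    return FitResult(_result_triples(refs, spec, params), float(fitness.min()),
                     "ga", evaluations, seed=spec.seed, history=tuple(history))
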