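"""Conformer generation, minimization, filtering and recovery accounting.

The benchmark protocol mirrors a standard bioactive-conformer recovery
study: up to 1000 conformers per molecule are generated by random
assignment of rotatable-bond dihedrals on a 30-degree grid (ring internal
coordinates untouched), each conformer is minimized by a pluggable energy
engine (300 conjugate-gradient then 5000 L-BFGS steps, dielectric constant
4 forwarded to the engine), conformers within 10 kcal/mol of the ensemble
minimum are kept as "low-energy conformers", and the lowest heavy-atom
symmetry-aware RMSD to a reference conformer is recorded per molecule.
Recovery tables report the cumulative fraction of molecules recovered below
RMSD thresholds; torsion diagnostics attribute failures to TorsionIDs.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolAlign

from . import symmetry
from .param_model import MissingParameterError, ParamTable, lookup, torsion_energy
from .torsion_id import (
    GraphBond,
    MolecularGraph,
    assign_mmff_types,
    detect_assignable_bonds,
    extract_fragment,
    encode,
)

__all__ = [
    "Conformer",
    "EnergyEngine",
    "TorsionOnlyEngine",
    "RigidTorsionEngine",
    "HarmonicWellEngine",
    "rotatable_bonds",
    "dihedral_quadruple",
    "measure_dihedral",
    "enumerate_conformers",
    "minimize_ensemble",
    "filter_low_energy",
    "best_rmsd",
    "RecoveryResult",
    "recovery_table",
    "diagnose_torsions",
    "aggregate_diagnostics",
    "torsion_engine_from_table",
]


@dataclass
class Conformer:
    coords: np.ndarray  # (n_atoms, 3) Angstrom
    assignment: tuple[float, ...] = ()
    energy: float | None = None
    status: str = "raw"  # {"raw", "ok", "failed"}


class EnergyEngine(Protocol):
    """Contract for pluggable energy engines.

    ``minimize`` must be deterministic for fixed inputs and must never
    return an energy above ``energy(coords)`` of its input.
    """

    def energy(self, coords: np.ndarray) -> float: ...

    def minimize(
        self, coords: np.ndarray, cg_steps: int, lbfgs_steps: int, dielectric: float
    ) -> tuple[np.ndarray, float]: ...


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def measure_dihedral(coords: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    p = np.asarray(coords, dtype=float)
    b0 = p[a] - p[b]
    b1 = p[c] - p[b]
    b2 = p[d] - p[c]
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return symmetry.wrap_angle(ang)


def _side_atoms(graph: MolecularGraph, keep: int, drop: int) -> list[int]:
    """Atoms on the ``keep`` side when the keep-drop bond is cut."""
    seen = {drop, keep}
    out = [keep]
    stack = [keep]
    while stack:
        cur = stack.pop()
        for nb in graph.neighbors(cur):
            if nb not in seen:
                seen.add(nb)
                out.append(nb)
                stack.append(nb)
    return out


def rotatable_bonds(graph: MolecularGraph) -> list[GraphBond]:
    """Assignable bonds that are acyclic (ring conformations are never altered)."""
    return [b for b in detect_assignable_bonds(graph) if not graph.is_ring_bond(b)]


def dihedral_quadruple(graph: MolecularGraph, bond: GraphBond) -> tuple[int, int, int, int]:
    """Deterministic reference quadruple (a, b, c, d) for a rotatable bond.

    Oriented so that the d-side branch (the one a dihedral driver rotates)
    is the smaller of the two; ties break toward the lower atom index.
    Reference atoms a and d are the lowest-index non-central neighbours.
    """
    s1 = _side_atoms(graph, bond.a1, bond.a2)
    s2 = _side_atoms(graph, bond.a2, bond.a1)
    key1 = (len(s1), min(s1))
    key2 = (len(s2), min(s2))
    b_at, c_at = (bond.a1, bond.a2) if key2 <= key1 else (bond.a2, bond.a1)
    a_at = min(x for x in graph.neighbors(b_at) if x != c_at)
    d_at = min(x for x in graph.neighbors(c_at) if x != b_at)
    return a_at, b_at, c_at, d_at


def _set_dihedral(
    graph: MolecularGraph, coords: np.ndarray, quad: tuple[int, int, int, int], value: float
) -> np.ndarray:
    """Rotate the d-side branch about the b-c axis so dihedral(a,b,c,d) == value."""
    a, b, c, d = quad
    current = measure_dihedral(coords, a, b, c, d)
    delta = math.radians(value - current)
    axis = coords[c] - coords[b]
    axis = axis / np.linalg.norm(axis)
    moving = [x for x in _side_atoms(graph, c, b) if x != c]
    out = coords.copy()
    cos_t, sin_t = math.cos(delta), math.sin(delta)
    for idx in moving:
        v = out[idx] - out[c]
        out[idx] = (
            out[c]
            + v * cos_t
            + np.cross(axis, v) * sin_t
            + axis * np.dot(axis, v) * (1.0 - cos_t)
        )
    return out


# ---------------------------------------------------------------------------
# conformer enumeration
# ---------------------------------------------------------------------------

def enumerate_conformers(
    graph: MolecularGraph,
    coords: np.ndarray | None = None,
    max_n: int = 1000,
    step: float = 30.0,
    seed: int | None = None,
) -> list[Conformer]:
    """Generate distinct dihedral-assignment conformers on a ``step``-degree grid.

    If the full grid (m^n for n rotatable bonds, m = 360/step values) fits
    within ``max_n`` it is enumerated exhaustively; otherwise ``max_n``
    distinct assignment vectors are sampled without replacement using
    ``seed``.  Ring internal coordinates are never altered.
    """
    if coords is None:
        mol = getattr(graph, "rdkit_mol", None)
        if mol is None or mol.GetNumConformers() == 0:
            raise ValueError("3D coordinates are required to enumerate conformers")
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(graph.atoms), 3):
        raise ValueError("coordinate array must be (n_atoms, 3)")
    bonds = rotatable_bonds(graph)
    if not bonds:
        return [Conformer(coords.copy(), ())]
    quads = [dihedral_quadruple(graph, b) for b in bonds]
    m = int(round(360.0 / step))
    values = tuple(i * step for i in range(m))
    total = m ** len(bonds)
    if total <= max_n:
        assignments = list(itertools.product(values, repeat=len(bonds)))
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[float, ...]] = set()
        assignments = []
        while len(assignments) < max_n:
            vec = tuple(values[i] for i in rng.integers(0, m, size=len(bonds)))
            if vec not in chosen:
                chosen.add(vec)
                assignments.append(vec)
    out = []
    for vec in assignments:
        c = coords
        for quad, value in zip(quads, vec):
            c = _set_dihedral(graph, c, quad, value)
        out.append(Conformer(c, vec))
    return out


# ---------------------------------------------------------------------------
# minimization and filtering
# ---------------------------------------------------------------------------

def minimize_ensemble(
    conformers: Sequence[Conformer],
    engine: EnergyEngine,
    cg_steps: int = 300,
    lbfgs_steps: int = 5000,
    dielectric: float = 4.0,
) -> list[Conformer]:
    """Minimize every conformer; engine exceptions downgrade to failed status."""
    out = []
    for conf in conformers:
        try:
            coords, energy = engine.minimize(
                conf.coords, cg_steps=cg_steps, lbfgs_steps=lbfgs_steps,
                dielectric=dielectric,
            )
            out.append(Conformer(np.asarray(coords, float), conf.assignment,
                                 float(energy), "ok"))
        except Exception:
            out.append(Conformer(conf.coords, conf.assignment, None, "failed"))
    return out


def filter_low_energy(conformers: Sequence[Conformer], window: float = 10.0) -> list[Conformer]:
    """Keep conformers within ``window`` kcal/mol of the ensemble minimum."""
    ok = [c for c in conformers if c.status == "ok" and c.energy is not None]
    if not ok:
        raise ValueError("no successfully minimized conformer to filter")
    e_min = min(c.energy for c in ok)
    return [c for c in ok if c.energy - e_min <= window]


# ---------------------------------------------------------------------------
# RMSD and recovery
# ---------------------------------------------------------------------------

def _mol_with_coords(template: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    mol = Chem.Mol(template)
    mol.RemoveAllConformers()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, (x, y, z) in enumerate(np.asarray(coords, float)):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    mol.AddConformer(conf, assignId=True)
    return mol


def best_rmsd(
    conformers: Sequence[Conformer],
    reference: np.ndarray | Conformer,
    graph: MolecularGraph,
) -> float:
    """Lowest heavy-atom RMSD of any conformer to the reference geometry.

    RMSD is computed after optimal rigid superposition and minimized over
    graph automorphisms (symmetry-equivalent atom relabelings).
    """
    mol = getattr(graph, "rdkit_mol", None)
    if mol is None:
        raise ValueError("graph must carry an RDKit molecule for RMSD computation")
    ref_coords = reference.coords if isinstance(reference, Conformer) else np.asarray(reference)
    if ref_coords.shape != (len(graph.atoms), 3):
        raise ValueError("reference atom count does not match the molecule")
    usable = [c for c in conformers if c.status in ("ok", "raw")]
    if not usable:
        raise ValueError("no conformers to compare")
    ref_mol = Chem.RemoveHs(_mol_with_coords(mol, ref_coords), sanitize=False)
    best = math.inf
    for conf in usable:
        if conf.coords.shape != ref_coords.shape:
            raise ValueError("conformer atom count does not match the reference")
        prb_mol = Chem.RemoveHs(_mol_with_coords(mol, conf.coords), sanitize=False)
        best = min(best, rdMolAlign.GetBestRMS(prb_mol, ref_mol))
    return best


@dataclass
class RecoveryResult:
    thresholds: tuple[float, ...]
    ratios: tuple[float, ...]
    n_molecules: int  # successfully processed molecules
    n_failures: int
    best_rmsds: tuple[float, ...] = ()

    @property
    def failure_rate(self) -> float:
        total = self.n_molecules + self.n_failures
        return self.n_failures / total if total else 0.0


def recovery_table(
    best_rmsds: Sequence[float],
    n_failures: int = 0,
    thresholds: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
) -> RecoveryResult:
    """Cumulative fraction of molecules recovered below each RMSD threshold."""
    rmsds = [float(r) for r in best_rmsds]
    if not rmsds and n_failures == 0:
        raise ValueError("recovery table needs at least one result")
    n = len(rmsds)
    ratios = tuple(
        (sum(1 for r in rmsds if r < t) / n) if n else 0.0 for t in thresholds
    )
    return RecoveryResult(tuple(thresholds), ratios, n, n_failures, tuple(rmsds))


# ---------------------------------------------------------------------------
# torsion diagnostics
# ---------------------------------------------------------------------------

@dataclass
class TorsionDiagnostic:
    torsion_id: str
    bond: tuple[int, int]
    raw_deviation: float
    effective_deviation: float
    pair: str
    exceeds: bool


def diagnose_torsions(
    reference_coords: np.ndarray,
    predicted_coords: np.ndarray,
    graph: MolecularGraph,
    threshold: float = 30.0,
) -> list[TorsionDiagnostic]:
    """Per-rotatable-bond symmetry-corrected deviation between two conformations."""
    ref = np.asarray(reference_coords, float)
    pred = np.asarray(predicted_coords, float)
    n = len(graph.atoms)
    if ref.shape != (n, 3) or pred.shape != (n, 3):
        raise ValueError("conformations do not match the molecular graph")
    out = []
    for bond in rotatable_bonds(graph):
        quad = dihedral_quadruple(graph, bond)
        phi_ref = measure_dihedral(ref, *quad)
        phi_pred = measure_dihedral(pred, *quad)
        la = symmetry.classify_end(graph, bond, bond.a1)
        lb = symmetry.classify_end(graph, bond, bond.a2)
        pair = symmetry.pair_class(la, lb)
        dev = symmetry.deviation_exceeds(phi_ref, phi_pred, pair, threshold)
        tid = encode(extract_fragment(graph, bond))
        out.append(
            TorsionDiagnostic(tid, (bond.a1, bond.a2), dev.raw, dev.effective,
                              pair, dev.exceeds)
        )
    return out


def aggregate_diagnostics(
    per_molecule: Sequence[Sequence[TorsionDiagnostic]],
) -> list[tuple[str, int]]:
    """Sum flagged (wrong) torsion counts per TorsionID, sorted descending."""
    counts: Counter[str] = Counter()
    for diags in per_molecule:
        for d in diags:
            if d.exceeds:
                counts[d.torsion_id] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


# ---------------------------------------------------------------------------
# energy engines
# ---------------------------------------------------------------------------

class TorsionOnlyEngine:
    """Energy engine containing only cosine torsion terms.

    ``terms`` is a list of ((a, b, c, d), (v1, v2, v3)) with atom indices
    into the molecule.  The dielectric constant is accepted for contract
    compatibility and ignored (there are no electrostatics).
    """

    def __init__(self, terms: Sequence[tuple[tuple[int, int, int, int],
                                             tuple[float, float, float]]]):
        self.terms = list(terms)

    def energy(self, coords: np.ndarray) -> float:
        total = 0.0
        for (a, b, c, d), (v1, v2, v3) in self.terms:
            phi = measure_dihedral(coords, a, b, c, d)
            total += torsion_energy(v1, v2, v3, phi)
        return total

    def minimize(
        self, coords: np.ndarray, cg_steps: int = 300, lbfgs_steps: int = 5000,
        dielectric: float = 4.0,
    ) -> tuple[np.ndarray, float]:
        from scipy.optimize import minimize as scipy_minimize

        x0 = np.asarray(coords, float).ravel()
        shape = np.asarray(coords).shape

        def fun(x):
            return self.energy(x.reshape(shape))

        res = scipy_minimize(fun, x0, method="CG", options={"maxiter": cg_steps})
        res = scipy_minimize(fun, res.x, method="L-BFGS-B",
                             options={"maxiter": lbfgs_steps, "gtol": 1e-6})
        e0 = fun(x0)
        if res.fun <= e0:
            return res.x.reshape(shape), float(res.fun)
        return np.asarray(coords, float), float(e0)  # never increase energy


class RigidTorsionEngine:
    """Torsion-only engine that minimizes in dihedral space.

    Minimization varies only the rotatable-bond dihedrals, rotating branches
    rigidly about each bond axis; bond lengths, angles and ring geometries
    are preserved exactly.  This is the natural minimizer for a pure torsion
    potential and the engine used by the synthetic recovery benchmark.
    """

    def __init__(self, graph: MolecularGraph,
                 terms: Sequence[tuple[tuple[int, int, int, int],
                                       tuple[float, float, float]]]):
        self.graph = graph
        self.terms = list(terms)
        self._rotors = [dihedral_quadruple(graph, b) for b in rotatable_bonds(graph)]

    def energy(self, coords: np.ndarray) -> float:
        total = 0.0
        for (a, b, c, d), (v1, v2, v3) in self.terms:
            phi = measure_dihedral(coords, a, b, c, d)
            total += torsion_energy(v1, v2, v3, phi)
        return total

    def _build(self, coords: np.ndarray, angles: np.ndarray) -> np.ndarray:
        out = coords
        for quad, ang in zip(self._rotors, angles):
            out = _set_dihedral(self.graph, out, quad, float(ang))
        return out

    def minimize(
        self, coords: np.ndarray, cg_steps: int = 300, lbfgs_steps: int = 5000,
        dielectric: float = 4.0,
    ) -> tuple[np.ndarray, float]:
        from scipy.optimize import minimize as scipy_minimize

        coords = np.asarray(coords, float)
        if not self._rotors:
            return coords.copy(), self.energy(coords)
        x0 = np.array([measure_dihedral(coords, *q) for q in self._rotors])

        def fun(x):
            return self.energy(self._build(coords, x))

        res = scipy_minimize(fun, x0, method="CG", options={"maxiter": cg_steps})
        res = scipy_minimize(fun, res.x, method="L-BFGS-B",
                             options={"maxiter": lbfgs_steps, "gtol": 1e-8})
        e0 = fun(x0)
        if res.fun <= e0:
            return self._build(coords, res.x), float(res.fun)
        return coords.copy(), float(e0)


class HarmonicWellEngine:
    """Quadratic well around target coordinates (convex test engine)."""

    def __init__(self, target: np.ndarray, k: float = 1.0):
        self.target = np.asarray(target, float)
        self.k = k

    def energy(self, coords: np.ndarray) -> float:
        d = np.asarray(coords, float) - self.target
        return float(self.k * np.sum(d * d))

    def minimize(self, coords, cg_steps=300, lbfgs_steps=5000, dielectric=4.0):
        return self.target.copy(), 0.0


def torsion_engine_from_table(
    graph: MolecularGraph,
    table: ParamTable,
    tt_candidates: Sequence[int] = (0, 1),
    strict: bool = False,
    rigid: bool = True,
) -> "RigidTorsionEngine | TorsionOnlyEngine":
    """Build a torsion-only engine from a parameter table.

    For every rotatable bond, every quadruple a-b-c-d across the bond whose
    four atoms receive MMFF numeric types is resolved against the table
    (trying the torsion-type indices in ``tt_candidates``); unresolvable
    quadruples are skipped unless ``strict``.
    """
    types = assign_mmff_types(graph)
    terms = []
    for bond in rotatable_bonds(graph):
        b, c = bond.a1, bond.a2
        for a in graph.neighbors(b):
            if a == c:
                continue
            for d in graph.neighbors(c):
                if d == b:
                    continue
                key_types = tuple(types.get(x) for x in (a, b, c, d))
                if None in key_types:
                    if strict:
                        raise MissingParameterError(-1, (0, 0, 0, 0))
                    continue
                rec = None
                for tt in tt_candidates:
                    try:
                        rec = lookup(table, tt, *key_types)
                        break
                    except MissingParameterError:
                        continue
                if rec is None:
                    if strict:
                        raise MissingParameterError(tt_candidates[0], key_types)
                    continue
                terms.append(((a, b, c, d), rec.triple))
    return RigidTorsionEngine(graph, terms) if rigid else TorsionOnlyEngine(terms)
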