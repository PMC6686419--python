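"""Local symmetry of rotatable-bond ends and symmetry-corrected deviations.

Each end of a rotatable bond is assigned a topological symmetry label:

* ``D3`` — three pairwise-equivalent substituent branches (e.g. a methyl
  carbon); collapsed to ``D1`` for pair classification;
* ``D2`` — a planar end with two equivalent branches (e.g. an unsubstituted
  phenyl ipso carbon), giving the torsion profile 180-degree periodicity;
* ``D1`` — a substituent pattern admitting a mirror, so the profile is even
  in the dihedral;
* ``C1`` — no symmetry.

The unordered pair of end labels determines how a raw dihedral deviation
(in [-180, +180] degrees) folds: pairs C1C1/C1D1 keep the full 360-degree
period, C1D2/D1D1 fold to 180 degrees, D1D2/D2D2 to 90 degrees.  Two
quantities are exposed: the literal piecewise mapping of the raw deviation,
and the *effective* deviation — the distance to the nearest
symmetry-equivalent angle — which is what threshold tests ("was this
torsion predicted more than 30 degrees wrong?") use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .torsion_id import GraphBond, MolecularGraph, branch_code, perceive_all

__all__ = [
    "SymmetryLabel",
    "PAIR_CLASSES",
    "pair_class",
    "pair_period",
    "classify_end",
    "fold_deviation",
    "effective_deviation",
    "deviation_exceeds",
    "TorsionDeviation",
    "wrap_angle",
]

SymmetryLabel = str  # one of "C1", "D1", "D2", "D3"

PAIR_CLASSES = ("C1C1", "C1D1", "C1D2", "D1D1", "D1D2", "D2D2")

_PERIOD = {
    "C1C1": 360.0,
    "C1D1": 360.0,
    "C1D2": 180.0,
    "D1D1": 180.0,
    "D1D2": 90.0,
    "D2D2": 90.0,
}

# a mirror image (-phi) is an allowed symmetry operation only for ends with
# D1 symmetry; D2 denotes the two-fold rotation already captured by the period
_HAS_MIRROR = {"C1C1": False, "C1D1": True, "C1D2": False,
               "D1D1": True, "D1D2": True, "D2D2": False}


def pair_class(label_a: SymmetryLabel, label_b: SymmetryLabel) -> str:
    """Unordered pair class of two end labels; D3 collapses to D1."""
    collapse = {"C1": "C1", "D1": "D1", "D2": "D2", "D3": "D1"}
    try:
        a, b = collapse[label_a], collapse[label_b]
    except KeyError as exc:
        raise ValueError(f"unknown symmetry label {exc.args[0]!r}") from None
    rank = {"C1": 0, "D1": 1, "D2": 2}
    a, b = sorted((a, b), key=rank.get)
    return a + b


def pair_period(pair: str) -> float:
    if pair not in _PERIOD:
        raise ValueError(f"unknown pair class {pair!r}")
    return _PERIOD[pair]


# ---------------------------------------------------------------------------
# end classification (topological)
# ---------------------------------------------------------------------------

def _is_planar_type(graph: MolecularGraph, idx: int) -> bool:
    atom = graph.atoms[idx]
    if atom.aromatic or atom.sp2_nitrogen:
        return True
    return any(b.order >= 2 for b in graph.bonds_of(idx))


def classify_end(graph: MolecularGraph, central_bond: GraphBond, end_atom: int) -> SymmetryLabel:
    """Topological symmetry of one end of a rotatable bond.

    Branch equivalence is decided by canonical rooted branch codes
    (:func:`torsionforge.torsion_id.branch_code`), so the classification is
    purely graph-based; geometry is never consulted.
    """
    if end_atom not in (central_bond.a1, central_bond.a2):
        raise ValueError("end_atom must be an endpoint of the central bond")
    if not graph.perceived:
        perceive_all(graph)
    other = central_bond.other(end_atom)
    branches = [a for a in graph.neighbors(end_atom) if a != other]
    if not branches:
        raise ValueError("terminal end atom: no dihedral definable")
    codes = sorted(branch_code(graph, b, end_atom) for b in branches)
    n = len(branches)
    all_equal = len(set(codes)) == 1
    if n == 3 and all_equal:
        return "D3"
    if n == 2 and all_equal:
        return "D2" if _is_planar_type(graph, end_atom) else "D1"
    if n == 3 and len(set(codes)) == 2:
        return "D1"  # two equivalent + one distinct: mirror through the odd branch
    if n == 1:
        return "D1"  # single branch: mirror through the central-bond plane
    return "C1"


# ---------------------------------------------------------------------------
# deviation folding
# ---------------------------------------------------------------------------

def wrap_angle(phi: float) -> float:
    """Wrap an angle to (-180, 180]."""
    w = math.fmod(phi, 360.0)
    if w <= -180.0:
        w += 360.0
    elif w > 180.0:
        w -= 360.0
    return w


def fold_deviation(phi: float, pair: str) -> float:
    """Literal piecewise symmetry mapping of a raw deviation in [-180, 180].

    C1C1/C1D1: phi + 360 for phi < 0, else phi.
    C1D2:      phi + 180 for phi < 0, else phi.
    D1D1:      |phi|.
    D1D2/D2D2: phi + 180 for phi < 0; 180 - phi for phi > 90; else phi.
    """
    if not (-180.0 <= phi <= 180.0):
        raise ValueError(f"raw deviation must lie in [-180, 180], got {phi}")
    if pair not in _PERIOD:
        raise ValueError(f"unknown pair class {pair!r}")
    if pair in ("C1C1", "C1D1"):
        return phi + 360.0 if phi < 0 else phi
    if pair == "C1D2":
        return phi + 180.0 if phi < 0 else phi
    if pair == "D1D1":
        return abs(phi)
    # D1D2 / D2D2; the printed mapping leaves 0 <= phi <= 90 implicit (identity)
    if phi < 0:
        return phi + 180.0
    if phi > 90.0:
        return 180.0 - phi
    return phi


def effective_deviation(phi_ref: float, phi_pred: float, pair: str) -> float:
    """Distance from ``phi_ref`` to the nearest symmetry image of ``phi_pred``.

    Images are ``s * phi_pred + k * P`` with period P from the pair class and
    the mirror ``s = -1`` allowed only for pairs containing a D1 end.  The
    result lies in [0, P/2].
    """
    period = pair_period(pair)
    signs = (1.0, -1.0) if _HAS_MIRROR[pair] else (1.0,)
    best = math.inf
    for s in signs:
        d = phi_ref - s * phi_pred
        r = math.fmod(d, period)
        r = min(abs(r), period - abs(r))
        best = min(best, r)
    return best


@dataclass
class TorsionDeviation:
    raw: float  # wrapped raw deviation, degrees in (-180, 180]
    pair: str
    folded: float  # literal piecewise mapping of the raw deviation
    effective: float  # nearest-symmetry-image distance, in [0, period/2]
    exceeds: bool


def deviation_exceeds(
    phi_ref: float, phi_pred: float, pair: str, threshold: float = 30.0
) -> TorsionDeviation:
    """Symmetry-corrected wrongness test for a predicted dihedral.

    The flag compares the *effective* deviation against the threshold; the
    literal folded value is reported alongside for diagnostics.
    """
    if not (math.isfinite(phi_ref) and math.isfinite(phi_pred)):
        raise ValueError("angles must be finite")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    raw = wrap_angle(phi_ref - phi_pred)
    folded = fold_deviation(raw, pair)
    eff = effective_deviation(phi_ref, phi_pred, pair)
    return TorsionDeviation(raw, pair, folded, eff, eff > threshold)
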