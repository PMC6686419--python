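"""Canonical torsion identifiers for rotatable bonds.

A TorsionID is a canonical string describing a rotatable bond and its
immediate chemical environment: for every fragment atom the element,
aromaticity, neighbour count and (for nitrogen) an sp2 flag; for every
fragment bond the order and a delocalization flag.  Two bonds embedded in
locally identical environments receive identical strings regardless of atom
input order, which makes the ID usable as a key for statistics over torsion
angles ("which torsion environments does a force field systematically get
wrong?").

Perception rules implemented here, on purpose, from scratch:

* aromaticity — Hückel 4n+2 counting per ring, applied only to rings of
  size <= 7 inside isolated (fused) ring systems;
* delocalized bonds — bonds of 6-membered aromatic rings; 5-membered
  heteroaromatic rings are *not* regarded as delocalized;
* sp2 nitrogens — aromatic N, amide N, enamine N, or N in resonance with an
  aromatic ring; a nitrogen whose aryl neighbour carries substituents on
  both ortho positions is assumed twisted out of plane and is not flagged.

TorsionIDs are assignable to bonds that are single, non-aromatic, not in a
ring of <= 5 members, and around which a dihedral can be defined (both ends
non-terminal).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from rdkit import Chem

__all__ = [
    "GraphAtom",
    "GraphBond",
    "MolecularGraph",
    "TorsionFragment",
    "TorsionIdError",
    "perceive_aromaticity",
    "flag_delocalized_bonds",
    "flag_sp2_nitrogens",
    "perceive_all",
    "detect_assignable_bonds",
    "extract_fragment",
    "encode",
    "decode",
    "branch_code",
    "assign_mmff_types",
]


class TorsionIdError(ValueError):
    pass


@dataclass
class GraphAtom:
    element: str
    charge: int = 0
    ring_sizes: list[int] = field(default_factory=list)
    aromatic: bool = False
    sp2_nitrogen: bool = False


@dataclass
class GraphBond:
    a1: int
    a2: int
    order: int = 1  # Kekulé order in {1, 2, 3}
    aromatic: bool = False
    delocalized: bool = False
    stereo: str = ""  # "", "E" or "Z"

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1


class MolecularGraph:
    """Light molecular graph with explicit hydrogens and Kekulé bond orders."""

    def __init__(self, atoms: list[GraphAtom], bonds: list[GraphBond],
                 rings: list[list[int]] | None = None, name: str = ""):
        self.atoms = atoms
        self.bonds = bonds
        self.name = name
        self.rings = rings if rings is not None else []
        self.perceived = False
        self._adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
        self._bond_index: dict[tuple[int, int], int] = {}
        for bi, b in enumerate(bonds):
            self._adj[b.a1].append(bi)
            self._adj[b.a2].append(bi)
            self._bond_index[(b.a1, b.a2)] = bi
            self._bond_index[(b.a2, b.a1)] = bi
        for at_idx, at in enumerate(atoms):
            at.ring_sizes = sorted(
                len(r) for r in self.rings if at_idx in r
            )

    # -- construction -------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "") -> "MolecularGraph":
        """Build from an RDKit molecule (hydrogens made explicit, Kekulé orders)."""
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        kek = Chem.Mol(mol)
        Chem.Kekulize(kek, clearAromaticFlags=True)
        atoms = [
            GraphAtom(a.GetSymbol(), a.GetFormalCharge()) for a in kek.GetAtoms()
        ]
        stereo_map = {
            Chem.BondStereo.STEREOE: "E",
            Chem.BondStereo.STEREOZ: "Z",
        }
        bonds = []
        for b in kek.GetBonds():
            order = int(round(b.GetBondTypeAsDouble()))
            bonds.append(
                GraphBond(
                    b.GetBeginAtomIdx(),
                    b.GetEndAtomIdx(),
                    order=order,
                    stereo=stereo_map.get(b.GetStereo(), ""),
                )
            )
        rings = [list(r) for r in mol.GetRingInfo().AtomRings()]
        g = cls(atoms, bonds, rings=rings, name=name or mol.GetProp("_Name")
                if mol.HasProp("_Name") else name)
        g.rdkit_mol = mol
        return g

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise TorsionIdError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol, name=name)

    # -- basic queries -------------------------------------------------------
    def neighbors(self, idx: int) -> list[int]:
        return [self.bonds[bi].other(idx) for bi in self._adj[idx]]

    def degree(self, idx: int) -> int:
        return len(self._adj[idx])

    def bond_between(self, a: int, b: int) -> GraphBond | None:
        bi = self._bond_index.get((a, b))
        return None if bi is None else self.bonds[bi]

    def bonds_of(self, idx: int) -> list[GraphBond]:
        return [self.bonds[bi] for bi in self._adj[idx]]

    def in_ring_of_size_leq(self, bond: GraphBond, size: int) -> bool:
        for r in self.rings:
            if len(r) <= size and bond.a1 in r and bond.a2 in r:
                rs = set(r)
                # both endpoints in the ring is enough only if the bond is a
                # ring bond (consecutive members)
                n = len(r)
                for t in range(n):
                    a, b = r[t], r[(t + 1) % n]
                    if {a, b} == {bond.a1, bond.a2}:
                        return True
        return False

    def is_ring_bond(self, bond: GraphBond) -> bool:
        for r in self.rings:
            n = len(r)
            for t in range(n):
                a, b = r[t], r[(t + 1) % n]
                if {a, b} == {bond.a1, bond.a2}:
                    return True
        return False


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

_PI_LONE_PAIR = {"N", "O", "S", "Se", "P"}


def _ring_systems(graph: MolecularGraph) -> list[set[int]]:
    """Isolated ring systems = connected components of ring atoms via ring bonds."""
    ring_atoms = set()
    for r in graph.rings:
        ring_atoms.update(r)
    systems: list[set[int]] = []
    seen: set[int] = set()
    for start in ring_atoms:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            a = stack.pop()
            for b in graph.neighbors(a):
                if b in ring_atoms and b not in comp:
                    bond = graph.bond_between(a, b)
                    if bond is not None and graph.is_ring_bond(bond):
                        comp.add(b)
                        stack.append(b)
        seen |= comp
        systems.append(comp)
    return systems


def _pi_contribution(graph: MolecularGraph, idx: int, ring: set[int]) -> int | None:
    """Hückel pi-electron contribution of a ring atom, or None if sp3-like."""
    atom = graph.atoms[idx]
    double_in_ring = any(
        b.order == 2 and b.other(idx) in ring for b in graph.bonds_of(idx)
    )
    double_exo = any(
        b.order == 2 and b.other(idx) not in ring for b in graph.bonds_of(idx)
    )
    if double_in_ring:
        return 1
    if double_exo:
        # carbonyl-like: empty p orbital toward the exocyclic pi system
        return 0
    if atom.element in _PI_LONE_PAIR:
        return 2  # pyrrole/furan/thiophene-type lone pair
    if atom.element == "C" and atom.charge == -1:
        return 2
    if atom.element == "C" and atom.charge == 1:
        return 0
    return None  # saturated centre breaks conjugation


def perceive_aromaticity(graph: MolecularGraph) -> MolecularGraph:
    """Flag aromatic atoms/bonds: Hückel 4n+2, ring size <= 7 only."""
    for ring in graph.rings:
        if len(ring) > 7:
            continue
        rset = set(ring)
        contribs = [_pi_contribution(graph, a, rset) for a in ring]
        if any(c is None for c in contribs):
            continue
        n_pi = sum(contribs)
        if n_pi >= 2 and (n_pi - 2) % 4 == 0:
            for a in ring:
                graph.atoms[a].aromatic = True
            n = len(ring)
            for t in range(n):
                bond = graph.bond_between(ring[t], ring[(t + 1) % n])
                if bond is not None:
                    bond.aromatic = True
    return graph


def flag_delocalized_bonds(graph: MolecularGraph) -> MolecularGraph:
    """Flag bonds of 6-membered aromatic rings as delocalized.

    Five-membered heteroaromatic rings keep their Kekulé orders.
    """
    for ring in graph.rings:
        if len(ring) != 6:
            continue
        if not all(graph.atoms[a].aromatic for a in ring):
            continue
        n = len(ring)
        if not all(
            (b := graph.bond_between(ring[t], ring[(t + 1) % n])) is not None
            and b.aromatic
            for t in range(n)
        ):
            continue
        for t in range(n):
            graph.bond_between(ring[t], ring[(t + 1) % n]).delocalized = True
    return graph


def _ortho_blocked(graph: MolecularGraph, n_idx: int, aryl_idx: int) -> bool:
    """True when both ortho positions of the aryl neighbour carry non-H substituents."""
    ring = None
    for r in graph.rings:
        if aryl_idx in r and all(graph.atoms[a].aromatic for a in r):
            ring = r
            break
    if ring is None:
        return False
    rset = set(ring)
    ortho = [a for a in graph.neighbors(aryl_idx) if a in rset]
    blocked = 0
    for o in ortho:
        subs = [
            a for a in graph.neighbors(o)
            if a not in rset and a != aryl_idx and graph.atoms[a].element != "H"
        ]
        if subs:
            blocked += 1
    return len(ortho) >= 2 and blocked == len(ortho)


def flag_sp2_nitrogens(graph: MolecularGraph) -> MolecularGraph:
    """Flag nitrogens expected to be planar (sp2).

    Conditions: aromatic N; amide N (bonded to a C doubly bonded to O);
    enamine N (bonded to a C doubly bonded to C); N in resonance with an
    aromatic ring — unless both ortho positions of that ring atom carry
    non-hydrogen substituents, which twists the nitrogen out of plane.
    """
    for idx, atom in enumerate(graph.atoms):
        if atom.element != "N":
            continue
        if atom.aromatic:
            atom.sp2_nitrogen = True
            continue
        flagged = False
        for nb in graph.neighbors(idx):
            nb_atom = graph.atoms[nb]
            if nb_atom.element == "C" and not nb_atom.aromatic:
                for b in graph.bonds_of(nb):
                    far = b.other(nb)
                    if far == idx or b.order != 2:
                        continue
                    if graph.atoms[far].element == "O":
                        flagged = True  # amide
                    elif graph.atoms[far].element == "C":
                        flagged = True  # enamine
            if not flagged and nb_atom.aromatic:
                if not _ortho_blocked(graph, idx, nb):
                    flagged = True  # aryl resonance
        atom.sp2_nitrogen = flagged
    return graph


def perceive_all(graph: MolecularGraph) -> MolecularGraph:
    perceive_aromaticity(graph)
    flag_delocalized_bonds(graph)
    flag_sp2_nitrogens(graph)
    graph.perceived = True
    return graph


# ---------------------------------------------------------------------------
# assignability and fragment extraction
# ---------------------------------------------------------------------------

def detect_assignable_bonds(graph: MolecularGraph) -> list[GraphBond]:
    """Bonds a TorsionID can be assigned to.

    Single, non-aromatic, not in a ring of <= 5 members, and both endpoints
    have at least two neighbours (a dihedral must be definable).
    """
    if not graph.perceived:
        perceive_all(graph)
    out = []
    for b in graph.bonds:
        if b.order != 1 or b.aromatic:
            continue
        if graph.in_ring_of_size_leq(b, 5):
            continue
        if graph.degree(b.a1) < 2 or graph.degree(b.a2) < 2:
            continue
        out.append(b)
    return out


def _is_linear_sp(graph: MolecularGraph, idx: int) -> bool:
    """Linear (sp) atom: degree 2 with a triple bond or two double bonds."""
    if graph.degree(idx) != 2:
        return False
    orders = sorted(b.order for b in graph.bonds_of(idx))
    return orders == [1, 3] or orders == [2, 2] or orders == [3, 3]


@dataclass
class FragmentAtom:
    element: str
    aromatic: bool
    sp2_nitrogen: bool
    n_neighbors: int  # neighbour count in the parent molecule, H inclusive
    charge: int = 0

    def descriptor(self) -> str:
        flags = []
        if self.aromatic:
            flags.append("a")
        if self.sp2_nitrogen:
            flags.append("N2")
        if self.charge:
            flags.append(f"{'+' if self.charge > 0 else '-'}{abs(self.charge)}")
        flags.append(f"n{self.n_neighbors}")
        return f"{self.element}[{','.join(flags)}]"


_BOND_TOKENS = {1: "-", 2: "=", 3: "#"}
_TOKEN_ORDERS = {v: k for k, v in _BOND_TOKENS.items()}
_TOKEN_ORDERS[":"] = 1


def _bond_token(bond_order: int, delocalized: bool, stereo: str = "") -> str:
    if delocalized:
        return ":"
    tok = _BOND_TOKENS[bond_order]
    if stereo and bond_order == 2:
        tok += stereo
    return tok


@dataclass
class TorsionFragment:
    """Local environment of a rotatable bond, ready for canonical encoding.

    ``chain`` holds the central atoms: two entries in the common case, more
    when the rotor sits on a consecutive sp-atom chain (then every linear
    atom belongs to the chain and the two chain-end atoms carry the
    substituent shells).  ``shells[t]`` lists (bond token, FragmentAtom)
    substituents of chain atom t; linear interior atoms carry empty shells.
    """

    chain: list[FragmentAtom]
    chain_bonds: list[str]  # bond token between chain[t] and chain[t+1]
    shells: list[list[tuple[str, "FragmentAtom"]]]
    central_index: int = 0  # chain bond index of the rotatable bond

    @property
    def n_atoms(self) -> int:
        return len(self.chain) + sum(len(s) for s in self.shells)


def extract_fragment(graph: MolecularGraph, bond: GraphBond) -> TorsionFragment:
    """Central-bond atoms + their direct neighbours; sp-chains are followed."""
    if not graph.perceived:
        perceive_all(graph)
    if bond not in detect_assignable_bonds(graph):
        raise TorsionIdError("fragment extraction requires an assignable bond")

    def walk(start: int, prev: int) -> list[int]:
        # follow consecutive linear sp atoms away from the bond
        path = []
        cur, last = start, prev
        while _is_linear_sp(graph, cur):
            path.append(cur)
            nxt = [a for a in graph.neighbors(cur) if a != last]
            if not nxt:
                break
            last, cur = cur, nxt[0]
        path.append(cur)  # chain end (first non-linear atom)
        return path

    left = walk(bond.a1, bond.a2)[::-1]  # ... end_left ... a1
    right = walk(bond.a2, bond.a1)  # a2 ... end_right
    chain_idx = left + right
    central_index = len(left) - 1

    def frag_atom(idx: int) -> FragmentAtom:
        a = graph.atoms[idx]
        return FragmentAtom(a.element, a.aromatic, a.sp2_nitrogen,
                            graph.degree(idx), a.charge)

    chain = [frag_atom(i) for i in chain_idx]
    chain_bonds = []
    for t in range(len(chain_idx) - 1):
        b = graph.bond_between(chain_idx[t], chain_idx[t + 1])
        chain_bonds.append(_bond_token(b.order, b.delocalized, b.stereo))
    shells: list[list[tuple[str, FragmentAtom]]] = []
    chain_set = set(chain_idx)
    for pos, idx in enumerate(chain_idx):
        if 0 < pos < len(chain_idx) - 1:
            shells.append([])  # interior (linear) atoms carry no shell
            continue
        shell = []
        for nb in graph.neighbors(idx):
            if nb in chain_set:
                continue
            b = graph.bond_between(idx, nb)
            shell.append((_bond_token(b.order, b.delocalized, b.stereo), frag_atom(nb)))
        shells.append(shell)
    return TorsionFragment(chain, chain_bonds, shells, central_index)


# ---------------------------------------------------------------------------
# canonical encode / decode
# ---------------------------------------------------------------------------

def _render(fragment: TorsionFragment, reverse: bool) -> str:
    chain = fragment.chain[::-1] if reverse else fragment.chain
    shells = fragment.shells[::-1] if reverse else fragment.shells
    cbonds = fragment.chain_bonds[::-1] if reverse else fragment.chain_bonds
    cidx = (
        len(fragment.chain_bonds) - 1 - fragment.central_index
        if reverse
        else fragment.central_index
    )
    parts = []
    for t, atom in enumerate(chain):
        unit = atom.descriptor()
        if shells[t]:
            branches = sorted(tok + a.descriptor() for tok, a in shells[t])
            unit += "(" + ",".join(branches) + ")"
        parts.append(unit)
        if t < len(cbonds):
            tok = cbonds[t]
            parts.append(f"({tok})" if t == cidx else tok)
    return "".join(parts)


def encode(fragment: TorsionFragment) -> str:
    """Canonical TorsionID string: the lexicographically smaller direction,
    with substituent branches in sorted order."""
    return min(_render(fragment, False), _render(fragment, True))


_ATOM_RE = re.compile(r"([A-Z][a-z]?)\[([^\]]*)\]")
_BOND_RE = re.compile(r"(:|#|=(?:E|Z)?|-)")


def _parse_atom(s: str, pos: int) -> tuple[FragmentAtom, int]:
    m = _ATOM_RE.match(s, pos)
    if not m:
        raise TorsionIdError(f"malformed TorsionID at position {pos}: expected atom")
    element, flag_str = m.group(1), m.group(2)
    aromatic = sp2n = False
    charge = 0
    n_nb = None
    for f in flag_str.split(","):
        if f == "a":
            aromatic = True
        elif f == "N2":
            sp2n = True
        elif f.startswith(("+", "-")):
            charge = int(f[1:]) * (1 if f[0] == "+" else -1)
        elif f.startswith("n"):
            n_nb = int(f[1:])
        else:
            raise TorsionIdError(f"malformed TorsionID at position {pos}: flag {f!r}")
    if n_nb is None:
        raise TorsionIdError(f"malformed TorsionID at position {pos}: missing neighbour count")
    return FragmentAtom(element, aromatic, sp2n, n_nb, charge), m.end()


def decode(torsion_id: str) -> TorsionFragment:
    """Parse a TorsionID string back into a fragment.

    Raises :class:`TorsionIdError` carrying the position of the first
    grammar violation.
    """
    s = torsion_id
    pos = 0
    chain: list[FragmentAtom] = []
    chain_bonds: list[str] = []
    shells: list[list[tuple[str, FragmentAtom]]] = []
    central_index = None
    while pos < len(s):
        atom, pos = _parse_atom(s, pos)
        shell: list[tuple[str, FragmentAtom]] = []
        if pos < len(s) and s[pos] == "(" and not _is_central_marker(s, pos):
            pos += 1
            while True:
                m = _BOND_RE.match(s, pos)
                if not m:
                    raise TorsionIdError(
                        f"malformed TorsionID at position {pos}: expected bond token")
                tok = m.group(1)
                nb, pos2 = _parse_atom(s, m.end())
                shell.append((tok, nb))
                pos = pos2
                if pos >= len(s):
                    raise TorsionIdError(
                        f"malformed TorsionID at position {pos}: unterminated branch list")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise TorsionIdError(
                    f"malformed TorsionID at position {pos}: expected ',' or ')'")
        chain.append(atom)
        shells.append(shell)
        if pos >= len(s):
            break
        if s[pos] == "(":  # central bond marker
            m = _BOND_RE.match(s, pos + 1)
            if not m or m.end() >= len(s) or s[m.end()] != ")":
                raise TorsionIdError(
                    f"malformed TorsionID at position {pos}: bad central-bond marker")
            if central_index is not None:
                raise TorsionIdError(
                    f"malformed TorsionID at position {pos}: duplicate central bond")
            central_index = len(chain_bonds)
            chain_bonds.append(m.group(1))
            pos = m.end() + 1
        else:
            m = _BOND_RE.match(s, pos)
            if not m:
                raise TorsionIdError(
                    f"malformed TorsionID at position {pos}: expected bond token")
            chain_bonds.append(m.group(1))
            pos = m.end()
    if len(chain) < 2 or central_index is None:
        raise TorsionIdError(
            f"malformed TorsionID at position {len(s)}: no central bond found")
    frag = TorsionFragment(chain, chain_bonds, shells, central_index)
    return frag


def _is_central_marker(s: str, pos: int) -> bool:
    """True if '(' at pos opens a central-bond marker like '(-)' rather than a shell."""
    m = _BOND_RE.match(s, pos + 1)
    return bool(m) and m.end() < len(s) and s[m.end()] == ")"


def torsion_id_for_bond(graph: MolecularGraph, bond: GraphBond) -> str:
    return encode(extract_fragment(graph, bond))


# ---------------------------------------------------------------------------
# rooted branch codes (used by symmetry classification)
# ---------------------------------------------------------------------------

def branch_code(graph: MolecularGraph, root: int, excluded: int, n_iter: int | None = None) -> str:
    """Canonical code of the branch rooted at ``root`` with ``excluded`` removed.

    Weisfeiler–Lehman style iterative label refinement on the graph minus the
    excluded atom; the returned code is the stable label of the root.  Two
    branches with equal codes are topologically equivalent substituents of
    the excluded atom (up to hash collision, which WL refinement makes
    vanishingly unlikely for molecular graphs).
    """
    nodes = [i for i in range(len(graph.atoms)) if i != excluded]
    if root == excluded or root not in nodes:
        raise ValueError("root must differ from the excluded atom")
    labels = {}
    for i in nodes:
        a = graph.atoms[i]
        labels[i] = f"{a.element}|{a.charge}|{graph.degree(i)}|{int(a.aromatic)}"

    def bond_label(i: int, j: int) -> str:
        b = graph.bond_between(i, j)
        # delocalized bonds form one equivalence class: their Kekulé orders
        # are artefacts that would break ring symmetry
        return "d" if b.delocalized else str(b.order)

    if n_iter is None:
        n_iter = len(nodes)
    history = [labels[root]]
    for _ in range(n_iter):
        new_labels = {}
        for i in nodes:
            nb_sig = sorted(
                f"{bond_label(i, j)}:{labels[j]}"
                for j in graph.neighbors(i)
                if j != excluded
            )
            digest = hashlib.sha1(
                (labels[i] + "||" + ";".join(nb_sig)).encode()
            ).hexdigest()[:16]
            new_labels[i] = digest
        if new_labels == labels:
            break
        labels = new_labels
        history.append(labels[root])
    return "/".join(history)


# ---------------------------------------------------------------------------
# minimal MMFF numeric typing for the atom types used by the shipped tables
# ---------------------------------------------------------------------------

def assign_mmff_types(graph: MolecularGraph) -> dict[int, int]:
    """Map atoms to the handful of MMFF94 numeric types the parameter tables use.

    Covered: 3 (amide carbonyl C), 10 (amide N), 28 (amide H), 37 (aromatic C
    in a 6-ring), 39 (pyrrole-type aromatic N), 44 (thiophene S), 63/64
    (alpha/beta C of a 5-ring heteroaromatic), 65/66 (alpha/beta aromatic
    5-ring N).  Atoms outside these environments are absent from the result;
    full MMFF typing is out of scope.
    """
    if not graph.perceived:
        perceive_all(graph)
    types: dict[int, int] = {}
    aromatic_5rings = [
        r for r in graph.rings
        if len(r) == 5 and all(graph.atoms[a].aromatic for a in r)
    ]

    def ring_pivot(ring: list[int]) -> int | None:
        # the lone-pair donor of the 5-ring: N with 3 neighbours, or O/S
        for a in ring:
            el = graph.atoms[a].element
            if el in ("O", "S") or (el == "N" and graph.degree(a) == 3):
                return a
        return None

    for ring in aromatic_5rings:
        pivot = ring_pivot(ring)
        rset = set(ring)
        for a in ring:
            el = graph.atoms[a].element
            alpha = pivot is not None and a in graph.neighbors(pivot)
            if a == pivot:
                if el == "S":
                    types[a] = 44
                elif el == "N":
                    types[a] = 39
            elif el == "C":
                types[a] = 63 if alpha else 64
            elif el == "N":
                types[a] = 65 if alpha else 66
    for idx, atom in enumerate(graph.atoms):
        if idx in types:
            continue
        if atom.element == "C" and atom.aromatic and 6 in atom.ring_sizes:
            types[idx] = 37
        elif atom.element == "C" and not atom.aromatic:
            has_o_double = any(
                b.order == 2 and graph.atoms[b.other(idx)].element == "O"
                for b in graph.bonds_of(idx)
            )
            has_n = any(graph.atoms[a].element == "N" for a in graph.neighbors(idx))
            if has_o_double and has_n:
                types[idx] = 3
        elif atom.element == "N" and not atom.aromatic:
            if any(
                graph.atoms[nb].element == "C"
                and any(
                    b.order == 2 and graph.atoms[b.other(nb)].element == "O"
                    for b in graph.bonds_of(nb)
                )
                for nb in graph.neighbors(idx)
            ):
                types[idx] = 10
    for idx, atom in enumerate(graph.atoms):
        if atom.element == "H":
            nbs = graph.neighbors(idx)
            if nbs and types.get(nbs[0]) == 10:
                types[idx] = 28
    return types
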