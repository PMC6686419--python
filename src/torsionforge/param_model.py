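"""Torsion energy term and torsion parameter tables.

The torsional energy of an atom quadruple i-j-k-l is modelled as a
three-term cosine series

    ET(phi) = 0.5 * (V1 (1 + cos phi) + V2 (1 - cos 2 phi) + V3 (1 + cos 3 phi))

with barrier heights V1 (onefold), V2 (twofold) and V3 (threefold) in
kcal/mol.  Parameters are keyed by a torsion-type index ``tt`` and the four
MMFF94 numeric atom types of the quadruple; atom type 0 is a wildcard that
matches any type at a terminal (i or l) position.  Two parameter tables ship
with the package: the original MMFF94s wildcard record for N-aryl amides and
the newly fitted set for N-aryl amides and phenylpyrroles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TorsionParamRecord",
    "ParamTable",
    "EnergyProfile",
    "MissingParameterError",
    "torsion_energy",
    "lookup",
    "compute_profile",
    "barrier_height",
    "canonical_quadruple",
    "load_param_table",
    "original_table",
    "new_table",
    "KCAL_PER_KJ",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184
KCAL_PER_KJ = 1.0 / KJ_PER_KCAL


class MissingParameterError(KeyError):
    """Raised when no parameter record (wildcard included) matches a quadruple."""

    def __init__(self, tt: int, quad: tuple[int, int, int, int]):
        self.tt = tt
        self.quad = quad
        super().__init__(
            f"no torsion parameter for tt={tt} quadruple "
            f"{quad[0]}-{quad[1]}-{quad[2]}-{quad[3]} (wildcard fallback exhausted)"
        )


def canonical_quadruple(i: int, j: int, k: int, l: int) -> tuple[int, int, int, int]:
    """Orient a quadruple so that j < k, or j == k and i <= l.

    The reversed quadruple l-k-j-i denotes the same torsion, so one of the two
    orientations is picked as the storage/lookup key.
    """
    if j > k or (j == k and i > l):
        return (l, k, j, i)
    return (i, j, k, l)


@dataclass(frozen=True)
class TorsionParamRecord:
    """One torsion parameter line: type index, quadruple and (V1, V2, V3)."""

    tt: int
    i: int
    j: int
    k: int
    l: int
    v1: float
    v2: float
    v3: float
    provenance: str = "new"  # {"original", "new"}

    def __post_init__(self):
        for t in (self.tt, self.i, self.j, self.k, self.l):
            if not isinstance(t, int) or t < 0:
                raise ValueError(f"atom types and tt must be integers >= 0, got {t!r}")
        quad = canonical_quadruple(self.i, self.j, self.k, self.l)
        if quad != (self.i, self.j, self.k, self.l):
            object.__setattr__(self, "i", quad[0])
            object.__setattr__(self, "j", quad[1])
            object.__setattr__(self, "k", quad[2])
            object.__setattr__(self, "l", quad[3])

    @property
    def key(self) -> tuple[int, int, int, int, int]:
        return (self.tt, self.i, self.j, self.k, self.l)

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.v1, self.v2, self.v3)


class ParamTable:
    """A set of torsion parameter records with wildcard-aware lookup."""

    def __init__(self, records: Iterable[TorsionParamRecord] = (), name: str = ""):
        self.name = name
        self._records: dict[tuple[int, int, int, int, int], TorsionParamRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: TorsionParamRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate torsion parameter key {rec.key}")
        self._records[rec.key] = rec

    @property
    def records(self) -> list[TorsionParamRecord]:
        return list(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: tuple[int, int, int, int, int]) -> bool:
        tt, i, j, k, l = key
        return (tt, *canonical_quadruple(i, j, k, l)) in self._records

    def get_exact(self, tt: int, i: int, j: int, k: int, l: int) -> TorsionParamRecord | None:
        return self._records.get((tt, *canonical_quadruple(i, j, k, l)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParamTable(name={self.name!r}, n={len(self)})"


def lookup(table: ParamTable, tt: int, i: int, j: int, k: int, l: int) -> TorsionParamRecord:
    """Resolve a concrete quadruple against a table with staged wildcard fallback.

    Resolution order after canonical orientation: (1) exact ``tt-i-j-k-l``;
    (2) single-end wildcards ``tt-0-j-k-l`` then ``tt-i-j-k-0``; (3) double
    wildcard ``tt-0-j-k-0``.  The first hit wins.

    Raises
    ------
    MissingParameterError
        if no stage matches.
    ValueError
        if the query itself contains wildcards (type 0).
    """
    if 0 in (i, j, k, l):
        raise ValueError("lookup queries must not contain wildcard atom types")
    if len(table) == 0:
        raise MissingParameterError(tt, canonical_quadruple(i, j, k, l))
    ci, cj, ck, cl = canonical_quadruple(i, j, k, l)
    for qi, qj, qk, ql in (
        (ci, cj, ck, cl),
        (0, cj, ck, cl),
        (ci, cj, ck, 0),
        (0, cj, ck, 0),
    ):
        rec = table.get_exact(tt, qi, qj, qk, ql)
        if rec is not None:
            return rec
    raise MissingParameterError(tt, (ci, cj, ck, cl))


def torsion_energy(v1: float, v2: float, v3: float, phi: float) -> float:
    """Three-term cosine torsion energy at dihedral ``phi`` (degrees), kcal/mol.

    Periodic with period 360 deg and even in phi.  E(0) = V1 + V3 and
    E(180) = 0 hold exactly.
    """
    for x in (v1, v2, v3, phi):
        if not math.isfinite(x):
            raise ValueError(f"non-finite input to torsion_energy: {x!r}")
    rad = math.radians(phi)
    return 0.5 * (
        v1 * (1.0 + math.cos(rad))
        + v2 * (1.0 - math.cos(2.0 * rad))
        + v3 * (1.0 + math.cos(3.0 * rad))
    )


@dataclass
class EnergyProfile:
    """A 1D torsion profile: angles (degrees, strictly increasing) + energies."""

    angles: list[float]
    energies: list[float]
    unit: str = "kcal/mol"

    def __post_init__(self):
        self.angles = [float(a) for a in self.angles]
        self.energies = [float(e) for e in self.energies]
        if len(self.angles) != len(self.energies):
            raise ValueError("angles and energies must have equal length")
        if not self.angles:
            raise ValueError("profile must contain at least one point")
        if any(b <= a for a, b in zip(self.angles, self.angles[1:])):
            raise ValueError("angles must be strictly increasing")
        if any(a < -180.0 or a > 360.0 for a in self.angles):
            raise ValueError("angles must lie within [-180, 360] degrees")
        if self.unit not in ("kcal/mol", "kJ/mol"):
            raise ValueError(f"unknown energy unit {self.unit!r}")

    def to_unit(self, unit: str) -> "EnergyProfile":
        if unit == self.unit:
            return EnergyProfile(list(self.angles), list(self.energies), self.unit)
        if unit == "kJ/mol" and self.unit == "kcal/mol":
            factor = KJ_PER_KCAL
        elif unit == "kcal/mol" and self.unit == "kJ/mol":
            factor = KCAL_PER_KJ
        else:
            raise ValueError(f"unknown energy unit {unit!r}")
        return EnergyProfile(list(self.angles), [e * factor for e in self.energies], unit)

    def relative(self) -> "EnergyProfile":
        """Shift so that the minimum over the grid is zero."""
        m = min(self.energies)
        return EnergyProfile(list(self.angles), [e - m for e in self.energies], self.unit)


def compute_profile(
    record: TorsionParamRecord | tuple[float, float, float],
    grid: Sequence[float],
    relative: bool = False,
) -> EnergyProfile:
    """Evaluate the torsion term of one record over an angle grid (degrees)."""
    if isinstance(record, TorsionParamRecord):
        v1, v2, v3 = record.triple
    else:
        v1, v2, v3 = record
    energies = [torsion_energy(v1, v2, v3, a) for a in grid]
    profile = EnergyProfile(list(grid), energies)
    return profile.relative() if relative else profile


def barrier_height(profile: EnergyProfile) -> float:
    """Max minus min energy over the profile grid, in the profile's unit."""
    return max(profile.energies) - min(profile.energies)


# ---------------------------------------------------------------------------
# parameter table text format: `TT I J K L V1 V2 V3`, '#' comments
# ---------------------------------------------------------------------------

def load_param_table(path: str | Path, name: str = "", provenance: str = "new") -> ParamTable:
    """Load a whitespace-separated `TT I J K L V1 V2 V3` parameter file."""
    path = Path(path)
    table = ParamTable(name=name or path.stem)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 8:
            raise ValueError(f"{path}:{lineno}: expected 8 fields, got {len(parts)}")
        tt, i, j, k, l = (int(p) for p in parts[:5])
        v1, v2, v3 = (float(p) for p in parts[5:])
        table.add(TorsionParamRecord(tt, i, j, k, l, v1, v2, v3, provenance=provenance))
    return table


def save_param_table(table: ParamTable, path: str | Path, header: str = "") -> None:
    path = Path(path)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for rec in table.records:
        lines.append(
            f"{rec.tt} {rec.i} {rec.j} {rec.k} {rec.l} "
            f"{rec.v1:g} {rec.v2:g} {rec.v3:g}"
        )
    path.write_text("\n".join(lines) + "\n")


def _builtin(fname: str, name: str, provenance: str) -> ParamTable:
    with resources.as_file(resources.files("torsionforge.data") / fname) as p:
        return load_param_table(p, name=name, provenance=provenance)


def original_table() -> ParamTable:
    """The original MMFF94s wildcard record(s) replaced by the refit."""
    return _builtin("mmff94s_patch_original.par", "original", "original")


def new_table() -> ParamTable:
    """The newly fitted torsion parameter set for N-aryl amides and phenylpyrroles."""
    return _builtin("mmff94s_patch_new.par", "new", "new")
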