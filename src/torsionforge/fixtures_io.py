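"""File I/O and synthetic fixtures.

Readers/writers for the package's plain-text interchange formats (SDF/MOL,
SMILES, PES CSV) plus a registry of small fixture molecules — N-aryl
amides, phenylpyrroles and related probes — with annotated ground truth,
and a synthetic PES generator that stands in for quantum-chemistry torsion
scans.  Fixture 3D coordinates were generated once with a distance-geometry
embedder and are frozen in the shipped SDF, so loading them requires no
embedding step and is bit-stable across runs.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .param_model import EnergyProfile
from .torsion_id import MolecularGraph

__all__ = [
    "FixtureMolecule",
    "SyntheticPES",
    "load_molecules",
    "builtin_fixture",
    "fixture_names",
    "synth_pes",
    "write_pes_csv",
    "read_pes_csv",
    "graph_coords",
]

log = logging.getLogger("torsionforge")

_EMBED_SEED = 20190807


# ---------------------------------------------------------------------------
# molecule loading
# ---------------------------------------------------------------------------

def _graph_from_mol(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    return MolecularGraph.from_rdkit(mol, name=name)


def graph_coords(graph: MolecularGraph) -> np.ndarray:
    """3D coordinates (Angstrom) of the molecule underlying a graph."""
    mol = getattr(graph, "rdkit_mol", None)
    if mol is None or mol.GetNumConformers() == 0:
        raise ValueError("graph carries no 3D coordinates")
    return np.array(mol.GetConformer().GetPositions(), dtype=float)


def load_molecules(path: str | Path, fmt: str | None = None) -> list[MolecularGraph]:
    """Load molecules from an SDF or SMILES file into molecular graphs.

    Malformed records are skipped with a logged reason; an unreadable file
    is fatal.  SMILES records get 3D coordinates from a deterministic
    distance-geometry embedding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "smiles" if path.suffix.lower() in (".smi", ".smiles", ".txt") else "sdf"
    fmt = fmt.lower()
    graphs: list[MolecularGraph] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        if len(supplier) == 0:
            log.warning("empty SDF file: %s", path)
        for idx, mol in enumerate(supplier):
            if mol is None:
                log.warning("skipping unparsable SDF record %d in %s", idx, path)
                continue
            graphs.append(_graph_from_mol(mol))
    elif fmt == "smiles":
        text = path.read_text().strip()
        if not text:
            log.warning("empty SMILES file: %s", path)
            return []
        for lineno, line in enumerate(text.splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                log.warning("skipping unparsable SMILES at %s:%d", path, lineno)
                continue
            mol = Chem.AddHs(mol)
            params = AllChem.ETKDGv3()
            params.randomSeed = _EMBED_SEED
            AllChem.EmbedMolecule(mol, params)
            name = parts[1] if len(parts) > 1 else f"mol{lineno}"
            mol.SetProp("_Name", name)
            graphs.append(_graph_from_mol(mol, name=name))
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")
    return graphs


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

@dataclass
class FixtureMolecule:
    """A fixture molecule plus annotated ground truth for perception tests."""

    name: str
    smiles: str
    graph: MolecularGraph
    truth: dict = field(default_factory=dict)


# name -> (SMILES, ground truth). Truth keys:
#   n_assignable        number of TorsionID-assignable bonds
#   central_bond        ("element_a", "element_b") of the bond of interest
#   end_symmetry        expected pair of end symmetry labels for that bond
#   mmff_types_present  subset of MMFF numeric types the mini-typer must find
_REGISTRY: dict[str, tuple[str, dict]] = {
    "n-phenylacetamide": (
        "CC(=O)Nc1ccccc1",
        {
            "n_assignable": 3,
            "central_bond": ("N", "C_aromatic"),
            "end_symmetry": ("C1", "D2"),
            "mmff_types_present": {3, 10, 28, 37},
        },
    ),
    "n-2-pyridylacetamide": (
        "CC(=O)Nc1ccccn1",
        {"n_assignable": 3, "mmff_types_present": {3, 10, 28, 37}},
    ),
    "n-thiophen-2-ylacetamide": (
        "CC(=O)Nc1cccs1",
        {"n_assignable": 3, "mmff_types_present": {3, 10, 28, 44, 63, 64}},
    ),
    "1-phenylpyrrole": (
        "c1ccc(-n2cccc2)cc1",
        {
            "n_assignable": 1,
            "central_bond": ("N", "C_aromatic"),
            "end_symmetry": ("D2", "D2"),
            "mmff_types_present": {37, 39, 63, 64},
        },
    ),
    "1-phenylpyrazole": (
        "c1ccc(-n2cccn2)cc1",
        {"n_assignable": 1, "mmff_types_present": {37, 39, 63, 64, 65}},
    ),
    "ortho-methyl-n-phenylacetamide": (
        "CC(=O)Nc1ccccc1C",
        # acetyl C-C, C(=O)-N, N-aryl and the ortho-methyl rotor
        {"n_assignable": 4, "mmff_types_present": {3, 10, 28, 37}},
    ),
    "n-methyl-n-phenylacetamide": (
        "CC(=O)N(C)c1ccccc1",
        # acetyl C-C, C(=O)-N, N-CH3 and N-aryl
        {"n_assignable": 4, "mmff_types_present": {3, 10, 37}},
    ),
    "ortho-fluoro-n-phenylacetamide": (
        "CC(=O)Nc1ccccc1F",
        {"n_assignable": 3, "mmff_types_present": {3, 10, 28, 37}},
    ),
    "toluene": (
        "Cc1ccccc1",
        {
            "n_assignable": 1,
            "central_bond": ("C", "C_aromatic"),
            "end_symmetry": ("D3", "D2"),
            "mmff_types_present": {37},
        },
    ),
    "biphenyl": (
        "c1ccc(-c2ccccc2)cc1",
        {
            "n_assignable": 1,
            "central_bond": ("C_aromatic", "C_aromatic"),
            "end_symmetry": ("D2", "D2"),
            "mmff_types_present": {37},
        },
    ),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def _load_fixture_sdf() -> dict[str, Chem.Mol]:
    with resources.as_file(resources.files("torsionforge.data") / "fixtures.sdf") as p:
        supplier = Chem.SDMolSupplier(str(p), removeHs=False, sanitize=True)
        return {m.GetProp("_Name"): m for m in supplier if m is not None}


_FIXTURE_MOLS: dict[str, Chem.Mol] | None = None


def builtin_fixture(name: str) -> FixtureMolecule:
    """Return a named fixture molecule with frozen 3D coordinates + ground truth."""
    global _FIXTURE_MOLS
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        )
    if _FIXTURE_MOLS is None:
        _FIXTURE_MOLS = _load_fixture_sdf()
    smiles, truth = _REGISTRY[name]
    mol = _FIXTURE_MOLS[name]
    graph = _graph_from_mol(mol, name=name)
    return FixtureMolecule(name, smiles, graph, dict(truth))


def regenerate_fixture_sdf(path: str | Path) -> None:
    """Re-embed all fixture molecules and write the frozen SDF (maintenance)."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for name in fixture_names():
        smiles, _ = _REGISTRY[name]
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = _EMBED_SEED
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"embedding failed for {name}")
        mol.SetProp("_Name", name)
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# synthetic PES generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPES:
    triples: tuple[tuple[float, float, float], ...]
    grid: tuple[float, ...]
    sigma: float
    seed: int | None
    profile: EnergyProfile


def synth_pes(
    triples,
    grid,
    sigma: float = 0.0,
    seed: int | None = None,
) -> SyntheticPES:
    """Synthetic reference profile: cosine-series sum plus optional noise.

    Energies are the summed three-term cosine series of the given triples
    (evaluated here by direct summation, independently of the profile code
    in :mod:`torsionforge.param_model`), plus N(0, sigma) noise, min-shifted
    to a relative profile.  Seed-reproducible.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    triples = tuple(tuple(float(v) for v in t) for t in triples)
    grid = tuple(float(a) for a in grid)
    energies = []
    for ang in grid:
        rad = ang * math.pi / 180.0
        e = 0.0
        for v1, v2, v3 in triples:
            e += 0.5 * v1 * (1.0 + math.cos(rad))
            e += 0.5 * v2 * (1.0 - math.cos(2.0 * rad))
            e += 0.5 * v3 * (1.0 + math.cos(3.0 * rad))
        energies.append(e)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        energies = list(np.asarray(energies) + rng.normal(0.0, sigma, len(energies)))
    profile = EnergyProfile(list(grid), energies).relative()
    return SyntheticPES(triples, grid, sigma, seed, profile)


# ---------------------------------------------------------------------------
# PES CSV format: header "angle_deg,energy,<unit>"
# ---------------------------------------------------------------------------

def write_pes_csv(profile: EnergyProfile, dest) -> None:
    """Write a profile as `angle_deg,energy,<unit>` CSV to a path or stream."""
    own = isinstance(dest, (str, Path))
    fh = open(dest, "w", newline="") if own else dest
    try:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "energy", profile.unit])
        for ang, e in zip(profile.angles, profile.energies):
            writer.writerow([f"{ang:g}", f"{e:.10g}"])
    finally:
        if own:
            fh.close()


def read_pes_csv(src) -> EnergyProfile:
    """Read a `angle_deg,energy,<unit>` CSV from a path or stream."""
    own = isinstance(src, (str, Path))
    fh = open(src, newline="") if own else src
    try:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or len(header) < 3 or header[0] != "angle_deg" or header[1] != "energy":
            raise ValueError("PES CSV must start with header 'angle_deg,energy,<unit>'")
        unit = header[2]
        angles, energies = [], []
        for row in reader:
            if not row:
                continue
            angles.append(float(row[0]))
            energies.append(float(row[1]))
        return EnergyProfile(angles, energies, unit)
    finally:
        if own:
            fh.close()
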