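"""Conformer enumeration, minimization, filtering, RMSD and diagnostics."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from torsionforge import conformer_pipeline as cp
from torsionforge import param_model as pm
from torsionforge.fixtures_io import builtin_fixture, graph_coords

from conftest import embedded_graph


@pytest.fixture(scope="module")
def ethane():
    return embedded_graph("CC", seed=3)


@pytest.fixture(scope="module")
def npa():
    return builtin_fixture("n-phenylacetamide").graph


class TestEnumeration:
    def test_single_bond_gives_twelve(self, ethane):
        confs = cp.enumerate_conformers(ethane, seed=0)
        assert len(confs) == 12
        assert sorted(c.assignment[0] for c in confs) == [30.0 * i for i in range(12)]

    def test_no_rotatable_bond_returns_input(self):
        g = embedded_graph("c1ccccc1", seed=5)
        confs = cp.enumerate_conformers(g)
        assert len(confs) == 1
        np.testing.assert_allclose(confs[0].coords, graph_coords(g))

    def test_three_bonds_hit_cap(self, npa):
        confs = cp.enumerate_conformers(npa, max_n=1000, seed=11)
        assert len(confs) == 1000
        assert len({c.assignment for c in confs}) == 1000

    def test_seed_determinism(self, npa):
        a = cp.enumerate_conformers(npa, max_n=50, seed=4)
        b = cp.enumerate_conformers(npa, max_n=50, seed=4)
        c = cp.enumerate_conformers(npa, max_n=50, seed=5)
        assert [x.assignment for x in a] == [x.assignment for x in b]
        assert [x.assignment for x in a] != [x.assignment for x in c]

    def test_dihedrals_actually_set(self, ethane):
        quad = cp.dihedral_quadruple(ethane, cp.rotatable_bonds(ethane)[0])
        for conf in cp.enumerate_conformers(ethane):
            measured = cp.measure_dihedral(conf.coords, *quad)
            target = conf.assignment[0]
            wrapped = (measured - target + 180.0) % 360.0 - 180.0
            assert abs(wrapped) < 1e-6

    def test_ring_coordinates_untouched(self, npa):
        ring = [i for i, a in enumerate(npa.atoms) if a.aromatic]
        base = graph_coords(npa)
        for conf in cp.enumerate_conformers(npa, max_n=20, seed=2):
            d_base = np.linalg.norm(
                base[ring][:, None] - base[ring][None], axis=-1)
            d_conf = np.linalg.norm(
                conf.coords[ring][:, None] - conf.coords[ring][None], axis=-1)
            np.testing.assert_allclose(d_conf, d_base, atol=1e-8)

    def test_missing_coordinates_rejected(self):
        from torsionforge.torsion_id import MolecularGraph
        g = MolecularGraph.from_smiles("CC")
        with pytest.raises(ValueError):
            cp.enumerate_conformers(g)


class _ThrowOnThird:
    def __init__(self, inner):
        self.inner = inner
        self.count = 0

    def energy(self, coords):
        return self.inner.energy(coords)

    def minimize(self, coords, cg_steps, lbfgs_steps, dielectric):
        self.count += 1
        if self.count == 3:
            raise RuntimeError("synthetic engine failure")
        return self.inner.minimize(coords, cg_steps, lbfgs_steps, dielectric)


class TestMinimization:
    def test_harmonic_well_converges_to_target(self, ethane):
        confs = cp.enumerate_conformers(ethane)
        target = confs[0].coords + 0.1
        engine = cp.HarmonicWellEngine(target)
        done = cp.minimize_ensemble(confs, engine)
        assert all(c.status == "ok" for c in done)
        for c in done:
            np.testing.assert_allclose(c.coords, target)
            assert c.energy == 0.0

    def test_positive_twofold_drives_planarity(self, ethane):
        # V2 > 0 places minima at 0/180 and the barrier at +-90
        quad = cp.dihedral_quadruple(ethane, cp.rotatable_bonds(ethane)[0])
        engine = cp.RigidTorsionEngine(ethane, [(quad, (0.0, 2.7, 0.0))])
        start = cp.enumerate_conformers(ethane)
        picked = [c for c in start if c.assignment[0] in (30.0, 150.0, 210.0)]
        done = cp.minimize_ensemble(picked, engine, cg_steps=100, lbfgs_steps=500)
        for c in done:
            assert c.status == "ok"
            phi = cp.measure_dihedral(c.coords, *quad)
            nearest = min(abs(abs(phi) - t) for t in (0.0, 180.0))
            assert nearest < 1e-3
            assert c.energy == pytest.approx(0.0, abs=1e-8)

    def test_engine_failure_downgrades_single_conformer(self, ethane):
        confs = cp.enumerate_conformers(ethane)[:5]
        engine = _ThrowOnThird(cp.HarmonicWellEngine(confs[0].coords))
        done = cp.minimize_ensemble(confs, engine)
        assert [c.status for c in done] == ["ok", "ok", "failed", "ok", "ok"]

    def test_cartesian_engine_never_increases_energy(self, ethane):
        quad = cp.dihedral_quadruple(ethane, cp.rotatable_bonds(ethane)[0])
        engine = cp.TorsionOnlyEngine([(quad, (1.0, -2.0, 0.5))])
        for conf in cp.enumerate_conformers(ethane)[:4]:
            e0 = engine.energy(conf.coords)
            _, e1 = engine.minimize(conf.coords, cg_steps=50, lbfgs_steps=200)
            assert e1 <= e0 + 1e-12


class TestEnergyWindow:
    def _confs(self, energies):
        return [
            cp.Conformer(np.zeros((1, 3)), (), e, "ok" if e is not None else "failed")
            for e in energies
        ]

    def test_window_boundary(self):
        kept = cp.filter_low_energy(self._confs([0.0, 5.0, 9.9, 10.1]), window=10.0)
        assert [c.energy for c in kept] == [0.0, 5.0, 9.9]

    def test_offset_invariance(self):
        a = cp.filter_low_energy(self._confs([0.0, 5.0, 9.9, 10.1]))
        b = cp.filter_low_energy(self._confs([100.0, 105.0, 109.9, 110.1]))
        assert len(a) == len(b) == 3

    def test_all_equal_and_single(self):
        assert len(cp.filter_low_energy(self._confs([2.0, 2.0, 2.0]))) == 3
        assert len(cp.filter_low_energy(self._confs([7.0]))) == 1

    def test_failed_only_rejected(self):
        with pytest.raises(ValueError):
            cp.filter_low_energy(self._confs([None, None]))


class TestBestRmsd:
    def test_identical_conformer_gives_zero(self, npa):
        confs = cp.enumerate_conformers(npa, max_n=5, seed=1)
        assert cp.best_rmsd(confs, confs[2].coords, npa) < 1e-6

    def test_rigid_motion_removed(self, npa):
        coords = graph_coords(npa)
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 1.0])
        conf = cp.Conformer(moved, (), 0.0, "ok")
        assert cp.best_rmsd([conf], coords, npa) < 1e-6

    def test_against_kabsch_oracle(self, rng):
        # brute-force oracle: optimal superposition via scipy on the identity
        # atom mapping of an asymmetric heavy-atom skeleton
        g = embedded_graph("CC(=O)NCO", seed=9)
        heavy = [i for i, a in enumerate(g.atoms) if a.element != "H"]
        coords = graph_coords(g)
        perturbed = coords.copy()
        perturbed[heavy] += rng.normal(0, 0.05, (len(heavy), 3))
        conf = cp.Conformer(perturbed, (), 0.0, "ok")
        got = cp.best_rmsd([conf], coords, g)

        a = coords[heavy] - coords[heavy].mean(0)
        b = perturbed[heavy] - perturbed[heavy].mean(0)
        rot, rssd = Rotation.align_vectors(a, b)
        want = rssd / np.sqrt(len(heavy))
        assert got == pytest.approx(want, abs=1e-6)

    def test_symmetry_aware_for_flipped_phenyl(self, npa):
        # rotating an unsubstituted phenyl by 180 degrees relabels equivalent
        # atoms; automorphism-aware RMSD must report zero
        bond = next(
            b for b in cp.rotatable_bonds(npa)
            if npa.atoms[b.a1].aromatic or npa.atoms[b.a2].aromatic
        )
        quad = cp.dihedral_quadruple(npa, bond)
        coords = graph_coords(npa)
        phi = cp.measure_dihedral(coords, *quad)
        flipped = cp._set_dihedral(npa, coords, quad, phi + 180.0)
        conf = cp.Conformer(flipped, (), 0.0, "ok")
        best = cp.best_rmsd([conf], coords, npa)
        # identity-mapping RMSD sees the ring flip as a large displacement
        ref_mol = cp._mol_with_coords(npa.rdkit_mol, coords)
        prb_mol = cp._mol_with_coords(npa.rdkit_mol, flipped)
        from rdkit.Chem import rdMolAlign
        identity = rdMolAlign.AlignMol(prb_mol, ref_mol)
        assert identity > 0.5
        # automorphism-aware RMSD only retains the ring's slight non-planarity
        assert best < 0.1

    def test_atom_count_mismatch_rejected(self, npa):
        with pytest.raises(ValueError):
            cp.best_rmsd([cp.Conformer(np.zeros((3, 3)), (), 0.0, "ok")],
                         graph_coords(npa), npa)


class TestRecoveryTable:
    def test_all_zero_rmsd(self):
        res = cp.recovery_table([0.0, 0.0, 0.0])
        assert res.ratios == (1.0, 1.0, 1.0, 1.0)

    def test_direct_counting(self):
        res = cp.recovery_table([0.3, 0.7, 1.2, 1.8, 2.5])
        assert res.ratios == (0.2, 0.4, 0.6, 0.8)

    def test_failure_rate(self):
        res = cp.recovery_table([0.1] * 9, n_failures=1)
        assert res.failure_rate == pytest.approx(0.1)

    def test_monotone_in_threshold(self, rng):
        rmsds = rng.uniform(0, 3, 50)
        res = cp.recovery_table(rmsds, thresholds=np.linspace(0.1, 3, 15))
        assert all(b >= a for a, b in zip(res.ratios, res.ratios[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cp.recovery_table([])


class TestDiagnostics:
    def test_identical_conformations_unflagged(self, npa):
        coords = graph_coords(npa)
        diags = cp.diagnose_torsions(coords, coords, npa)
        assert len(diags) == len(cp.rotatable_bonds(npa))
        assert not any(d.exceeds for d in diags)

    def test_forty_degree_deviation_flagged(self, npa):
        bond = next(
            b for b in cp.rotatable_bonds(npa)
            if not npa.atoms[b.a1].aromatic and not npa.atoms[b.a2].aromatic
            and {npa.atoms[b.a1].element, npa.atoms[b.a2].element} == {"C", "N"}
        )
        quad = cp.dihedral_quadruple(npa, bond)
        coords = graph_coords(npa)
        phi = cp.measure_dihedral(coords, *quad)
        twisted = cp._set_dihedral(npa, coords, quad, phi + 40.0)
        diags = cp.diagnose_torsions(coords, twisted, npa)
        flagged = [d for d in diags if d.exceeds]
        assert len(flagged) == 1
        assert flagged[0].bond in ((bond.a1, bond.a2), (bond.a2, bond.a1))

    def test_aggregation_sums_shared_ids(self, npa):
        d = cp.diagnose_torsions(graph_coords(npa), graph_coords(npa), npa)
        fake = [
            cp.TorsionDiagnostic("X", (0, 1), 40.0, 40.0, "C1C1", True),
            cp.TorsionDiagnostic("Y", (0, 1), 10.0, 10.0, "C1C1", False),
        ]
        agg = cp.aggregate_diagnostics([fake, fake])
        assert agg == [("X", 2)]

    def test_shape_mismatch_rejected(self, npa):
        with pytest.raises(ValueError):
            cp.diagnose_torsions(np.zeros((2, 3)), np.zeros((2, 3)), npa)


class TestEngineFromTable:
    def test_npa_aryl_torsion_resolves_to_wildcard(self, npa):
        engine = cp.torsion_engine_from_table(npa, pm.new_table())
        triples = {t for _, t in engine.terms}
        assert (0.0, 2.7, 0.0) in triples  # the aryl-amide wildcard row

    def test_phenylpyrrole_uses_tt1_row(self):
        g = builtin_fixture("1-phenylpyrrole").graph
        engine = cp.torsion_engine_from_table(g, pm.new_table())
        assert {t for _, t in engine.terms} == {(0.0, 2.6, 0.0)}
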