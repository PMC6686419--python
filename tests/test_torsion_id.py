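"""Perception rules, assignability, fragment extraction and canonical IDs."""

import pytest
from rdkit import Chem

from torsionforge import torsion_id as tid
from torsionforge.fixtures_io import builtin_fixture

from conftest import perceived


class TestAromaticity:
    def test_benzene_is_huckel_aromatic(self):
        g = perceived("c1ccccc1")
        assert sum(a.aromatic for a in g.atoms) == 6
        assert sum(b.aromatic for b in g.bonds) == 6

    def test_cyclooctatetraene_exceeds_ring_size_limit(self):
        g = perceived("C1=CC=CC=CC=C1")
        assert not any(a.aromatic for a in g.atoms)

    def test_pyrrole_lone_pair_counts_two_electrons(self):
        g = perceived("c1cc[nH]c1")
        ring_atoms = [a for a in g.atoms if a.element != "H"]
        assert all(a.aromatic for a in ring_atoms)

    def test_cyclohexane_not_aromatic(self):
        g = perceived("C1CCCCC1")
        assert not any(a.aromatic for a in g.atoms)


class TestDelocalization:
    def test_six_ring_aromatic_bonds_delocalized(self):
        g = perceived("c1ccccc1")
        ring_bonds = [b for b in g.bonds if b.aromatic]
        assert len(ring_bonds) == 6
        assert all(b.delocalized for b in ring_bonds)

    def test_five_ring_heteroaromatic_not_delocalized(self):
        g = perceived("c1cc[nH]c1")
        assert not any(b.delocalized for b in g.bonds)

    def test_butadiene_central_bond_not_delocalized(self):
        g = perceived("C=CC=C")
        assert not any(b.delocalized for b in g.bonds)


class TestSp2Nitrogens:
    def test_amide_nitrogen_flagged(self):
        g = perceived("CC(=O)Nc1ccccc1")
        assert all(a.sp2_nitrogen for a in g.atoms if a.element == "N")

    def test_trimethylamine_not_flagged(self):
        g = perceived("CN(C)C")
        assert not any(a.sp2_nitrogen for a in g.atoms if a.element == "N")

    def test_enamine_nitrogen_flagged(self):
        g = perceived("CN(C)C=C")
        assert any(a.sp2_nitrogen for a in g.atoms if a.element == "N")

    def test_aniline_resonance_flagged(self):
        g = perceived("Nc1ccccc1")
        assert all(a.sp2_nitrogen for a in g.atoms if a.element == "N")

    def test_double_ortho_substitution_blocks_flag(self):
        g = perceived("CN(C)c1c(C)cccc1C")
        amine_n = [a for a in g.atoms if a.element == "N"]
        assert not any(a.sp2_nitrogen for a in amine_n)

    def test_single_ortho_substitution_does_not_block(self):
        g = perceived("CN(C)c1ccccc1C")
        assert any(a.sp2_nitrogen for a in g.atoms if a.element == "N")


class TestAssignability:
    def test_benzene_has_no_assignable_bonds(self):
        assert tid.detect_assignable_bonds(perceived("c1ccccc1")) == []

    def test_cyclopentane_ring_bonds_excluded(self):
        g = perceived("C1CCCC1")
        assert tid.detect_assignable_bonds(g) == []

    def test_six_ring_bonds_permitted_by_the_rule(self):
        # the size cutoff is <= 5, so cyclohexane ring bonds qualify as printed
        g = perceived("C1CCCCC1")
        assert len(tid.detect_assignable_bonds(g)) == 6

    def test_n_phenylacetamide_bonds(self):
        g = builtin_fixture("n-phenylacetamide").graph
        bonds = tid.detect_assignable_bonds(g)
        kinds = set()
        for b in bonds:
            e1, e2 = g.atoms[b.a1], g.atoms[b.a2]
            if {e1.element, e2.element} == {"N", "C"}:
                kinds.add("aryl-N" if (e1.aromatic or e2.aromatic) else "N-C(=O)")
        # the aryl-N and N-C(=O) bonds are both assignable (plus the acetyl C-C)
        assert kinds == {"aryl-N", "N-C(=O)"}
        assert len(bonds) == 3

    def test_terminal_bonds_excluded(self):
        g = perceived("CO")  # methanol C-O: O end has only H besides C
        bonds = tid.detect_assignable_bonds(g)
        assert len(bonds) == 1  # C-O qualifies (O bears an H); O-H does not
        b = bonds[0]
        assert {g.atoms[b.a1].element, g.atoms[b.a2].element} == {"C", "O"}


class TestFragments:
    def test_ethane_fragment_holds_all_eight_atoms(self):
        g = perceived("CC")
        frag = tid.extract_fragment(g, tid.detect_assignable_bonds(g)[0])
        assert frag.n_atoms == 8

    def test_butane_central_bond_shell(self):
        g = perceived("CCCC")
        bonds = tid.detect_assignable_bonds(g)
        central = next(
            b for b in bonds
            if g.degree(b.a1) == 4 and g.degree(b.a2) == 4
            and g.atoms[b.a1].element == "C"
            and sum(g.atoms[x].element == "C" for x in g.neighbors(b.a1)) == 2
        )
        frag = tid.extract_fragment(g, central)
        # 2 central C + 2 methyl C + 4 H directly bonded to the central atoms
        assert frag.n_atoms == 8
        elements = [a.element for _, a in frag.shells[0] + frag.shells[1]]
        assert sorted(elements) == ["C", "C", "H", "H", "H", "H"]

    def test_sp_chain_spans_all_linear_atoms(self):
        g = perceived("c1ccccc1C#CC#Cc1ccccc1")
        bonds = tid.detect_assignable_bonds(g)
        aryl_sp = next(
            b for b in bonds
            if g.atoms[b.a1].aromatic != g.atoms[b.a2].aromatic
        )
        frag = tid.extract_fragment(g, aryl_sp)
        assert len(frag.chain) == 6  # ipso + 4 sp carbons + far ipso
        assert len(frag.shells[0]) == 2 and len(frag.shells[-1]) == 2
        assert all(not s for s in frag.shells[1:-1])

    def test_non_assignable_bond_rejected(self):
        g = perceived("c1ccccc1")
        with pytest.raises(tid.TorsionIdError):
            tid.extract_fragment(g, g.bonds[0])


def _ids_for(graph):
    return sorted(
        tid.encode(tid.extract_fragment(graph, b))
        for b in tid.detect_assignable_bonds(graph)
    )


class TestCanonicalEncoding:
    @pytest.mark.parametrize("name", [
        "n-phenylacetamide", "1-phenylpyrrole", "n-thiophen-2-ylacetamide",
        "biphenyl", "toluene",
    ])
    def test_invariant_under_atom_renumbering(self, name):
        fx = builtin_fixture(name)
        base = _ids_for(fx.graph)
        mol = Chem.MolFromSmiles(fx.smiles)
        n = mol.GetNumAtoms()
        for shift in (1, 3, 5):
            order = [(i + shift) % n for i in range(n)]
            shuffled = Chem.RenumberAtoms(mol, order)
            g = tid.MolecularGraph.from_rdkit(shuffled)
            assert _ids_for(g) == base

    def test_locality_remote_substitution_keeps_id(self):
        def aryl_n_id(smiles):
            g = perceived(smiles)
            for b in tid.detect_assignable_bonds(g):
                e1, e2 = g.atoms[b.a1], g.atoms[b.a2]
                if {e1.element, e2.element} == {"N", "C"} and (e1.aromatic or e2.aromatic):
                    return tid.encode(tid.extract_fragment(g, b))
            raise AssertionError("aryl-N bond not found")

        assert aryl_n_id("CC(=O)Nc1ccccc1") == aryl_n_id("CC(=O)Nc1ccc(C)cc1")

    def test_ortho_substitution_changes_id(self):
        g1 = perceived("CC(=O)Nc1ccccc1")
        g2 = perceived("CC(=O)Nc1ccccc1C")
        # ortho methyl changes the ipso shell's neighbour environment only at
        # the aryl-N torsion for the ring side; the full ID sets must differ
        assert _ids_for(g1) != _ids_for(g2)

    def test_round_trip_encode_decode(self):
        for name in ("n-phenylacetamide", "1-phenylpyrrole", "biphenyl",
                     "n-thiophen-2-ylacetamide", "toluene"):
            g = builtin_fixture(name).graph
            for b in tid.detect_assignable_bonds(g):
                s = tid.encode(tid.extract_fragment(g, b))
                frag = tid.decode(s)
                assert tid.encode(frag) == s

    @pytest.mark.parametrize("bad,pos_hint", [
        ("C[n3", "position"),
        ("C[n3](-H[n1]", "position"),
        ("C[n3]%C[n3]", "position"),
        ("C[n3]-C[n3]", "central"),  # no central-bond marker
        ("C[zz,n3](-)C[n3]", "position"),
    ])
    def test_malformed_ids_rejected_with_position(self, bad, pos_hint):
        with pytest.raises(tid.TorsionIdError) as err:
            tid.decode(bad)
        assert pos_hint in str(err.value) or "position" in str(err.value)


class TestMmffMiniTyper:
    def test_fixture_types(self, all_fixtures):
        for name, fx in all_fixtures.items():
            expected = fx.truth.get("mmff_types_present")
            if not expected:
                continue
            found = set(tid.assign_mmff_types(fx.graph).values())
            assert expected <= found, f"{name}: missing {expected - found}"

    def test_thiophene_alpha_beta(self):
        g = perceived("c1ccsc1")
        types = tid.assign_mmff_types(g)
        by_type = {}
        for idx, t in types.items():
            by_type.setdefault(t, []).append(idx)
        assert len(by_type.get(44, [])) == 1
        assert len(by_type.get(63, [])) == 2  # both carbons next to S
        assert len(by_type.get(64, [])) == 2
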