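"""Residue templates and chain assembly: chair invariants, stereochemistry,
and the set-then-measure torsion contract."""

import numpy as np
import pytest

from chondronmr.errors import StructuralError, UnknownResidueKindError
from chondronmr.geometry import dihedral
from chondronmr.glycan import (
    RING_ATOMS,
    ChainBuilder,
    assemble_chain,
    build_residue_template,
    measure_glycosidic_torsions,
    ring_pucker_torsions,
)

FIXTURE_TORSIONS = [(-73, 108), (-73, -118), (-73, 107), (-73, -116), (-72, 109)]


class TestResidueTemplates:
    @pytest.mark.parametrize("kind", ["GlcA", "GalNAc"])
    def test_ring_is_4c1_chair(self, kind):
        t = build_residue_template(kind)
        tors = ring_pucker_torsions(t)
        assert np.all(np.abs(np.abs(tors) - 60.0) <= 20.0)
        signs = np.sign(tors)
        assert np.all(signs[:-1] * signs[1:] == -1)  # alternating

    @pytest.mark.parametrize("kind", ["GlcA", "GalNAc"])
    def test_bond_lengths_physical(self, kind):
        t = build_residue_template(kind)
        heavy = [i for i, e in enumerate(t.elements) if e != "H"]
        for i, j in t.bonds:
            if i in heavy and j in heavy:
                d = np.linalg.norm(t.coords[i] - t.coords[j])
                assert 1.2 <= d <= 1.7

    @pytest.mark.parametrize("kind", ["GlcA", "GalNAc"])
    def test_atom_names_unique(self, kind):
        t = build_residue_template(kind)
        assert len(t.names) == len(set(t.names))

    def test_glca_atom_inventory(self):
        t = build_residue_template("GlcA")
        for name in ("C1", "C2", "C3", "C4", "C5", "C6", "O5", "O6A", "O6B"):
            assert name in t.names

    def test_galnac_has_acetamido_and_axial_o4(self):
        t = build_residue_template("GalNAc")
        for name in ("N2", "HN", "C7", "O7", "C8", "O6"):
            assert name in t.names
        # galacto configuration: H4 equatorial makes the H3-C3-C4-H4 and
        # H4-C4-C5-H5 torsions gauche, unlike the all-trans gluco pattern
        h34 = dihedral(*(t.position(n) for n in ("H3", "C3", "C4", "H4")))
        h45 = dihedral(*(t.position(n) for n in ("H4", "C4", "C5", "H5")))
        assert abs(abs(h34) - 60) < 25 and abs(abs(h45) - 60) < 25
        g = build_residue_template("GlcA")
        g34 = dihedral(*(g.position(n) for n in ("H3", "C3", "C4", "H4")))
        assert abs(abs(g34) - 180) < 25

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnknownResidueKindError):
            build_residue_template("xylose")

    def test_acetamido_default_trans(self):
        t = build_residue_template("GalNAc")
        tor = dihedral(*(t.position(n) for n in ("H2", "C2", "N2", "HN")))
        assert abs(abs(tor) - 180) < 1e-6


class TestRingPucker:
    def test_planar_ring_flags_non_chair(self):
        t = build_residue_template("GlcA")
        flat = t.coords.copy()
        flat[:6, 2] = 0.0  # flatten ring atoms
        t2 = type(t)(kind=t.kind, names=t.names, coords=flat, bonds=t.bonds)
        tors = ring_pucker_torsions(t2)
        assert np.allclose(tors, 0.0, atol=1e-8)

    def test_displaced_atom_leaves_window(self):
        t = build_residue_template("GlcA")
        coords = t.coords.copy()
        c3 = t.index["C3"]
        coords[c3, 2] *= -1.0  # reflect one ring atom through the plane
        t2 = type(t)(kind=t.kind, names=t.names, coords=coords, bonds=t.bonds)
        tors = np.abs(ring_pucker_torsions(t2))
        assert np.any((tors < 40.0) | (tors > 80.0))

    def test_broken_ring_raises(self):
        t = build_residue_template("GlcA").drop(["O5"])
        with pytest.raises(StructuralError):
            ring_pucker_torsions(t)


class TestAssembly:
    def test_disaccharide_has_one_linkage(self):
        m = assemble_chain(2, [(-72, 109)])
        assert m.n_residues == 2
        assert len(m.linkages) == 1
        assert m.linkages[0].type == "beta1-3"
        assert m.kinds == ["GalNAc", "GlcA"]

    def test_odd_length_rejected(self):
        with pytest.raises(StructuralError):
            assemble_chain(5, [(-73, 108)] * 4)

    def test_torsion_count_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            assemble_chain(6, [(-73, 108)] * 3)

    def test_set_then_measure_roundtrip(self):
        m = assemble_chain(6, FIXTURE_TORSIONS)
        measured = [(phi, psi) for _, phi, psi in measure_glycosidic_torsions(m)]
        assert np.allclose(measured, FIXTURE_TORSIONS, atol=1e-9)

    def test_set_then_measure_grid(self):
        """36x36 phi/psi grid on the disaccharide round-trips to 1e-6 deg."""
        builder = ChainBuilder(2)
        grid = np.arange(-175.0, 180.0, 10.0)
        assert grid.size == 36
        for phi in grid:
            for psi in grid:
                m = builder.model([(phi, psi)], check_clashes=False)
                (_, mphi, mpsi), = measure_glycosidic_torsions(m)
                assert abs(mphi - phi) < 1e-6 and abs(mpsi - psi) < 1e-6

    def test_linkage_alternation(self):
        m = assemble_chain(6, FIXTURE_TORSIONS)
        assert [lk.type for lk in m.linkages] == [
            "beta1-3", "beta1-4", "beta1-3", "beta1-4", "beta1-3",
        ]
        # donor indices run 2..6 toward the non-reducing end
        assert [lk.donor_residue_index for lk in m.linkages] == [2, 3, 4, 5, 6]

    def test_clash_reported_not_silent(self):
        with pytest.warns(UserWarning, match="closer than"):
            m = assemble_chain(4, [(180, 180), (180, 180), (180, 180)])
        assert m.clashes

    def test_missing_atom_named_in_error(self, cn6_fixture):
        with pytest.raises(StructuralError, match="H99"):
            cn6_fixture.atom_index("U2", "H99")

    def test_rings_stay_chairs_in_chain(self, cn6_fixture):
        for i in range(1, 7):
            tors = ring_pucker_torsions(cn6_fixture.residue(i))
            assert np.all(np.abs(np.abs(tors) - 60.0) <= 20.0)
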