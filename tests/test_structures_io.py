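"""Structure types, file formats, topology perception, parameterization."""

import numpy as np
import pytest

from stericds import (
    Atom,
    Structure,
    assign_parameters,
    build_chitin_host,
    perceive_topology,
    read_pdb,
    read_sdf,
    read_xyz,
    write_sdf,
    write_xyz,
)
from stericds.errors import (
    ClashError,
    ParseError,
    UnparameterizedPatternError,
    UnsupportedDialectError,
    UnsupportedElementError,
)
from stericds.structures_io import derive_angles, derive_torsions
from stericds.synthetic_data import MoleculeSpec, gen_molecule

from conftest import ETHANE_MOL


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_atom_mass_defaults_from_element(self):
        assert Atom("C", (0, 0, 0)).mass == pytest.approx(12.011)

    def test_unknown_element_rejected(self):
        with pytest.raises(UnsupportedElementError):
            Atom("Xx", (0, 0, 0))

    @pytest.mark.parametrize("bonds", [[(0, 0, 1)], [(0, 5, 1)],
                                       [(0, 1, 1), (1, 0, 1)]])
    def test_bad_bond_lists_rejected(self, bonds):
        atoms = [Atom("C", (float(i), 0, 0)) for i in range(2)]
        with pytest.raises(ValueError):
            Structure(atoms, bonds)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            Structure([])


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

class TestXyz:
    def test_minimal_file(self, tmp_path):
        path = tmp_path / "c.xyz"
        path.write_text("1\ntoy\nC 0.0 0.0 0.0\n")
        s = read_xyz(path)
        assert s.n_atoms == 1
        assert s.atoms[0].element == "C"
        assert s.atoms[0].coords == (0.0, 0.0, 0.0)
        assert s.bonds == []

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(0)
        s = Structure([Atom(e, tuple(c)) for e, c in
                       zip("CNOH", rng.normal(0, 3, (4, 3)))])
        path = tmp_path / "m.xyz"
        write_xyz(s, path)
        back = read_xyz(path)
        assert back.elements == s.elements
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-6)

    def test_count_mismatch_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nC 0 0 0\n")
        with pytest.raises(ParseError):
            read_xyz(path)

    def test_malformed_count_line_names_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("nope\ncomment\nC 0 0 0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_xyz(path)

    def test_unknown_element(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\nc\nQq 0 0 0\n")
        with pytest.raises(UnsupportedElementError):
            read_xyz(path)


# ---------------------------------------------------------------------------
# SDF / MOL V2000
# ---------------------------------------------------------------------------

class TestSdf:
    def test_ethane(self, ethane_file):
        s = read_sdf(ethane_file)
        assert s.n_atoms == 8
        assert len(s.bonds) == 7
        assert s.elements[:2] == ["C", "C"]
        # file indices are 1-based; internal are 0-based
        assert (0, 1, 1) in s.bonds

    def test_roundtrip(self, ethane_file, tmp_path):
        s = read_sdf(ethane_file)
        out = tmp_path / "back.sdf"
        write_sdf(s, out)
        back = read_sdf(out)
        assert back.elements == s.elements
        assert back.bonds == s.bonds
        # the V2000 dialect carries 4 decimals of coordinate precision
        np.testing.assert_allclose(back.coords, s.coords, atol=5e-5)

    def test_v3000_unsupported(self, tmp_path):
        path = tmp_path / "v3.sdf"
        path.write_text("m\n\n\n  0  0  0  0  0  0  0  0  0  0999 V3000\n")
        with pytest.raises(UnsupportedDialectError):
            read_sdf(path)

    def test_truncated_bond_block(self, tmp_path):
        lines = ETHANE_MOL.splitlines()
        path = tmp_path / "trunc.sdf"
        path.write_text("\n".join(lines[:4 + 8 + 5]))  # drop last two bonds
        with pytest.raises(ParseError):
            read_sdf(path)

    def test_bond_referencing_missing_atom(self, tmp_path):
        bad = ETHANE_MOL.replace("  2  6  1  0  0  0  0",
                                 "  2  9  1  0  0  0  0")
        path = tmp_path / "bad.sdf"
        path.write_text(bad)
        with pytest.raises(ParseError):
            read_sdf(path)


def test_sdf_roundtrip_preserves_partial_charges(tmp_path):
    """Charges travel in a partial_charges data field so polar guests stay
    polar through file exchange."""
    s = gen_molecule(MoleculeSpec("polar-probe", 2, 5))
    path = tmp_path / "polar.sdf"
    write_sdf(s, path)
    back = read_sdf(path)
    np.testing.assert_allclose(back.charges, s.charges, atol=1e-6)


def test_sdf_reader_agrees_with_rdkit(ethane_file):
    """Independent cross-check of the V2000 parser against RDKit."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    mol = Chem.MolFromMolFile(str(ethane_file), removeHs=False)
    s = read_sdf(ethane_file)
    assert s.n_atoms == mol.GetNumAtoms()
    assert len(s.bonds) == mol.GetNumBonds()
    ref = mol.GetConformer().GetPositions()
    np.testing.assert_allclose(s.coords, ref, atol=1e-4)


def test_read_pdb_minimal(tmp_path):
    path = tmp_path / "w.pdb"
    path.write_text(
        "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
        "  1.00  0.00           O\n"
        "HETATM    2  H1  HOH A   1       0.960   0.000   0.000"
        "  1.00  0.00           H\n"
        "END\n")
    s = read_pdb(path)
    assert s.elements == ["O", "H"]
    assert s.atoms[1].coords[0] == pytest.approx(0.96)


# ---------------------------------------------------------------------------
# topology perception
# ---------------------------------------------------------------------------

def brute_force_topology(structure, factor=1.2):
    """Independent O(n^2)/O(n^3)/O(n^4) enumeration with the same cutoff."""
    from stericds.constants import COVALENT_RADII

    x = structure.coords
    els = structure.elements
    n = len(els)
    bonds = set()
    for i in range(n):
        for j in range(i + 1, n):
            if (np.linalg.norm(x[i] - x[j])
                    < factor * (COVALENT_RADII[els[i]]
                                + COVALENT_RADII[els[j]])):
                bonds.add((i, j))
    angles = set()
    for i in range(n):
        for j in range(n):
            for k in range(i + 1, n):
                if j in (i, k):
                    continue
                if (min(i, j), max(i, j)) in bonds and \
                        (min(j, k), max(j, k)) in bonds:
                    angles.add((i, j, k))
    torsions = set()
    for (i, j) in bonds:
        for (a, b) in ((i, j), (j, i)):
            for p in range(n):
                if p in (a, b) or (min(p, a), max(p, a)) not in bonds:
                    continue
                for q in range(n):
                    if q in (a, b, p) or \
                            (min(q, b), max(q, b)) not in bonds:
                        continue
                    quad = (p, a, b, q)
                    torsions.add(min(quad, quad[::-1]))
    return bonds, angles, torsions


class TestPerceiveTopology:
    def test_water(self, water):
        out = perceive_topology(water)
        b, a, t = brute_force_topology(water)
        assert {(i, j) for i, j, _ in out.bonds} == b == {(0, 1), (0, 2)}
        assert set(out.angles) == a == {(1, 0, 2)}
        assert set(out.torsions) == t == set()

    def test_single_atom(self):
        out = perceive_topology(Structure([Atom("C", (0, 0, 0))]))
        assert out.bonds == [] and out.angles == [] and out.torsions == []

    def test_linear_chain_of_four(self):
        s = Structure([Atom("C", (1.4 * k, 0, 0)) for k in range(4)])
        out = perceive_topology(s)
        assert len(out.bonds) == 3
        assert len(out.angles) == 2
        assert len(out.torsions) == 1

    def test_clash_raises(self):
        s = Structure([Atom("C", (0, 0, 0)), Atom("C", (0.2, 0, 0))])
        with pytest.raises(ClashError):
            perceive_topology(s)

    def test_permutation_covariance(self):
        """Relabeling atoms relabels bonds/angles/torsions identically."""
        s = gen_molecule(MoleculeSpec("polar-probe", 2, 4))
        bare = Structure(s.atoms, [], name=s.name)
        out = perceive_topology(bare)
        rng = np.random.default_rng(5)
        perm = rng.permutation(s.n_atoms)
        inv = np.argsort(perm)
        permuted = Structure([s.atoms[i] for i in perm], [])
        out_p = perceive_topology(permuted)

        def canon_bonds(bonds, mapping=None):
            out_set = set()
            for i, j, _ in bonds:
                if mapping is not None:
                    i, j = mapping[i], mapping[j]
                out_set.add((min(i, j), max(i, j)))
            return out_set

        # mapping: atom k of permuted = atom perm[k] of original
        assert canon_bonds(out_p.bonds, perm) == canon_bonds(out.bonds)
        angles_p = {tuple(sorted((perm[i], perm[k]))) + (perm[j],)
                    for i, j, k in out_p.angles}
        angles_o = {tuple(sorted((i, k))) + (j,) for i, j, k in out.angles}
        assert angles_p == angles_o

    def test_random_molecules_match_brute_force(self):
        for seed in range(5):
            s = gen_molecule(MoleculeSpec("chain", 3 + seed % 3, seed))
            bare = Structure(s.atoms, [])
            out = perceive_topology(bare)
            b, a, t = brute_force_topology(bare)
            assert {(i, j) for i, j, _ in out.bonds} == b
            assert set(out.angles) == a
            assert set(out.torsions) == t


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

class TestAssignParameters:
    def test_ethane_term_counts(self, ethane_file):
        system = assign_parameters(read_sdf(ethane_file))
        assert len(system.stretch_idx) == 7
        assert len(system.bend_idx) == 12
        assert len(system.torsion_idx) == 9

    def test_every_bond_has_one_stretch_term(self, ethane_file):
        system = assign_parameters(read_sdf(ethane_file))
        bond_set = {(i, j) for i, j, _ in system.structure.bonds}
        term_set = {tuple(sorted(p)) for p in system.stretch_idx.tolist()}
        assert bond_set == term_set

    def test_astatine_unparameterized(self):
        s = Structure([Atom("At", (0, 0, 0)), Atom("C", (2.3, 0, 0))])
        with pytest.raises(UnparameterizedPatternError) as err:
            assign_parameters(s)
        assert "At" in str(err.value)

    def test_water_donors_acceptors(self, water):
        system = assign_parameters(water)
        assert {h for _, h in system.donors} == {1, 2}
        assert {d for d, _ in system.donors} == {0}
        assert system.acceptors == [0]

    def test_total_on_generated_molecules(self):
        """Every supported-element structure parameterizes without error."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            template = rng.choice(["chain", "ring", "polar-probe"])
            lo, hi = {"chain": (1, 8), "ring": (3, 8),
                      "polar-probe": (1, 6)}[template]
            spec = MoleculeSpec(template, int(rng.integers(lo, hi + 1)),
                                int(rng.integers(0, 1000)))
            system = assign_parameters(gen_molecule(spec))
            assert np.isfinite(system.stretch_k).all()
            assert np.isfinite(system.bend_theta0).all()

    def test_lorentz_berthelot_combination(self, water):
        system = assign_parameters(water)
        import yaml
        from importlib import resources
        params = yaml.safe_load(resources.files("stericds.data")
                                .joinpath("params_minimal.yaml").read_text())
        eps_o, sig_o = (params["vdw"]["O"]["epsilon"],
                        params["vdw"]["O"]["sigma"])
        eps_h, sig_h = (params["vdw"]["H"]["epsilon"],
                        params["vdw"]["H"]["sigma"])
        # the only nonbonded pair in water is H...H (O-H excluded as 1-2,
        # H-H as 1-3) -- so check a 4-atom chain instead
        s = Structure([Atom("O", (0, 0, 0)), Atom("H", (3.0, 0, 0))])
        sys2 = assign_parameters(s)
        assert sys2.nb_eps[0] == pytest.approx(np.sqrt(eps_o * eps_h))
        assert sys2.nb_sigma[0] == pytest.approx((sig_o + sig_h) / 2)


# ---------------------------------------------------------------------------
# chitin host
# ---------------------------------------------------------------------------

class TestChitinHost:
    def test_monomer_matches_template_size(self):
        assert build_chitin_host(1).n_atoms == 30

    def test_linkage_eliminates_three_atoms(self):
        # condensation: anomeric O + H from one unit, hydroxyl H from the next
        for n in (2, 3, 4):
            assert build_chitin_host(n).n_atoms == 30 * n - 3 * (n - 1)

    def test_no_clash_and_parameterizable(self):
        host = build_chitin_host(3)
        perceive_topology(Structure(host.atoms, host.bonds))  # raises on clash
        system = assign_parameters(host)
        assert len(system.stretch_idx) == len(host.bonds)

    def test_neutral(self):
        assert abs(build_chitin_host(4).charges.sum()) < 1e-9

    @pytest.mark.parametrize("n", [0, 9])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            build_chitin_host(n)

    def test_deterministic(self):
        a, b = build_chitin_host(2), build_chitin_host(2)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.bonds == b.bonds


def test_xyz_roundtrip_property(tmp_path):
    """Hypothesis: write/read is the identity on elements and coordinates
    for arbitrary supported-element structures."""
    from hypothesis import given, settings, strategies as st

    elements = st.sampled_from(["H", "C", "N", "O", "F", "P", "S", "Cl"])
    coord = st.floats(min_value=-999.0, max_value=999.0, allow_nan=False,
                      width=32)
    atom = st.tuples(elements, coord, coord, coord)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(atoms=st.lists(atom, min_size=1, max_size=12))
    def check(atoms):
        s = Structure([Atom(e, (x, y, z)) for e, x, y, z in atoms])
        path = tmp_path / "prop.xyz"
        write_xyz(s, path)
        back = read_xyz(path)
        assert back.elements == s.elements
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-6)

    check()


def test_sdf_roundtrip_on_generated_molecules(tmp_path):
    """write_sdf . read_sdf is the identity on elements/bonds for assorted
    generated structures."""
    for k, spec in enumerate([MoleculeSpec("chain", 5, 0),
                              MoleculeSpec("ring", 6, 1),
                              MoleculeSpec("polar-probe", 3, 2)]):
        s = gen_molecule(spec)
        path = tmp_path / f"m{k}.sdf"
        write_sdf(s, path)
        back = read_sdf(path)
        assert back.elements == s.elements
        assert [(i, j) for i, j, _ in back.bonds] == \
               [(i, j) for i, j, _ in s.bonds]
        np.testing.assert_allclose(back.coords, s.coords, atol=5e-5)
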