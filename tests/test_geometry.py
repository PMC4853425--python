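import itertools
import math

import gemmi
import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from c60kit import geometry, synth
from c60kit.errors import (
    IncompleteResidueError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UnsupportedSymmetryError,
)


class TestBuildC60:
    def test_truncated_icosahedron_topology(self):
        topo = geometry.build_c60(1.4392)
        assert len(topo.vertices) == 60
        assert len(topo.edges) == 90
        assert len(topo.pentagons) == 12
        assert len(topo.hexagons) == 20
        assert topo.euler_characteristic() == 2
        # uniform bonds at exactly the requested length
        lengths = topo.edge_lengths()
        assert np.allclose(lengths, 1.4392, atol=1e-9)
        assert abs(lengths.mean() - 1.4392) < 1e-12
        # every carbon is three-connected
        degree = np.zeros(60, int)
        for i, j in topo.edges:
            degree[i] += 1
            degree[j] += 1
        assert (degree == 3).all()

    def test_centroid_and_circumradius(self):
        bond = 1.4392
        topo = geometry.build_c60(bond)
        assert np.allclose(topo.centroid, 0.0, atol=1e-12)
        radii = np.linalg.norm(topo.vertices, axis=1)
        # closed form: R = (a/4) * sqrt(58 + 18 sqrt(5))
        expected = bond / 4.0 * math.sqrt(58.0 + 18.0 * math.sqrt(5.0))
        assert np.allclose(radii, expected, atol=1e-9)

    def test_distance_multiset_reproducible(self):
        a = geometry.build_c60(1.4392)
        b = geometry.build_c60(1.4392)
        da = np.sort(cdist(a.vertices, a.vertices).ravel())
        db = np.sort(cdist(b.vertices, b.vertices).ravel())
        assert np.allclose(da, db, atol=1e-12)

    def test_scaling_linearity(self):
        small = geometry.build_c60(1.0)
        big = geometry.build_c60(2.0)
        assert np.allclose(2.0 * np.sort(np.linalg.norm(small.vertices, axis=1)),
                           np.sort(np.linalg.norm(big.vertices, axis=1)))

    def test_invalid_bond_length(self):
        with pytest.raises(InvalidParameterError):
            geometry.build_c60(0.0)
        with pytest.raises(InvalidParameterError):
            geometry.build_c60(-1.0)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(25, 3))
        res = geometry.kabsch_superpose(pts, pts)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert res.atom_count == 25

    def test_exact_recovery_of_rigid_transform(self, rng):
        pts = rng.normal(size=(40, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        res = geometry.kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-9
        assert np.allclose(res.apply(pts), moved, atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-10

    def test_rmsd_symmetric_and_rigid_invariant(self, rng):
        a = rng.normal(size=(30, 3))
        b = a + rng.normal(scale=0.4, size=(30, 3))
        r_ab = geometry.kabsch_superpose(a, b).rmsd
        r_ba = geometry.kabsch_superpose(b, a).rmsd
        assert abs(r_ab - r_ba) < 1e-9
        rot = Rotation.random(random_state=7).as_matrix()
        t = np.array([3.0, 1.0, -4.0])
        r_moved = geometry.kabsch_superpose(a @ rot.T + t, b @ rot.T + t).rmsd
        assert abs(r_ab - r_moved) < 1e-9

    def test_agrees_with_scipy_align_vectors(self, rng):
        a = rng.normal(size=(20, 3))
        b = a + rng.normal(scale=0.3, size=(20, 3))
        ours = geometry.kabsch_superpose(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        assert abs(ours.rmsd - rssd / math.sqrt(len(a))) < 1e-9
        assert abs(geometry.pairwise_rmsd(a, b) - ours.rmsd) < 1e-12

    def test_rotation_orthonormality(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        rot = geometry.kabsch_superpose(a, b).rotation
        assert np.abs(rot @ rot.T - np.eye(3)).max() < 1e-8

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            geometry.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(InvalidInputError):
            geometry.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestExtractMotif:
    def test_binding_site_counts_112_atoms(self, bundle):
        query = geometry.extract_motif(
            bundle, [("A", 2, 9), ("B", 2, 9), ("C", 19, 24), ("D", 19, 24)])
        assert query.atom_count == 112
        assert query.segment_lengths == [8, 8, 6, 6]

    def test_single_segment_and_empty(self, bundle):
        assert geometry.extract_motif(bundle, [("A", 2, 9)]).atom_count == 32
        assert geometry.extract_motif(bundle, []).atom_count == 0

    def test_atom_ordering_is_backbone_within_residue(self, bundle):
        query = geometry.extract_motif(bundle, [("A", 1, 2)])
        resmap = bundle.residue_map()
        expected = [resmap[("A", ri)][a].position
                    for ri in (1, 2) for a in ("N", "CA", "C", "O")]
        assert np.allclose(query.coordinates, np.array(expected))

    def test_missing_backbone_atom_is_reported(self, bundle):
        broken = geometry.Structure(
            [a for a in bundle.atoms
             if not (a.chain_id == "B" and a.residue_index == 4 and a.atom_name == "O")])
        with pytest.raises(IncompleteResidueError) as err:
            geometry.extract_motif(broken, [("B", 2, 9)])
        assert err.value.chain_id == "B"
        assert err.value.residue_index == 4

    def test_overlapping_segments_rejected(self, bundle):
        with pytest.raises(InvalidInputError):
            geometry.extract_motif(bundle, [("A", 2, 9), ("A", 8, 12)])


def brute_force_images(structure, cutoff, min_atoms, trans_range=2):
    """Independent exhaustive operator x translation enumeration."""
    ops = geometry._space_group_ops(structure.space_group)
    cell = gemmi.UnitCell(*structure.cell)
    orth = np.array(cell.orth.mat.tolist())
    frac = structure.positions() @ np.array(cell.frac.mat.tolist()).T
    cart0 = structure.positions()
    found = set()
    rng_t = range(-trans_range, trans_range + 1)
    for op_idx, (rot, tran) in enumerate(ops):
        img = frac @ rot.T + tran
        for n in itertools.product(rng_t, rng_t, rng_t):
            if op_idx == 0 and n == (0, 0, 0):
                continue
            cart = (img + np.array(n)) @ orth.T
            close = (cdist(cart, cart0).min(axis=1) <= cutoff).sum()
            if close >= min_atoms:
                found.add((op_idx, n))
    return found


class TestExpandLattice:
    def test_p1_single_atom_keeps_identity_only(self):
        st = geometry.Structure(
            [geometry.AtomRecord("A", 1, "ALA", "CA", "C", [0.0, 0.0, 0.0])],
            cell=(40, 40, 40, 90, 90, 90), space_group="P 1")
        assembly = geometry.expand_lattice(st, cutoff=16.0, min_atoms=3)
        assert len(assembly.images) == 1
        assert assembly.images[0].is_identity

    def test_min_atoms_zero_is_superset(self, default_config):
        st = synth.generate_crystal_fixture(default_config)
        strict = geometry.expand_lattice(st, 16.0, 3)
        loose = geometry.expand_lattice(st, 16.0, 0)
        keys = lambda a: {(i.operator_index, i.translation) for i in a.images}  # noqa: E731
        assert keys(strict) <= keys(loose)

    @pytest.mark.parametrize("seed,min_atoms", [(3, 3), (11, 3), (3, 1)])
    def test_matches_brute_force_enumeration(self, seed, min_atoms):
        st = synth.generate_crystal_fixture(synth.GeneratorConfig(seed=seed))
        assembly = geometry.expand_lattice(st, cutoff=16.0, min_atoms=min_atoms)
        got = {(i.operator_index, i.translation) for i in assembly.images
               if not i.is_identity}
        expected = brute_force_images(st, 16.0, min_atoms)
        assert got == expected
        assert assembly.images[0].is_identity

    def test_unknown_space_group(self):
        st = geometry.Structure(
            [geometry.AtomRecord("A", 1, "ALA", "CA", "C", [0.0, 0.0, 0.0])],
            cell=(40, 40, 40, 90, 90, 90), space_group="Q 99")
        with pytest.raises(UnsupportedSymmetryError):
            geometry.expand_lattice(st)

    def test_requires_cell(self, bundle):
        with pytest.raises(InvalidInputError):
            geometry.expand_lattice(bundle)


class TestChannelDistances:
    def test_alternating_spacings_recovered(self):
        assembly = synth.generate_fullerene_channel(spacings=(12.0, 17.0), n_sites=8)
        d = geometry.fullerene_channel_distances(assembly, "FUL")
        assert np.allclose(d, [12, 17, 12, 17, 12, 17, 12])

    def test_single_centroid_is_an_error(self):
        assembly = synth.generate_fullerene_channel(n_sites=1)
        with pytest.raises(InsufficientDataError):
            geometry.fullerene_channel_distances(assembly, "FUL")

    def test_unknown_residue_name_is_an_error(self):
        assembly = synth.generate_fullerene_channel(n_sites=4)
        with pytest.raises(InsufficientDataError):
            geometry.fullerene_channel_distances(assembly, "XYZ")


class TestMatthews:
    def test_printed_coefficient_gives_51_5_percent(self):
        assert abs(100 * geometry.solvent_fraction(2.54) - 51.5) <= 0.2

    def test_boundary_clamps_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert geometry.solvent_fraction(1.0) == 0.0
        assert geometry.solvent_fraction(1.23) == 0.0

    def test_monotone_in_vm(self):
        grid = np.linspace(1.24, 6.0, 200)
        vals = [geometry.solvent_fraction(v) for v in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_hexagonal_cell_volume_matches_triple_product(self):
        a, c = 42.15, 66.79
        cell = (a, a, c, 90.0, 90.0, 120.0)
        # explicit hexagonal basis: a1 = (a,0,0), a2 = a(-1/2, sqrt3/2, 0), a3 = (0,0,c)
        a1 = np.array([a, 0, 0])
        a2 = np.array([-a / 2, a * math.sqrt(3) / 2, 0])
        a3 = np.array([0, 0, c])
        triple = abs(np.dot(a1, np.cross(a2, a3)))
        assert abs(geometry.cell_volume(cell) - triple) < 1e-6 * triple

    def test_z_counting_through_space_group(self):
        # P 62 has six symmetry operators
        cell = (42.15, 42.15, 66.79, 90.0, 90.0, 120.0)
        mass = geometry.cell_volume(cell) / (6 * 2.54)
        vm, solvent = geometry.matthews_solvent(cell, "P 62", mass)
        assert abs(vm - 2.54) < 1e-9
        assert abs(100 * solvent - 51.5) <= 0.2

    def test_invalid_mass(self):
        with pytest.raises(InvalidParameterError):
            geometry.matthews_solvent((40, 40, 40, 90, 90, 90), "P 1", 0.0)


class TestStructureIO:
    def test_pdb_round_trip(self, tmp_path, bundle):
        path = tmp_path / "bundle.pdb"
        geometry.write_pdb(bundle, path)
        back = geometry.read_structure(path)
        assert len(back.atoms) == len(bundle.atoms)
        assert np.allclose(back.positions(), bundle.positions(), atol=1e-3)
        assert back.chains() == bundle.chains()

    def test_assembly_sidecar_mapping(self, tmp_path, default_config):
        st = synth.generate_crystal_fixture(default_config)
        assembly = geometry.expand_lattice(st, 16.0, 3)
        pdb = tmp_path / "lattice.pdb"
        sidecar = tmp_path / "lattice.json"
        geometry.write_assembly(assembly, pdb, sidecar)
        import json
        mapping = json.loads(sidecar.read_text())
        assert len(mapping) == len(assembly.images)  # one source chain each
        back = geometry.read_structure(pdb)
        assert len(back.atoms) == sum(len(i.atoms) for i in assembly.images)
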