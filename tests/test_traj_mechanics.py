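"""Superposition, RMSD, contact maps and the unbound-frame filter.

Brute-force oracles: the Kabsch fit is cross-checked against
scipy.spatial.transform.Rotation.align_vectors, and distances against
exhaustive pair enumeration.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allostat.errors import EmptyInputError, SelectionError, SuperpositionError
from allostat.structure_io import TrajectoryEnsemble
from allostat.synthetic_data import mutant_like, simulate_trajectory
from allostat.traj_mechanics import (
    contact_map,
    filter_unbound_frames,
    ligand_rmsd_series,
    min_residue_distance,
    region_rmsd,
    rmsd,
    superpose,
)
from conftest import make_structure


def random_rigid(rng):
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-2, 2, 3)
    return rot, trans


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(8, 3))
        tf = superpose(pts, pts)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tf.translation, 0, atol=1e-12)

    def test_recovers_known_rotation_and_shift(self, rng):
        pts = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 0.0, 0.0])
        tf = superpose(moved, pts)
        assert rmsd(tf.apply(moved), pts) < 1e-10

    def test_random_rigid_motions_are_inverted(self, rng):
        """100 random clouds + rigid motions -> post-fit RMSD < 1e-9 nm."""
        for _ in range(100):
            pts = rng.normal(size=(10, 3))
            rot, trans = random_rigid(rng)
            tf = superpose(pts @ rot.T + trans, pts)
            assert rmsd(tf.apply(pts @ rot.T + trans), pts) < 1e-9

    def test_matches_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's weighted Wahba solution."""
        mobile = rng.normal(size=(12, 3))
        ref = rng.normal(size=(12, 3))
        tf = superpose(mobile, ref)
        r_scipy, _ = Rotation.align_vectors(ref - ref.mean(0), mobile - mobile.mean(0))
        assert np.allclose(tf.rotation, r_scipy.as_matrix(), atol=1e-8)

    def test_proper_rotation_even_for_reflected_input(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tf = superpose(mirrored, pts)
        assert np.isclose(np.linalg.det(tf.rotation), 1.0)

    def test_too_few_atoms(self):
        with pytest.raises(SuperpositionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_geometry(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(SuperpositionError):
            superpose(line, line)


class TestRegionRmsd:
    @pytest.fixture
    def flat_ensemble(self, reference):
        frames = np.repeat(reference.coords[None], 5, axis=0)
        return TrajectoryEnsemble(reference, frames, np.arange(5.0))

    def test_reference_against_itself_is_zero(self, reference, flat_ensemble):
        series = region_rmsd(flat_ensemble, reference, "enzyme", "srm_helix")
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_uniform_displacement_of_measured_region(self, reference):
        coords = reference.coords
        helix = reference.region_indices("srm_helix", ("CA",))
        shifted = coords.copy()
        shifted[helix] += np.array([0.1, 0.0, 0.0])
        ens = TrajectoryEnsemble(reference, shifted[None], np.array([0.0]))
        # fit on the loop region, which is untouched, so the fit is identity
        series = region_rmsd(ens, reference, "ezh2_loop", "srm_helix")
        assert np.isclose(series.values[0], 0.1, atol=1e-9)

    def test_matches_bruteforce_oracle(self, reference, rng):
        """20 perturbed frames: explicit scipy Kabsch + sqrt-mean-square."""
        n = 20
        frames = np.repeat(reference.coords[None], n, axis=0)
        frames += rng.normal(0, 0.05, frames.shape)
        ens = TrajectoryEnsemble(reference, frames, np.arange(float(n)))
        series = region_rmsd(ens, reference, "enzyme", "srm_helix", atom_filter="heavy")
        fit_idx = reference.region_indices("enzyme", ("C", "CA", "N", "O"))
        mea_idx = reference.region_indices("srm_helix", "heavy")
        ref_fit = reference.coords[fit_idx]
        ref_mea = reference.coords[mea_idx]
        for i in range(n):
            rot, _ = Rotation.align_vectors(
                ref_fit - ref_fit.mean(0), frames[i][fit_idx] - frames[i][fit_idx].mean(0)
            )
            moved = rot.apply(frames[i][mea_idx] - frames[i][fit_idx].mean(0)) + ref_fit.mean(0)
            expected = np.sqrt(np.mean(np.sum((moved - ref_mea) ** 2, axis=1)))
            assert abs(series.values[i] - expected) < 1e-9

    def test_rigid_motion_invariance(self, reference, rng):
        frames = np.repeat(reference.coords[None], 3, axis=0)
        frames += rng.normal(0, 0.05, frames.shape)
        ens = TrajectoryEnsemble(reference, frames, np.arange(3.0))
        base = region_rmsd(ens, reference, "enzyme", "srm_helix").values
        rot, trans = random_rigid(rng)
        moved = frames @ rot.T + trans
        ens2 = TrajectoryEnsemble(reference, moved, np.arange(3.0))
        assert np.allclose(
            region_rmsd(ens2, reference, "enzyme", "srm_helix").values, base, atol=1e-9
        )


class TestUnboundFilter:
    def displaced_ensemble(self, reference, displacements):
        lig = reference.region_indices("ligand", "all")
        frames = []
        for d in displacements:
            c = reference.coords
            c[lig] += np.array([d, 0.0, 0.0])
            frames.append(c)
        return TrajectoryEnsemble(reference, np.array(frames), np.arange(float(len(frames))))

    def test_threshold_boundary(self, reference):
        """0.9 nm removed, 0.7 nm kept, exactly 0.8 nm kept (strict >)."""
        ens = self.displaced_ensemble(reference, [0.9, 0.7, 0.8])
        filtered, mask = filter_unbound_frames(ens, reference, 0.8)
        assert list(mask.kept) == [False, True, True]
        assert filtered.n_frames == 2
        assert list(filtered.times) == [1.0, 2.0]

    def test_ligand_rmsd_equals_displacement(self, reference):
        ens = self.displaced_ensemble(reference, [0.0, 0.5, 1.2])
        assert np.allclose(ligand_rmsd_series(ens, reference), [0.0, 0.5, 1.2], atol=1e-9)

    def test_idempotent(self, reference):
        ens = self.displaced_ensemble(reference, [0.9, 0.1, 0.3, 2.0])
        once, mask1 = filter_unbound_frames(ens, reference)
        twice, mask2 = filter_unbound_frames(once, reference)
        assert mask2.n_removed == 0
        assert np.array_equal(once.frames, twice.frames)

    def test_all_removed_warns_and_returns_none(self, reference):
        ens = self.displaced_ensemble(reference, [2.0, 3.0])
        with pytest.warns(UserWarning, match="all frames"):
            filtered, mask = filter_unbound_frames(ens, reference)
        assert filtered is None
        assert mask.n_kept == 0

    def test_kept_fraction_tracks_bound_fraction(self, reference):
        """bound_fraction 0.8, 1000 frames -> kept in [0.75, 0.85]."""
        scen = mutant_like(n_frames=1000, seed=42)
        ens = simulate_trajectory(scen, reference)
        _, mask = filter_unbound_frames(ens, reference)
        assert 0.75 <= mask.n_kept / 1000 <= 0.85

    def test_truth_labelled_unbound_frames_all_removed(self, reference):
        """Displacement 2.0 nm >= 1.5 nm: every unbound frame exceeds 0.8 nm."""
        scen = mutant_like(n_frames=400, seed=5)
        ens = simulate_trajectory(scen, reference)
        filtered, mask = filter_unbound_frames(ens, reference)
        truth = ens.truth_labels["bound"].to_numpy()
        assert not mask.kept[~truth].any()
        assert mask.kept[truth].all()


class TestDistancesAndContacts:
    def test_single_atom_pair(self):
        frame = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.3]])
        assert np.isclose(min_residue_distance(frame, [0], [1]), 0.3)

    def test_exhaustive_oracle_3v3(self, rng):
        frame = rng.uniform(-1, 1, (6, 3))
        got = min_residue_distance(frame, [0, 1, 2], [3, 4, 5])
        expected = min(
            np.linalg.norm(frame[i] - frame[j]) for i in (0, 1, 2) for j in (3, 4, 5)
        )
        assert np.isclose(got, expected, atol=1e-12)

    def test_far_atom_does_not_change_minimum(self, rng):
        frame = rng.uniform(-1, 1, (6, 3))
        base = min_residue_distance(frame, [0, 1], [3, 4])
        frame2 = np.vstack([frame, [100.0, 100.0, 100.0]])
        assert np.isclose(min_residue_distance(frame2, [0, 1, 6], [3, 4]), base)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(SelectionError):
            min_residue_distance(np.zeros((3, 3)), [0, 1], [1, 2])

    @pytest.fixture
    def two_chain_structure(self, rng):
        coords = rng.uniform(-1, 1, (8, 3))
        names = ["CA", "CB", "CA", "CB"] * 2
        from allostat.structure_io import AnnotatedStructure, AtomRecord

        atoms = []
        for i in range(8):
            chain = "A" if i < 4 else "B"
            resnum = 1 + (i % 4) // 2
            atoms.append(AtomRecord(names[i], "C", chain, resnum, "ALA", tuple(coords[i])))
        return AnnotatedStructure(atoms)

    def test_single_frame_map_equals_per_frame_minimum(self, two_chain_structure):
        s = two_chain_structure
        ens = TrajectoryEnsemble(s, s.coords[None], np.array([0.0]))
        cm = contact_map(ens, "A", (1, 2), "B", (1, 2), atom_filter="all")
        for i, ra in enumerate((1, 2)):
            for j, rb in enumerate((1, 2)):
                ia = np.flatnonzero((s.chain_ids == "A") & (s.residue_numbers == ra))
                ib = np.flatnonzero((s.chain_ids == "B") & (s.residue_numbers == rb))
                assert np.isclose(cm.values[i, j], min_residue_distance(s.coords, ia, ib))

    def test_two_frame_map_is_arithmetic_mean(self, two_chain_structure, rng):
        s = two_chain_structure
        f2 = s.coords + rng.normal(0, 0.2, (8, 3))
        ens = TrajectoryEnsemble(s, np.stack([s.coords, f2]), np.arange(2.0))
        cm = contact_map(ens, "A", (1, 2), "B", (1, 2), atom_filter="all")
        for i, ra in enumerate((1, 2)):
            for j, rb in enumerate((1, 2)):
                ia = np.flatnonzero((s.chain_ids == "A") & (s.residue_numbers == ra))
                ib = np.flatnonzero((s.chain_ids == "B") & (s.residue_numbers == rb))
                expected = 0.5 * (
                    min_residue_distance(s.coords, ia, ib) + min_residue_distance(f2, ia, ib)
                )
                assert np.isclose(cm.values[i, j], expected, atol=1e-12)
        assert cm.n_frames_used == 2

    def test_transposed_computation_agrees(self, two_chain_structure):
        s = two_chain_structure
        ens = TrajectoryEnsemble(s, s.coords[None], np.array([0.0]))
        ab = contact_map(ens, "A", (1, 2), "B", (1, 2), atom_filter="all")
        ba = contact_map(ens, "B", (1, 2), "A", (1, 2), atom_filter="all")
        assert np.allclose(ab.values, ba.values.T)

    def test_engineered_salt_bridge_is_argmin(self, reference):
        """The persistent ligand-NZ / ASP140 contact dominates the map."""
        scen = mutant_like(n_frames=150, seed=3)
        ens = simulate_trajectory(scen, reference)
        filtered, _ = filter_unbound_frames(ens, reference)
        cm = contact_map(filtered, "Z", (130, 153), "L", (1, 1))
        assert cm.argmin() == ("ASP140", "LIG1")

    def test_relaxing_atom_filter_never_increases_entries(self, tri_residue, rng):
        from allostat.structure_io import AnnotatedStructure, AtomRecord

        # two copies of the H-bearing residue on separate chains
        atoms = list(tri_residue.atoms)
        offset = rng.uniform(0.5, 1.0, 3)
        atoms += [
            AtomRecord(a.atom_name, a.element, "B", a.residue_number, a.residue_name,
                       tuple(np.array(a.coordinates) + offset))
            for a in tri_residue.atoms
        ]
        s = AnnotatedStructure(atoms)
        ens = TrajectoryEnsemble(s, s.coords[None], np.array([0.0]))
        maps = [
            contact_map(ens, "A", (5, 5), "B", (5, 5), atom_filter=f).values
            for f in ("side_chain", "heavy", "all")
        ]
        assert np.all(maps[1] <= maps[0] + 1e-12)
        assert np.all(maps[2] <= maps[1] + 1e-12)

    def test_empty_ensemble_rejected(self, reference):
        with pytest.raises(EmptyInputError):
            contact_map(None, "Z", (130, 153), "L", (1, 1))
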