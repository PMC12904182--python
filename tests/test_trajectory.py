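"""Ligand RMSD/stability, RMSF, contact persistence, pocket volume."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from plgic.errors import SelectionError, SpecError, TrajectoryError
from plgic.structures import StructureModel
from plgic.synth import (TrajectorySpec, add_ligand, synth_ligand_trajectory)
from plgic.trajectory import (RMSDSeries, TrajectoryEnsemble,
                              backbone_rmsd_series, classify_ligand_stability,
                              contact_persistence, ligand_rmsd_series,
                              pocket_volume, residue_rmsf)


@pytest.fixture(scope="module")
def frozen_traj(pentamer):
    traj, _ = synth_ligand_trajectory(
        pentamer, TrajectorySpec(mode="stable", n_frames=20, noise_sigma=0.0))
    return traj


class TestLigandRmsd:
    def test_frozen_everything_gives_zero(self, frozen_traj):
        s = ligand_rmsd_series(frozen_traj)
        assert np.allclose(s.rmsd, 0.0, atol=1e-12)

    def test_step_displacement_measured_exactly(self, pentamer):
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=10,
                                     noise_sigma=0.0))
        lig = traj.ligand_indices()
        frames = traj.frames.copy()
        frames[5:, lig] += np.array([0.0, 6.0, 0.0])  # rigid 6 Å jump
        traj2 = TrajectoryEnsemble(topology=traj.topology, frames=frames)
        s = ligand_rmsd_series(traj2)
        assert np.allclose(s.rmsd[:5], 0.0, atol=1e-12)
        assert np.allclose(s.rmsd[5:], 6.0, atol=1e-9)

    def test_gaussian_jitter_matches_sigma_sqrt3(self, pentamer):
        sigma, n = 0.1, 10_000
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=n,
                                     noise_sigma=sigma, seed=7))
        s = ligand_rmsd_series(traj)
        assert np.mean(s.rmsd[1:]) == pytest.approx(sigma * np.sqrt(3),
                                                    rel=0.05)

    def test_series_invariant_to_global_rigid_motion(self, pentamer):
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="drift", n_frames=30,
                                     noise_sigma=0.05, seed=3))
        base = ligand_rmsd_series(traj).rmsd
        R = Rotation.from_euler("xyz", [12, -8, 30], degrees=True).as_matrix()
        moved = TrajectoryEnsemble(
            topology=traj.topology,
            frames=traj.frames @ R.T + np.array([4.0, 5.0, -6.0]))
        assert np.allclose(ligand_rmsd_series(moved).rmsd, base, atol=1e-9)

    def test_missing_ligand_raises(self, pentamer):
        frames = np.stack([pentamer.coords, pentamer.coords])
        traj = TrajectoryEnsemble(topology=pentamer, frames=frames)
        with pytest.raises(SelectionError):
            ligand_rmsd_series(traj)


class TestStability:
    def series(self, values):
        return RMSDSeries(rmsd=np.asarray(values, dtype=float),
                          fit_selection="", measured_selection="")

    def test_low_rmsd_stable(self):
        assert classify_ligand_stability(
            self.series([0.5] * 100)).call == "stable"

    def test_drift_to_six_unstable(self):
        vals = np.concatenate([np.full(80, 0.5), np.linspace(0.5, 6.0, 20)])
        out = classify_ligand_stability(self.series(vals))
        assert out.call == "unstable"

    def test_boundary_two_angstrom_inclusive(self):
        out = classify_ligand_stability(self.series([2.0] * 50))
        assert out.call == "stable" and out.evidence == pytest.approx(2.0)
        out = classify_ligand_stability(self.series([2.0 + 1e-9] * 50))
        assert out.call == "unstable"

    def test_empty_window_rejected(self):
        with pytest.raises(SpecError):
            classify_ligand_stability(self.series([1.0, 1.0]),
                                      window_fraction=0.01)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 10), min_size=10, max_size=50),
           st.floats(0.0, 3.0))
    def test_monotone_increase_never_flips_to_stable(self, vals, bump):
        base = classify_ligand_stability(self.series(vals))
        bumped = classify_ligand_stability(
            self.series(np.asarray(vals) + bump))
        if base.call == "unstable":
            assert bumped.call == "unstable"


class TestBackboneRmsdAndRmsf:
    def test_frozen_backbone_zero(self, frozen_traj):
        s = backbone_rmsd_series(frozen_traj)
        assert np.allclose(s.rmsd, 0.0, atol=1e-12)

    def test_loop_displacement_plateau(self, pentamer):
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=10,
                                     noise_sigma=0.0))
        top = traj.topology
        loopc = np.nonzero((top.chain_id == "A")
                           & (top.residue_number >= 26)
                           & (top.residue_number <= 31))[0]
        frames = traj.frames.copy()
        frames[5:, loopc] += np.array([2.0, 0.0, 0.0])
        traj2 = TrajectoryEnsemble(topology=top, frames=frames)
        s = backbone_rmsd_series(traj2, measure_idx=loopc, label="loopC")
        # whole-backbone fit barely moves (6 of ~2400 backbone atoms shifted)
        assert np.allclose(s.rmsd[:5], 0.0, atol=1e-3)
        assert np.allclose(s.rmsd[5:], 2.0, atol=0.02)

    def test_rmsf_frozen_atom_zero(self, frozen_traj):
        rf = residue_rmsf(frozen_traj)
        assert max(rf.values()) < 1e-9

    def test_rmsf_matches_sigma_sqrt3(self, pentamer):
        sigma, n = 0.2, 10_000
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=n,
                                     noise_sigma=sigma, seed=11))
        lig = traj.ligand_indices()
        rf = residue_rmsf(traj, selection=lig)
        assert rf[("X", 1)] == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_rmsf_ordering_preserved(self, pentamer):
        """Atoms with σ=0.1 vs σ=0.4 keep their RMSF ordering, every seed."""
        top = add_ligand(pentamer)
        lig = np.nonzero(top.residue_name == "LIG")[0][:2]
        # distinguish the two jittered atoms as separate residues
        top.residue_number[lig[1]] = 2
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frames = np.repeat(top.coords[None], 50, axis=0)
            frames[:, lig[0]] += rng.normal(0, 0.1, (50, 3))
            frames[:, lig[1]] += rng.normal(0, 0.4, (50, 3))
            traj = TrajectoryEnsemble(topology=top, frames=frames)
            rf = residue_rmsf(traj, selection=lig)
            assert rf[("X", 2)] > rf[("X", 1)]

    def test_too_few_frames_rejected(self, pentamer):
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=5,
                                     noise_sigma=0.0))
        with pytest.raises(TrajectoryError):
            residue_rmsf(traj)


class TestContacts:
    def test_scheduled_contacts_exact(self, pentamer):
        sched = {("A", 10): set(range(250)), ("B", 12): set(range(0))}
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=500,
                                     noise_sigma=0.0,
                                     contact_schedule=sched))
        fp = contact_persistence(traj, [("A", 10), ("B", 12)])
        assert fp.persistence[("A", 10)] == 0.5
        assert fp.persistence[("B", 12)] == 0.0

    def test_73_of_100_frames(self, pentamer):
        sched = {("A", 10): set(range(73))}
        traj, _ = synth_ligand_trajectory(
            pentamer, TrajectorySpec(mode="stable", n_frames=100,
                                     noise_sigma=0.0,
                                     contact_schedule=sched))
        fp = contact_persistence(traj, [("A", 10)])
        assert fp.persistence[("A", 10)] == 0.73

    def test_unknown_residue_raises(self, frozen_traj):
        with pytest.raises(SelectionError):
            contact_persistence(frozen_traj, [("Q", 999)])


def wall_box_model(inner=8.0, spacing=1.0, probe=1.4, vdw=1.70):
    """Carbon-walled cubic cavity whose probe-free interior is ~inner³."""
    half = inner / 2.0 + vdw + probe
    grid = np.arange(-half, half + 1e-9, spacing)
    coords = []
    for axis in range(3):
        for sign in (-1.0, 1.0):
            for u in grid:
                for v in grid:
                    p = [u, v]
                    p.insert(axis, sign * half)
                    coords.append(p)
    n = len(coords)
    return StructureModel.from_arrays(
        "box", coords=np.array(coords), name=["C1"] * n, element=["C"] * n,
        residue_name=["BOX"] * n, chain_id=["A"] * n,
        residue_number=list(range(1, n + 1)))


class TestPocketVolume:
    def test_cubic_cavity_volume(self):
        model = wall_box_model(inner=8.0)
        # seed offset by half a grid spacing so cell centres straddle the
        # cavity boundary symmetrically (unbiased counting of an even-width
        # cavity)
        res = pocket_volume(model, [0.25, 0.25, 0.25],
                            lining_residues=[("A", i + 1)
                                             for i in range(model.n_atoms)])
        assert res.volume == res.n_grid_points * res.grid_spacing ** 3
        assert not res.open_pocket
        # fine-grid oracle count of the qualifying region
        from scipy.spatial import cKDTree
        fine = 0.25
        xs = np.arange(-6.0, 6.01, fine)
        pts = np.array([[x, y, z] for x in xs for y in xs for z in xs])
        d, _ = cKDTree(model.coords).query(pts)
        oracle = np.sum(d - 1.70 >= 1.4) * fine ** 3
        assert res.volume == pytest.approx(oracle, rel=0.12)
        assert res.volume == pytest.approx(512.0, rel=0.15)

    def test_occluded_seed_rejected(self):
        model = wall_box_model(inner=8.0)
        with pytest.raises(SelectionError):
            pocket_volume(model, model.coords[0])

    def test_open_region_flagged(self, pentamer):
        # a seed in free space outside the receptor: not buried → ~0 volume,
        # possibly truncated at the box
        res = pocket_volume(pentamer, [60.0, 60.0, 60.0])
        assert res.volume == 0.0


def test_trajectory_contract_enforced(pentamer):
    with pytest.raises(TrajectoryError):
        TrajectoryEnsemble(topology=pentamer,
                           frames=np.zeros((1, pentamer.n_atoms, 3)))
    with pytest.raises(TrajectoryError):
        TrajectoryEnsemble(topology=pentamer, frames=np.zeros((3, 5, 3)))
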