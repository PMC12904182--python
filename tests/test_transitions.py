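"""Domain COM shift, tilt/rotation, projection and displacement metrics.

All inputs here are generator outputs sharing the build frame, so the
operations are exercised exactly as specified: on models already in a
common reference frame.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plgic.errors import CorrespondenceError, SelectionError
from plgic.geometry import pore_axis, superpose_model
from plgic.structures import build_correspondence
from plgic.synth import (MotionSpec, apply_domain_transform,
                         interpolate_states)
from plgic.transitions import (domain_com_shift, domain_tilt_rotation,
                               projection_profile, residue_displacement)

from conftest import make_desensitized, radial_unit


@pytest.fixture(scope="module")
def axis(pentamer):
    return pore_axis(pentamer)


class TestComShift:
    def test_single_subunit_translation_pythagorean(self, pentamer):
        moved = apply_domain_transform(pentamer, MotionSpec(
            chain="B", domain="TMD", com_shift_vec=(3.0, 4.0, 0.0)))
        corr = build_correspondence(pentamer, moved)
        shifts = {m.chain: m.com_shift
                  for m in domain_com_shift(corr, pentamer, moved, "TMD")}
        assert shifts["B"] == pytest.approx(5.0, abs=1e-9)
        for ch in "ACDE":
            assert shifts[ch] == pytest.approx(0.0, abs=1e-12)

    def test_identical_models_all_zero(self, pentamer):
        corr = build_correspondence(pentamer, pentamer)
        for m in domain_com_shift(corr, pentamer, pentamer, "TMD"):
            assert m.com_shift == 0.0

    def test_empty_domain_raises(self, pentamer):
        corr = build_correspondence(pentamer, pentamer)
        dd = pentamer.domains
        dd.domains["ghost"] = {"alpha1": [(900, 910)], "beta": [(900, 910)]}
        try:
            with pytest.raises(SelectionError):
                domain_com_shift(corr, pentamer, pentamer, "ghost")
        finally:
            del dd.domains["ghost"]


class TestTiltRotation:
    def test_pure_twist_recovered_noiseless(self, pentamer, axis):
        moved = apply_domain_transform(pentamer, MotionSpec(
            chain="A", domain="TMD", rotation_deg=12.8))
        corr = build_correspondence(pentamer, moved)
        rows = {m.chain: m for m in domain_tilt_rotation(
            corr, pentamer, moved, "TMD", axis)}
        assert rows["A"].rotation_deg == pytest.approx(12.8, abs=1e-6)
        assert rows["A"].tilt_deg == pytest.approx(0.0, abs=1e-6)
        assert rows["B"].rotation_deg == pytest.approx(0.0, abs=1e-9)

    def test_identical_models_zero_angles(self, pentamer, axis):
        corr = build_correspondence(pentamer, pentamer)
        for m in domain_tilt_rotation(corr, pentamer, pentamer, "TMD", axis):
            assert m.tilt_deg == pytest.approx(0.0, abs=1e-9)
            assert m.rotation_deg == pytest.approx(0.0, abs=1e-9)

    def test_tilt_and_twist_with_noise_recovered(self, pentamer, axis):
        """Applied (7.0°, 14.2°) recovered within 0.5° at σ=0.2 Å, 20 seeds."""
        for seed in range(20):
            moved = apply_domain_transform(pentamer, MotionSpec(
                chain="C", domain="TMD", tilt_deg=7.0, rotation_deg=14.2,
                noise_sigma=0.2, seed=seed))
            corr = build_correspondence(pentamer, moved)
            rows = {m.chain: m for m in domain_tilt_rotation(
                corr, pentamer, moved, "TMD", axis)}
            assert rows["C"].tilt_deg == pytest.approx(7.0, abs=0.5)
            assert rows["C"].rotation_deg == pytest.approx(14.2, abs=0.5)


class TestProjection:
    def _profiles(self, pentamer, desensitized, query):
        corr_cd = build_correspondence(pentamer, desensitized)
        corr_cq = build_correspondence(pentamer, query)
        return projection_profile(pentamer, desensitized, query,
                                  corr_cd, corr_cq)

    def test_query_at_closed_gives_zero(self, pentamer, desensitized):
        prof = self._profiles(pentamer, desensitized, pentamer)
        fr = [r["fraction"] for r in prof.records if r["defined"]]
        assert fr and np.allclose(fr, 0.0, atol=1e-12)

    def test_query_at_desensitized_gives_one(self, pentamer, desensitized):
        prof = self._profiles(pentamer, desensitized, desensitized)
        fr = [r["fraction"] for r in prof.records if r["defined"]]
        assert fr and np.allclose(fr, 1.0, atol=1e-12)

    @pytest.mark.parametrize("lam", [-0.5, 0.0, 0.25, 0.35, 0.5, 0.75, 1.0,
                                     1.5])
    def test_linearity_over_interpolated_states(self, pentamer, desensitized,
                                                lam):
        query = interpolate_states(pentamer, desensitized, lam)
        prof = self._profiles(pentamer, desensitized, query)
        fr = np.array([r["fraction"] for r in prof.records if r["defined"]])
        assert len(fr) > 500
        assert np.abs(fr - lam).max() < 1e-9

    def test_orthogonal_displacement_projects_to_zero(self, pentamer,
                                                      desensitized):
        corr_cd = build_correspondence(pentamer, desensitized)
        query = pentamer.copy()
        k = corr_cd.idx_A[100]
        v = desensitized.coords[corr_cd.idx_B[100]] - pentamer.coords[k]
        perp = np.cross(v, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(v, [1.0, 0.0, 0.0])
        query.coords[k] += 2.0 * perp / np.linalg.norm(perp)
        prof = self._profiles(pentamer, desensitized, query)
        rec = next(r for r in prof.records
                   if (r["chain"], r["residue_number"])
                   == (pentamer.chain_id[k], pentamer.residue_number[k]))
        assert rec["projection"] == pytest.approx(0.0, abs=1e-9)

    def test_small_axis_length_flagged_undefined(self, pentamer):
        query = pentamer.copy()
        near = pentamer.copy()
        near.coords = near.coords + 1e-3  # |v| ≪ epsilon everywhere
        corr = build_correspondence(pentamer, near)
        prof = projection_profile(pentamer, near, query, corr,
                                  build_correspondence(pentamer, query))
        assert all(not r["defined"] for r in prof.records)

    def test_insufficient_coverage_raises(self, pentamer, desensitized):
        half = pentamer.subset(
            np.nonzero(np.isin(pentamer.chain_id, ["A", "B"]))[0])
        half.roles = {"A": "alpha1", "B": "alpha1"}
        corr_cd = build_correspondence(pentamer, desensitized)
        corr_cq = build_correspondence(pentamer, half)
        with pytest.raises(CorrespondenceError):
            projection_profile(pentamer, desensitized, half, corr_cd, corr_cq)


class TestDisplacement:
    def test_single_residue_move_reported_at_argmax(self, pentamer):
        moved = pentamer.copy()
        mask = (pentamer.chain_id == "A") & (pentamer.residue_number == 28) \
            & (pentamer.name == "CA")
        moved.coords[mask] += np.array([0.0, 0.0, 4.0])
        corr = build_correspondence(pentamer, moved)
        rep = residue_displacement(corr, pentamer, moved, "LoopC")
        assert rep.max_displacement == pytest.approx(4.0, abs=1e-9)
        assert (rep.max_chain, rep.max_residue) == ("A", 28)

    def test_identical_models_zero(self, pentamer):
        corr = build_correspondence(pentamer, pentamer)
        rep = residue_displacement(corr, pentamer, pentamer, "M1M2loop")
        assert rep.max_displacement == 0.0

    def test_global_rigid_motion_absorbed_by_superposition(self, pentamer):
        R = Rotation.from_euler("zyx", [40, 10, -25], degrees=True).as_matrix()
        moved = pentamer.transformed(R, np.array([8.0, -2.0, 3.0]))
        corr = build_correspondence(pentamer, moved)
        aligned, _ = superpose_model(moved, pentamer, corr)
        rep = residue_displacement(corr, pentamer, aligned, "TMD")
        assert rep.max_displacement < 1e-9


def test_metrics_invariant_to_common_rigid_motion(pentamer, axis):
    """Transforming both states by one rigid motion leaves all metrics fixed."""
    moved = apply_domain_transform(pentamer, MotionSpec(
        chain="D", domain="TMD", tilt_deg=3.0, rotation_deg=5.0,
        com_shift_vec=(1.0, 0.0, 0.5)))
    corr = build_correspondence(pentamer, moved)
    base_com = {m.chain: m.com_shift
                for m in domain_com_shift(corr, pentamer, moved, "TMD")}
    base_ang = {m.chain: (m.tilt_deg, m.rotation_deg)
                for m in domain_tilt_rotation(corr, pentamer, moved, "TMD",
                                              axis)}
    Q = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
    t = np.array([3.0, -7.0, 11.0])
    pen_q = pentamer.transformed(Q, t)
    mov_q = moved.transformed(Q, t)
    from plgic.geometry import Axis
    axis_q = Axis(point=Q @ axis.point + t, direction=Q @ axis.direction)
    corr_q = build_correspondence(pen_q, mov_q)
    for m in domain_com_shift(corr_q, pen_q, mov_q, "TMD"):
        assert m.com_shift == pytest.approx(base_com[m.chain], abs=1e-9)
    for m in domain_tilt_rotation(corr_q, pen_q, mov_q, "TMD", axis_q):
        t0, r0 = base_ang[m.chain]
        assert m.tilt_deg == pytest.approx(t0, abs=1e-6)
        assert m.rotation_deg == pytest.approx(r0, abs=1e-6)


def test_symmetric_motion_full_transition_recovery(pentamer, axis):
    """All five TMDs moved by (7.0°, 14.2°, 2.8 Å radial): per-subunit
    recovery matches in the shared build frame."""
    desens = make_desensitized(pentamer)
    corr = build_correspondence(pentamer, desens)
    for m in domain_tilt_rotation(corr, pentamer, desens, "TMD", axis):
        assert m.tilt_deg == pytest.approx(7.0, abs=1e-6)
        assert m.rotation_deg == pytest.approx(14.2, abs=1e-6)
    for m in domain_com_shift(corr, pentamer, desens, "TMD"):
        assert m.com_shift == pytest.approx(2.8, abs=1e-6)
    for m in domain_tilt_rotation(corr, pentamer, desens, "ECD", axis):
        assert m.tilt_deg == pytest.approx(4.3, abs=1e-6)
        assert m.rotation_deg == pytest.approx(6.3, abs=1e-6)
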