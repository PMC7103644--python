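"""Inertia tensor, principal axes, Tait-Bryan extraction, and series/histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_inertia
from memborient.orientation import (
    DegenerateInertiaWarning,
    EulerAngles,
    InertiaTensor,
    PrincipalAxes,
    ReferenceBasis,
    STANDARD_BASIS,
    angle_heatmap_table,
    angle_histogram,
    compute_inertia_tensor,
    direction_cosine_matrix,
    orientation_series,
    principal_axes,
    rotation_zyx,
    taitbryan_zyx,
)
from memborient.synthetic_data import make_rigid_body
from memborient.traj_model import select


class TestInertiaTensor:
    def test_two_point_closed_form(self):
        """Two unit masses at (±1,0,0): diag(0, 2, 2) amu·nm²."""
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 0, 0]])
        masses = np.array([1.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            # collinear cloud: axes ill-defined
            compute_inertia_tensor(coords[:2], masses[:2])
        # add an off-axis point with negligible mass to regularise geometry
        coords2 = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0.0, 1e-3, 0]])
        t = compute_inertia_tensor(coords2, np.array([1.0, 1.0, 1e-12]))
        np.testing.assert_allclose(t.matrix, np.diag([0.0, 2.0, 2.0]), atol=1e-8)

    def test_center_is_mass_weighted_mean(self, rng):
        coords = rng.normal(size=(40, 3))
        masses = rng.uniform(1, 20, 40)
        t = compute_inertia_tensor(coords, masses)
        np.testing.assert_allclose(
            t.center, (masses[:, None] * coords).sum(0) / masses.sum()
        )

    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(25):
            m = rng.integers(3, 100)
            coords = rng.normal(size=(m, 3)) * rng.uniform(0.5, 3.0, 3)
            masses = rng.uniform(1, 20, m)
            t = compute_inertia_tensor(coords, masses)
            expect = brute_inertia(coords, masses)
            scale = np.abs(expect).max()
            np.testing.assert_allclose(t.matrix, expect, atol=1e-12 * scale)

    def test_zero_total_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_inertia_tensor(np.eye(3), np.zeros(3))


class TestPrincipalAxes:
    def test_diagonal_tensor_gives_standard_axes(self):
        t = InertiaTensor(matrix=np.diag([1.0, 2.0, 3.0]), center=np.zeros(3))
        axes = principal_axes(t)
        U = axes.matrix
        np.testing.assert_allclose(np.abs(U), np.eye(3), atol=1e-12)
        assert np.all(np.einsum("ik,ik->k", U, np.eye(3)) >= 0)
        assert np.linalg.det(U) == pytest.approx(1.0)
        np.testing.assert_allclose(axes.moments, [1.0, 2.0, 3.0])

    def test_known_rotation_recovered(self, rng):
        """Tensor built as R·diag·Rᵀ yields R's columns up to the sign convention."""
        for _ in range(20):
            R = rotation_zyx(*rng.uniform(-170, 170, 1), *rng.uniform(-80, 80, 1),
                             *rng.uniform(-170, 170, 1))
            I = R @ np.diag([1.0, 2.5, 4.0]) @ R.T
            axes = principal_axes(InertiaTensor(matrix=I, center=np.zeros(3)))
            for k in range(3):
                col = axes.matrix[:, k]
                assert min(np.linalg.norm(col - R[:, k]), np.linalg.norm(col + R[:, k])) < 1e-9

    def test_reconstruction_identity(self, rng):
        """U·Λ·Uᵀ = I within 1e-10 relative Frobenius norm."""
        for _ in range(20):
            coords = rng.normal(size=(50, 3)) * [3.0, 1.5, 0.7]
            masses = rng.uniform(1, 16, 50)
            t = compute_inertia_tensor(coords, masses)
            axes = principal_axes(t)
            recon = axes.matrix @ np.diag(axes.moments) @ axes.matrix.T
            rel = np.linalg.norm(recon - t.matrix) / np.linalg.norm(t.matrix)
            assert rel < 1e-10

    def test_spherical_tensor_warns_degenerate(self):
        t = InertiaTensor(matrix=np.eye(3), center=np.zeros(3))
        with pytest.warns(DegenerateInertiaWarning):
            axes = principal_axes(t)
        assert axes.degenerate

    def test_sign_continuity_with_previous(self):
        t = InertiaTensor(matrix=np.diag([1.0, 2.0, 3.0]), center=np.zeros(3))
        first = principal_axes(t)
        flipped = PrincipalAxes(
            p1=-first.p1, p2=first.p2, p3=-first.p3, moments=first.moments
        )
        cont = principal_axes(t, previous=flipped)
        for k in range(3):
            assert cont.matrix[:, k] @ flipped.matrix[:, k] >= 0
        assert np.linalg.det(cont.matrix) == pytest.approx(1.0)


class TestDirectionCosineMatrix:
    def test_identity_for_reference_axes(self):
        axes = PrincipalAxes(
            p1=np.array([1.0, 0, 0]), p2=np.array([0, 1.0, 0]),
            p3=np.array([0, 0, 1.0]), moments=np.array([1.0, 2, 3]),
        )
        np.testing.assert_allclose(direction_cosine_matrix(axes), np.eye(3))

    def test_rotated_axes_give_rotation(self):
        Rz = rotation_zyx(90.0, 0.0, 0.0)
        axes = PrincipalAxes(p1=Rz[:, 0], p2=Rz[:, 1], p3=Rz[:, 2],
                             moments=np.array([1.0, 2, 3]))
        np.testing.assert_allclose(direction_cosine_matrix(axes), Rz, atol=1e-12)

    def test_orthogonality_property(self, rng):
        for _ in range(20):
            R = rotation_zyx(*rng.uniform(-179, 179, 3))
            axes = PrincipalAxes(p1=R[:, 0], p2=R[:, 1], p3=R[:, 2],
                                 moments=np.array([1.0, 2, 3]))
            D = direction_cosine_matrix(axes)
            np.testing.assert_allclose(D.T @ D, np.eye(3), atol=1e-12)


class TestTaitBryanZYX:
    def test_identity_is_zero(self):
        a = taitbryan_zyx(np.eye(3))
        assert (a.yaw, a.pitch, a.roll) == (0.0, 0.0, 0.0)

    def test_reference_aligned_axes_give_zero_pitch(self):
        """Long axis in the membrane plane ⇔ pitch 0°."""
        axes = PrincipalAxes(
            p1=np.array([1.0, 0, 0]), p2=np.array([0, 1.0, 0]),
            p3=np.array([0, 0, 1.0]), moments=np.array([1.0, 2, 3]),
        )
        angles = taitbryan_zyx(direction_cosine_matrix(axes, STANDARD_BASIS))
        assert angles.pitch == 0.0

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.floats(-179.9, 180.0),
        st.floats(-85.0, 85.0),
        st.floats(-179.9, 180.0),
    )
    def test_composition_roundtrip(self, yaw, pitch, roll):
        got = taitbryan_zyx(rotation_zyx(yaw, pitch, roll))
        assert not got.gimbal_lock
        assert got.yaw == pytest.approx(yaw, abs=1e-9)
        assert got.pitch == pytest.approx(pitch, abs=1e-9)
        assert got.roll == pytest.approx(roll, abs=1e-9)

    def test_gimbal_lock_flagged_and_consistent(self):
        for pitch in (90.0, -90.0):
            R = rotation_zyx(25.0, pitch, 40.0)
            a = taitbryan_zyx(R)
            assert a.gimbal_lock and a.roll == 0.0
            np.testing.assert_allclose(rotation_zyx(a.yaw, a.pitch, a.roll), R, atol=1e-9)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            taitbryan_zyx(np.eye(3) * 2.0)


class TestOrientationSeries:
    def test_static_trajectory_constant_pitch(self):
        sched = pd.DataFrame({"pitch": [25.0] * 5})
        top, traj, _ = make_rigid_body(sched, n_particles=100, seed=3)
        s = orientation_series(traj, select(top, "all"))
        np.testing.assert_allclose(s.pitch, 25.0, atol=1e-9)

    def test_programmed_ramp_recovered(self):
        sched = pd.DataFrame({"pitch": np.linspace(0, 60, 100)})
        top, traj, _ = make_rigid_body(sched, n_particles=200, seed=3)
        s = orientation_series(traj, select(top, "all"))
        np.testing.assert_allclose(s.pitch, sched["pitch"].values, atol=0.1)

    def test_reference_modes_coincide_when_frame0_aligned(self):
        sched = pd.DataFrame({"pitch": np.linspace(0, 40, 30)})
        top, traj, _ = make_rigid_body(sched, n_particles=150, seed=6)
        std = orientation_series(traj, select(top, "all"), "standard_basis")
        first = orientation_series(traj, select(top, "all"), "first_frame")
        np.testing.assert_allclose(std.pitch, first.pitch, atol=1e-8)

    def test_global_rotation_equivariance(self):
        """Rotating every frame and the reference identically leaves angles unchanged."""
        sched = pd.DataFrame({"pitch": np.linspace(5, 35, 10), "yaw": 10.0})
        top, traj, _ = make_rigid_body(sched, n_particles=150, seed=8)
        sel = select(top, "all")
        base = orientation_series(traj, sel)
        G = rotation_zyx(33.0, 12.0, -21.0)
        for f in traj.frames:
            f.coordinates = f.coordinates @ G.T
        ref = ReferenceBasis(e_x=G[:, 0], e_y=G[:, 1], e_z=G[:, 2])
        rotated_axes = []
        prev = None
        from memborient.orientation import compute_inertia_tensor as cit

        for f in traj.frames:
            t = cit(f.coordinates[sel.atom_indices], top.masses[sel.atom_indices])
            prev = principal_axes(t, previous=prev, reference=ref)
            rotated_axes.append(prev)
        angles = [taitbryan_zyx(direction_cosine_matrix(ax, ref)) for ax in rotated_axes]
        np.testing.assert_allclose([a.pitch for a in angles], base.pitch, atol=1e-8)

    def test_sign_continuity_no_jumps(self):
        sched = pd.DataFrame({"pitch": np.linspace(-80, 80, 200)})
        top, traj, _ = make_rigid_body(sched, n_particles=150, seed=2)
        s = orientation_series(traj, select(top, "all"))
        assert np.abs(np.diff(s.pitch)).max() < 90.0


class TestHistogramsAndHeatmap:
    def _series(self, pitches):
        s = pd.DataFrame({"pitch": pitches})
        top, traj, _ = make_rigid_body(s, n_particles=80, seed=1)
        return orientation_series(traj, select(top, "all"))

    def test_constant_series_single_bin(self):
        s = self._series([0.0] * 20)
        h = angle_histogram(s, bin_width=5.0)
        assert h["probability"].sum() == pytest.approx(1.0)
        top_bin = h.loc[h["probability"].idxmax()]
        assert top_bin["bin_left_deg"] == 0.0 and top_bin["probability"] == 1.0

    def test_unequal_replicas_pool_as_concatenation(self):
        a = self._series(np.linspace(0, 30, 17))
        b = self._series(np.linspace(10, 50, 31))
        pooled = angle_histogram([a, b], bin_width=2.0)
        concat = np.concatenate([a.pitch, b.pitch])
        expect, _ = np.histogram(concat, bins=np.arange(-90, 90.1, 2.0))
        np.testing.assert_allclose(pooled["probability"], expect / expect.sum())

    def test_replica_order_invariance(self):
        a = self._series(np.linspace(0, 30, 17))
        b = self._series(np.linspace(10, 50, 31))
        h1 = angle_histogram([a, b], bin_width=2.0)
        h2 = angle_histogram([b, a], bin_width=2.0)
        np.testing.assert_allclose(h1["probability"], h2["probability"])

    def test_pooling_modes_agree_for_equal_lengths(self):
        a = self._series(np.linspace(0, 30, 20))
        b = self._series(np.linspace(10, 50, 20))
        hf = angle_histogram([a, b], bin_width=5.0, pooling="frames")
        hr = angle_histogram([a, b], bin_width=5.0, pooling="replicas")
        np.testing.assert_allclose(hf["probability"], hr["probability"], atol=1e-12)

    def test_heatmap_rows_are_runs(self):
        rows = [self._series([v] * 10) for v in (10.0, 20.0, 30.0)]
        table = angle_heatmap_table(rows)
        assert table.shape == (3, 10)
        np.testing.assert_allclose(table.iloc[0], 10.0, atol=1e-9)
        np.testing.assert_allclose(table.iloc[2], 30.0, atol=1e-9)

    def test_single_series_heatmap(self):
        s = self._series(np.linspace(0, 9, 10))
        table = angle_heatmap_table(s)
        assert table.shape == (1, 10)
        np.testing.assert_allclose(table.iloc[0].values, s.pitch, atol=1e-9)
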