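"""Orientation recovery and forward-kinematics correctness.

The independent oracle for the transform chain is scipy's Rotation
(extrinsic z-y-x Euler composition) combined with explicit 4x4 matrix
products, coded separately from the package's chain recursion.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from premac import kinematics as kin


def _oracle_R(o: kin.Orientation) -> np.ndarray:
    return Rotation.from_euler("ZYX", [o.yaw, o.pitch, o.roll]).as_matrix()


class TestOrientation:
    def test_level_north_facing_is_identity(self):
        s = kin.ImuSample(0, 0, 1, 0.5, 0, -0.4)
        o = kin.orientation_from_accel_mag(s)
        assert o.as_tuple() == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        roll=st.floats(-3.0, 3.0),
        pitch=st.floats(-1.4, 1.4),
        yaw=st.floats(-3.1, 3.1),
    )
    def test_synthesize_recover_round_trip(self, roll, pitch, yaw):
        """Readings rotated through a known orientation recover it exactly."""
        o = kin.Orientation(roll, pitch, yaw)
        rec = kin.orientation_from_accel_mag(kin.synthesize_readings(o))
        assert rec.roll == pytest.approx(roll, abs=1e-9)
        assert rec.pitch == pytest.approx(pitch, abs=1e-9)
        assert rec.yaw == pytest.approx(yaw, abs=1e-9)

    def test_known_tilt_example(self):
        o = kin.Orientation(np.deg2rad(10), np.deg2rad(20), np.deg2rad(35))
        rec = kin.orientation_from_accel_mag(kin.synthesize_readings(o))
        assert np.rad2deg(rec.roll) == pytest.approx(10, abs=1e-9)
        assert np.rad2deg(rec.pitch) == pytest.approx(20, abs=1e-9)
        assert np.rad2deg(rec.yaw) == pytest.approx(35, abs=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(kin.DegenerateInputError):
            kin.orientation_from_accel_mag(kin.ImuSample(0, 0, 0, 0.5, 0, -0.4))
        with pytest.raises(kin.YawUndefinedError):
            kin.orientation_from_accel_mag(kin.ImuSample(0, 0, 1, 0, 0, 0))

    def test_angles_invariant_to_accel_scale(self, rng):
        """A stronger gravity reading is the same orientation."""
        o = kin.Orientation(0.3, -0.5, 1.1)
        s = kin.synthesize_readings(o)
        scaled = kin.ImuSample(3 * s.acclx, 3 * s.accly, 3 * s.acclz,
                               s.magx, s.magy, s.magz)
        rec = kin.orientation_from_accel_mag(scaled)
        assert rec.as_tuple() == pytest.approx(o.as_tuple(), abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        accel = rng.normal(size=(20, 3))
        mag = rng.normal(size=(20, 3))
        got = kin.orientations_from_stream(accel, mag)
        for i in range(20):
            o = kin.orientation_from_accel_mag(kin.ImuSample(*accel[i], *mag[i]))
            assert got[i] == pytest.approx(o.as_tuple(), abs=1e-12)


class TestRotationMatrix:
    def test_identity(self):
        np.testing.assert_allclose(kin.rotation_matrix(kin.IDENTITY), np.eye(3))

    def test_pure_roll_maps_y_to_z(self):
        R = kin.rotation_matrix(kin.Orientation(np.pi / 2, 0, 0))
        np.testing.assert_allclose(R @ [0, 1, 0], [0, 0, 1], atol=1e-12)

    def test_random_orientations_orthonormal(self, rng):
        for _ in range(1000):
            o = kin.Orientation(*rng.uniform(-np.pi, np.pi, 3))
            R = kin.rotation_matrix(o)
            assert np.abs(R @ R.T - np.eye(3)).max() < 1e-12
            assert abs(np.linalg.det(R) - 1.0) < 1e-12

    def test_matches_scipy_euler_convention(self, rng):
        for _ in range(50):
            o = kin.Orientation(*rng.uniform(-np.pi, np.pi, 3))
            np.testing.assert_allclose(kin.rotation_matrix(o), _oracle_R(o),
                                       atol=1e-12)


class TestHomogeneousTransform:
    def test_identity_orientation(self):
        H = kin.homogeneous_transform(kin.IDENTITY, (0, 0, 300))
        np.testing.assert_allclose(H[:3, :3], np.eye(3))
        np.testing.assert_allclose(H[:3, 3], [0, 0, 300])

    def test_origin_maps_to_translation(self, rng):
        for _ in range(20):
            o = kin.Orientation(*rng.uniform(-np.pi, np.pi, 3))
            d = rng.normal(size=3) * 100
            H = kin.homogeneous_transform(o, d)
            np.testing.assert_allclose(H @ [0, 0, 0, 1], [*d, 1], atol=1e-9)

    def test_composition_matches_pointwise_oracle(self, rng):
        """H1 @ H2 acts on a point cloud like rotate-then-translate twice."""
        o1 = kin.Orientation(0.2, -0.4, 0.9)
        o2 = kin.Orientation(-1.0, 0.3, 0.1)
        d1, d2 = np.array([10.0, 0, 5]), np.array([0.0, -3, 7])
        H = (kin.homogeneous_transform(o1, d1)
             @ kin.homogeneous_transform(o2, d2))
        pts = rng.normal(size=(30, 3)) * 50
        inner = (_oracle_R(o2) @ pts.T).T + d2
        expect = (_oracle_R(o1) @ inner.T).T + d1
        got = (H @ np.column_stack([pts, np.ones(30)]).T).T[:, :3]
        np.testing.assert_allclose(got, expect, atol=1e-9)


def _chain(*links):
    joints = []
    for i, d in enumerate(links):
        joints.append(kin.Joint(f"j{i}", f"j{i - 1}" if i else None, d))
    return kin.BodyModel(joints)


def _fk_oracle(orients, model):
    """Brute-force: multiply explicit 4x4s along each joint's ancestry."""
    out = {}
    for j in model.joints:
        chain, cur = [], j
        while cur is not None:
            chain.append(cur)
            cur = next((x for x in model.joints if x.name == cur.parent), None)
        H = np.eye(4)
        for link in reversed(chain):
            Hl = np.eye(4)
            Hl[:3, :3] = _oracle_R(orients[link.name])
            Hl[:3, 3] = link.translation_mm
            H = H @ Hl
        out[j.name] = H[:3, 3]
    return out


class TestForwardKinematics:
    def test_straight_chain(self):
        model = _chain((0, 0, 300), (0, 0, 250))
        pose = kin.forward_kinematics(
            {"j0": kin.IDENTITY, "j1": kin.IDENTITY}, model)
        np.testing.assert_allclose(pose.positions["j0"], [0, 0, 300])
        np.testing.assert_allclose(pose.positions["j1"], [0, 0, 550])
        pose.validate(model)

    def test_pitched_elbow_matches_oracle(self):
        model = _chain((0, 0, 300), (0, 0, 250))
        orients = {"j0": kin.IDENTITY, "j1": kin.Orientation(0, np.pi / 2, 0)}
        pose = kin.forward_kinematics(orients, model)
        expect = _fk_oracle(orients, model)
        np.testing.assert_allclose(pose.positions["j1"], expect["j1"],
                                   atol=1e-9)

    def test_random_poses_match_oracle_and_conserve_links(self, rng):
        model = kin.BodyModel.default_child()
        for _ in range(500):
            orients = {
                name: kin.Orientation(*rng.uniform(-np.pi, np.pi, 3))
                for name in model.joint_names
            }
            pose = kin.forward_kinematics(orients, model)
            expect = _fk_oracle(orients, model)
            for name in model.joint_names:
                np.testing.assert_allclose(pose.positions[name], expect[name],
                                           atol=1e-9)
            pose.validate(model, tol_mm=1e-6)  # rigid links conserved

    def test_orientation_count_mismatch(self):
        model = _chain((0, 0, 100))
        with pytest.raises(kin.ConfigurationError):
            kin.forward_kinematics({}, model)
        with pytest.raises(kin.ConfigurationError):
            kin.forward_kinematics(
                {"j0": kin.IDENTITY, "ghost": kin.IDENTITY}, model)

    def test_body_model_yaml_round_trip(self, tmp_path):
        import yaml

        model = kin.BodyModel.default_child()
        doc = {"joints": [
            {"name": j.name, "parent": j.parent,
             "translation_mm": list(j.translation_mm)}
            for j in model.joints
        ]}
        p = tmp_path / "body.yaml"
        p.write_text(yaml.safe_dump(doc))
        assert kin.BodyModel.from_yaml(p).joints == model.joints
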