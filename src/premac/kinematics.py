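"""IMU orientation estimation and upper-body forward kinematics.

The wearable hoodie carries seven accelerometer+magnetometer IMUs (one
per forearm and upper arm, three along the back).  Each IMU's absolute
orientation is recovered from gravity (roll and pitch) and from the
tilt-compensated magnetic field (yaw); joint positions then follow from
a homogeneous-transform chain over the measured body link lengths.

Conventions
-----------
Angles are named by rotation axis: roll about x (front), pitch about y
(left), yaw about z (up).  A segment's body-to-parent rotation is

    R = Rz(yaw) @ Ry(pitch) @ Rx(roll)

i.e. roll applied first.  At rest the accelerometer reads +1 g opposite
gravity, so a level, north-facing sensor reads accel=(0,0,1).  With the
local magnetic field pointing north and downward (northern hemisphere),
its horizontal projection defines yaw zero.  Gyroscopes present in the
hardware are not used: the orientation estimate is purely
accelerometer+magnetometer, with no sensor-fusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class DegenerateInputError(ValueError):
    """Zero acceleration vector: gravity direction undefined."""


class YawUndefinedError(ValueError):
    """Zero magnetic vector: heading undefined."""


class ConfigurationError(ValueError):
    """Body model and orientation set do not match."""


@dataclass(frozen=True)
class ImuSample:
    """One accelerometer (g) + magnetometer (arbitrary units) reading."""

    acclx: float
    accly: float
    acclz: float
    magx: float
    magy: float
    magz: float

    @property
    def accel(self) -> np.ndarray:
        return np.array([self.acclx, self.accly, self.acclz])

    @property
    def mag(self) -> np.ndarray:
        return np.array([self.magx, self.magy, self.magz])


@dataclass(frozen=True)
class Orientation:
    """Roll/pitch/yaw in radians (axes x/y/z respectively).

    Pitch is confined to [-pi/2, pi/2] by construction of the gravity
    decomposition; roll and yaw live on (-pi, pi].
    """

    roll: float
    pitch: float
    yaw: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.roll, self.pitch, self.yaw)


IDENTITY = Orientation(0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Orientation from raw readings
# ---------------------------------------------------------------------------


def orientation_from_accel_mag(sample: ImuSample) -> Orientation:
    """Recover absolute orientation from one accelerometer+magnetometer pair.

    Roll and pitch come from the gravity direction; yaw from the
    magnetometer after de-rotating (tilt compensating) by roll and pitch:

        roll  = atan2(ay, az)
        pitch = atan2(-ax, sqrt(ay^2 + az^2))
        yaw   = atan2(mz*sin(roll) - my*cos(roll),
                      mx*cos(pitch) + (my*sin(roll) + mz*cos(roll))*sin(pitch))

    which is the exact inverse of ``rotation_matrix`` applied to gravity
    (0,0,1) and a north-pointing field, for pitch in (-pi/2, pi/2).
    """
    a, m = sample.accel, sample.mag
    if np.linalg.norm(a) == 0.0:
        raise DegenerateInputError("zero acceleration vector: orientation undefined")
    if np.linalg.norm(m) == 0.0:
        raise YawUndefinedError("zero magnetic vector: yaw undefined")
    roll, pitch, yaw = _angles_from_readings(
        a[None, :], m[None, :]
    )[0]
    return Orientation(float(roll), float(pitch), float(yaw))


def _angles_from_readings(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Vectorized (n,3),(n,3) -> (n,3) array of [roll, pitch, yaw].

    Rows with zero-norm accelerometer or magnetometer become NaN rather
    than raising, so corrupted samples propagate as missing.
    """
    ax, ay, az = accel[:, 0], accel[:, 1], accel[:, 2]
    with np.errstate(invalid="ignore"):
        roll = np.arctan2(ay, az)
        pitch = np.arctan2(-ax, np.hypot(ay, az))
        sr, cr = np.sin(roll), np.cos(roll)
        sp, cp = np.sin(pitch), np.cos(pitch)
        mx, my, mz = mag[:, 0], mag[:, 1], mag[:, 2]
        yaw = np.arctan2(
            mz * sr - my * cr,
            mx * cp + my * sp * sr + mz * sp * cr,
        )
    out = np.column_stack([roll, pitch, yaw])
    bad = (np.linalg.norm(accel, axis=1) == 0) | (np.linalg.norm(mag, axis=1) == 0)
    out[bad] = np.nan
    return out


def orientations_from_stream(accel: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Per-sample [roll, pitch, yaw] (radians) for whole-stream arrays."""
    return _angles_from_readings(np.asarray(accel, float), np.asarray(mag, float))


def synthesize_readings(
    o: Orientation,
    mag_field: tuple[float, float, float] = (0.5, 0.0, -0.4),
) -> ImuSample:
    """Ideal noise-free readings a resting IMU at orientation ``o`` produces.

    The inverse of ``orientation_from_accel_mag``; used by the simulator
    and by round-trip tests.
    """
    R = rotation_matrix(o)
    a = R.T @ np.array([0.0, 0.0, 1.0])
    m = R.T @ np.asarray(mag_field, float)
    return ImuSample(*a, *m)


# ---------------------------------------------------------------------------
# Rotations and homogeneous transforms
# ---------------------------------------------------------------------------


def rotation_matrix(o: Orientation) -> np.ndarray:
    """Body-to-parent rotation Rz(yaw) @ Ry(pitch) @ Rx(roll)."""
    sr, cr = np.sin(o.roll), np.cos(o.roll)
    sp, cp = np.sin(o.pitch), np.cos(o.pitch)
    sy, cy = np.sin(o.yaw), np.cos(o.yaw)
    return np.array([
        [cy * cp, cy * sp * sr - sy * cr, sy * sr + cy * sp * cr],
        [sy * cp, sy * sp * sr + cy * cr, sy * sp * cr - cy * sr],
        [-sp, cp * sr, cp * cr],
    ])


def homogeneous_transform(o: Orientation, d) -> np.ndarray:
    """4x4 transform [R d; 0 1] with translation ``d`` in mm."""
    H = np.eye(4)
    H[:3, :3] = rotation_matrix(o)
    H[:3, 3] = np.asarray(d, float)
    return H


# ---------------------------------------------------------------------------
# Body model and forward kinematics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Joint:
    name: str
    parent: str | None
    translation_mm: tuple[float, float, float]


@dataclass
class BodyModel:
    """Joint tree rooted at the spine base, with manually measured links.

    The base frame sits at the spine base: +x front, +y the child's
    left, +z up.  ``translation_mm`` of a joint is the link vector from
    its parent's frame origin, expressed in the parent frame.
    """

    joints: list[Joint] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [j.name for j in self.joints]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate joint names in body model")
        seen: set[str] = set()
        for j in self.joints:
            if j.parent is not None and j.parent not in seen:
                raise ConfigurationError(
                    f"joint '{j.name}' listed before its parent '{j.parent}'"
                )
            if np.linalg.norm(j.translation_mm) <= 0:
                raise ConfigurationError(f"joint '{j.name}' has zero link length")
            seen.add(j.name)

    @property
    def joint_names(self) -> list[str]:
        return [j.name for j in self.joints]

    def link_length(self, name: str) -> float:
        j = next(j for j in self.joints if j.name == name)
        return float(np.linalg.norm(j.translation_mm))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BodyModel":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls([
            Joint(j["name"], j.get("parent"), tuple(j["translation_mm"]))
            for j in doc["joints"]
        ])

    @classmethod
    def default_child(cls) -> "BodyModel":
        """A medium child-size upper-body model (link lengths in mm)."""
        return cls([
            Joint("torso", None, (0.0, 0.0, 300.0)),
            Joint("l_shoulder", "torso", (0.0, 170.0, 120.0)),
            Joint("l_elbow", "l_shoulder", (0.0, 40.0, -260.0)),
            Joint("l_wrist", "l_elbow", (0.0, 0.0, -250.0)),
            Joint("r_shoulder", "torso", (0.0, -170.0, 120.0)),
            Joint("r_elbow", "r_shoulder", (0.0, -40.0, -260.0)),
            Joint("r_wrist", "r_elbow", (0.0, 0.0, -250.0)),
        ])


@dataclass
class SkeletonPose:
    """Per-joint 3-D positions (mm, base frame) and rotation matrices."""

    positions: dict[str, np.ndarray]
    rotations: dict[str, np.ndarray]

    def validate(self, model: BodyModel, tol_mm: float = 1e-6) -> "SkeletonPose":
        for j in model.joints:
            R = self.rotations[j.name]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
                raise ValueError(f"rotation of '{j.name}' is not orthonormal")
            if abs(np.linalg.det(R) - 1.0) > 1e-9:
                raise ValueError(f"rotation of '{j.name}' has det != +1")
            parent_pos = (
                np.zeros(3) if j.parent is None else self.positions[j.parent]
            )
            d = np.linalg.norm(self.positions[j.name] - parent_pos)
            if abs(d - model.link_length(j.name)) > tol_mm:
                raise ValueError(
                    f"link to '{j.name}' has length {d:.9f} mm, expected "
                    f"{model.link_length(j.name):.9f} mm"
                )
        return self


def forward_kinematics(
    orientations: dict[str, Orientation], model: BodyModel
) -> SkeletonPose:
    """Joint positions by chaining homogeneous transforms root-to-leaf.

    Joint n's transform to the base frame is H_1 @ H_2 @ ... @ H_n along
    its chain; its position is the translation part of that product.
    """
    missing = [n for n in model.joint_names if n not in orientations]
    extra = [n for n in orientations if n not in model.joint_names]
    if missing or extra:
        raise ConfigurationError(
            f"orientations do not match body model (missing {missing}, "
            f"unexpected {extra})"
        )
    H_abs: dict[str, np.ndarray] = {}
    positions: dict[str, np.ndarray] = {}
    rotations: dict[str, np.ndarray] = {}
    for j in model.joints:
        H_local = homogeneous_transform(orientations[j.name], j.translation_mm)
        H = H_local if j.parent is None else H_abs[j.parent] @ H_local
        H_abs[j.name] = H
        positions[j.name] = H[:3, 3].copy()
        rotations[j.name] = H[:3, :3].copy()
    return SkeletonPose(positions=positions, rotations=rotations)


def plot_pose(pose: SkeletonPose, model: BodyModel, path: str | Path) -> None:
    """Save a static 3-D stick-figure plot of one pose (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure()
    ax = fig.add_subplot(projection="3d")
    for j in model.joints:
        p0 = np.zeros(3) if j.parent is None else pose.positions[j.parent]
        p1 = pose.positions[j.name]
        ax.plot(*zip(p0, p1), "b-o", markersize=3)
    ax.set_xlabel("x front (mm)")
    ax.set_ylabel("y left (mm)")
    ax.set_zlabel("z up (mm)")
    fig.savefig(path, dpi=100)
    plt.close(fig)
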