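"""Binocular viewing geometry for a fixed-eyed animal, in Fick coordinates.

The world frame is right-handed with the Z-axis pointing out in front of the
animal and Y vertically upwards; positive azimuth is an anticlockwise rotation
about Y, so azimuth increases towards the animal's left.  Head pose is
described by an azimuth-longitude and an elevation-latitude (Fick coordinates:
the elevation rotation is applied first, then the azimuth).  The two eyes are
fixed on the head, displaced +/- I/2 along the head's X-axis (left eye at +X),
and share the head's orientation, so each eye's visual axis is parallel to the
gaze vector.

For a point at finite distance inside the binocular overlap the azimuths seen
by the two eyes differ; their difference ``delta = alpha_R - alpha_L`` is the
binocular disparity (positive, larger for nearer points) and their mean is the
cyclopean (headcentric) azimuth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Eye",
    "HeadPose",
    "HeadDirection",
    "RetinalDirection",
    "fick_rotation",
    "eye_nodal_point",
    "world_to_head",
    "head_direction_to_world",
    "project_to_retina",
    "refixate",
    "cyclopean_azimuth",
    "disparity",
    "direction_unit_vector",
]

_X = np.array([1.0, 0.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


class Eye(str, enum.Enum):
    """Which eye a retinal quantity refers to."""

    LEFT = "left"
    RIGHT = "right"


def fick_rotation(azimuth: float, elevation: float) -> np.ndarray:
    """Rotation matrix for Fick azimuth-longitude / elevation-latitude.

    Parameters are in degrees.  The elevation rotation (about X) is applied
    first, then the azimuth rotation (about Y):  ``M = Ry(azimuth) @
    Rx(elevation)``.  Applying the result to the gaze axis Z gives the unit
    vector ``[cos k sin a, sin k, cos k cos a]``.
    """
    a = np.deg2rad(azimuth)
    k = np.deg2rad(elevation)
    ry = np.array(
        [
            [np.cos(a), 0.0, np.sin(a)],
            [0.0, 1.0, 0.0],
            [-np.sin(a), 0.0, np.cos(a)],
        ]
    )
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(k), np.sin(k)],
            [0.0, -np.sin(k), np.cos(k)],
        ]
    )
    return ry @ rx


def direction_unit_vector(azimuth: float, elevation: float) -> np.ndarray:
    """Unit vector for a (azimuth, elevation) direction, degrees in."""
    a = np.deg2rad(azimuth)
    k = np.deg2rad(elevation)
    return np.array([np.cos(k) * np.sin(a), np.sin(k), np.cos(k) * np.cos(a)])


def _extract_fick(vec: np.ndarray) -> tuple[float, float, float]:
    """Split a head/eye-frame vector into (azimuth, elevation, distance).

    Azimuth uses the two-argument arctangent of (x, z) so quadrants are
    correct; elevation is the latitude asin(y/r), restricted to [-90, 90].
    """
    dist = float(np.linalg.norm(vec))
    if dist == 0.0:
        raise ValueError("degenerate point: coincides with the reference point")
    azimuth = float(np.degrees(np.arctan2(vec[0], vec[2])))
    elevation = float(np.degrees(np.arcsin(np.clip(vec[1] / dist, -1.0, 1.0))))
    return azimuth, elevation, dist


@dataclass(frozen=True)
class HeadPose:
    """Pose of the head: Fick angles, position and interocular distance.

    ``rotation`` (the world-from-head matrix M_W^H) is normally derived from
    the angles.  A pose produced by composing rotations (see :func:`refixate`)
    may carry a torsion component that pure Fick angles cannot express, so the
    full matrix is stored; ``azimuth``/``elevation`` always describe the gaze
    direction of ``rotation``.
    """

    azimuth: float = 0.0
    elevation: float = 0.0
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    interocular: float = 1.0
    rotation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.interocular > 0:
            raise ValueError("interocular distance must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("position must be a finite 3-vector")
        if self.rotation is None:
            object.__setattr__(
                self, "rotation", fick_rotation(self.azimuth, self.elevation)
            )
        else:
            m = np.asarray(self.rotation, float)
            if m.shape != (3, 3):
                raise ValueError("rotation must be 3x3")
            if not np.allclose(m @ m.T, np.eye(3), atol=1e-8) or not np.isclose(
                np.linalg.det(m), 1.0, atol=1e-8
            ):
                raise ValueError("rotation must be orthonormal with det +1")
            object.__setattr__(self, "rotation", m)

    @classmethod
    def from_rotation(
        cls,
        rotation: np.ndarray,
        position: np.ndarray | None = None,
        interocular: float = 1.0,
    ) -> "HeadPose":
        """Build a pose from a full rotation matrix (gaze angles extracted)."""
        gaze = np.asarray(rotation, float) @ _Z
        azimuth, elevation, _ = _extract_fick(gaze)
        return cls(
            azimuth=azimuth,
            elevation=elevation,
            position=np.zeros(3) if position is None else position,
            interocular=interocular,
            rotation=rotation,
        )

    @property
    def gaze(self) -> np.ndarray:
        """Gaze direction in world coordinates (unit vector)."""
        return self.rotation @ _Z


@dataclass(frozen=True)
class HeadDirection:
    """Direction and range of a point as seen from the head origin."""

    azimuth: float
    elevation: float
    distance: float

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError("distance must be positive")


@dataclass(frozen=True)
class RetinalDirection:
    """Direction and range of a point as seen from one eye's nodal point."""

    eye: Eye
    azimuth: float
    elevation: float
    distance: float

    def __post_init__(self) -> None:
        if not self.distance > 0:
            raise ValueError("distance must be positive")


def eye_nodal_point(pose: HeadPose, eye: Eye) -> np.ndarray:
    """World position of an eye's nodal point: P_W^H +/- (I/2) M_W^H X."""
    sign = 1.0 if Eye(eye) is Eye.LEFT else -1.0
    return pose.position + sign * 0.5 * pose.interocular * (pose.rotation @ _X)


def world_to_head(pose: HeadPose, point: np.ndarray) -> HeadDirection:
    """Headcentric Fick direction and distance of a world point."""
    rel = pose.rotation.T @ (np.asarray(point, float) - pose.position)
    azimuth, elevation, dist = _extract_fick(rel)
    return HeadDirection(azimuth=azimuth, elevation=elevation, distance=dist)


def head_direction_to_world(pose: HeadPose, direction: HeadDirection) -> np.ndarray:
    """Inverse of :func:`world_to_head`: world coordinates of a direction."""
    vec = direction.distance * direction_unit_vector(
        direction.azimuth, direction.elevation
    )
    return pose.position + pose.rotation @ vec


def project_to_retina(pose: HeadPose, eye: Eye, point: np.ndarray) -> RetinalDirection:
    """Retinal Fick direction of a world point as seen by one eye.

    The eyes share the head's rotation matrix; the projection is the
    head-frame extraction applied about the eye's nodal point.
    """
    nodal = eye_nodal_point(pose, eye)
    rel = pose.rotation.T @ (np.asarray(point, float) - nodal)
    azimuth, elevation, dist = _extract_fick(rel)
    return RetinalDirection(
        eye=Eye(eye), azimuth=azimuth, elevation=elevation, distance=dist
    )


def refixate(pose: HeadPose, target: HeadDirection) -> HeadPose:
    """New head pose after a saccade that fixates ``target``.

    The new rotation is the old one postmultiplied by the Fick matrix of the
    target's headcentric direction; the head position is unchanged.  The
    target then lies on the gaze vector, i.e. re-projects to (0, 0).
    """
    m_new = pose.rotation @ fick_rotation(target.azimuth, target.elevation)
    return HeadPose.from_rotation(
        m_new, position=pose.position, interocular=pose.interocular
    )


def cyclopean_azimuth(left: RetinalDirection, right: RetinalDirection) -> float:
    """Headcentric azimuth alpha_H = (alpha_R + alpha_L) / 2."""
    return 0.5 * (right.azimuth + left.azimuth)


def disparity(left: RetinalDirection, right: RetinalDirection) -> float:
    """Binocular disparity delta = alpha_R - alpha_L (positive when near)."""
    return right.azimuth - left.azimuth
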