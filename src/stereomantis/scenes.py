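"""Synthetic scenes of spherical targets and their lat-long retinal images.

Scenes emulate the training environment of the saccade model: a handful of
bright spheres in front of the animal, directions drawn from a broad normal
distribution, distances uniform over the near field, and diameters scaled so
every sphere subtends the same angle at the origin (forcing the downstream
network to use disparity rather than angular size as its distance cue).

Retinae are modelled as equally spaced lat-long grids of units (a Mercator-
style flattening of azimuth-longitude and elevation-latitude); a unit is
active when its direction falls inside a sphere's silhouette as seen from
that eye's nodal point.  Rendering is binary by unit-centre inclusion, with
no anti-aliasing or occlusion handling — spheres simply union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    Eye,
    HeadDirection,
    HeadPose,
    direction_unit_vector,
    eye_nodal_point,
    head_direction_to_world,
    world_to_head,
)

__all__ = [
    "RetinalGrid",
    "Sphere",
    "Scene",
    "RetinalImage",
    "SceneLabel",
    "sphere_diameter_for_subtense",
    "angular_subtense",
    "sample_training_scene",
    "render_scene",
    "add_noise",
    "label_scene",
    "scenes_to_frame",
    "scenes_from_frame",
]


@dataclass(frozen=True)
class RetinalGrid:
    """Equally spaced lat-long grid of retinal (or headcentric) units.

    The default is 51 x 51 units spanning -70 to +70 degrees in both azimuth
    and elevation, a spacing of 2.8 degrees.  Flattened (linear) indices are
    row-major over elevation then azimuth: ``index = i_el * n_azimuth + i_az``.
    """

    n_azimuth: int = 51
    n_elevation: int = 51
    extent: float = 70.0

    def __post_init__(self) -> None:
        if self.n_azimuth < 2 or self.n_elevation < 2:
            raise ValueError("grids need at least 2 units per axis")
        if not self.extent > 0:
            raise ValueError("extent must be positive")

    @property
    def azimuths(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.n_azimuth)

    @property
    def elevations(self) -> np.ndarray:
        return np.linspace(-self.extent, self.extent, self.n_elevation)

    @property
    def spacing(self) -> tuple[float, float]:
        """(azimuth, elevation) spacing between adjacent units, degrees."""
        return (
            2 * self.extent / (self.n_azimuth - 1),
            2 * self.extent / (self.n_elevation - 1),
        )

    @property
    def n_units(self) -> int:
        return self.n_azimuth * self.n_elevation

    def unit_directions(self) -> np.ndarray:
        """Unit vectors of every grid direction, shape (n_el, n_az, 3)."""
        az = np.deg2rad(self.azimuths)[None, :]
        el = np.deg2rad(self.elevations)[:, None]
        return np.stack(
            [
                np.cos(el) * np.sin(az) + 0.0 * el,
                np.sin(el) + 0.0 * az,
                np.cos(el) * np.cos(az),
            ],
            axis=-1,
        )

    def linear_index(self, i_elevation: int, i_azimuth: int) -> int:
        return i_elevation * self.n_azimuth + i_azimuth

    def direction_of(self, linear_index: int) -> tuple[float, float]:
        """(azimuth, elevation) of a flattened unit index."""
        i_el, i_az = divmod(int(linear_index), self.n_azimuth)
        return float(self.azimuths[i_az]), float(self.elevations[i_el])

    def nearest_unit(self, azimuth: float, elevation: float) -> tuple[int, int]:
        """(i_elevation, i_azimuth) of the unit angularly nearest a direction.

        Nearest is measured by great-circle separation between 3D direction
        vectors (exhaustive over the grid), not per-coordinate rounding.
        """
        target = direction_unit_vector(azimuth, elevation)
        dots = self.unit_directions() @ target
        flat = int(np.argmax(dots))
        return divmod(flat, self.n_azimuth)


def sphere_diameter_for_subtense(distance: float, subtense: float) -> float:
    """Diameter of a sphere subtending ``subtense`` degrees at ``distance``.

    The subtense of a sphere's silhouette seen from range d is
    ``2 asin(r / d)``; this is its exact inverse.  A sphere at 8 cm
    subtending 15 degrees has diameter 2.1 cm.
    """
    if not distance > 0:
        raise ValueError("distance must be positive")
    if not 0 <= subtense < 180:
        raise ValueError("subtense must lie in [0, 180) degrees")
    return 2.0 * distance * np.sin(np.deg2rad(subtense) / 2.0)


def angular_subtense(diameter: float, distance: float) -> float:
    """Angular subtense (degrees) of a sphere's silhouette from a viewpoint."""
    r = diameter / 2.0
    if distance <= r:
        raise ValueError("viewpoint lies inside the sphere")
    return float(2.0 * np.degrees(np.arcsin(r / distance)))


@dataclass(frozen=True)
class Sphere:
    """A spherical target: headcentric direction, range and physical size."""

    azimuth: float
    elevation: float
    distance: float
    diameter: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if not self.distance > self.diameter / 2:
            raise ValueError("sphere must not contain the origin")

    @property
    def direction(self) -> HeadDirection:
        return HeadDirection(self.azimuth, self.elevation, self.distance)

    def centre(self) -> np.ndarray:
        """World coordinates of the sphere centre (identity frame)."""
        return self.distance * direction_unit_vector(self.azimuth, self.elevation)


@dataclass(frozen=True)
class Scene:
    """An ordered collection of spheres (possibly empty)."""

    spheres: tuple[Sphere, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))

    def __len__(self) -> int:
        return len(self.spheres)


@dataclass
class RetinalImage:
    """Per-unit activation of one eye (background 0, targets 1 pre-noise)."""

    eye: Eye
    values: np.ndarray
    grid: RetinalGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.grid.n_elevation, self.grid.n_azimuth):
            raise ValueError("image shape does not match its grid")


@dataclass(frozen=True)
class SceneLabel:
    """Supervised target for a scene: the output unit to saccade towards."""

    index: tuple[int, int]  # (i_elevation, i_azimuth)
    azimuth: float
    elevation: float
    is_no_action: bool


def sample_training_scene(
    rng: np.random.Generator,
    n_objects: int = 4,
    direction_sd: float = 45.0,
    distance_range: tuple[float, float] = (1.0, 11.0),
    subtense: float = 10.0,
) -> Scene:
    """Draw one training scene.

    Azimuths and elevations are independent N(0, direction_sd) in degrees,
    distances uniform over ``distance_range`` (cm), and each diameter is
    scaled so the sphere subtends ``subtense`` degrees at the origin.
    """
    lo, hi = distance_range
    if not (0 < lo <= hi):
        raise ValueError("invalid distance range")
    if n_objects < 0 or direction_sd < 0 or not 0 < subtense < 180:
        raise ValueError("invalid scene parameters")
    spheres = []
    for _ in range(n_objects):
        az, el = rng.normal(0.0, direction_sd, size=2)
        dist = rng.uniform(lo, hi)
        spheres.append(
            Sphere(
                azimuth=float(az),
                elevation=float(el),
                distance=float(dist),
                diameter=sphere_diameter_for_subtense(dist, subtense),
            )
        )
    return Scene(spheres=tuple(spheres))


def render_scene(
    scene: Scene,
    pose: HeadPose,
    eye: Eye,
    grid: RetinalGrid,
) -> RetinalImage:
    """Binary lat-long image of a scene as seen by one eye.

    A unit is active iff the angle (at the eye's nodal point) between its
    direction and some sphere's centre direction is at most that sphere's
    angular radius as seen from the eye.
    """
    values = np.zeros((grid.n_elevation, grid.n_azimuth))
    if len(scene) == 0:
        return RetinalImage(eye=Eye(eye), values=values, grid=grid)
    nodal = eye_nodal_point(pose, eye)
    dirs = grid.unit_directions()  # eye frame == head frame orientation
    for sph in scene.spheres:
        rel = pose.rotation.T @ (sph.centre() - nodal)
        dist = np.linalg.norm(rel)
        r = sph.diameter / 2.0
        if dist <= r:
            values[:] = 1.0  # eye inside the sphere: everything is covered
            continue
        cos_radius = np.cos(np.arcsin(r / dist))
        values[dirs @ (rel / dist) >= cos_radius] = 1.0
    return RetinalImage(eye=Eye(eye), values=values, grid=grid)


def add_noise(
    image: RetinalImage, sigma: float, rng: np.random.Generator
) -> RetinalImage:
    """Add i.i.d. zero-mean Gaussian noise of s.d. ``sigma``, clipped at 0."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return RetinalImage(eye=image.eye, values=image.values.copy(), grid=image.grid)
    noisy = np.clip(image.values + rng.normal(0.0, sigma, image.values.shape), 0.0, None)
    return RetinalImage(eye=image.eye, values=noisy, grid=image.grid)


def _centre_visible(sph: Sphere, pose: HeadPose, grid: RetinalGrid) -> bool:
    """Is the sphere's centre inside the grid extent of at least one eye?"""
    centre = sph.centre()
    for eye in (Eye.LEFT, Eye.RIGHT):
        nodal = eye_nodal_point(pose, eye)
        rel = pose.rotation.T @ (centre - nodal)
        if np.linalg.norm(rel) == 0:
            continue
        az = np.degrees(np.arctan2(rel[0], rel[2]))
        el = np.degrees(np.arcsin(np.clip(rel[1] / np.linalg.norm(rel), -1, 1)))
        if abs(az) <= grid.extent and abs(el) <= grid.extent:
            return True
    return False


def label_scene(
    scene: Scene,
    grid: RetinalGrid,
    pose: HeadPose | None = None,
) -> SceneLabel:
    """Output-grid unit nearest the headcentric direction of the nearest
    visible sphere; the (0, 0) 'no action' unit when nothing is visible.

    Visibility means the sphere's *centre* projects within the grid extent of
    at least one eye.  Nearness is distance from the head position.
    """
    pose = pose if pose is not None else HeadPose()
    visible = [s for s in scene.spheres if _centre_visible(s, pose, grid)]
    if not visible:
        i_el, i_az = grid.nearest_unit(0.0, 0.0)
        az, el = grid.direction_of(grid.linear_index(i_el, i_az))
        return SceneLabel(index=(i_el, i_az), azimuth=az, elevation=el,
                          is_no_action=True)
    nearest = min(
        visible, key=lambda s: np.linalg.norm(s.centre() - pose.position)
    )
    hd = world_to_head(pose, nearest.centre())
    i_el, i_az = grid.nearest_unit(hd.azimuth, hd.elevation)
    az, el = grid.direction_of(grid.linear_index(i_el, i_az))
    return SceneLabel(index=(i_el, i_az), azimuth=az, elevation=el,
                      is_no_action=(az == 0.0 and el == 0.0))


def scenes_to_frame(scenes: list[Scene]) -> pd.DataFrame:
    """Tabulate scenes, one sphere per row (scene, azimuth, elevation,
    distance, diameter).  Empty scenes contribute no rows but keep their id
    implicitly via the contiguous scene counter of ``scenes_from_frame``."""
    rows = []
    for i, scene in enumerate(scenes):
        for s in scene.spheres:
            rows.append(
                dict(scene=i, azimuth=s.azimuth, elevation=s.elevation,
                     distance=s.distance, diameter=s.diameter)
            )
    return pd.DataFrame(
        rows, columns=["scene", "azimuth", "elevation", "distance", "diameter"]
    )


def scenes_from_frame(frame: pd.DataFrame) -> list[Scene]:
    """Inverse of :func:`scenes_to_frame` (empty trailing scenes are lost)."""
    scenes: list[Scene] = []
    if len(frame) == 0:
        return scenes
    n = int(frame["scene"].max()) + 1
    for i in range(n):
        sub = frame[frame["scene"] == i]
        spheres = tuple(
            Sphere(r.azimuth, r.elevation, r.distance, r.diameter)
            for r in sub.itertuples()
        )
        scenes.append(Scene(spheres=spheres))
    return scenes


def write_scenes_csv(scenes: list[Scene], path) -> None:
    scenes_to_frame(scenes).to_csv(path, index=False)


def read_scenes_csv(path) -> list[Scene]:
    return scenes_from_frame(pd.read_csv(path))
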