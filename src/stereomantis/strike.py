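"""Single centre-surround disparity sensor triggering predatory strikes.

A lone binocular neuron receives one inner-product drive per eye.  Each
monocular pathway first low-pass filters the image spatially (coarse
ommatidial sampling), then high-pass filters in time and full-wave rectifies,
so only temporal change drives the sensor, regardless of contrast sign.  The
receptive field in each eye has an excitatory centre and an inhibitory
surround, positioned nasally so the two lines of sight intersect a few
centimetres in front of the head — the catch range.  Binocular combination is
a thresholded sum raised to an expansive power (default 5): the threshold
silences purely monocular stimulation and the power law strongly favours
simultaneous excitation of both centres.  Strike probability per frame is
proportional to the instantaneous activity.

Because the surrounds inhibit, a pair of distant objects that locally mimics
a single near target (a 'ghost match') necessarily stimulates the surround in
one eye and evokes less activity than the real target, without any
sensor-to-sensor interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import Eye, HeadPose, direction_unit_vector
from .scenes import (
    RetinalGrid,
    Scene,
    Sphere,
    render_scene,
    sphere_diameter_for_subtense,
)

__all__ = [
    "MonocularPreproc",
    "CentreSurroundRF",
    "StrikeSensor",
    "DichopticStimulus",
    "default_strike_grid",
    "make_default_sensor",
    "preprocess",
    "monocular_drive",
    "binocular_response",
    "run_trial",
    "build_stimulus",
]


def default_strike_grid() -> RetinalGrid:
    """Fine frontal grid (1 deg spacing over +/-35 deg) for strike stimuli."""
    return RetinalGrid(n_azimuth=71, n_elevation=71, extent=35.0)


@dataclass(frozen=True)
class MonocularPreproc:
    """Early monocular processing shared by both eyes.

    spatial_scale : Gaussian low-pass s.d. in degrees (ommatidial blur).
    time_constant : first-order temporal high-pass constant, seconds.  The
        default (250 ms) retains a motion trail comparable to the preferred
        target size for typical sweep speeds, so the drive image resembles
        the recently moved target rather than only its instantaneous edges.
    """

    spatial_scale: float = 2.0
    time_constant: float = 0.25

    def __post_init__(self) -> None:
        if self.spatial_scale <= 0 or self.time_constant <= 0:
            raise ValueError("preprocessing scales must be positive")

    def highpass_gain(self, frame_interval: float) -> float:
        """Single-step retention factor a = tau / (tau + dt)."""
        return self.time_constant / (self.time_constant + frame_interval)


@dataclass(frozen=True)
class CentreSurroundRF:
    """Excitatory-centre / inhibitory-surround window for one eye.

    The window is a difference of Gaussians in angular separation from the
    RF centre: a narrow excitatory Gaussian of scale ``centre_radius / 2``
    minus a broad inhibitory Gaussian of scale ``surround_radius / 2`` (the
    radii are the ~2-sigma extents of each lobe).  The default surround
    weight balances the centre's integral, so very large uniform stimuli are
    roughly self-cancelling — the origin of the size tuning.

    Directions are retinal (azimuth, elevation) in degrees; the centre sits
    nasally so both eyes' lines of sight cross in front of the animal.
    """

    eye: Eye
    centre_azimuth: float
    centre_elevation: float = 0.0
    centre_radius: float = 5.0
    surround_radius: float = 15.0
    centre_weight: float = 1.0
    surround_weight: float = -1.0 / 9.0  # balances the default radii

    def __post_init__(self) -> None:
        if not self.surround_radius > self.centre_radius > 0:
            raise ValueError("need surround radius > centre radius > 0")
        if not (self.centre_weight > 0 > self.surround_weight):
            raise ValueError("centre weight must be positive, surround negative")

    def window(self, grid: RetinalGrid) -> np.ndarray:
        """Difference-of-Gaussians weight evaluated at every grid unit."""
        centre_dir = direction_unit_vector(self.centre_azimuth, self.centre_elevation)
        sep = np.degrees(
            np.arccos(np.clip(grid.unit_directions() @ centre_dir, -1.0, 1.0))
        )
        sigma_c = self.centre_radius / 2.0
        sigma_s = self.surround_radius / 2.0
        return self.centre_weight * np.exp(-0.5 * (sep / sigma_c) ** 2) + (
            self.surround_weight * np.exp(-0.5 * (sep / sigma_s) ** 2)
        )

    @staticmethod
    def balanced_surround_weight(
        centre_radius: float, surround_radius: float, centre_weight: float = 1.0
    ) -> float:
        """Surround weight whose 2D integral cancels the centre's."""
        return -centre_weight * (centre_radius / surround_radius) ** 2


@dataclass(frozen=True)
class StrikeSensor:
    """The binocular strike neuron: two RFs plus output nonlinearity.

    activity = max(drive_L + drive_R - threshold, 0) ** exponent; the strike
    probability per frame is min(gain * activity, 1).
    """

    left_rf: CentreSurroundRF
    right_rf: CentreSurroundRF
    exponent: float = 5.0
    threshold: float = 0.0
    gain: float = 0.0

    def __post_init__(self) -> None:
        if not self.exponent > 1:
            raise ValueError("output nonlinearity must be expansive (exponent > 1)")
        if self.threshold < 0 or self.gain < 0:
            raise ValueError("threshold and gain must be non-negative")


@dataclass(frozen=True)
class DichopticStimulus:
    """Paired per-eye frame sequences on a common grid."""

    left: np.ndarray  # (n_frames, n_elevation, n_azimuth)
    right: np.ndarray
    frame_interval: float = 0.01
    grid: RetinalGrid = field(default_factory=default_strike_grid)

    def __post_init__(self) -> None:
        left = np.asarray(self.left, float)
        right = np.asarray(self.right, float)
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        if left.shape != right.shape:
            raise ValueError("per-eye frame sequences must have equal shape")
        shape = (self.grid.n_elevation, self.grid.n_azimuth)
        if left.ndim != 3 or left.shape[1:] != shape:
            raise ValueError("frames must be (n_frames, n_elevation, n_azimuth)")

    @property
    def n_frames(self) -> int:
        return self.left.shape[0]


def make_default_sensor(
    grid: RetinalGrid | None = None,
    interocular: float = 1.0,
    preferred_distance: float = 2.5,
    centre_radius: float = 5.0,
    surround_radius: float = 15.0,
    preproc: MonocularPreproc | None = None,
    frame_interval: float = 0.01,
    gain: float | None = None,
) -> StrikeSensor:
    """Sensor whose lines of sight cross ``preferred_distance`` cm ahead.

    The nasal offset of each RF centre is the azimuth of a midline point at
    the preferred distance as seen from that eye.  The threshold is set to
    the analytic upper bound of any single eye's centre drive (onset of a
    unit-amplitude stimulus filling the centre), which makes the sensor
    silent to purely monocular stimulation by construction.  ``gain``
    defaults to a value giving a peak per-frame strike probability of about
    0.05 for the optimal stimulus.
    """
    grid = grid if grid is not None else default_strike_grid()
    preproc = preproc if preproc is not None else MonocularPreproc()
    nasal = float(np.degrees(np.arctan2(0.5 * interocular, preferred_distance)))
    w_s = CentreSurroundRF.balanced_surround_weight(centre_radius, surround_radius)
    left_rf = CentreSurroundRF(
        eye=Eye.LEFT, centre_azimuth=-nasal,
        centre_radius=centre_radius, surround_radius=surround_radius,
        surround_weight=w_s,
    )
    right_rf = CentreSurroundRF(
        eye=Eye.RIGHT, centre_azimuth=+nasal,
        centre_radius=centre_radius, surround_radius=surround_radius,
        surround_weight=w_s,
    )
    # calibrate against the optimal moving target: a disc of the centre's
    # diameter sweeping through the preferred distance.  The threshold is
    # placed just above the strongest drive either eye alone receives, so a
    # stimulus visible in only one eye cannot activate the sensor, while a
    # binocular near-optimal target still clears it comfortably.
    calib = build_stimulus(
        "moving_disc", grid=grid, distance=preferred_distance,
        diameter_deg=2 * centre_radius, frame_interval=frame_interval,
        interocular=interocular,
    )
    drives = []
    for frames, rf in ((calib.left, left_rf), (calib.right, right_rf)):
        drv = preprocess(frames, preproc, grid, frame_interval)
        drives.append(np.tensordot(drv, rf.window(grid), axes=([1, 2], [0, 1])))
    mono_peak = float(max(drives[0].max(), drives[1].max()))
    threshold = 1.05 * mono_peak
    if gain is None:
        peak_activity = float(
            np.maximum(drives[0] + drives[1] - threshold, 0.0).max() ** 5.0
        )
        gain = 0.05 / max(peak_activity, 1e-12)
    return StrikeSensor(
        left_rf=left_rf, right_rf=right_rf, exponent=5.0,
        threshold=threshold, gain=gain,
    )


def preprocess(
    frames: np.ndarray,
    preproc: MonocularPreproc,
    grid: RetinalGrid,
    frame_interval: float = 0.01,
) -> np.ndarray:
    """Spatial low-pass, first-order temporal high-pass, full-wave rectify.

    The high-pass is ``y_t = a (y_{t-1} + x_t - x_{t-1})`` with
    ``a = tau/(tau+dt)`` and ``y_0 = a x_0`` (stimulus onset counts as
    change); the returned drive is ``|y_t|``.  Static sequences decay to zero
    within a few time constants.
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, n_el, n_az) sequence")
    daz, de = grid.spacing
    sigma = (preproc.spatial_scale / de, preproc.spatial_scale / daz)
    blurred = np.stack(
        [ndimage.gaussian_filter(f, sigma=sigma, mode="constant") for f in frames]
    )
    a = preproc.highpass_gain(frame_interval)
    out = np.empty_like(blurred)
    y = a * blurred[0]
    out[0] = np.abs(y)
    for t in range(1, len(blurred)):
        y = a * (y + blurred[t] - blurred[t - 1])
        out[t] = np.abs(y)
    return out


def monocular_drive(frame: np.ndarray, rf: CentreSurroundRF, grid: RetinalGrid) -> float:
    """Inner product of one processed frame with the RF window."""
    frame = np.asarray(frame, float)
    if frame.shape != (grid.n_elevation, grid.n_azimuth):
        raise ValueError("frame shape does not match the grid")
    return float(np.sum(frame * rf.window(grid)))


def binocular_response(
    left_drive: float, right_drive: float, sensor: StrikeSensor
) -> float:
    """Thresholded-sum power law: max(L + R - theta, 0)^p."""
    s = left_drive + right_drive - sensor.threshold
    return float(max(s, 0.0) ** sensor.exponent)


def activity_trace(
    stimulus: DichopticStimulus,
    sensor: StrikeSensor,
    preproc: MonocularPreproc,
) -> np.ndarray:
    """Per-frame activity of the binocular neuron for a stimulus."""
    grid = stimulus.grid
    drv_l = preprocess(stimulus.left, preproc, grid, stimulus.frame_interval)
    drv_r = preprocess(stimulus.right, preproc, grid, stimulus.frame_interval)
    wl = sensor.left_rf.window(grid)
    wr = sensor.right_rf.window(grid)
    l = np.tensordot(drv_l, wl, axes=([1, 2], [0, 1]))
    r = np.tensordot(drv_r, wr, axes=([1, 2], [0, 1]))
    s = np.maximum(l + r - sensor.threshold, 0.0)
    return s**sensor.exponent


def run_trial(
    stimulus: DichopticStimulus,
    sensor: StrikeSensor,
    preproc: MonocularPreproc,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """(time-averaged activity, stochastic strike count) for one trial.

    A strike is a Bernoulli draw per frame with probability
    ``min(gain * activity, 1)``, so the expected count is
    ``gain * sum(activity)`` whenever no frame clips.
    """
    acts = activity_trace(stimulus, sensor, preproc)
    p = np.minimum(sensor.gain * acts, 1.0)
    strikes = int(np.sum(rng.random(len(p)) < p))
    return float(np.mean(acts)), strikes


# -- stimulus construction -------------------------------------------------


def _sphere_frames(
    spheres_per_frame: list[tuple[Sphere, ...]],
    grid: RetinalGrid,
    eye: Eye,
    interocular: float,
    elevation_shift: float = 0.0,
) -> np.ndarray:
    pose = HeadPose(interocular=interocular)
    frames = np.zeros((len(spheres_per_frame), grid.n_elevation, grid.n_azimuth))
    for t, spheres in enumerate(spheres_per_frame):
        if elevation_shift:
            spheres = tuple(
                replace(s, elevation=s.elevation + elevation_shift) for s in spheres
            )
        frames[t] = render_scene(Scene(spheres=spheres), pose, eye, grid).values
    return frames


def build_stimulus(
    kind: str,
    grid: RetinalGrid | None = None,
    distance: float = 2.5,
    diameter_deg: float = 10.0,
    speed: float = 40.0,
    sweep: float = 20.0,
    frame_interval: float = 0.01,
    interocular: float = 1.0,
    vertical_offset: float = 0.0,
    ghost_scale: float = 2.0,
) -> DichopticStimulus:
    """Dichoptic stimulus of one of three kinds.

    moving_disc
        A sphere of angular diameter ``diameter_deg`` (subtense at the
        origin) at ``distance`` cm sweeps horizontally at ``speed`` deg/s
        from headcentric azimuth ``-sweep`` to ``+sweep`` at zero elevation.
    vertical_disparity
        The same disc but with a geometrically impossible pure vertical
        dichoptic offset: the left-eye image is shifted down and the
        right-eye image up by ``vertical_offset / 2`` each.  Offset zero
        reduces exactly to ``moving_disc``.
    ghost_pair
        For every frame of the corresponding ``moving_disc`` target, the
        near sphere is replaced by two identical spheres ``ghost_scale``
        times further along the left and right eyes' lines of sight, scaled
        to subtend the same angle from their defining eye.  Locally each eye
        sees the same image as for the single near target, plus a second
        image from the other sphere.
    """
    grid = grid if grid is not None else default_strike_grid()
    if speed <= 0 or sweep <= 0 or frame_interval <= 0:
        raise ValueError("speed, sweep and frame interval must be positive")
    n_frames = max(int(round(2 * sweep / (speed * frame_interval))) + 1, 2)
    azimuths = np.linspace(-sweep, sweep, n_frames)
    diameter = sphere_diameter_for_subtense(distance, diameter_deg)
    targets = [
        (Sphere(azimuth=float(az), elevation=0.0, distance=distance,
                diameter=diameter),)
        for az in azimuths
    ]

    if kind in ("moving_disc", "vertical_disparity"):
        shift = vertical_offset if kind == "vertical_disparity" else 0.0
        left = _sphere_frames(targets, grid, Eye.LEFT, interocular, -shift / 2)
        right = _sphere_frames(targets, grid, Eye.RIGHT, interocular, +shift / 2)
    elif kind == "ghost_pair":
        if ghost_scale <= 1.0:
            raise ValueError("ghost objects must lie beyond the near target")
        pose = HeadPose(interocular=interocular)
        eye_pos = {
            Eye.LEFT: np.array([+0.5 * interocular, 0.0, 0.0]),
            Eye.RIGHT: np.array([-0.5 * interocular, 0.0, 0.0]),
        }
        ghost_frames: list[tuple[Sphere, ...]] = []
        for (near,) in targets:
            centre = near.centre()
            pair = []
            for eye in (Eye.LEFT, Eye.RIGHT):
                p = eye_pos[eye] + ghost_scale * (centre - eye_pos[eye])
                az = float(np.degrees(np.arctan2(p[0], p[2])))
                el = float(
                    np.degrees(np.arcsin(np.clip(p[1] / np.linalg.norm(p), -1, 1)))
                )
                pair.append(
                    Sphere(
                        azimuth=az, elevation=el,
                        distance=float(np.linalg.norm(p)),
                        diameter=ghost_scale * near.diameter,
                    )
                )
            ghost_frames.append(tuple(pair))
        left = _sphere_frames(ghost_frames, grid, Eye.LEFT, interocular)
        right = _sphere_frames(ghost_frames, grid, Eye.RIGHT, interocular)
    else:
        raise ValueError(
            "kind must be 'moving_disc', 'vertical_disparity' or 'ghost_pair'"
        )
    return DichopticStimulus(
        left=left, right=right, frame_interval=frame_interval, grid=grid
    )
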