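"""Behavioural experiment runners: saccade choices and strike sweeps.

Each runner returns a tidy :class:`pandas.DataFrame`, one row per trial or
per sweep condition, with enough columns (condition, repeat, seed) to
re-aggregate every summary statistic from the raw rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Eye, HeadPose
from .network import SaccadeNetworkClassifier, decide_saccade
from .scenes import (
    RetinalGrid,
    Scene,
    Sphere,
    add_noise,
    render_scene,
    sphere_diameter_for_subtense,
)
from .strike import (
    MonocularPreproc,
    StrikeSensor,
    build_stimulus,
    default_strike_grid,
    make_default_sensor,
    run_trial,
)

__all__ = [
    "two_target_scene",
    "run_two_target_experiment",
    "run_preference_map",
    "run_strike_sweeps",
]


def two_target_scene(
    left_azimuth: float = -15.0,
    left_distance: float = 4.0,
    right_azimuth: float = +15.0,
    right_distance: float = 8.0,
    left_subtense: float = 15.0,
    right_subtense: float = 15.0,
    elevation: float = 0.0,
) -> Scene:
    """Two spheres at mirrored azimuths, sized by angular subtense."""
    return Scene(
        spheres=(
            Sphere(
                azimuth=left_azimuth, elevation=elevation, distance=left_distance,
                diameter=sphere_diameter_for_subtense(left_distance, left_subtense),
            ),
            Sphere(
                azimuth=right_azimuth, elevation=elevation, distance=right_distance,
                diameter=sphere_diameter_for_subtense(right_distance, right_subtense),
            ),
        )
    )


def _decide_noisy(
    net: SaccadeNetworkClassifier,
    scene: Scene,
    pose: HeadPose,
    noise_sigma: float,
    n_repeats: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    grid, _ = net._grids()
    left = render_scene(scene, pose, Eye.LEFT, grid)
    right = render_scene(scene, pose, Eye.RIGHT, grid)
    rows = []
    for rep in range(n_repeats):
        dec = decide_saccade(
            net, add_noise(left, noise_sigma, rng), add_noise(right, noise_sigma, rng)
        )
        rows.append(
            dict(repeat=rep, azimuth=dec.azimuth, elevation=dec.elevation,
                 index=dec.index, no_action=dec.no_action)
        )
    return pd.DataFrame(rows)


def run_two_target_experiment(
    net: SaccadeNetworkClassifier,
    left_azimuth: float = -15.0,
    left_distance: float = 4.0,
    right_azimuth: float = +15.0,
    right_distance: float = 8.0,
    subtense: float = 15.0,
    n_repeats: int = 1000,
    noise_sigma: float = 0.1,
    seed: int = 0,
    interocular: float = 1.0,
) -> pd.DataFrame:
    """Repeated noisy presentations of a two-sphere scene.

    The default reproduces the near-preference paradigm: equal 15-degree
    targets at -15 deg / 4 cm and +15 deg / 8 cm, 1000 presentations with
    clipped Gaussian pixel noise.  Rows carry the saccade direction and
    whether it fell on the nearer target's side.
    """
    if not hasattr(net, "coef_"):
        raise ValueError("the network must be trained (or loaded) first")
    scene = two_target_scene(
        left_azimuth, left_distance, right_azimuth, right_distance,
        left_subtense=subtense, right_subtense=subtense,
    )
    pose = HeadPose(interocular=interocular)
    rng = np.random.default_rng(seed)
    out = _decide_noisy(net, scene, pose, noise_sigma, n_repeats, rng)
    near_side = np.sign(
        left_azimuth if left_distance <= right_distance else right_azimuth
    )
    out["chose_near"] = np.sign(out["azimuth"]) == near_side
    out["seed"] = seed
    return out


def run_preference_map(
    net: SaccadeNetworkClassifier,
    mode: str = "distances",
    distances: tuple[float, ...] = (2.0, 3.0, 4.0, 6.0, 8.0, 10.0),
    subtenses: tuple[float, ...] = (2.0, 6.0, 10.0, 15.0, 20.0, 25.0),
    fixed_subtense: float = 10.0,
    fixed_distances: tuple[float, float] = (8.0, 4.0),
    target_azimuth: float = 15.0,
    n_repeats: int = 200,
    noise_sigma: float = 0.1,
    seed: int = 0,
    interocular: float = 1.0,
) -> pd.DataFrame:
    """Proportion of saccades toward the nearer target over a condition grid.

    mode='distances': both targets subtend ``fixed_subtense`` but their
    distances range over ``distances`` x ``distances``.
    mode='sizes': target distances are fixed (left, right) =
    ``fixed_distances`` while each target's subtense ranges over
    ``subtenses`` x ``subtenses``.
    """
    if not hasattr(net, "coef_"):
        raise ValueError("the network must be trained (or loaded) first")
    pose = HeadPose(interocular=interocular)
    rows = []
    if mode == "distances":
        grid_cells = [
            dict(left_distance=dl, right_distance=dr,
                 left_subtense=fixed_subtense, right_subtense=fixed_subtense)
            for dl in distances for dr in distances
        ]
    elif mode == "sizes":
        dl, dr = fixed_distances
        grid_cells = [
            dict(left_distance=dl, right_distance=dr,
                 left_subtense=sl, right_subtense=sr)
            for sl in subtenses for sr in subtenses
        ]
    else:
        raise ValueError("mode must be 'distances' or 'sizes'")
    rng = np.random.default_rng(seed)
    for cell in grid_cells:
        scene = two_target_scene(
            left_azimuth=-target_azimuth, right_azimuth=+target_azimuth, **cell
        )
        dec = _decide_noisy(net, scene, pose, noise_sigma, n_repeats, rng)
        near_side = -1.0 if cell["left_distance"] <= cell["right_distance"] else 1.0
        prop = float(np.mean(np.sign(dec["azimuth"]) == near_side))
        rows.append(dict(**cell, proportion_near=prop,
                         n_repeats=n_repeats, seed=seed))
    return pd.DataFrame(rows)


def run_strike_sweeps(
    sensor: StrikeSensor | None = None,
    preproc: MonocularPreproc | None = None,
    grid: RetinalGrid | None = None,
    diameters: tuple[float, ...] = (2.0, 5.0, 8.0, 10.0, 13.0, 18.0, 25.0),
    distances: tuple[float, ...] = (1.25, 2.5, 5.0),
    vertical_offsets: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 14.0),
    preferred_distance: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Strike-sensor tuning sweeps, one row per condition.

    Three families of conditions are emitted, marked by ``kind``:
    size/distance tuning of the moving disc, vertical-disparity tuning (at
    the preferred distance, for each diameter), and the ghost-pair versus
    matched real-target comparison.
    """
    grid = grid if grid is not None else default_strike_grid()
    preproc = preproc if preproc is not None else MonocularPreproc()
    sensor = sensor if sensor is not None else make_default_sensor(grid, preproc=preproc)
    rng = np.random.default_rng(seed)
    rows = []

    def trial(family: str, stimulus_kind: str, **params) -> None:
        stim = build_stimulus(stimulus_kind, grid=grid, **params)
        mean_act, strikes = run_trial(stim, sensor, preproc, rng)
        rows.append(
            dict(kind=family, diameter=params.get("diameter_deg"),
                 distance=params.get("distance"),
                 vertical_offset=params.get("vertical_offset", 0.0),
                 mean_activity=mean_act, strikes=strikes, seed=seed)
        )

    for dist in distances:
        for diam in diameters:
            trial("size_distance", "moving_disc", distance=dist, diameter_deg=diam)
    for diam in diameters:
        for off in vertical_offsets:
            trial("vertical_disparity", "vertical_disparity",
                  distance=preferred_distance, diameter_deg=diam,
                  vertical_offset=off)
    for diam in (10.0, 15.0):
        trial("real", "moving_disc", distance=preferred_distance,
              diameter_deg=diam)
        trial("ghost", "ghost_pair", distance=preferred_distance,
              diameter_deg=diam)
    return pd.DataFrame(rows)
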