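"""Didactic models of local stereo correspondence.

Two executable miniatures:

* A binocular unit fed by scalar monocular inner products drawn from a small
  discrete ensemble.  A purely linear unit responds, on average, identically
  to matching and non-matching left/right draws (no correspondence); a
  squaring 'energy' unit or a thresholded linear unit responds more on
  average to matching draws (weak correspondence).
* A lattice of disparity sensors, one per (left location, right location)
  pair.  With two objects the eyes cannot tell apart, four sensors activate
  instead of two — the classic matching ambiguity that global interactions
  exist to resolve.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitKind",
    "BinocularUnit",
    "DiscreteEnsemble",
    "mean_response",
    "SensorLattice",
    "LatticeObject",
    "lattice_activations",
]


class UnitKind(str, enum.Enum):
    LINEAR = "linear"
    ENERGY = "energy"
    THRESHOLDED_LINEAR = "thresholded_linear"


@dataclass(frozen=True)
class BinocularUnit:
    """Binocular combination rule applied to monocular inner products.

    linear: l + r;  energy: (l + r)^2;  thresholded_linear: l + r if at
    least ``threshold`` else 0 (default threshold 4).
    """

    kind: UnitKind
    threshold: float = 4.0

    def response(self, left: float, right: float) -> float:
        s = left + right
        kind = UnitKind(self.kind)
        if kind is UnitKind.LINEAR:
            return s
        if kind is UnitKind.ENERGY:
            return s * s
        return s if s >= self.threshold else 0.0


@dataclass(frozen=True)
class DiscreteEnsemble:
    """Equiprobable set of possible monocular inner-product values."""

    values: tuple[float, ...] = (1.0, 2.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("ensemble must be non-empty")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


def mean_response(
    unit: BinocularUnit, ensemble: DiscreteEnsemble, matched: bool
) -> float:
    """Exact enumeration mean of the unit's response over the ensemble.

    Matched pairs are (v, v) for each ensemble value; non-matched pairs are
    the unordered pairs {v, w} with v != w, each weighted uniformly.  For
    the default ensemble and a thresholded linear unit (threshold 4) the
    means are 10/3 (matched) and 3 (non-matched); an energy unit gives
    56/3 versus 50/3; a linear unit gives 4 for both.
    """
    vals = ensemble.values
    if matched:
        pairs = [(v, v) for v in vals]
    else:
        pairs = list(itertools.combinations(vals, 2))
        if not pairs:
            raise ValueError("non-matching mean needs at least two distinct draws")
    return float(np.mean([unit.response(l, r) for l, r in pairs]))


@dataclass(frozen=True)
class LatticeObject:
    """An object image pair on the lattice, with an identity tag.

    ``left``/``right`` are the indices of the monocular locations the object
    projects to.  Objects sharing a ``kind`` tag are indistinguishable to
    the sensors; differing tags are distinguishable (e.g. square versus
    pentagon).
    """

    left: int
    right: int
    kind: str = "object"


@dataclass(frozen=True)
class SensorLattice:
    """All (left location, right location) disparity sensors.

    One sensor exists for every pair of monocular locations, so the sensor
    count is the product of the per-eye location counts.
    """

    n_left: int
    n_right: int

    def __post_init__(self) -> None:
        if self.n_left < 1 or self.n_right < 1:
            raise ValueError("need at least one location per eye")

    @property
    def sensors(self) -> list[tuple[int, int]]:
        return list(itertools.product(range(self.n_left), range(self.n_right)))


def lattice_activations(
    lattice: SensorLattice,
    objects: list[LatticeObject],
    distinguishable: bool = True,
) -> set[tuple[int, int]]:
    """Sensors activated by a set of object images.

    A sensor (l, r) is active iff some object projects to left location l,
    some object projects to right location r, and the local-match predicate
    accepts the pair: identical object identity when the objects are
    distinguishable, any pairing otherwise.  With two indistinguishable
    objects this yields the four-sensor ambiguity; distinguishable objects
    activate only their own two sensors.
    """
    for obj in objects:
        if not (0 <= obj.left < lattice.n_left and 0 <= obj.right < lattice.n_right):
            raise ValueError(f"object projects outside the lattice: {obj}")
    active = set()
    for a in objects:
        for b in objects:
            if distinguishable and a.kind != b.kind:
                continue
            active.add((a.left, b.right))
    return active
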