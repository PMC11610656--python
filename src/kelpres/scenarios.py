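"""Synthetic scenario generation: baseline parameters, initial-condition
grids, disturbance perturbations, and analytic toy fields with known
quasipotentials.

Everything here is a pure function of its inputs, so every pipeline stage can
be exercised without external data.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .params import ParameterSet

__all__ = [
    "GridSpec",
    "Disturbance",
    "baseline_parameters",
    "default_distributions_path",
    "make_ic_grid",
    "apply_disturbance",
    "toy_double_well",
]


def _data_path(name: str):
    return importlib.resources.files("kelpres.data").joinpath(name)


def baseline_parameters() -> ParameterSet:
    """The packaged baseline parameter set (bull-kelp system calibration)."""
    with importlib.resources.as_file(_data_path("baseline_parameters.json")) as p:
        return ParameterSet.from_dict(json.loads(p.read_text()))


def default_distributions_path() -> str:
    """Path to the packaged default sampling-distribution table (JSON)."""
    with importlib.resources.as_file(_data_path("distributions.json")) as p:
        return str(p)


@dataclass(frozen=True)
class GridSpec:
    """One axis of an initial-condition grid.

    ``spacing`` is ``"linear"`` or ``"log"``; log spacing requires
    ``low > 0``.
    """

    low: float
    high: float
    count: int
    spacing: str = "linear"

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low ({self.low}) must be <= high ({self.high})")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.spacing not in ("linear", "log"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        if self.spacing == "log" and self.low <= 0:
            raise ValueError("log spacing requires low > 0")

    def points(self) -> np.ndarray:
        if self.count == 1:
            return np.array([self.low], dtype=float)
        if self.spacing == "log":
            return np.geomspace(self.low, self.high, self.count)
        return np.linspace(self.low, self.high, self.count)


def make_ic_grid(specs: Sequence[GridSpec]) -> np.ndarray:
    """Cartesian product of per-dimension grids, in lexicographic order.

    Returns an ``(n, ndim)`` array; with the three reduced-state axes
    ``(A, U, S)`` this is the initial-condition grid used by the
    recovery-likelihood metric.
    """
    axes = [spec.points() for spec in specs]
    return np.array(list(itertools.product(*axes)), dtype=float)


@dataclass(frozen=True)
class Disturbance:
    """A pulse perturbation applied to a community state.

    ``kelp_loss`` removes a proportion of live kelp, ``urchin_pulse`` adds
    urchins, ``predator_removal`` removes a proportion of predators.  The
    resilience metrics themselves are agnostic of the disturbance source;
    these kinds mirror heat-wave kelp mortality, grazer outbreaks and
    predator disease.
    """

    kind: str
    magnitude: float

    _PROPORTIONAL = ("kelp_loss", "predator_removal")

    def __post_init__(self) -> None:
        if self.kind not in ("kelp_loss", "urchin_pulse", "predator_removal"):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        if self.kind in self._PROPORTIONAL and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError(f"{self.kind} magnitude must lie in [0, 1]")
        if self.kind == "urchin_pulse" and self.magnitude < 0:
            raise ValueError("urchin_pulse magnitude must be >= 0")


def apply_disturbance(state: np.ndarray, d: Disturbance) -> np.ndarray:
    """Apply a :class:`Disturbance` to a reduced state ``(A, U, S)``."""
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise ValueError("state must be nonnegative")
    out = state.copy()
    if d.kind == "kelp_loss":
        out[..., 0] *= 1.0 - d.magnitude
    elif d.kind == "urchin_pulse":
        out[..., 1] += d.magnitude
    else:  # predator_removal
        out[..., 2] *= 1.0 - d.magnitude
    return out


def toy_double_well(
    dimension: int = 1,
) -> tuple[Callable, Callable, np.ndarray, float]:
    """Analytic gradient system with a known quasipotential, for testing.

    Returns ``(field, potential, minima, quasipotential)`` where the field is
    ``f = -grad V`` with ``V(x) = (x^2 - 1)^2 / 4`` (plus ``y^2/2`` in 2D).
    The minima sit at ``x = +/-1`` (``y = 0``), the barrier at the origin has
    height 0.25, and for a gradient system with additive unit noise the
    quasipotential between the wells is twice the barrier, i.e. 0.5.
    """
    if dimension not in (1, 2):
        raise ValueError("dimension must be 1 or 2")

    if dimension == 1:

        def potential(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)[..., 0]
            return (x * x - 1.0) ** 2 / 4.0

        def field(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return np.stack([-(x[..., 0] ** 3 - x[..., 0])], axis=-1)

        minima = np.array([[-1.0], [1.0]])
    else:

        def potential(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return (x[..., 0] ** 2 - 1.0) ** 2 / 4.0 + x[..., 1] ** 2 / 2.0

        def field(x: np.ndarray) -> np.ndarray:
            x = np.asarray(x, dtype=float)
            return np.stack(
                [-(x[..., 0] ** 3 - x[..., 0]), -x[..., 1]], axis=-1
            )

        minima = np.array([[-1.0, 0.0], [1.0, 0.0]])

    return field, potential, minima, 0.5
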