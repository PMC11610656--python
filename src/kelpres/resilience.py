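"""The three resilience metrics of the kelp forest state.

* **Recovery likelihood** — the share of a grid of initial community
  densities whose 1000-week trajectory ends at the kelp forest state
  (final-window mean kelp above 95% of the forest equilibrium kelp
  density).  A basin-of-attraction measure: the width of the cup in a
  ball-and-cup picture.
* **Recovery rate** — minus the largest real part among the eigenvalues of
  the reduced-model Jacobian at the forest equilibrium: the asymptotic
  return rate after a small perturbation.  The steepness of the cup.
* **Resistance** — the Freidlin-Wentzell quasipotential barrier from the
  forest state to the urchin barren state, computed by minimum-action path
  optimization in rescaled coordinates.  The depth of the cup.

Metrics that are undefined for a parameter set (no forest state, no barren
state, optimizer failure) are reported as missing values with a reason
code, never silently as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _fastsim
from .action_solver import ActionConfig, Path, minimize_action
from .equilibria import (
    Equilibrium,
    SearchConfig,
    find_equilibria,
    get_labeled,
    urchin_free_kelp_equilibrium,
)
from .model_core import _jacobian_analytic, rhs_reduced
from .params import ParameterSet
from .scenarios import GridSpec, make_ic_grid

logger = logging.getLogger(__name__)

__all__ = [
    "MetricResult",
    "default_grid",
    "recovery_likelihood",
    "recovery_rate",
    "resistance",
    "compute_metrics",
]

#: reason codes for missing metrics
NO_FOREST = "no_forest"
NO_BARREN = "no_barren"
NOT_CONVERGED = "not_converged"

_RESCALE_FALLBACK = ("K", 1.0, 1.0)  # per-component fallback scales
_RESCALE_FLOOR = 1e-6  # forest components below floor*fallback use the fallback


@dataclass
class MetricResult:
    """The three metrics for one parameter set, with provenance."""

    recovery_likelihood: float
    recovery_rate: float | None
    resistance: float | None
    reasons: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def default_grid(
    params: ParameterSet, equilibria: Sequence[Equilibrium] | None = None
) -> np.ndarray:
    """The default 8 x 8 x 5 initial-condition grid (320 states).

    Kelp spans (0.02K, 1.2K]; urchins span [0, 2x the barren urchin density]
    (or twice the attractor-scan maximum when no barren state exists); sea
    stars span [0, 2x the forest sea-star density] (or [0, 1] when no forest
    state exists).  Chosen to straddle both basins; fully overridable by
    passing an explicit grid to :func:`recovery_likelihood`.
    """
    if equilibria is None:
        equilibria = find_equilibria(params)
    forest = get_labeled(equilibria, "forest")
    barren = get_labeled(equilibria, "barren")

    K = params.K
    if barren is not None and barren.state[1] > 0:
        u_hi = 2.0 * barren.state[1]
    else:
        u_hi = 2.0 * max((eq.state[1] for eq in equilibria), default=1.0)
    u_hi = max(u_hi, 1.0)
    s_hi = 2.0 * forest.state[2] if forest is not None and forest.state[2] > 0 else 1.0

    # kelp axis: 8 points on the half-open interval (0.02K, 1.2K]
    a_lo = float(np.linspace(0.02 * K, 1.2 * K, 9)[1])
    specs = (
        GridSpec(a_lo, 1.2 * K, 8),
        GridSpec(0.0, u_hi, 8),
        GridSpec(0.0, s_hi, 5),
    )
    return make_ic_grid(specs)


def recovery_likelihood(
    params: ParameterSet,
    grid: np.ndarray | None = None,
    horizon: float = 1000.0,
    threshold: float = 0.95,
    tail: float = 100.0,
    equilibria: Sequence[Equilibrium] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    return_details: bool = False,
):
    """Proportion of initial conditions that recover to the kelp forest.

    Each grid state is integrated for ``horizon`` weeks; it counts as
    recovered when its mean kelp density over the final ``tail`` weeks
    exceeds ``threshold`` times the forest-equilibrium kelp density (the
    tail mean, rather than the endpoint, is robust to oscillatory
    attractors).  Returns 0 when no forest state exists.  Integration
    failures count as non-recovered and are logged.
    """
    if equilibria is None:
        equilibria = find_equilibria(params)
    forest = get_labeled(equilibria, "forest")
    if forest is None:
        if return_details:
            return 0.0, {"reason": NO_FOREST}
        return 0.0
    if grid is None:
        grid = default_grid(params, equilibria)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[1] != 3 or len(grid) == 0:
        raise ValueError("grid must be a nonempty (n, 3) array")

    tails, finals, status = _fastsim.batch_tail_mean(
        grid, params.to_array(), horizon, tail, rtol, atol
    )
    n_failed = int(np.sum(status != 0))
    if n_failed:
        logger.warning(
            "%d/%d initial conditions failed to integrate; counted as non-recovered",
            n_failed,
            len(grid),
        )
    success = (status == 0) & (tails > threshold * forest.state[0])
    value = float(np.mean(success))
    if return_details:
        return value, {
            "tail_means": tails,
            "final_states": finals,
            "status": status,
            "success": success,
            "forest_A": forest.state[0],
            "n_failed": n_failed,
        }
    return value


def recovery_rate(
    params: ParameterSet, equilibria: Sequence[Equilibrium] | None = None
) -> float | None:
    """Return rate at the forest state: minus the dominant eigenvalue real part.

    Positive values mean faster return to the forest after a small
    disturbance.  ``None`` (missing) when no forest state exists.
    """
    if equilibria is None:
        equilibria = find_equilibria(params)
    forest = get_labeled(equilibria, "forest")
    if forest is None:
        return None
    return float(-np.max(forest.eigenvalues.real))


def _rescale_vector(params: ParameterSet, forest: Equilibrium) -> np.ndarray:
    """Per-coordinate scales: forest equilibrium values, with fallbacks.

    Components of the forest state that are essentially zero (e.g. urchin
    densities of 1e-7 at a predator-protected forest) would distort the
    isotropic-noise geometry if used as scales, so they fall back to
    ``(K, 1, 1)``.
    """
    fallback = np.array(
        [params.K if v == "K" else float(v) for v in _RESCALE_FALLBACK]
    )
    scale = np.where(
        forest.state > _RESCALE_FLOOR * fallback, forest.state, fallback
    )
    return scale


def _flow_leg(
    start: np.ndarray,
    target_scaled: np.ndarray,
    params: ParameterSet,
    scale: np.ndarray,
    horizon: float = 2e5,
) -> np.ndarray | None:
    """Deterministic-flow node sequence from ``start`` toward the barren.

    Integrates the reduced dynamics, truncates the recorded trajectory at
    its closest (rescaled) approach to the target and appends the target.
    Returns rescaled nodes, or None when the flow never comes close (the
    start is not in the barren's attracting region).
    """
    nodes, _n, status = _fastsim.integrate_nodes(
        np.asarray(start, dtype=float), params.to_array(), horizon
    )
    if status == 2:
        return None
    scaled = nodes / scale
    dist = np.sqrt(np.sum((scaled - target_scaled) ** 2, axis=1))
    k = int(np.argmin(dist))
    if dist[k] > 0.05 * (1.0 + float(np.linalg.norm(target_scaled))):
        return None
    return np.vstack([scaled[: k + 1], target_scaled])


def resistance(
    params: ParameterSet,
    action_cfg: ActionConfig | None = None,
    equilibria: Sequence[Equilibrium] | None = None,
    return_path: bool = False,
    direct: bool = True,
):
    """Quasipotential barrier from the forest state to the urchin barren.

    The reduced vector field is rescaled coordinate-wise (kelp by the
    forest kelp density, and so on; see :func:`_rescale_vector`) so the
    assumed additive isotropic noise acts on comparable magnitudes.  Two
    transition strategies are evaluated and the smaller action wins:

    * **direct** — minimum-action path straight from forest to barren;
    * **gate** — an optimized leg from the forest to its sea-star-free
      projection ``(A*, U*, 0)``, continued by the deterministic collapse
      flow (urchin outbreak and kelp collapse), which carries zero action
      in the continuum.  This captures the typically cheapest escape in
      this model: suppressing the slow predator releases urchins, after
      which the barren is reached for free.

    Both strategies produce valid transition paths, so each value is an
    upper bound on the quasipotential and the minimum is the tightest
    bound available.  Returns ``None`` with a reason code when either
    labeled state is missing or no strategy converges.
    """
    if equilibria is None:
        equilibria = find_equilibria(params)
    forest = get_labeled(equilibria, "forest")
    barren = get_labeled(equilibria, "barren")
    if forest is None:
        return (None, None, NO_FOREST) if return_path else None
    if barren is None:
        return (None, None, NO_BARREN) if return_path else None

    cfg = action_cfg or ActionConfig(nonnegative=True)
    scale = _rescale_vector(params, forest)

    def field_rescaled(y: np.ndarray) -> np.ndarray:
        return rhs_reduced(y * scale, params) / scale

    def jac_rescaled(y: np.ndarray) -> np.ndarray:
        J = _jacobian_analytic(y * scale, params)
        return J * (scale[None, None, :] / scale[None, :, None])

    x0 = forest.state / scale
    x1 = barren.state / scale
    candidates: list[tuple[float, Path]] = []

    # gate strategy
    if forest.state[2] > 0:
        gate = forest.state.copy()
        gate[2] = 0.0
        leg2 = _flow_leg(gate, x1, params, scale)
        if leg2 is not None:
            leg1 = minimize_action(field_rescaled, x0, gate / scale, cfg=cfg, jac=jac_rescaled)
            if leg1.converged:
                from .action_solver import action_of_path

                total = leg1.action + action_of_path(leg2, field_rescaled)
                full = Path(
                    nodes=np.vstack([leg1.nodes, leg2[1:]]),
                    action=float(total),
                    converged=True,
                    iterations=leg1.iterations,
                    grad_norm=leg1.grad_norm,
                )
                candidates.append((full.action, full))

    if direct or not candidates:
        path_d = minimize_action(field_rescaled, x0, x1, cfg=cfg, jac=jac_rescaled)
        if path_d.converged:
            candidates.append((float(path_d.action), path_d))

    if not candidates:
        logger.warning("action minimization did not converge; resistance undefined")
        return (None, None, NOT_CONVERGED) if return_path else None
    value, best = min(candidates, key=lambda t: t[0])
    best.rescale = scale
    return (value, best, None) if return_path else value


def compute_metrics(
    params: ParameterSet,
    grid: np.ndarray | None = None,
    horizon: float = 1000.0,
    threshold: float = 0.95,
    action_cfg: ActionConfig | None = None,
    search_cfg: SearchConfig | None = None,
    skip_resistance: bool = False,
) -> MetricResult:
    """All three metrics for one parameter set (one equilibrium search)."""
    equilibria = find_equilibria(params, search_cfg)
    forest = get_labeled(equilibria, "forest")
    barren = get_labeled(equilibria, "barren")

    reasons: dict = {}
    likelihood = recovery_likelihood(
        params, grid=grid, horizon=horizon, threshold=threshold, equilibria=equilibria
    )
    rate = recovery_rate(params, equilibria)
    if rate is None:
        reasons["recovery_rate"] = NO_FOREST

    resist: float | None = None
    if skip_resistance:
        reasons["resistance"] = "skipped"
    else:
        resist, _path, why = resistance(
            params, action_cfg=action_cfg, equilibria=equilibria, return_path=True
        )
        if resist is None:
            reasons["resistance"] = why

    return MetricResult(
        recovery_likelihood=likelihood,
        recovery_rate=rate,
        resistance=resist,
        reasons=reasons,
        provenance={
            "horizon": horizon,
            "threshold": threshold,
            "forest_state": None if forest is None else forest.state.tolist(),
            "barren_state": None if barren is None else barren.state.tolist(),
            "A_urchin_free": urchin_free_kelp_equilibrium(params),
        },
    )
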