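"""Core dynamics of the kelp-urchin-predator food chain.

The full model tracks live kelp ``A``, drift kelp ``D``, urchins ``U`` and a
predator (sea star) ``S``.  Live kelp grows logistically and sloughs into
drift at rate ``delta_A``; urchins split their grazing time between active
grazing on live kelp and passive subsistence on drift according to drift
availability (factor ``1/(1 + kappa_D*D)``); predation on urchins saturates
(Holling Type II) and is modulated by urchin starvation state (factor
``1/(1 + kappa_A*(A+D))``); fear of predators suppresses active grazing
(factor ``1/(1 + kappa_S*S)``); and predator energetic gain increases with
kelp-conditioned urchin quality (factor ``1 + beta*(A+D)``).

Because drift kelp turns over much faster than the other state variables, it
is eliminated through its quasi-steady state ``D* = D*(A, U)`` (the
nonnegative root of a quadratic), giving a reduced three-dimensional system
in ``(A, U, S)`` that all downstream analyses use.

State conventions: full states are arrays ``[A, D, U, S]``, reduced states
``[A, U, S]``.  All rates are per week.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterSet

__all__ = [
    "FULL_STATE_NAMES",
    "REDUCED_STATE_NAMES",
    "Trajectory",
    "drift_equilibrium",
    "rhs_full",
    "rhs_reduced",
    "jacobian_reduced",
    "simulate",
]

FULL_STATE_NAMES = ("A", "D", "U", "S")
REDUCED_STATE_NAMES = ("A", "U", "S")

#: below this, kappa_D is treated as exactly zero (degenerate linear D*).
_KAPPA_D_TINY = 1e-12


def _check_state(state: np.ndarray, n: int, clip: bool) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != n:
        raise ValueError(f"expected state with {n} components, got shape {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite values")
    if clip:
        return np.maximum(state, 0.0)
    if np.any(state < 0):
        raise ValueError("state contains negative densities")
    return state


def drift_equilibrium(
    A: np.ndarray | float, U: np.ndarray | float, params: ParameterSet
) -> np.ndarray | float:
    """Quasi-steady-state drift kelp density ``D*(A, U)``.

    Setting ``dD/dt = 0`` and multiplying through by ``(1 + kappa_D*D)``
    gives the quadratic

        kappa_D*(alpha_D*U + delta_D)*D^2
          + (delta_D - eps_D*delta_A*A*kappa_D)*D - eps_D*delta_A*A = 0,

    which has exactly one nonnegative root when ``A > 0`` (the product of
    roots is negative).  The root is evaluated with the cancellation-free
    quadratic formula.  For ``kappa_D -> 0`` the drift-consumption term
    (which carries a factor ``1 - 1/(1 + kappa_D*D)``) vanishes and
    ``D* = eps_D*delta_A*A/delta_D``, the continuous limit of the quadratic
    root.

    Accepts scalars or broadcasting arrays; returns the matching shape.
    """
    A = np.asarray(A, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(A < 0) or np.any(U < 0):
        raise ValueError("A and U must be nonnegative")
    p = params
    prod = p.eps_D * p.delta_A * A  # drift production rate
    if p.kappa_D < _KAPPA_D_TINY:
        out = prod / p.delta_D
        return out if out.shape else float(out)

    a = p.kappa_D * (p.alpha_D * U + p.delta_D)
    b = p.delta_D - prod * p.kappa_D
    c = -prod
    disc = b * b - 4.0 * a * c
    s = np.sqrt(np.maximum(disc, 0.0))
    # nonnegative root; branch avoids subtracting nearly equal quantities
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b > 0, np.where(c == 0, 0.0, 2.0 * c / (-b - s)), (-b + s) / (2.0 * a))
    out = np.maximum(out, 0.0)
    return out if out.shape else float(out)


def rhs_full(
    state: np.ndarray, params: ParameterSet, *, clip: bool = True
) -> np.ndarray:
    """Time derivative ``(dA, dD, dU, dS)`` of the full four-variable model.

    ``clip=True`` (default) clamps small negative inputs to zero before
    evaluation, so solver undershoot cannot produce spurious source terms.
    """
    y = _check_state(state, 4, clip)
    A, D, U, S = np.moveaxis(y, -1, 0)
    p = params

    # overflow to inf on extreme search iterates is handled by callers
    with np.errstate(over="ignore", invalid="ignore"):
        T = A + D
        P = 1.0 / (1.0 + p.kappa_D * D)  # share of grazing time on live kelp
        fear = 1.0 / (1.0 + p.kappa_S * S)
        susc = 1.0 / (1.0 + p.kappa_A * T)
        nutr = 1.0 + p.beta * T
        pred = p.alpha_U * U * S / (1.0 + p.gamma_U * U) * susc

        graze_live = P * p.alpha_A * A * U * fear
        graze_drift = (1.0 - P) * p.alpha_D * D * U

        dA = p.r * A * (1.0 - A / p.K) - graze_live - p.delta_A * A
        dD = p.eps_D * p.delta_A * A - graze_drift - p.delta_D * D
        dU = p.eps_U * (graze_live + graze_drift) - pred - p.delta_U * U
        dS = p.eps_S * nutr * pred - p.delta_S * S
        return np.stack([dA, dD, dU, dS], axis=-1)


def rhs_reduced(
    state: np.ndarray, params: ParameterSet, *, clip: bool = True
) -> np.ndarray:
    """Time derivative ``(dA, dU, dS)`` of the reduced model.

    Drift kelp is replaced by its quasi-equilibrium ``D*(A, U)`` everywhere
    it appears in the full model.
    """
    y = _check_state(state, 3, clip)
    A, U, S = np.moveaxis(y, -1, 0)
    D = drift_equilibrium(A, U, params)
    full = np.stack(np.broadcast_arrays(A, np.asarray(D, dtype=float), U, S), axis=-1)
    dA, _dD, dU, dS = np.moveaxis(rhs_full(full, params, clip=False), -1, 0)
    return np.stack([dA, dU, dS], axis=-1)


def _jacobian_analytic(state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Closed-form Jacobian of :func:`rhs_reduced`, shape ``(..., 3, 3)``.

    Built from the partials of the full-model rates combined with the
    implicit derivatives of ``D*`` (implicit-function theorem on the
    defining quadratic).
    """
    y = _check_state(state, 3, clip=True)
    A, U, S = np.moveaxis(y, -1, 0)
    p = params
    D = np.asarray(drift_equilibrium(A, U, params), dtype=float)
    A, U, S, D = np.broadcast_arrays(A, U, S, D)

    # implicit derivatives of D*(A, U)
    prod = p.eps_D * p.delta_A
    if p.kappa_D < _KAPPA_D_TINY:
        D_A = np.full_like(D, prod / p.delta_D)
        D_U = np.zeros_like(D)
    else:
        a = p.kappa_D * (p.alpha_D * U + p.delta_D)
        b = p.delta_D - prod * A * p.kappa_D
        # dg/dD = 2aD + b equals the discriminant sqrt at the selected root
        gD = np.maximum(2.0 * a * D + b, 1e-300)
        D_A = prod * (1.0 + p.kappa_D * D) / gD
        D_U = -p.kappa_D * p.alpha_D * D * D / gD

    T = A + D
    P = 1.0 / (1.0 + p.kappa_D * D)
    Q = 1.0 - P
    P_D = -p.kappa_D * P * P
    Ff = 1.0 / (1.0 + p.kappa_S * S)
    Ff_S = -p.kappa_S * Ff * Ff
    Fs = 1.0 / (1.0 + p.kappa_A * T)
    Fs_T = -p.kappa_A * Fs * Fs
    Fn = 1.0 + p.beta * T
    H = U / (1.0 + p.gamma_U * U)
    H_U = 1.0 / (1.0 + p.gamma_U * U) ** 2

    # partials of the full-model rates w.r.t. (A, D, U, S)
    fA_A = p.r * (1.0 - 2.0 * A / p.K) - P * p.alpha_A * U * Ff - p.delta_A
    fA_D = -P_D * p.alpha_A * A * U * Ff
    fA_U = -P * p.alpha_A * A * Ff
    fA_S = -P * p.alpha_A * A * U * Ff_S

    fU_A = p.eps_U * P * p.alpha_A * Ff * U - p.alpha_U * H * S * Fs_T
    fU_D = (
        p.eps_U * U * (P_D * p.alpha_A * A * Ff - P_D * p.alpha_D * D + Q * p.alpha_D)
        - p.alpha_U * H * S * Fs_T
    )
    fU_U = (
        p.eps_U * (P * p.alpha_A * A * Ff + Q * p.alpha_D * D)
        - p.alpha_U * H_U * S * Fs
        - p.delta_U
    )
    fU_S = p.eps_U * P * p.alpha_A * A * U * Ff_S - p.alpha_U * H * Fs

    fS_A = p.eps_S * p.alpha_U * H * S * (p.beta * Fs + Fn * Fs_T)
    fS_D = fS_A
    fS_U = p.eps_S * Fn * p.alpha_U * H_U * S * Fs
    fS_S = p.eps_S * Fn * p.alpha_U * H * Fs - p.delta_S

    J = np.empty(A.shape + (3, 3), dtype=float)
    J[..., 0, 0] = fA_A + fA_D * D_A
    J[..., 0, 1] = fA_U + fA_D * D_U
    J[..., 0, 2] = fA_S
    J[..., 1, 0] = fU_A + fU_D * D_A
    J[..., 1, 1] = fU_U + fU_D * D_U
    J[..., 1, 2] = fU_S
    J[..., 2, 0] = fS_A + fS_D * D_A
    J[..., 2, 1] = fS_U + fS_D * D_U
    J[..., 2, 2] = fS_S
    return J


def _jacobian_fd(state: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Finite-difference Jacobian of :func:`rhs_reduced` (single state).

    Central differences with a per-component relative step; one-sided at the
    nonnegativity boundary so clamped evaluations never contaminate the
    stencil.
    """
    y = np.maximum(np.asarray(state, dtype=float), 0.0)
    if y.shape != (3,):
        raise ValueError("finite-difference Jacobian expects a single state")
    h = np.cbrt(np.finfo(float).eps) * np.maximum(np.abs(y), 1.0)
    J = np.empty((3, 3), dtype=float)
    f0 = rhs_reduced(y, params)
    for j in range(3):
        e = np.zeros(3)
        e[j] = h[j]
        if y[j] - h[j] >= 0.0:
            J[:, j] = (rhs_reduced(y + e, params) - rhs_reduced(y - e, params)) / (2 * h[j])
        else:
            J[:, j] = (rhs_reduced(y + e, params) - f0) / h[j]
    return J


def jacobian_reduced(
    state: np.ndarray, params: ParameterSet, *, method: str = "analytic"
) -> np.ndarray:
    """Jacobian of the reduced vector field at ``state``.

    Parameters
    ----------
    method:
        ``"analytic"`` (default) uses the closed-form Jacobian including the
        implicit derivatives of ``D*``; ``"fd"`` uses central finite
        differences and exists mainly as an independent cross-check.
    """
    if method == "analytic":
        return _jacobian_analytic(state, params)
    if method == "fd":
        return _jacobian_fd(state, params)
    raise ValueError(f"unknown Jacobian method {method!r}")


@dataclass
class Trajectory:
    """A simulated time course of the model with solver diagnostics."""

    times: np.ndarray
    states: np.ndarray
    success: bool
    message: str = ""
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    state_names: tuple[str, ...] = field(default=REDUCED_STATE_NAMES)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def tail_mean(self, column: str = "A", window: float = 100.0) -> float:
        """Time-average of one state variable over the final ``window`` weeks."""
        j = self.state_names.index(column)
        t, x = self.times, self.states[:, j]
        t0 = t[-1] - window
        mask = t >= t0
        if mask.sum() < 2:
            return float(x[-1])
        return float(np.trapezoid(x[mask], t[mask]) / (t[mask][-1] - t[mask][0]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{n: self.states[:, j] for j, n in enumerate(self.state_names)}}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate(
    state0: np.ndarray,
    params: ParameterSet,
    horizon: float = 1000.0,
    *,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    rhs: Callable[[np.ndarray, ParameterSet], np.ndarray] | None = None,
) -> Trajectory:
    """Integrate the reduced model from ``state0`` for ``horizon`` weeks.

    Uses an adaptive, stiffness-switching integrator (LSODA) by default.
    Output states are clamped to nonnegative values; integration failure is
    reported through ``Trajectory.success``, never silently.

    Pass ``rhs=rhs_full`` (and a 4-component ``state0``) to integrate the
    full model instead.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    f = rhs_reduced if rhs is None else rhs
    y0 = np.asarray(state0, dtype=float)
    names = REDUCED_STATE_NAMES if y0.shape[-1] == 3 else FULL_STATE_NAMES
    _check_state(y0, y0.shape[-1], clip=False)
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, max(int(horizon) + 1, 2))

    sol = solve_ivp(
        lambda t, y: f(y, params),
        (0.0, float(horizon)),
        y0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    states = np.maximum(sol.y.T, 0.0)
    return Trajectory(
        times=sol.t,
        states=states,
        success=bool(sol.success),
        message=sol.message,
        method=method,
        rtol=rtol,
        atol=atol,
        state_names=names,
    )
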