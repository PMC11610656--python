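"""Location, classification and labeling of equilibria of the reduced model.

Equilibria fall into four structural classes (all other boundary classes are
ruled out analytically: with no live kelp urchins starve, and with no urchins
sea stars starve):

* extinction ``(0, 0, 0)``;
* the urchin-free kelp equilibrium ``(K(1 - delta_A/r), 0, 0)``;
* sea-star-free coexistence ``(A, U, 0)`` with ``U > 0``;
* interior coexistence ``(A, U, S)`` with all components positive.

Interior and in-plane equilibria are found by multistart Newton-type root
searches on the per-capita rates in log coordinates, which keeps iterates
positive and resolves the near-boundary forest equilibria (urchin densities
at the forest state can be many orders of magnitude below one).

Stability is classified against a tolerance ``stab_tol`` (default
1e-3/week, the reciprocal of the 1000-week study horizon): an eigenvalue
whose real part is below the tolerance corresponds to growth or decay that
is negligible on the horizon over which the resilience metrics are defined.
The exact eigenvalues are always stored so callers can apply a stricter
reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import root

from . import _fastsim
from .model_core import jacobian_reduced, rhs_reduced
from .params import ParameterSet

__all__ = [
    "Equilibrium",
    "SearchConfig",
    "urchin_free_kelp_equilibrium",
    "find_equilibria",
    "label_states",
    "equilibria_to_dataframe",
    "export_equilibria",
]


def urchin_free_kelp_equilibrium(params: ParameterSet) -> float:
    """Kelp density ``max(0, K(1 - delta_A/r))`` with no grazers present.

    Logistic growth minus drift production; zero when drift production
    outpaces low-density growth (``r <= delta_A``).
    """
    return max(0.0, params.K * (1.0 - params.delta_A / params.r))


@dataclass
class Equilibrium:
    """An equilibrium of the reduced model with stability diagnostics."""

    state: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stable: bool
    label: str = "other"

    @property
    def dominant_eigenvalue(self) -> complex:
        return self.eigenvalues[np.argmax(self.eigenvalues.real)]


@dataclass
class SearchConfig:
    """Configuration of the multistart equilibrium search."""

    residual_tol: float = 1e-8  # scaled by 1 + r*K/4 (peak kelp production)
    dedup_rtol: float = 1e-6
    stab_tol: float = 1e-3  # week^-1; ~1/study horizon
    horizon: float = 1000.0  # weeks, for the attractor scan
    n_extra_starts: int = 0  # additional random interior starts
    seed: int = 0
    forest_frac: float = 0.10  # forest label: A >= forest_frac * A_uf
    barren_frac: float = 0.05  # barren label: A < barren_frac * A_uf (or K)


def _attractor_scan(pa: np.ndarray, cfg: SearchConfig) -> tuple[np.ndarray, np.ndarray]:
    """Crude bounds on the attractor from a long simulation.

    Integrates from ``(K/2, 1, 0.01)`` for the configured horizon, sampling
    intermediate states, and returns (endpoint, componentwise max seen).
    """
    y = np.array([pa[1] / 2.0, 1.0, 0.01])
    seen = y.copy()
    t_prev = 0.0
    for t in np.geomspace(cfg.horizon / 64.0, cfg.horizon, 7):
        y, _st = _fastsim.integrate_final(y, pa, t - t_prev)
        seen = np.maximum(seen, y)
        t_prev = t
    return y, seen


def _percap_interior(z: np.ndarray, pa: np.ndarray) -> np.ndarray:
    A, U, S = np.exp(np.clip(z, -300.0, 300.0))
    f = _fastsim.rhs3(np.array([A, U, S]), pa)
    out = np.array([f[0] / A, f[1] / U, f[2] / S])
    return np.where(np.isfinite(out), out, 1e6)


def _percap_plane(z: np.ndarray, pa: np.ndarray) -> np.ndarray:
    A, U = np.exp(np.clip(z, -300.0, 300.0))
    f = _fastsim.rhs3(np.array([A, U, 0.0]), pa)
    out = np.array([f[0] / A, f[1] / U])
    return np.where(np.isfinite(out), out, 1e6)


def find_equilibria(
    params: ParameterSet, cfg: SearchConfig | None = None
) -> list[Equilibrium]:
    """Locate the biologically relevant equilibria of the reduced model.

    Multistart search seeded by the structural equilibria, a coarse grid in
    log coordinates, and the endpoint of a long simulation.  Every returned
    equilibrium passes a residual check; duplicates are merged.  The list
    always contains the extinction state ``(0, 0, 0)``.
    """
    cfg = cfg or SearchConfig()
    p = params
    pa = p.to_array()
    res_scale = 1.0 + p.r * p.K / 4.0
    tol = cfg.residual_tol * res_scale

    A_uf = urchin_free_kelp_equilibrium(p)
    endpoint, seen = _attractor_scan(pa, cfg)

    candidates: list[np.ndarray] = [np.zeros(3)]
    if A_uf > 0:
        candidates.append(np.array([A_uf, 0.0, 0.0]))

    # characteristic scales for start points
    A_ref = A_uf if A_uf > 0 else p.K / 2.0
    U_c = p.r / p.alpha_A if p.alpha_A > 0 else max(1.0, 10.0 * seen[1])
    S_vals = [0.01, 1.0, 100.0]
    if seen[2] > 0:
        S_vals.append(max(seen[2], 1e-3))

    # sea-star-free coexistence: 2D per-capita solve in log(A, U)
    plane_starts = [
        (a, u)
        for a in (1e-3 * A_ref, 0.05 * A_ref, 0.5 * A_ref)
        for u in (0.5 * U_c, 2.0 * U_c)
        if u > 0
    ]
    for a0, u0 in plane_starts:
        sol = root(_percap_plane, np.log([a0, u0]), args=(pa,), method="hybr")
        if sol.success:
            A, U = np.exp(sol.x)
            candidates.append(np.array([A, U, 0.0]))

    # interior coexistence: 3D per-capita solve in log(A, U, S)
    interior_starts = [
        np.array([a, u, s])
        for a in (0.3 * A_ref, A_ref)
        for u in (1e-6, 1.0, U_c)
        for s in S_vals
    ]
    if np.all(endpoint > 0):
        interior_starts.append(endpoint)
    if cfg.n_extra_starts:
        rng = np.random.default_rng(cfg.seed)
        lo = np.log([1e-4 * A_ref, 1e-8, 1e-6])
        hi = np.log([1.2 * p.K, max(10.0 * seen[1], 10.0), max(10.0 * seen[2], 10.0)])
        for _ in range(cfg.n_extra_starts):
            interior_starts.append(np.exp(rng.uniform(lo, hi)))
    for s0 in interior_starts:
        if np.any(np.asarray(s0) <= 0):
            continue
        sol = root(_percap_interior, np.log(s0), args=(pa,), method="hybr")
        if sol.success:
            candidates.append(np.exp(np.clip(sol.x, -300.0, 300.0)))

    # residual filter + dedup
    scale_vec = np.array(
        [max(p.K, 1.0), max(seen[1], U_c if U_c > 0 else 1.0, 1.0), max(seen[2], 1.0)]
    )
    accepted: list[Equilibrium] = []
    for st in candidates:
        st = np.where(np.abs(st) < 1e-14 * scale_vec, 0.0, st)
        resid = float(np.max(np.abs(rhs_reduced(st, p))))
        if resid > tol:
            continue
        dup = False
        for eq in accepted:
            if np.max(np.abs(eq.state - st) / scale_vec) < cfg.dedup_rtol:
                dup = True
                break
        if dup:
            continue
        eig = np.linalg.eigvals(jacobian_reduced(st, p))
        stable = bool(np.max(eig.real) < cfg.stab_tol)
        accepted.append(Equilibrium(state=st, residual=resid, eigenvalues=eig, stable=stable))

    if not accepted:
        raise RuntimeError(
            "equilibrium search returned nothing; even extinction failed the "
            "residual check, which indicates a broken vector field"
        )
    return label_states(accepted, params, cfg)


def label_states(
    equilibria: list[Equilibrium],
    params: ParameterSet,
    cfg: SearchConfig | None = None,
) -> list[Equilibrium]:
    """Assign ``forest`` / ``barren`` / ``extinction`` / ``other`` labels.

    * ``extinction``: the origin.
    * ``forest``: the stable equilibrium with the largest kelp density,
      provided that density is at least ``forest_frac`` of the urchin-free
      kelp equilibrium (which must be positive).  At most one equilibrium
      receives the label.
    * ``barren``: a low-kelp (below ``barren_frac`` of the urchin-free
      equilibrium, or of ``K`` when the former is zero) equilibrium with
      urchins present.  Stable candidates are preferred; when none exists
      the sea-star-free coexistence equilibrium is accepted even if
      formally unstable, because with slow sea-star and urchin mortality it
      is the metastable barren community on the study horizon (its
      ``stable`` flag stays ``False``).
    * everything else: ``other``.
    """
    cfg = cfg or SearchConfig()
    A_uf = urchin_free_kelp_equilibrium(params)
    barren_ref = cfg.barren_frac * (A_uf if A_uf > 0 else params.K)

    for eq in equilibria:
        eq.label = "other"
        if np.all(eq.state == 0.0):
            eq.label = "extinction"

    if A_uf > 0:
        stable_pool = [
            e for e in equilibria if e.stable and e.label != "extinction"
        ]
        if stable_pool:
            best = max(stable_pool, key=lambda e: e.state[0])
            if best.state[0] >= cfg.forest_frac * A_uf:
                best.label = "forest"

    barren_pool = [
        e
        for e in equilibria
        if e.label == "other" and e.state[0] < barren_ref and e.state[1] > 0
    ]
    stable_barren = [e for e in barren_pool if e.stable]
    if stable_barren:
        max(stable_barren, key=lambda e: e.state[1]).label = "barren"
    else:
        fallback = [e for e in barren_pool if e.state[2] == 0.0]
        if fallback:
            max(fallback, key=lambda e: e.state[1]).label = "barren"
    return equilibria


def get_labeled(equilibria: list[Equilibrium], label: str) -> Equilibrium | None:
    """First equilibrium carrying ``label``, or None."""
    for eq in equilibria:
        if eq.label == label:
            return eq
    return None


def equilibria_to_dataframe(equilibria: list[Equilibrium]):
    import pandas as pd

    rows = []
    for eq in equilibria:
        row = {
            "A": eq.state[0],
            "U": eq.state[1],
            "S": eq.state[2],
            "residual": eq.residual,
            "stable": eq.stable,
            "label": eq.label,
        }
        for i, ev in enumerate(eq.eigenvalues[np.argsort(-eq.eigenvalues.real)]):
            row[f"eig{i}_re"] = ev.real
            row[f"eig{i}_im"] = ev.imag
        rows.append(row)
    return pd.DataFrame(rows)


def export_equilibria(equilibria: list[Equilibrium], path: str | Path) -> None:
    """Write equilibria (state, residual, eigenvalues, stability, label) to CSV."""
    equilibria_to_dataframe(equilibria).to_csv(path, index=False)
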