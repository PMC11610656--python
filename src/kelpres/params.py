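"""Model parameters for the kelp-urchin-predator food chain.

The model has 17 parameters: logistic growth of live kelp, linear (Type I)
grazing of live and drift kelp by urchins, saturating (Type II) predation on
urchins, density-independent loss terms, trophic conversion efficiencies, and
four nonconsumptive-effect (NCE) coefficients that modulate consumption rates
(drift-kelp preference, fear of predation, starvation-dependent predation
susceptibility, and kelp-dependent urchin nutritional value).

Time is measured in weeks, kelp biomass in grams, urchins and sea stars in
individuals (densities per unit reef area, with the area factor absorbed into
the rate constants).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = ["ParameterSet", "PARAMETER_NAMES", "PARAMETER_DESCRIPTIONS"]

#: Canonical parameter order, used for array round-trips and sample tables.
PARAMETER_NAMES: tuple[str, ...] = (
    "r",
    "K",
    "kappa_D",
    "alpha_A",
    "kappa_S",
    "delta_A",
    "delta_D",
    "eps_D",
    "eps_U",
    "alpha_D",
    "alpha_U",
    "gamma_U",
    "kappa_A",
    "delta_U",
    "beta",
    "eps_S",
    "delta_S",
)

PARAMETER_DESCRIPTIONS: dict[str, str] = {
    "r": "kelp growth rate at low density (week^-1)",
    "K": "kelp carrying capacity (g kelp)",
    "kappa_D": "drift-kelp preference strength ((g kelp)^-1)",
    "alpha_A": "urchin grazing rate on live kelp ((urchins week)^-1)",
    "kappa_S": "fear-of-predation strength (sea stars^-1)",
    "delta_A": "live-to-drift kelp conversion rate (week^-1)",
    "delta_D": "drift kelp escape/degradation rate (week^-1)",
    "eps_D": "proportion of drift kelp retained (dimensionless)",
    "eps_U": "kelp-to-urchin conversion efficiency (dimensionless)",
    "alpha_D": "drift kelp consumption rate by urchins ((urchins week)^-1)",
    "alpha_U": "predation rate on urchins at low urchin counts ((sea stars week)^-1)",
    "gamma_U": "predation saturation constant (multiplies urchin density)",
    "kappa_A": "starvation effect on urchin predation susceptibility ((g kelp)^-1)",
    "delta_U": "natural urchin death rate (week^-1)",
    "beta": "kelp-density effect on urchin nutritional value ((g kelp)^-1)",
    "eps_S": "urchin-to-predator conversion efficiency (dimensionless)",
    "delta_S": "natural predator death rate (week^-1)",
}

_UNIT_INTERVAL = ("eps_D", "eps_U", "eps_S")


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """Immutable, validated set of the 17 food-chain parameters.

    Behaves as a read-only mapping keyed by parameter name.  Use
    :meth:`replace` to derive variants, :meth:`to_array` /
    :meth:`from_array` for numerical pipelines, and :meth:`to_file` /
    :meth:`from_file` for JSON/YAML round-trips.
    """

    r: float
    K: float
    kappa_D: float
    alpha_A: float
    kappa_S: float
    delta_A: float
    delta_D: float
    eps_D: float
    eps_U: float
    alpha_D: float
    alpha_U: float
    gamma_U: float
    kappa_A: float
    delta_U: float
    beta: float
    eps_S: float
    delta_S: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value!r}")
        if self.r <= 0:
            raise ValueError("parameter 'r' must be > 0")
        if self.K <= 0:
            raise ValueError("parameter 'K' must be > 0")
        if self.delta_D <= 0:
            raise ValueError("parameter 'delta_D' must be > 0")
        for name in _UNIT_INTERVAL:
            value = getattr(self, name)
            if value > 1:
                raise ValueError(f"parameter {name!r} must lie in [0, 1], got {value!r}")

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, key: str) -> float:
        if key not in PARAMETER_NAMES:
            raise KeyError(key)
        return getattr(self, key)

    def __iter__(self) -> Iterator[str]:
        return iter(PARAMETER_NAMES)

    def __len__(self) -> int:
        return len(PARAMETER_NAMES)

    # -- conversions ------------------------------------------------------
    def to_array(self) -> np.ndarray:
        """Parameters as a float array in :data:`PARAMETER_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ParameterSet":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAMETER_NAMES),):
            raise ValueError(
                f"expected {len(PARAMETER_NAMES)} values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAMETER_NAMES, values.tolist())))

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        unknown = set(mapping) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter(s): {sorted(missing)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given parameters replaced."""
        unknown = set(changes) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    # -- serialization ----------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write as flat key->value JSON or YAML (by file extension)."""
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of parameter values")
        return cls.from_dict(data)
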