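"""Configuration reading, result writing and run manifests.

CSV is the primary tabular format; JSON (or YAML) is used for configs,
manifests and single-result outputs.  Write/read round-trips preserve
values to full precision.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .params import ParameterSet

__all__ = ["RunManifest", "read_config", "write_results", "read_results", "load_parameters"]


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run (timestamps aside)."""

    subcommand: str
    config: dict
    seeds: dict = field(default_factory=dict)
    package_version: str = __version__
    distributions_hash: str | None = None
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify) + "\n")


def _jsonify(obj: Any):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def timestamp() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S%z")


def read_config(path: str | Path) -> dict:
    """Read a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    return dict(data)


def load_parameters(config: Mapping | str | Path | None) -> ParameterSet:
    """Resolve a parameter specification to a :class:`ParameterSet`.

    Accepts a path to a JSON/YAML file, a mapping of overrides (missing
    parameters fall back to the packaged baselines), or None (baselines).
    """
    from .scenarios import baseline_parameters

    if config is None:
        return baseline_parameters()
    if isinstance(config, (str, Path)):
        config = read_config(config)
    base = baseline_parameters().to_dict()
    unknown = set(config) - set(base)
    if unknown:
        raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
    base.update({k: float(v) for k, v in config.items()})
    return ParameterSet.from_dict(base)


def write_results(table: pd.DataFrame, path: str | Path, format: str | None = None) -> None:
    """Write a result table as CSV or JSON (by extension, or explicitly).

    Missing values are serialized as empty cells (CSV) or null (JSON) and
    parse back as missing.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt == "json":
        records = [
            {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in row.items()
            }
            for row in table.to_dict(orient="records")
        ]
        path.write_text(json.dumps(records, indent=2, default=_jsonify) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return pd.read_json(path, orient="records", precise_float=True)
    return pd.read_csv(path, float_precision="round_trip")
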