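"""Global sensitivity analysis of the resilience metrics.

The GSA follows a sample-then-attribute design: draw parameter sets from
per-parameter uncertainty distributions, compute the three resilience
metrics for each draw, then train a random-forest regressor per metric and
rank parameters by permutation importance.  The four nonconsumptive-effect
parameters (``kappa_D``, ``kappa_S``, ``beta``, ``kappa_A``) are
zero-inflated: each draw is multiplied by an independent Bernoulli indicator
that is 0 with probability 0.1, so the analysis probes the presence as well
as the strength of each feedback.

Importance scores are comparable only within a metric; their absolute
values are arbitrary and must not be compared across metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .action_solver import ActionConfig
from .params import PARAMETER_NAMES, ParameterSet
from .resilience import MetricResult, compute_metrics
from .scenarios import baseline_parameters, default_distributions_path

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "SampleTable",
    "ImportanceRanking",
    "GsaConfig",
    "load_distributions",
    "default_distributions",
    "sample_parameters",
    "evaluate_metrics_batch",
    "rank_importance",
    "local_sweep",
]

METRIC_COLUMNS = ("recovery_likelihood", "recovery_rate", "resistance")


@dataclass(frozen=True)
class DistributionSpec:
    """Marginal sampling distribution of one parameter.

    ``kind`` is one of ``normal`` (mean ``a``, sd ``b``; truncated at zero
    by resampling), ``lognormal`` (log-mean ``a``, log-sd ``b``),
    ``uniform`` and ``loguniform`` (bounds ``a``, ``b``).
    ``zero_inflation_prob`` is the probability that the draw is replaced by
    exactly zero (used for the NCE parameters).
    """

    kind: str
    a: float
    b: float
    zero_inflation_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal", "uniform", "loguniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if not 0.0 <= self.zero_inflation_prob <= 1.0:
            raise ValueError("zero_inflation_prob must lie in [0, 1]")
        if self.kind == "normal" and self.b <= 0:
            raise ValueError("normal sd must be > 0")
        if self.kind == "lognormal" and self.b <= 0:
            raise ValueError("lognormal sdlog must be > 0")
        if self.kind in ("uniform", "loguniform") and not self.a < self.b:
            raise ValueError("bounds must satisfy a < b")
        if self.kind == "loguniform" and self.a <= 0:
            raise ValueError("loguniform bounds must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "normal":
            out = rng.normal(self.a, self.b, size=n)
            # truncate at 0 by resampling (preserves the shape above 0)
            for _ in range(1000):
                neg = out <= 0
                if not neg.any():
                    break
                out[neg] = rng.normal(self.a, self.b, size=int(neg.sum()))
            out = np.abs(out)  # fallback for pathological specs
        elif self.kind == "lognormal":
            out = rng.lognormal(self.a, self.b, size=n)
        elif self.kind == "uniform":
            out = rng.uniform(self.a, self.b, size=n)
        else:
            out = np.exp(rng.uniform(np.log(self.a), np.log(self.b), size=n))
        if self.zero_inflation_prob > 0:
            out = out * (rng.random(n) >= self.zero_inflation_prob)
        return out


def load_distributions(path: str | Path) -> dict[str, DistributionSpec]:
    """Read a distribution table (JSON mapping parameter -> spec fields)."""
    data = json.loads(Path(path).read_text())
    unknown = set(data) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter name(s) in distribution table: {sorted(unknown)}")
    missing = set(PARAMETER_NAMES) - set(data)
    if missing:
        raise ValueError(f"distribution table missing parameter(s): {sorted(missing)}")
    out = {}
    for name in PARAMETER_NAMES:
        try:
            out[name] = DistributionSpec(**data[name])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid distribution for parameter {name!r}: {exc}") from exc
    return out


def default_distributions() -> dict[str, DistributionSpec]:
    """The packaged default distribution table."""
    return load_distributions(default_distributions_path())


def distributions_hash(table: Mapping[str, DistributionSpec]) -> str:
    """Stable short hash of a distribution table, for run manifests."""
    payload = json.dumps(
        {k: vars(v) for k, v in sorted(table.items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SampleTable:
    """Parameter draws with (possibly empty) metric columns."""

    data: pd.DataFrame
    seed: int
    distributions_hash: str

    @property
    def n(self) -> int:
        return len(self.data)

    def parameter_set(self, i: int) -> ParameterSet:
        return ParameterSet.from_dict(
            {name: float(self.data.iloc[i][name]) for name in PARAMETER_NAMES}
        )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def sample_parameters(
    n: int,
    table: Mapping[str, DistributionSpec] | None = None,
    seed: int = 0,
) -> SampleTable:
    """Draw ``n`` independent parameter sets from the distribution table.

    Fully reproducible from ``seed``; metric columns are initialized to
    missing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    table = table or default_distributions()
    rng = np.random.default_rng(seed)
    cols = {name: table[name].draw(rng, n) for name in PARAMETER_NAMES}
    df = pd.DataFrame(cols)
    for m in METRIC_COLUMNS:
        df[m] = np.nan
    df["reason_recovery_rate"] = ""
    df["reason_resistance"] = ""
    return SampleTable(data=df, seed=seed, distributions_hash=distributions_hash(table))


@dataclass
class GsaConfig:
    """Settings of the batch metric evaluation."""

    metrics: tuple[str, ...] = METRIC_COLUMNS
    horizon: float = 1000.0
    threshold: float = 0.95
    resistance_subsample: int = 1000  # quasipotential solves are the costly part
    resistance_seed_offset: int = 7919  # subsample seed = table seed + offset
    action_cfg: ActionConfig | None = None
    direct_paths: bool = False  # gate strategy only (fast) unless enabled


def evaluate_metrics_batch(samples: SampleTable, cfg: GsaConfig | None = None) -> SampleTable:
    """Fill the metric columns of a sample table, row by row.

    Rows are independent; a failure in one row is logged and recorded as
    missing values with reason ``error`` without aborting the batch.
    Resistance is evaluated on a seeded subsample of rows (it requires a
    path optimization per row); other rows carry reason ``skipped``.
    """
    cfg = cfg or GsaConfig()
    df = samples.data
    n = len(df)

    do_resist = "resistance" in cfg.metrics
    resist_rows = np.zeros(n, dtype=bool)
    if do_resist:
        k = min(cfg.resistance_subsample, n)
        rng = np.random.default_rng(samples.seed + cfg.resistance_seed_offset)
        resist_rows[rng.choice(n, size=k, replace=False)] = True

    action_cfg = cfg.action_cfg or ActionConfig(
        nonnegative=True, max_cycles=6, maxiter_per_cycle=200
    )

    for i in range(n):
        try:
            params = samples.parameter_set(i)
        except ValueError as exc:
            logger.warning("row %d: invalid parameters (%s)", i, exc)
            df.loc[i, "reason_recovery_rate"] = "error"
            df.loc[i, "reason_resistance"] = "error"
            continue
        try:
            result = compute_metrics(
                params,
                horizon=cfg.horizon,
                threshold=cfg.threshold,
                action_cfg=action_cfg,
                skip_resistance=not (do_resist and resist_rows[i]),
            )
        except Exception:  # noqa: BLE001 -- row isolation is the contract
            logger.exception("row %d: metric evaluation failed", i)
            df.loc[i, "reason_recovery_rate"] = "error"
            df.loc[i, "reason_resistance"] = "error"
            continue
        _store_result(df, i, result, cfg)
    return samples


def _store_result(df: pd.DataFrame, i: int, result: MetricResult, cfg: GsaConfig) -> None:
    if "recovery_likelihood" in cfg.metrics:
        df.loc[i, "recovery_likelihood"] = result.recovery_likelihood
    if "recovery_rate" in cfg.metrics:
        if result.recovery_rate is None:
            df.loc[i, "reason_recovery_rate"] = result.reasons.get("recovery_rate", "")
        else:
            df.loc[i, "recovery_rate"] = result.recovery_rate
    if "resistance" in cfg.metrics:
        if result.resistance is None:
            df.loc[i, "reason_resistance"] = result.reasons.get("resistance", "")
        else:
            df.loc[i, "resistance"] = result.resistance


@dataclass
class ImportanceRanking:
    """Per-metric parameter importance from the random-forest analysis."""

    metric: str
    ranking: list  # [(parameter, permutation importance), ...] descending
    impurity_importance: dict
    n_used: int
    seed: int
    rf_params: dict = dc_field(default_factory=dict)

    def top(self, k: int = 2) -> list[str]:
        return [name for name, _ in self.ranking[:k]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [n for n, _ in self.ranking],
                "permutation_importance": [v for _, v in self.ranking],
                "impurity_importance": [
                    self.impurity_importance[n] for n, _ in self.ranking
                ],
            }
        )


def rank_importance(
    samples: SampleTable,
    metric: str,
    seed: int = 0,
    n_estimators: int = 500,
    holdout: float = 0.25,
    n_repeats: int = 10,
    min_rows: int = 100,
) -> ImportanceRanking:
    """Random-forest importance ranking of the parameters for one metric.

    Trains a random-forest regressor of the metric on the 17 parameters
    (rows where the metric is defined), then scores each parameter by
    permutation importance on a held-out quarter of the rows; impurity
    importance is stored as a secondary diagnostic.  Deterministic given
    ``seed``.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance
    from sklearn.model_selection import train_test_split

    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    df = samples.data
    mask = df[metric].notna()
    n_used = int(mask.sum())
    if n_used < min_rows:
        reason_col = f"reason_{metric}"
        tally = (
            df.loc[~mask, reason_col].value_counts().to_dict()
            if reason_col in df
            else {}
        )
        raise ValueError(
            f"only {n_used} rows have {metric} defined (need >= {min_rows}); "
            f"reasons: {tally}"
        )
    X = df.loc[mask, list(PARAMETER_NAMES)].to_numpy()
    y = df.loc[mask, metric].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout, random_state=seed
    )
    rf = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(X_tr, y_tr)
    perm = permutation_importance(
        rf, X_te, y_te, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    order = np.argsort(-perm.importances_mean)
    ranking = [(PARAMETER_NAMES[j], float(perm.importances_mean[j])) for j in order]
    impurity = dict(zip(PARAMETER_NAMES, map(float, rf.feature_importances_)))
    return ImportanceRanking(
        metric=metric,
        ranking=ranking,
        impurity_importance=impurity,
        n_used=n_used,
        seed=seed,
        rf_params={"n_estimators": n_estimators, "holdout": holdout, "n_repeats": n_repeats},
    )


def local_sweep(
    params: ParameterSet,
    sweep_names: Sequence[str],
    ranges: Sequence[np.ndarray],
    metric: str,
    cfg: GsaConfig | None = None,
) -> pd.DataFrame:
    """Evaluate one metric on a 1D or 2D grid of parameter values.

    All parameters other than the swept ones stay at the values in
    ``params`` (typically the baselines).  Returns a long-format frame with
    one row per grid point (parameter values, metric value, reason for
    missing values).
    """
    cfg = cfg or GsaConfig()
    if len(sweep_names) not in (1, 2) or len(ranges) != len(sweep_names):
        raise ValueError("sweep_names and ranges must have length 1 or 2 and match")
    for name in sweep_names:
        if name not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter name {name!r}")
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")

    grids = np.meshgrid(*[np.asarray(r, dtype=float) for r in ranges], indexing="ij")
    points = np.stack([g.ravel() for g in grids], axis=-1)
    action_cfg = cfg.action_cfg or ActionConfig(
        nonnegative=True, max_cycles=6, maxiter_per_cycle=200
    )

    rows = []
    for pt in points:
        row = {name: float(v) for name, v in zip(sweep_names, pt)}
        try:
            pset = params.replace(**row)
            result = compute_metrics(
                pset,
                horizon=cfg.horizon,
                threshold=cfg.threshold,
                action_cfg=action_cfg,
                skip_resistance=metric != "resistance",
            )
            value = getattr(result, metric)
            row[metric] = np.nan if value is None else value
            row["reason"] = result.reasons.get(metric, "")
        except Exception as exc:  # noqa: BLE001 -- isolate grid points
            logger.exception("sweep point %r failed", row)
            row[metric] = np.nan
            row["reason"] = f"error: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
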