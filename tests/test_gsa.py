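import numpy as np
import pandas as pd
import pytest

from kelpres.gsa import (
    DistributionSpec,
    GsaConfig,
    SampleTable,
    default_distributions,
    evaluate_metrics_batch,
    local_sweep,
    rank_importance,
    sample_parameters,
)
from kelpres.params import PARAMETER_NAMES
from kelpres.resilience import compute_metrics


class TestDistributionSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="bogus", a=0, b=1),
            dict(kind="normal", a=1, b=0),
            dict(kind="uniform", a=1, b=1),
            dict(kind="loguniform", a=0, b=1),
            dict(kind="lognormal", a=0, b=1, zero_inflation_prob=1.5),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DistributionSpec(**kwargs)

    def test_truncated_normal_stays_positive(self, rng):
        spec = DistributionSpec(kind="normal", a=0.5, b=2.0)
        draws = spec.draw(rng, 5000)
        assert np.all(draws > 0)

    def test_loguniform_bounds(self, rng):
        spec = DistributionSpec(kind="loguniform", a=1e-5, b=1e-1)
        draws = spec.draw(rng, 5000)
        assert np.all((draws >= 1e-5) & (draws <= 1e-1))


class TestSampleParameters:
    def test_same_seed_identical(self):
        a = sample_parameters(200, seed=7).data
        b = sample_parameters(200, seed=7).data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_parameters(50, seed=1).data
        b = sample_parameters(50, seed=2).data
        assert not np.array_equal(a["r"].to_numpy(), b["r"].to_numpy())

    def test_nce_zero_inflation_fraction(self):
        """The four NCE parameters are zeroed with probability 0.10."""
        df = sample_parameters(10000, seed=3).data
        for name in ("kappa_D", "kappa_S", "beta", "kappa_A"):
            frac = float((df[name] == 0.0).mean())
            assert frac == pytest.approx(0.10, abs=0.01)
        assert float((df["r"] == 0.0).mean()) == 0.0

    def test_truncated_normal_mean_of_r(self):
        """Sample mean of r matches the zero-truncated Normal(2.5, 1.5) mean
        (2.657, shifted above 2.5 by the truncation) within 3 SE."""
        from scipy.stats import norm

        mu, sd, n = 2.5, 1.5, 10000
        alpha = -mu / sd
        trunc_mean = mu + sd * norm.pdf(alpha) / (1.0 - norm.cdf(alpha))
        df = sample_parameters(n, seed=4).data
        se = sd / np.sqrt(n)
        assert abs(df["r"].mean() - trunc_mean) < 3 * se

    def test_all_parameters_nonnegative(self):
        df = sample_parameters(2000, seed=5).data
        assert (df[list(PARAMETER_NAMES)].to_numpy() >= 0).all()

    def test_n_validation(self):
        with pytest.raises(ValueError):
            sample_parameters(0)


def _fake_table(rng, n=600):
    """A sample table with metric columns left empty, for ranking tests."""
    table = sample_parameters(n, seed=11)
    return table, table.data


class TestRankImportance:
    def test_constructed_signal_orders_features(self, rng):
        """y = x1 + 0.1 x2 + noise: the strong feature must outrank the
        weak one."""
        table, df = _fake_table(rng)
        x1 = rng.uniform(0, 1, len(df))
        x2 = rng.uniform(0, 1, len(df))
        df["r"] = x1
        df["K"] = x2
        df["recovery_likelihood"] = x1 + 0.1 * x2 + rng.normal(0, 0.01, len(df))
        ranking = rank_importance(table, "recovery_likelihood", seed=0)
        scores = dict(ranking.ranking)
        assert scores["r"] > scores["K"]

    def test_single_driver_ranked_first(self, rng):
        table, df = _fake_table(rng)
        df["recovery_rate"] = np.log(df["delta_U"].to_numpy())
        ranking = rank_importance(table, "recovery_rate", seed=0)
        assert ranking.top(1) == ["delta_U"]

    def test_deterministic_given_seed(self, rng):
        table, df = _fake_table(rng)
        df["resistance"] = df["r"].to_numpy() * df["K"].to_numpy()
        a = rank_importance(table, "resistance", seed=3)
        b = rank_importance(table, "resistance", seed=3)
        assert a.ranking == b.ranking

    def test_too_few_rows_reports_reason_tally(self):
        table = sample_parameters(200, seed=6)
        table.data.loc[:150, "reason_recovery_rate"] = "no_forest"
        with pytest.raises(ValueError, match="no_forest"):
            rank_importance(table, "recovery_rate")

    def test_unknown_metric(self):
        table = sample_parameters(5, seed=0)
        with pytest.raises(ValueError):
            rank_importance(table, "shininess")


class TestEvaluateBatch:
    def test_baseline_row_fully_defined(self, baseline):
        table = sample_parameters(2, seed=8)
        for name in PARAMETER_NAMES:
            table.data.loc[0, name] = baseline[name]
        table.data.loc[1, "r"] = 0.5  # below delta_A: no forest
        table.data.loc[1, "delta_A"] = 1.8
        evaluate_metrics_batch(table, GsaConfig(resistance_subsample=2))
        df = table.data
        assert 0 < df.loc[0, "recovery_likelihood"] <= 1
        assert np.isfinite(df.loc[0, "recovery_rate"])
        assert np.isfinite(df.loc[0, "resistance"])
        assert df.loc[1, "recovery_likelihood"] == 0.0
        assert np.isnan(df.loc[1, "recovery_rate"])
        assert df.loc[1, "reason_recovery_rate"] == "no_forest"
        assert df.loc[1, "reason_resistance"] == "no_forest"

    def test_row_order_independence(self):
        t1 = sample_parameters(6, seed=9)
        evaluate_metrics_batch(
            t1, GsaConfig(metrics=("recovery_likelihood", "recovery_rate"))
        )
        t2 = sample_parameters(6, seed=9)
        perm = np.array([3, 1, 5, 0, 2, 4])
        t2.data = t2.data.iloc[perm].reset_index(drop=True)
        evaluate_metrics_batch(
            t2, GsaConfig(metrics=("recovery_likelihood", "recovery_rate"))
        )
        got = t2.data["recovery_likelihood"].to_numpy()
        want = t1.data["recovery_likelihood"].to_numpy()[perm]
        np.testing.assert_array_equal(got, want)

    def test_resistance_subsample_marks_skipped(self):
        table = sample_parameters(6, seed=10)
        evaluate_metrics_batch(table, GsaConfig(resistance_subsample=2))
        skipped = (table.data["reason_resistance"] == "skipped").sum()
        assert skipped == 4


class TestLocalSweep:
    def test_single_point_matches_direct_call(self, baseline):
        frame = local_sweep(
            baseline, ["r"], [np.array([2.5])], "recovery_likelihood"
        )
        direct = compute_metrics(baseline, skip_resistance=True).recovery_likelihood
        assert frame.loc[0, "recovery_likelihood"] == pytest.approx(direct)

    def test_recovery_likelihood_steps_at_drift_rate(self, baseline):
        """Sweeping kelp growth r across delta_A: recovery likelihood is 0
        below the drift-production rate and positive above it."""
        rs = np.array([1.0, 1.5, 2.1, 2.6])
        frame = local_sweep(baseline, ["r"], [rs], "recovery_likelihood")
        vals = frame["recovery_likelihood"].to_numpy()
        assert np.all(vals[rs < baseline.delta_A] == 0.0)
        assert np.all(vals[rs > baseline.delta_A] > 0.0)

    def test_2d_sweep_shape(self, baseline):
        frame = local_sweep(
            baseline,
            ["r", "delta_A"],
            [np.array([1.0, 2.5]), np.array([0.5, 1.8])],
            "recovery_likelihood",
        )
        assert len(frame) == 4
        assert set(["r", "delta_A", "recovery_likelihood"]) <= set(frame.columns)

    def test_invalid_names_rejected(self, baseline):
        with pytest.raises(ValueError):
            local_sweep(baseline, ["bogus"], [np.array([1.0])], "recovery_likelihood")
        with pytest.raises(ValueError):
            local_sweep(baseline, ["r"], [np.array([1.0])], "bogus")


def test_default_distribution_table_brackets_baselines(baseline):
    """Every sampled distribution should place nonzero density at (or
    bracketing) the Table-style baseline value of its parameter."""
    table = default_distributions()
    for name, spec in table.items():
        base = baseline[name]
        if spec.kind in ("uniform", "loguniform"):
            assert spec.a <= base <= spec.b, name
        elif spec.kind == "normal":
            assert abs(base - spec.a) < 3 * spec.b, name
        else:  # lognormal
            assert abs(np.log(base) - spec.a) < 3 * spec.b, name
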