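"""Reference fixtures, population sampling, and the full study runners."""

import numpy as np
import pytest

from toxcea import (
    ScenarioSuite,
    default_suite,
    run_suite,
    sample_population,
    table1_demo,
)


class TestSamplePopulation:
    def test_bounds_and_determinism(self):
        a = sample_population(n=5000, seed=11)
        b = sample_population(n=5000, seed=11)
        assert a.n == 5000
        assert np.all((a.samples >= -5) & (a.samples <= 2))
        np.testing.assert_array_equal(a.samples, b.samples)
        c = sample_population(n=5000, seed=12)
        assert not np.array_equal(a.samples, c.samples)

    def test_degenerate_bounds(self):
        pop = sample_population(n=1, bounds=(-3.0, -3.0), seed=0)
        assert pop.samples.tolist() == [-3.0]

    def test_empirical_mean_matches_uniform(self):
        pop = sample_population(n=100_000, seed=5)
        se = (7.0 / np.sqrt(12.0)) / np.sqrt(pop.n)
        assert abs(pop.samples.mean() - (-1.5)) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sample_population(n=0)
        with pytest.raises(ValueError):
            sample_population(bounds=(2.0, -5.0))


class TestTable1Demo:
    def test_printed_ledger_cells(self):
        ledger = table1_demo()
        year11 = ledger.loc[ledger["year"] == 11, "discounted_dmv"].item()
        assert round(year11, 3) == 0.670
        assert round(ledger.attrs["npv_outcome"], 2) == 5.88
        assert round(ledger.attrs["cer"], 2) == 0.85
        assert ledger.attrs["npv_cost"] == 5.0
        # cost charged entirely in year 1
        assert ledger["cost_millions"].sum() == 5.0
        assert ledger.loc[0, "cost_millions"] == 5.0

    def test_undiscounted_variant(self):
        ledger = table1_demo(discount_rate=0.0)
        used = ledger["discounted_dmv"].dropna()
        assert np.allclose(used, 0.9)

    def test_horizon_must_exceed_duration(self):
        with pytest.raises(ValueError):
            table1_demo(duration_years=20, horizon=20)


@pytest.fixture(scope="module")
def small_result():
    suite = default_suite()
    pop = sample_population(n=400, seed=3)
    return suite, run_suite(suite, pop)


class TestRunSuite:
    def test_output_shape(self, small_result):
        suite, result = small_result
        assert len(result.per_chemical) == 400
        # sorted by potency for curve plotting
        assert result.per_chemical["mu_tox"].is_monotonic_increasing
        assert set(result.aggregates.index) == {m.name for m in suite.methodologies}
        for rule in ("simple", "complex"):
            assert f"mean_cer_{rule}" in result.aggregates.columns
            assert f"max_cer_{rule}" in result.aggregates.columns

    def test_cost_reduction_row_is_exactly_five(self, small_result):
        _, result = small_result
        row = result.reductions.iloc[0]
        assert all(v == pytest.approx(5.0, rel=1e-12) for v in row)

    def test_duration_reduction_row_is_constant(self, small_result):
        _, result = small_result
        row = result.reductions.iloc[1]
        assert all(v == pytest.approx(row.iloc[0], rel=1e-12) for v in row)

    def test_rules_coincide_for_clearly_safe_chemicals(self, small_result):
        # far above the TRL threshold both rules reduce to the same
        # two-sided-correct probability
        suite, result = small_result
        df = result.per_chemical
        sigma = suite.methodologies[0].sigma_mu_hat
        safe = df["mu_tox"] > suite.context.trl_mu_tox + 4 * sigma
        assert safe.sum() > 0
        rel = (
            df.loc[safe, "cer_base_case_complex"]
            / df.loc[safe, "cer_base_case_simple"]
            - 1.0
        )
        assert np.all(np.abs(rel) < 0.01)

    def test_complex_curve_peaks_at_decision_thresholds(self):
        # with a low-uncertainty methodology the CER-vs-potency curve has
        # a sharp local maximum at the sampled point nearest each threshold
        suite = default_suite()
        pop = sample_population(n=5000, seed=3)
        result = run_suite(suite, pop)
        df = result.per_chemical
        mu = df["mu_tox"].to_numpy()
        cer = df["cer_reduced_uncertainty_complex"].to_numpy()
        thresholds = suite.context.thresholds_descending[:3]
        for thr in thresholds:
            window = np.abs(mu - thr) < 0.14
            local_peak = mu[window][np.argmax(cer[window])]
            nearest = mu[np.argmin(np.abs(mu - thr))]
            assert local_peak == nearest

    def test_aggregate_means_stable_across_seeds(self):
        suite = default_suite()
        r1 = run_suite(suite, sample_population(n=5000, seed=101))
        r2 = run_suite(suite, sample_population(n=5000, seed=202))
        mean_cols = [c for c in r1.aggregates.columns if c.startswith("mean")]
        rel = (r1.aggregates[mean_cols] / r2.aggregates[mean_cols] - 1.0).abs()
        assert (rel < 0.05).all().all()

    def test_results_written_to_directory(self, small_result, tmp_path):
        _, result = small_result
        result.to_dir(tmp_path / "out")
        for name in (
            "per_chemical.csv",
            "aggregate_cer.csv",
            "cer_reductions.csv",
            "summary.json",
        ):
            assert (tmp_path / "out" / name).exists()


class TestScenarioConfig:
    def _default_dict(self):
        return {
            "trl": 1e-6,
            "sigma_tox": 1.0,
            "baseline_exposure": {"mu_exp": -8.0, "sigma_exp": 0.5},
            "actions": [
                {"id": 1, "mu_exp": -8.5, "sigma_exp": 0.4, "cost_rank": 1},
                {"id": 2, "mu_exp": -8.8, "sigma_exp": 0.4, "cost_rank": 2},
                {"id": 3, "mu_exp": -14.0, "sigma_exp": 0.1, "cost_rank": 3},
            ],
            "methodologies": [
                {
                    "name": "base case",
                    "duration_years": 10,
                    "cost_per_chemical": 5.0,
                    "sigma_mu_hat": 1.0,
                }
            ],
            "program": {
                "annual_budget": 10.0,
                "discount_rate": 0.03,
                "time_horizon": [11, 20],
            },
        }

    def test_yaml_round_trip_matches_defaults(self, tmp_path):
        import yaml

        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(self._default_dict()))
        suite = ScenarioSuite.from_file(path)
        ref = default_suite()
        assert suite.context.trl_mu_tox == ref.context.trl_mu_tox
        assert suite.context.dp_mu_tox == ref.context.dp_mu_tox
        assert suite.program == ref.program
        assert suite.methodologies[0] == ref.methodologies[0]

    def test_json_config_accepted(self, tmp_path):
        import json

        path = tmp_path / "scenario.json"
        path.write_text(json.dumps(self._default_dict()))
        suite = ScenarioSuite.from_file(path)
        assert suite.program.horizons == tuple(range(11, 21))

    def test_unknown_rule_rejected(self):
        cfg = self._default_dict()
        cfg["rules"] = ["simple", "bayes"]
        with pytest.raises(ValueError, match="unknown decision rules"):
            ScenarioSuite.from_dict(cfg)
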