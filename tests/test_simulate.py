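"""Simulation harness: populations, grids, repeats, closed-form SE."""

import math

import numpy as np
import pytest
from scipy import stats

from prevstab import (
    PopulationSpec,
    StabilityParams,
    expected_se,
    make_population,
    repeat_runs,
    run_default_grid,
    run_from_config,
    run_parameter_sweep,
    run_single,
    subsample_proportions,
    summarize_grid,
)
from prevstab.simulate import load_config


class TestPopulation:
    @pytest.mark.parametrize(
        "n,p,ones", [(10, 0.5, 5), (1000, 0.5, 500), (100, 0.0, 0), (100, 1.0, 100)]
    )
    def test_exact_presence_counts(self, n, p, ones):
        pop = make_population(PopulationSpec(n, p))
        assert pop.size == n and pop.sum() == ones

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(100, 1.5)
        with pytest.raises(ValueError):
            PopulationSpec(0, 0.5)


class TestExpectedSE:
    def test_census_has_zero_error(self):
        assert expected_se(0.4, 50, 50) == 0.0

    def test_single_draw_from_large_population(self):
        assert expected_se(0.5, 1, 10**9) == pytest.approx(50.0, rel=1e-6)

    def test_symmetric_in_p(self):
        for p in (0.1, 0.25, 0.4):
            assert expected_se(p, 7, 100) == expected_se(1 - p, 7, 100)

    def test_k_beyond_population_rejected(self):
        with pytest.raises(ValueError):
            expected_se(0.5, 51, 50)

    def test_matches_empirical_sd_of_subsamples(self):
        N, p, k, n = 50, 0.4, 10, 100_000
        pop = make_population(PopulationSpec(N, p))
        props = subsample_proportions(pop, k, n, np.random.default_rng(8)) * 100
        theory = expected_se(p, k, N)
        assert abs(props.std(ddof=1) - theory) < 5 * theory / math.sqrt(2 * n)


class TestRunSingle:
    def test_constant_population_stabilises_immediately(self):
        rec = run_single(PopulationSpec(100, 1.0), StabilityParams(seed=0))
        assert rec["stability_point"] == 10  # first full window
        assert rec["abs_error_pp"] == 0.0

    def test_population_shorter_than_window_is_na(self):
        rec = run_single(PopulationSpec(5, 0.4), StabilityParams(seed=0))
        assert math.isnan(rec["stability_point"])
        assert math.isnan(rec["abs_error_pp"])

    def test_focal_case_accuracy(self):
        rec = run_single(
            PopulationSpec(1000, 0.5), StabilityParams(seed=1),
            np.random.default_rng(1),
        )
        assert not math.isnan(rec["stability_point"])
        assert rec["abs_error_pp"] <= 2.0


def test_reduced_grid_smoke():
    df = run_default_grid(seed=0, sizes=(100,), prevalences=(0.5,), replicates=(10,))
    assert len(df) == 1
    rec = df.iloc[0]
    assert rec["population_size"] == 100 and rec["n_replicates"] == 10
    assert rec["successive_points"] == 10


def test_grid_record_invariants():
    df = run_default_grid(
        seed=3, sizes=(100, 1000), prevalences=(0.2, 0.5, 0.8), replicates=(20, 50)
    )
    finite = df[df["stability_point"].notna()]
    assert (finite["abs_error_pp"] >= 0).all()
    assert finite["estimated_prevalence"].between(0, 100).all()
    assert (finite["stability_point"] >= 10).all()
    assert df.loc[df["stability_point"].isna(), "abs_error_pp"].isna().all()
    s = summarize_grid(df)
    assert s["n_cells"] == 12
    assert s["grand_mean_stability_point"] > 0


def test_grid_deterministic_per_seed():
    kw = dict(sizes=(100,), prevalences=(0.3, 0.6), replicates=(20,))
    a = run_default_grid(seed=9, **kw)
    b = run_default_grid(seed=9, **kw)
    assert a.equals(b)


@pytest.fixture(scope="module")
def sweep():
    return run_parameter_sweep(seed=4)


class TestParameterSweep:
    def test_full_factorial(self, sweep):
        assert len(sweep) == 36
        assert set(sweep["successive_points"]) == {2, 10, 50}

    def test_more_successive_points_need_more_samples(self, sweep):
        by_x = sweep.groupby("successive_points")["stability_point"].mean()
        assert by_x[50] > by_x[10]

    def test_stricter_delta_needs_more_samples(self, sweep):
        by_z = sweep.groupby("delta_threshold")["stability_point"].mean()
        assert by_z[0.5] >= by_z[2.0]

    def test_loosest_combination_is_cheapest(self, sweep):
        loosest = sweep.query(
            "successive_points == 2 and mean_diff_threshold == 10 and delta_threshold == 2"
        )["stability_point"].iloc[0]
        assert loosest == sweep["stability_point"].min()


class TestRepeatRuns:
    def test_certain_population_has_no_spread(self):
        s = repeat_runs(PopulationSpec(100, 1.0), StabilityParams(), runs=10, seed=0)
        assert s.mean_stability_point == 10 and s.sd_stability_point == 0.0
        assert s.na_count == 0

    def test_single_run_sd_zero_by_convention(self):
        s = repeat_runs(PopulationSpec(100, 0.3), StabilityParams(), runs=1, seed=0)
        assert s.runs == 1 and s.sd_stability_point == 0.0
        assert "convention" in s.note

    def test_invalid_runs_rejected(self):
        with pytest.raises(ValueError):
            repeat_runs(PopulationSpec(100, 0.3), StabilityParams(), runs=0, seed=0)

    def test_focal_case_reports_spread(self):
        s = repeat_runs(PopulationSpec(1000, 0.5), StabilityParams(), runs=10, seed=2)
        assert s.na_count == 0
        assert s.sd_stability_point > 0
        assert len(s.stability_points) == 10


def test_mid_prevalence_needs_more_samples_than_extremes():
    """Binomial-like variance peaks at p = 0.5, so stability comes later."""
    mid = repeat_runs(PopulationSpec(1000, 0.5), StabilityParams(), runs=10, seed=6)
    low = repeat_runs(PopulationSpec(1000, 0.1), StabilityParams(), runs=10, seed=6)
    assert mid.mean_stability_point >= low.mean_stability_point


def test_stability_distribution_symmetric_in_p():
    """p and 1-p populations are statistically indistinguishable."""
    a, b = [], []
    for i in range(100):
        a.append(
            run_single(PopulationSpec(500, 0.3), StabilityParams(), np.random.default_rng([21, i]))[
                "stability_point"
            ]
        )
        b.append(
            run_single(PopulationSpec(500, 0.7), StabilityParams(), np.random.default_rng([22, i]))[
                "stability_point"
            ]
        )
    a = [v for v in a if not math.isnan(v)]
    b = [v for v in b if not math.isnan(v)]
    assert stats.mannwhitneyu(a, b).pvalue > 0.01


class TestConfig:
    def test_unknown_key_named(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("mode: grid\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            load_config(p)

    def test_empty_config_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_config(p)

    def test_repeat_mode_round_trip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(
            "mode: repeat\npopulation_size: 200\ntrue_prevalence: 0.5\nruns: 3\nseed: 5\n"
        )
        records, summary = run_from_config(load_config(p))
        assert records is None
        assert summary["runs"] == 3

    def test_grid_mode_round_trip(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text(
            "mode: grid\nsizes: [100]\nprevalences: [0.5]\nreplicates: [10, 20]\nseed: 5\n"
        )
        records, summary = run_from_config(load_config(p))
        assert len(records) == 2
        assert summary["n_cells"] == 2
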