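"""Grid accounting, the statistics layer, and the orchestrated run."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm, rankdata

from nichetransfer.errors import DataError
from nichetransfer.experiment import (
    ExperimentConfig,
    ExperimentGrid,
    kruskal_wallis,
    pairwise_mann_whitney,
    run_experiment,
    summarize,
)
from nichetransfer.synthetic_world import ScenarioConfig, generate_scenario


class TestGridAccounting:
    def test_small_grid_arithmetic(self):
        grid = ExperimentGrid(
            species=["a", "b", "c"], procedures=["bioclim", "glm"],
            variable_sets=["apriori3", "pca3"],
        )
        assert grid.expected_rows == 12
        assert len(grid.plan()) == 12

    def test_plan_seeds_are_stable(self):
        grid = ExperimentGrid(species=["a"], procedures=["glm"], master_seed=5)
        assert grid.plan().equals(grid.plan())

    def test_unknown_procedure_rejected(self):
        with pytest.raises(DataError):
            ExperimentGrid(species=["a"], procedures=["mars"])


def _kw_reference(groups):
    """Independent tie-corrected Kruskal-Wallis from the rank formulas."""
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - ((counts**3 - counts).sum()) / (N**3 - N)
    H /= tie
    return H, chi2.sf(H, len(groups) - 1)


def _mw_reference(x, y):
    """Independent tie-corrected normal-approximation Mann-Whitney p."""
    nx, ny = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    U = ranks[:nx].sum() - nx * (nx + 1) / 2
    mu = nx * ny / 2.0
    N = nx + ny
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie = ((counts**3 - counts).sum()) / (N * (N - 1))
    sd = np.sqrt(nx * ny / 12.0 * (N + 1 - tie))
    z = (abs(U - mu) - 0.5) / sd
    return 2 * norm.sf(z)


class TestKruskalWallis:
    def test_hand_rank_oracle(self):
        # groups (1,2,3) and (4,5,6): ranks 1..6, H = 12/42*(36/3+225/3)-21 = 27/7
        H, p = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert H == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert p == pytest.approx(chi2.sf(27.0 / 7.0, 1), abs=1e-12)

    def test_matches_reference_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = [
                rng.integers(0, 8, size=rng.integers(4, 12)).astype(float)
                for _ in range(rng.integers(2, 6))
            ]
            H, p = kruskal_wallis(groups)
            H_ref, p_ref = _kw_reference(groups)
            assert H == pytest.approx(H_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_identical_values(self):
        assert kruskal_wallis([np.ones(5), np.ones(4)]) == (0.0, 1.0)

    def test_permutation_symmetry_of_the_null(self):
        """Relabeling pooled observations leaves the null distribution of H
        unchanged: the empirical H distribution over random relabelings is the
        same regardless of which labeling generated the pool."""
        rng = np.random.default_rng(1)
        pooled = rng.normal(size=30)
        ref = []
        for _ in range(500):
            x = rng.permutation(pooled)
            ref.append(kruskal_wallis([x[:10], x[10:20], x[20:]])[0])
        # H for the original labeling is an unexceptional draw from that null
        H0, _ = kruskal_wallis([pooled[:10], pooled[10:20], pooled[20:]])
        frac_above = np.mean(np.array(ref) >= H0)
        assert 0.005 < frac_above < 0.995


class TestPairwiseMannWhitney:
    def test_bonferroni_threshold_for_twelve_groups(self):
        rng = np.random.default_rng(2)
        groups = {f"p{i}": rng.normal(size=10) for i in range(12)}
        mat = pairwise_mann_whitney(groups, alpha=0.01)
        assert mat.threshold == pytest.approx(0.01 / 66)

    def test_identical_groups_yield_no_significance(self):
        g = np.arange(10.0)
        mat = pairwise_mann_whitney({"a": g, "b": g.copy(), "c": g.copy()})
        assert mat.n_significant == 0

    def test_strongly_shifted_group_is_always_flagged(self):
        rng = np.random.default_rng(3)
        groups = {f"p{i}": rng.normal(size=25) for i in range(4)}
        groups["shifted"] = rng.normal(size=25) + 10.0
        mat = pairwise_mann_whitney(groups, alpha=0.01)
        for other in ("p0", "p1", "p2", "p3"):
            assert bool(mat.significant.loc["shifted", other])

    def test_matches_reference_p_values(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = rng.integers(0, 6, size=rng.integers(5, 15)).astype(float)
            y = rng.integers(0, 6, size=rng.integers(5, 15)).astype(float)
            mat = pairwise_mann_whitney({"x": x, "y": y})
            assert mat.pvalues.loc["x", "y"] == pytest.approx(
                _mw_reference(x, y), abs=1e-10
            )

    def test_tiny_group_raises(self):
        with pytest.raises(DataError):
            pairwise_mann_whitney({"a": np.arange(5.0), "b": np.array([1.0])})


class TestSummarize:
    def _results(self, d_values):
        return pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(len(d_values))],
                "procedure": ["p"] * len(d_values),
                "variable_set": ["apriori3"] * len(d_values),
                "D": 0.8, "S": 50.0, "RSV": list(np.linspace(-6, 6, len(d_values))),
                "d": d_values,
            }
        )

    @pytest.mark.parametrize(
        "mean_d,expected",
        [(55.0, "low"), (65.0, "intermediate"), (60.0, "intermediate"), (75.0, "high")],
    )
    def test_distance_classes_with_closed_lower_bound(self, mean_d, expected):
        out = summarize(self._results([mean_d] * 4))
        assert out["means"]["distance_class"].iloc[0] == expected

    def test_rsv_bins_partition_all_rows(self):
        out = summarize(self._results([50.0] * 9))
        assert sum(out["rsv_bins"].values()) == 9

    def test_scatter_has_one_point_per_row(self):
        out = summarize(self._results([50.0] * 7))
        assert len(out["scatter"]) == 7


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def tiny_run(self, small_scenario):
        grid = ExperimentGrid(
            species=small_scenario.species_ids,
            procedures=["bioclim", "glm"],
            variable_sets=["apriori3", "pca3"],
            master_seed=11,
        )
        cfg = ExperimentConfig(
            evaluate=True, run_mop=True, binarize_mode="expected_count"
        )
        return run_experiment(small_scenario, grid, cfg), grid

    def test_row_accounting(self, tiny_run):
        result, grid = tiny_run
        assert len(result.results) + len(result.failures) == grid.expected_rows
        assert result.failures.empty

    def test_metrics_are_within_domain(self, tiny_run):
        result, _ = tiny_run
        df = result.results
        assert df["D"].between(0, 1).all()
        assert df["S"].between(0, 100).all()
        assert (df["d"] >= 0).all()
        assert df["AUC_TEST"].between(0, 1).all()
        assert np.allclose(df["AUC_DIFF"], df["AUC_TRAIN"] - df["AUC_TEST"])

    def test_mop_summary_covers_species_by_variable_set(self, tiny_run):
        result, grid = tiny_run
        assert len(result.mop_summary) == len(grid.species) * len(grid.variable_sets)

    def test_rerun_is_bit_identical(self, small_scenario, tiny_run):
        result, grid = tiny_run
        again = run_experiment(
            small_scenario, grid,
            ExperimentConfig(evaluate=True, run_mop=True, binarize_mode="expected_count"),
        )
        pd.testing.assert_frame_equal(result.results, again.results)


def test_run_is_resumable_from_a_results_table(small_scenario):
    grid = ExperimentGrid(
        species=small_scenario.species_ids, procedures=["bioclim"],
        variable_sets=["apriori3"], master_seed=11,
    )
    cfg = ExperimentConfig(evaluate=False, run_mop=False, binarize_mode="expected_count")
    full = run_experiment(small_scenario, grid, cfg)
    resumed = run_experiment(small_scenario, grid, cfg, completed=full.results)
    pd.testing.assert_frame_equal(
        resumed.results.reset_index(drop=True), full.results.reset_index(drop=True)
    )
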