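import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radscreen import (
    CountMatrix,
    SampleTable,
    SimConfig,
    condition_means,
    fold_change_table,
    linear_r2,
    overlap_sets,
    presence_cutoff,
    presence_cutoffs,
    select_linear_genes,
    simulate_dataset,
)
from radscreen.dose_response import STATUS_ABSENT, STATUS_DEFINED, STATUS_ZERO_CONTROL

from conftest import make_fc_table


def ols_oracle(x, y):
    """Normal-equations OLS, independent of the screen's implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sstot = np.sum((y - y.mean()) ** 2)
    return beta[1], beta[0], 1 - np.sum(resid**2) / sstot


def mean_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "timepoint_days",
            "dose_roentgen",
            "mean_expression",
            "n_replicates",
        ],
    )


class TestConditionMeans:
    @pytest.mark.parametrize(
        "replicates,expected", [((10, 20, 30), 20.0), ((10, 20), 15.0), ((7,), 7.0)]
    )
    def test_arithmetic_mean_over_present_replicates(self, replicates, expected):
        samples = SampleTable(
            pd.DataFrame(
                {
                    "sample_id": [f"r{i}" for i in range(len(replicates))] + ["c"],
                    "timepoint_days": 2,
                    "dose_roentgen": [10.0] * len(replicates) + [0.0],
                    "replicate": list(range(1, len(replicates) + 1)) + [1],
                }
            )
        )
        counts = CountMatrix(
            pd.DataFrame(
                [list(replicates) + [5.0]],
                index=["g"],
                columns=samples.sample_ids,
            ),
            normalized=True,
        )
        means = condition_means(counts, samples)
        row = means[(means.dose_roentgen == 10.0)]
        assert row["mean_expression"].item() == expected
        assert row["n_replicates"].item() == len(replicates)

    def test_dropped_control_replicate_uses_remaining_two(self, zero_noise_dataset):
        _, counts, samples, _ = zero_noise_dataset
        means = condition_means(counts, samples)
        row = means[(means.timepoint_days == 20) & (means.dose_roentgen == 0)]
        assert (row["n_replicates"] == 2).all()


class TestPresenceCutoff:
    def test_linear_interpolation_quartile(self):
        means = mean_table(
            [("g%d" % i, 2, d, v, 3) for i, (d, v) in enumerate([(10, 10), (1000, 20), (5000, 30), (0, 40)])]
        )
        assert presence_cutoff(means, 2) == pytest.approx(17.5)

    def test_constant_distribution(self):
        means = mean_table([("g", 2, d, 5, 3) for d in (0, 10, 1000, 5000)])
        assert presence_cutoff(means, 2) == 5

    def test_quantile_zero_is_minimum(self):
        means = mean_table([("g", 2, d, v, 3) for d, v in [(0, 3), (10, 9), (1000, 1)]])
        assert presence_cutoff(means, 2, quantile=0) == 1

    def test_missing_timepoint_rejected(self):
        means = mean_table([("g", 2, 0, 3, 3)])
        with pytest.raises(ValueError):
            presence_cutoff(means, 10)


class TestFoldChangeTable:
    def _table(self, exp, control, cutoff=18.0):
        means = mean_table(
            [("g", 2, 0.0, control, 3), ("g", 2, 1000.0, exp, 3)]
        )
        return fold_change_table(means, {2: cutoff}).iloc[0]

    def test_defined_ratio(self):
        row = self._table(40, 20)
        assert row["status"] == STATUS_DEFINED
        assert row["fold_change"] == pytest.approx(2.0)

    def test_both_below_cutoff_is_absent(self):
        row = self._table(10, 12)
        assert row["status"] == STATUS_ABSENT
        assert np.isnan(row["fold_change"])

    def test_zero_control_with_present_experimental_is_undefined(self):
        row = self._table(30, 0)
        assert row["status"] == STATUS_ZERO_CONTROL
        assert np.isnan(row["fold_change"])

    def test_zero_control_both_below_cutoff_is_absent(self):
        row = self._table(5, 0)
        assert row["status"] == STATUS_ABSENT


class TestLinearR2:
    def test_exact_line_recovers_slope_and_intercept(self):
        doses = np.array([10, 1000, 5000, 10000, 20000.0])
        fit = linear_r2(doses, 1 + 1e-4 * doses)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1e-4)
        assert fit.intercept == pytest.approx(1.0)

    def test_worked_example_matches_normal_equations_oracle(self):
        x = [1000, 5000, 10000, 20000]
        y = [1.0, 1.1, 1.4, 2.2]
        fit = linear_r2(np.array(x), np.array(y))
        slope, intercept, r2 = ols_oracle(x, y)
        assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        # frozen oracle value, computed independently before the build
        assert fit.r_squared == pytest.approx(0.971915, abs=1e-6)

    def test_constant_fold_changes_have_undefined_r2(self):
        fit = linear_r2(np.array([10, 1000, 5000, 10000.0]), np.array([2.0, 2, 2, 2]))
        assert np.isnan(fit.r_squared)

    def test_fewer_than_two_points_undefined(self):
        fit = linear_r2(np.array([10.0]), np.array([1.5]))
        assert np.isnan(fit.r_squared)

    def test_agrees_with_oracle_on_random_inputs(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = rng.integers(4, 6)
            x = rng.uniform(1, 20000, n)
            y = rng.uniform(0.1, 5, n)
            if np.ptp(y) == 0:
                continue
            fit = linear_r2(x, y)
            slope, intercept, r2 = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
        seed=st.integers(0, 1000),
    )
    def test_r2_invariant_under_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 20000, 5)
        y = rng.uniform(0.5, 4, 5)
        r2 = linear_r2(x, y).r_squared
        r2_affine = linear_r2(x, a * y + b).r_squared
        assert 0 <= r2 <= 1
        assert r2_affine == pytest.approx(r2, abs=1e-9)


class TestSelectLinearGenes:
    def test_perfect_line_at_three_doses_fails_min_doses_gate(self):
        fc = make_fc_table(
            {"g": {1000: 1.1, 5000: 1.5, 10000: 2.0, 20000: None, 10: None}}
        )
        result = select_linear_genes(fc, min_doses=4)
        assert result.selected[2] == set()
        assert result.records["r_squared"].notna().all()

    def test_r2_exactly_at_threshold_not_selected(self):
        fc = make_fc_table({"g": {10: 1.0, 1000: 1.2, 5000: 1.1, 20000: 2.0}})
        r2 = select_linear_genes(fc).records["r_squared"].item()
        result = select_linear_genes(fc, r2_min=r2)  # strict inequality
        assert result.selected[2] == set()

    def test_monotone_in_r2_threshold(self):
        rng = np.random.default_rng(5)
        fc = make_fc_table(
            {
                f"g{i}": {
                    d: 1 + 1e-4 * d + rng.normal(0, 0.2)
                    for d in (10, 1000, 5000, 10000, 20000)
                }
                for i in range(50)
            }
        )
        previous = None
        for r2_min in (0.5, 0.7, 0.9, 0.99):
            selected = select_linear_genes(fc, r2_min=r2_min).selected[2]
            if previous is not None:
                assert selected <= previous
            previous = selected

    def test_zero_noise_planted_truth_recovered_exactly(self):
        config = SimConfig(
            n_genes=1000,
            seed=2,
            zero_noise=True,
            frac_linear=0.05,
            frac_spike=0.0,
            slope_range=(1e-4, 1e-4),
        )
        counts, samples, truth = simulate_dataset(config)
        from radscreen import normalize_counts

        means = condition_means(normalize_counts(counts), samples)
        fc = fold_change_table(means, presence_cutoffs(means))
        result = select_linear_genes(fc)
        planted = set(truth.loc[truth["class"] == "linear", "gene_id"])
        assert len(planted) == 50
        for tp in (2, 10, 20):
            assert result.selected[tp] == planted
        assert result.full_overlap() == planted

    def test_excluding_all_doses_is_design_error(self):
        from radscreen import DesignError

        fc = make_fc_table({"g": {10: 1.0, 1000: 1.2}})
        with pytest.raises(DesignError):
            select_linear_genes(fc, exclude_doses=(10, 1000))

    def test_lowest_dose_excluded_uses_only_high_doses(self):
        fc = make_fc_table(
            {"g": {10: 5.0, 1000: 1.1, 5000: 1.5, 10000: 2.0, 20000: 3.0}}
        )
        result = select_linear_genes(fc, exclude_doses=(10,), min_doses=4)
        assert result.records["n_doses_used"].item() == 4
        assert result.label == "lowest-dose-excluded"


class TestOverlapSets:
    def test_triple_intersection(self):
        overlaps, exclusive = overlap_sets({2: {"A", "B"}, 10: {"B", "C"}, 20: {"B"}})
        assert overlaps[frozenset({2, 10, 20})] == {"B"}
        assert exclusive[frozenset({2})] == {"A"}
        assert exclusive[frozenset({2, 10})] == set()

    def test_disjoint_sets_have_empty_intersections(self):
        overlaps, _ = overlap_sets({2: {"A"}, 10: {"B"}, 20: {"C"}})
        assert all(not v for k, v in overlaps.items() if len(k) > 1)

    def test_identical_sets_everywhere(self):
        s = {"X", "Y"}
        overlaps, exclusive = overlap_sets({2: set(s), 10: set(s), 20: set(s)})
        assert all(v == s for v in overlaps.values())
        assert exclusive[frozenset({2, 10, 20})] == s

    def test_nesting_triple_within_pairwise(self, zero_noise_dataset):
        _, counts, samples, _ = zero_noise_dataset
        from radscreen import normalize_counts

        means = condition_means(normalize_counts(counts), samples)
        fc = fold_change_table(means, presence_cutoffs(means))
        result = select_linear_genes(fc)
        triple = result.overlaps[frozenset({2, 10, 20})]
        for pair in (frozenset({2, 10}), frozenset({2, 20}), frozenset({10, 20})):
            assert triple <= result.overlaps[pair]
            for tp in pair:
                assert result.overlaps[pair] <= result.selected[tp]
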