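"""Four-stage descriptor selection: stage semantics and recovery."""

import numpy as np
import pandas as pd
import pytest

from quinoscreen.selection import (
    SelectionConfig,
    backward_stepwise,
    low_variance_filter,
    mutual_correlation_filter,
    normalize,
    select_descriptors,
    target_correlation_filter,
)
from quinoscreen.synthetic import planted_selection_dataset


class TestNormalize:
    def test_three_point_example(self):
        # population sd of [1,2,3] is sqrt(2/3); z-scores are +/- 1.2247
        out = normalize([1.0, 2.0, 3.0])
        assert out == pytest.approx([-1.22474487, 0.0, 1.22474487], abs=1e-8)

    def test_output_moments(self):
        rng = np.random.default_rng(0)
        out = normalize(rng.normal(3.0, 7.0, size=500))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize([2.0, 2.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        z = normalize(rng.normal(size=100))
        assert normalize(z) == pytest.approx(z, abs=1e-12)


class TestLowVariance:
    def test_constant_column_removed(self):
        table = pd.DataFrame({"const": np.ones(10), "varied": np.arange(10.0)})
        report = low_variance_filter(table)
        assert [r.column for r in report.removed] == ["const"]

    def test_mode_at_threshold_removed(self):
        # 6/10 identical values: "60% or more" -> removed
        col = np.array([5.0] * 6 + [1, 2, 3, 4])
        report = low_variance_filter(pd.DataFrame({"x": col}))
        assert report.survivors == []

    def test_mode_below_threshold_kept(self):
        col = np.array([5.0] * 5 + [1, 2, 3, 4, 6])
        report = low_variance_filter(pd.DataFrame({"x": col}))
        assert report.survivors == ["x"]


class TestTargetCorrelation:
    def test_perfect_predictor_kept(self):
        y = np.arange(8.0)
        table = pd.DataFrame({"same": y.copy()})
        assert target_correlation_filter(table, y).survivors == ["same"]

    def test_orthogonal_column_removed(self):
        # x orthogonal to y by construction on n=4
        y = np.array([1.0, 1.0, -1.0, -1.0])
        x = np.array([1.0, -1.0, 1.0, -1.0])
        report = target_correlation_filter(pd.DataFrame({"x": x}), y)
        assert report.survivors == []
        assert report.removed[0].statistic == pytest.approx(0.0, abs=1e-12)

    def test_negative_predictor_kept_in_absolute_mode(self):
        y = np.arange(8.0)
        table = pd.DataFrame({"neg": -y})
        assert target_correlation_filter(table, y, use_absolute=True).survivors == ["neg"]

    def test_negative_predictor_dropped_in_signed_mode(self):
        y = np.arange(8.0)
        table = pd.DataFrame({"neg": -y})
        assert target_correlation_filter(table, y, use_absolute=False).survivors == []

    def test_boundary_value_kept(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        x = rng.normal(size=50)
        r = float(np.mean(normalize(x) * normalize(y)))
        report = target_correlation_filter(pd.DataFrame({"x": x}), y, threshold=abs(r))
        assert report.survivors == ["x"]

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError):
            target_correlation_filter(pd.DataFrame({"x": [1.0, 2.0]}), None)


class TestMutualCorrelation:
    def test_identical_columns_one_survivor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + 0.1 * rng.normal(size=40)
        table = pd.DataFrame({"a": x, "b": x.copy()})
        report = mutual_correlation_filter(table, y)
        assert report.survivors == ["a"]  # tie broken by column order

    def test_three_duplicates_one_survivor(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": x.copy()})
        assert mutual_correlation_filter(table, y).survivors == ["a"]

    def test_boundary_pair_both_kept(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        y = a + b
        r = float(np.mean(normalize(a) * normalize(b)))
        table = pd.DataFrame({"a": a, "b": b})
        # removal requires r STRICTLY above the threshold
        report = mutual_correlation_filter(table, y, threshold=abs(r))
        assert report.survivors == ["a", "b"]

    def test_keeps_best_target_correlated_representative(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        good = y + 0.1 * rng.normal(size=100)
        worse = good + 0.2 * rng.normal(size=100)
        table = pd.DataFrame({"worse": worse, "good": good})
        assert mutual_correlation_filter(table, y).survivors == ["good"]

    def test_survivors_pairwise_below_threshold(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(120, 4))
        table = pd.DataFrame(
            {
                **{f"b{i}": base[:, i] for i in range(4)},
                **{f"copy{i}": base[:, i] + 0.05 * rng.normal(size=120) for i in range(4)},
            }
        )
        y = base.sum(axis=1)
        report = mutual_correlation_filter(table, y, threshold=0.7)
        surv = report.survivors
        for i, a in enumerate(surv):
            for b in surv[i + 1 :]:
                r = abs(np.corrcoef(table[a], table[b])[0, 1])
                assert r <= 0.7 + 1e-12


class TestBackwardStepwise:
    def test_noise_column_removed_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(120, 3))
            y = x[:, 0] + 0.5 * x[:, 1] + 0.1 * rng.normal(size=120)
            table = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "noise": x[:, 2]})
            report = backward_stepwise(table, y, fold_seed=seed)
            if report.removed and report.removed[0].column == "noise":
                hits += 1
        assert hits >= 9

    def test_infinite_tolerance_reduces_to_floor(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        y = rng.normal(size=50)
        report = backward_stepwise(table, y, tolerance=np.inf, min_survivors=1)
        assert len(report.survivors) == 1

    def test_single_column_is_noop(self):
        table = pd.DataFrame({"only": np.arange(20.0)})
        report = backward_stepwise(table, np.arange(20.0))
        assert report.survivors == ["only"] and not report.removed

    def test_deterministic_given_fold_seed(self):
        table, y, _ = planted_selection_dataset(seed=8)
        a = backward_stepwise(table, y, fold_seed=3)
        b = backward_stepwise(table, y, fold_seed=3)
        assert a.survivors == b.survivors


class TestFullPipeline:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_recovery(self, seed):
        table, y, mask = planted_selection_dataset(seed=seed)
        report = select_descriptors(table, y, SelectionConfig(fold_seed=seed))
        survivors = set(report.survivors)
        assert set(mask["informative"]) <= survivors
        assert not survivors & set(mask["noise"])
        assert not survivors & set(mask["duplicate"])

    def test_stage_accounting_is_exhaustive(self):
        table, y, _ = planted_selection_dataset(seed=0)
        report = select_descriptors(table, y)
        assert set(report.removed_columns) | set(report.survivors) == set(table.columns)
        assert [s.stage for s in report.stages] == [
            "low_variance",
            "target_correlation",
            "mutual_correlation",
            "backward_stepwise",
        ]

    def test_trivial_dataset_survivors_equal_informative(self):
        table, y, mask = planted_selection_dataset(
            seed=1, n_noise=0, n_duplicates=0
        )
        report = select_descriptors(table, y)
        assert set(report.survivors) == set(mask["informative"])

    def test_redundant_blocks_strictly_reduced(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(200, 13))
        cols = {}
        for i in range(13):
            for j in range(4):
                cols[f"f{i}_{j}"] = base[:, i] + 0.05 * rng.normal(size=200)
        table = pd.DataFrame(cols)  # 52 strongly redundant columns
        y = base[:, :5].sum(axis=1) + 0.2 * rng.normal(size=200)
        report = select_descriptors(table, y)
        assert 0 < len(report.survivors) < 52

    def test_selection_improves_or_holds_cv_r2(self):
        """Survivor set should not fit worse than the full noisy table."""
        from quinoscreen.evaluation import cross_validate
        from quinoscreen.models import fit_ridge

        wins = 0
        for seed in range(10):
            table, y, _ = planted_selection_dataset(seed=seed)
            report = select_descriptors(table, y, SelectionConfig(fold_seed=seed))
            fit = lambda X, t: fit_ridge(X, t, lam=0.0)
            full = cross_validate(fit, table, y, fold_seed=seed).mean_val_r2
            sel = cross_validate(
                fit, table[report.survivors], y, fold_seed=seed
            ).mean_val_r2
            wins += sel >= full - 1e-9
        assert wins >= 8
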