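import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitmass.evaluation import (
    EvalReport,
    SplitSpec,
    correlation_matrix,
    descriptive_stats,
    evaluate_model,
    kfold_indices,
    r_squared,
    rmse,
    select_best,
    split_dataset,
    train_size,
    transfer_validate,
)
from fruitmass.models import FittedForm, fit_form
from fruitmass.synthetic import CohortSpec, generate_tabular_cohort

from conftest import make_records


class TestRmse:
    def test_identical_series_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_unit_error(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_hand_arithmetic_sqrt5(self):
        assert rmse([2.0, 4.0], [3.0, 1.0]) == pytest.approx(np.sqrt(5.0), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestRSquared:
    def test_perfect_prediction(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_zero(self):
        m = [1.0, 2.0, 3.0]
        assert r_squared(m, [2.0, 2.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert r_squared([1.0, 2.0, 3.0], [1.1, 1.9, 3.2]) == pytest.approx(0.97, abs=1e-12)

    def test_can_be_negative(self):
        assert r_squared([1.0, 2.0, 3.0], [10.0, 10.0, 10.0]) < 0

    def test_constant_measured_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2.0, 2.0], [1.0, 3.0])


class TestSplitDataset:
    # printed partition sizes reproduced by half-up rounding of 0.7*n
    @pytest.mark.parametrize(
        "n,expected_train",
        [(1028, 720), (518, 363), (508, 356), (530, 371), (486, 340), (10, 7)],
    )
    def test_train_sizes(self, n, expected_train):
        records = make_records(np.ones(n), np.ones(n), np.ones(n))
        train, test = split_dataset(records, SplitSpec(0.7, seed=1))
        assert len(train) == expected_train
        assert len(test) == n - expected_train

    def test_exact_partition(self):
        records = make_records(np.arange(100.0), np.arange(100.0), np.arange(100.0))
        train, test = split_dataset(records, SplitSpec(0.7, seed=3))
        combined = sorted(train.index.tolist() + test.index.tolist())
        assert combined == list(range(100))

    def test_deterministic_per_seed(self):
        records = make_records(np.arange(50.0), np.arange(50.0), np.arange(50.0))
        a1, _ = split_dataset(records, SplitSpec(0.7, seed=9))
        a2, _ = split_dataset(records, SplitSpec(0.7, seed=9))
        b, _ = split_dataset(records, SplitSpec(0.7, seed=10))
        assert a1.equals(a2)
        assert not a1.equals(b)

    def test_degenerate_split_rejected(self):
        records = make_records([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            split_dataset(records, SplitSpec(0.9, seed=0))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)

    def test_train_size_half_up(self):
        assert train_size(10, 0.75) == 8  # 7.5 rounds up


class TestKfoldIndices:
    def test_equal_folds(self):
        folds = kfold_indices(20, k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 2 for f in folds)

    def test_uneven_folds(self):
        folds = kfold_indices(23, k=10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {2, 3}
        assert sum(sizes) == 23

    @given(st.integers(10, 60), st.integers(2, 10))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, n, k):
        folds = kfold_indices(n, k=k, seed=1)
        cat = np.concatenate(folds)
        assert len(cat) == n
        assert set(cat.tolist()) == set(range(n))

    def test_n_less_than_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(5, k=10)


def _ld_cohort(n, noise_sd, seed, name="eval"):
    spec = CohortSpec(
        name=name, n=n,
        L_mean=25.74, L_sd=1.64, L_min=21.13, L_max=32.22,
        D_mean=24.50, D_sd=1.84, D_min=19.17, D_max=30.55,
        rho_LD=0.8, gen_form="LD", gen_a=-4.494, gen_b=0.0225, noise_sd=noise_sd,
    )
    return generate_tabular_cohort(spec, seed=seed)


class TestEvaluateModel:
    def test_noise_free_is_perfect(self):
        records = _ld_cohort(100, 0.0, seed=2)
        report = evaluate_model(lambda r: fit_form(r, "LD"), records, SplitSpec(0.7, 1))
        assert report.r2_train == pytest.approx(1.0, abs=1e-12)
        assert report.r2_test == pytest.approx(1.0, abs=1e-12)
        assert report.rmse_train == pytest.approx(0.0, abs=1e-9)
        assert report.rmse_test == pytest.approx(0.0, abs=1e-9)
        assert report.n_train + report.n_test == 100

    def test_test_rmse_tracks_noise_level(self):
        # 50-seed consistency simulation: average test RMSE within 15% of sigma
        sigma = 0.5
        vals, slopes, intercepts = [], [], []
        for seed in range(50):
            records = _ld_cohort(300, sigma, seed=seed)
            rep = evaluate_model(lambda r: fit_form(r, "LD"), records, SplitSpec(0.7, seed))
            vals.append(rep.rmse_test)
            slopes.append(rep.identity_slope)
            intercepts.append(rep.identity_intercept)
        assert np.mean(vals) == pytest.approx(sigma, rel=0.15)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)
        assert abs(np.mean(intercepts)) < 0.2

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            evaluate_model(lambda r: fit_form(r, "LD"), _ld_cohort(100, 0.0, 1).head(5), SplitSpec())


class TestSelectBest:
    def _report(self, rmse_train, r2_train, label="m"):
        return EvalReport(
            label=label, rmse_train=rmse_train, rmse_test=0.0, r2_train=r2_train,
            r2_test=0.0, n_train=1, n_test=1, identity_slope=1.0, identity_intercept=0.0,
        )

    def test_lowest_rmse_wins(self):
        reports = [self._report(r, 0.9, f"m{i}") for i, r in enumerate([0.49, 0.50, 0.55])]
        assert select_best(reports).label == "m0"

    def test_tie_broken_by_r2(self):
        reports = [self._report(0.5, 0.93, "a"), self._report(0.5, 0.94, "b")]
        assert select_best(reports).label == "b"

    def test_single_report(self):
        rep = self._report(1.0, 0.5)
        assert select_best([rep]) is rep

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestDescriptiveStats:
    def test_hand_arithmetic(self):
        stats = descriptive_stats(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        row = stats.loc["x"]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(1.0, abs=1e-12)
        assert row["se"] == pytest.approx(0.577, abs=5e-4)
        assert row["min"] == 1.0 and row["max"] == 3.0

    def test_constant_series_zero_sd(self):
        stats = descriptive_stats(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))
        assert stats.loc["x", "sd"] == 0.0

    def test_cohort_mean_within_two_se_of_recipe(self, cohort_2019):
        stats = descriptive_stats(cohort_2019)
        se = 1.64 / np.sqrt(1028)
        assert abs(stats.loc["length_mm", "mean"] - 25.74) < 2 * se

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            descriptive_stats(pd.DataFrame({"x": [1.0]}))


class TestCorrelationMatrix:
    def test_perfect_linear_pair(self):
        df = make_records([1, 2, 3, 4], [2, 4, 6, 8], [1, 2, 3, 4])
        rep = correlation_matrix(df)
        assert rep.r.loc["length_mm", "diameter_mm"] == pytest.approx(1.0, abs=1e-12)

    def test_diagonal_and_symmetry(self, small_cohort):
        rep = correlation_matrix(small_cohort)
        np.testing.assert_allclose(np.diag(rep.r.values), 1.0)
        np.testing.assert_allclose(rep.r.values, rep.r.values.T)
        assert rep.significant.loc["length_mm", "weight_g"]

    def test_independent_pairs_stay_small(self):
        # null simulation: |r| < 0.12 in at least 99 of 100 seeds at n=500
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
            r = correlation_matrix(df, alpha=0.01).r.iloc[0, 1]
            hits += abs(r) < 0.12
        assert hits >= 99

    def test_constant_variable_rejected(self):
        df = make_records([1, 1, 1], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            correlation_matrix(df)


class TestTransferValidate:
    def test_same_law_transfer_keeps_r2(self):
        src = _ld_cohort(400, 0.3, seed=1, name="src")
        dst = _ld_cohort(400, 0.3, seed=2, name="dst")
        model = fit_form(src, "LD")
        L, D, FW = dst["length_mm"], dst["diameter_mm"], dst["weight_g"]
        report = transfer_validate(model, {"dst": dst})
        src_rep = evaluate_model(lambda r: fit_form(r, "LD"), src, SplitSpec(0.7, 1))
        assert report.loc[0, "r2"] == pytest.approx(src_rep.r2_test, abs=0.05)

    def test_intercept_shift_raises_rmse_by_shift(self):
        cohort = _ld_cohort(500, 0.0, seed=3)
        model = fit_form(cohort, "LD")
        shifted = cohort.assign(weight_g=cohort["weight_g"] + 1.0)
        report = transfer_validate(model, {"shifted": shifted})
        assert report.loc[0, "rmse"] == pytest.approx(1.0, abs=1e-6)

    def test_row_per_cohort(self):
        cohort = _ld_cohort(100, 0.2, seed=4)
        model = fit_form(cohort, "LD")
        cohorts = {f"c{i}": _ld_cohort(50, 0.2, seed=i, name=f"c{i}") for i in range(4)}
        report = transfer_validate(model, cohorts)
        assert len(report) == 4
        assert list(report["cohort"]) == list(cohorts)

    def test_unfitted_model_rejected(self):
        from fruitmass.errors import FitError

        with pytest.raises(FitError):
            transfer_validate(object(), {"c": _ld_cohort(10, 0.0, 0)})


class TestNestedFamilies:
    def test_identity_line_pvalues_reported(self):
        records = _ld_cohort(200, 0.3, seed=8)
        rep = evaluate_model(lambda r: fit_form(r, "LD"), records, SplitSpec(0.7, 2))
        # well-specified model: no significant 1:1 deviation at alpha=0.05
        assert rep.identity_slope_p > 0.05
        assert rep.identity_intercept_p > 0.05
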