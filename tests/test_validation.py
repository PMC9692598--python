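"""Fold construction, RMSE definitions and model evaluation reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iambcf import (
    CompoundRecord,
    CompoundTable,
    FoldAssignment,
    LinearModel,
    evaluate_models,
    make_folds,
    pooled_cv_rmse,
    rmse,
    rmsecv,
)
from iambcf.validation import refit_fitter


class TestFolds:
    def test_120_by_5_gives_folds_of_24(self):
        folds = make_folds(120, 5, seed=1)
        sizes = [len(folds.indices(j)) for j in range(5)]
        assert sizes == [24] * 5

    def test_leave_one_out(self):
        folds = make_folds(10, 10, seed=1)
        assert sorted(folds.fold_of) == list(range(10))

    def test_determinism(self):
        assert make_folds(37, 4, seed=9) == make_folds(37, 4, seed=9)
        assert make_folds(37, 4, seed=9) != make_folds(37, 4, seed=10)

    @settings(deadline=None, max_examples=50)
    @given(n=st.integers(5, 200), k=st.integers(2, 8), seed=st.integers(0, 10**6))
    def test_fold_sizes_differ_by_at_most_one(self, n, k, seed):
        if k > n:
            return
        folds = make_folds(n, k, seed)
        sizes = [len(folds.indices(j)) for j in range(k)]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            make_folds(5, 6, seed=1)
        with pytest.raises(ValueError):
            make_folds(5, 1, seed=1)


class TestRmse:
    def test_identical_inputs_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_residuals(self):
        assert rmse([1.0, -1.0], [0.0, 0.0]) == 1.0

    def test_hand_arithmetic(self):
        assert rmse([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    @settings(deadline=None, max_examples=50)
    @given(c=st.floats(-10, 10, allow_nan=False))
    def test_symmetry_and_scale_equivariance(self, c):
        a = np.array([0.3, -1.2, 2.5])
        b = np.array([0.1, 0.4, -0.7])
        assert rmse(a, b) == pytest.approx(rmse(b, a))
        assert rmse(c * a, c * b) == pytest.approx(abs(c) * rmse(a, b), rel=1e-9)


class TestRmsecv:
    def test_equal_folds_aggregate_equals_pooled(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        y = X @ [1.0, -0.5] + 0.3 * rng.standard_normal(n)
        folds = make_folds(n, 4, seed=2)
        fitter = refit_fitter(["a", "b"])
        agg = rmsecv(fitter, y, X, folds)
        pooled = pooled_cv_rmse(fitter, y, X, folds)
        assert agg == pytest.approx(pooled, abs=1e-12)

    def test_unequal_folds_hand_example(self):
        """n=10, k=3 (fold sizes 4,3,3) with a constant-zero predictor:
        the quadratic-mean aggregate weights folds, not observations."""
        y = np.arange(1.0, 11.0)
        X = np.zeros((10, 1))
        folds = make_folds(10, 3, seed=5)

        def zero_fitter(y_tr, X_tr, X_te):
            return np.zeros(len(X_te))

        # hand computation from the fold assignment itself
        per_fold_ms = [
            np.mean(y[folds.indices(j)] ** 2) for j in range(3)
        ]
        expected_agg = np.sqrt(np.mean(per_fold_ms))
        expected_pooled = np.sqrt(np.mean(y**2))
        agg = rmsecv(zero_fitter, y, X, folds)
        pooled = pooled_cv_rmse(zero_fitter, y, X, folds)
        assert agg == pytest.approx(expected_agg, abs=1e-12)
        assert pooled == pytest.approx(expected_pooled, abs=1e-12)
        assert agg != pooled  # unequal folds: the two aggregations differ

    def test_perfect_linear_data(self, rng):
        n = 30
        X = rng.standard_normal((n, 1))
        y = 2.0 * X[:, 0] + 1.0
        folds = make_folds(n, 5, seed=3)
        assert rmsecv(refit_fitter(["x"]), y, X, folds) < 1e-10

    def test_fold_relabeling_invariance(self, rng):
        n = 24
        X = rng.standard_normal((n, 1))
        y = X[:, 0] + 0.2 * rng.standard_normal(n)
        folds = make_folds(n, 4, seed=7)
        relabel = {0: 2, 1: 0, 2: 3, 3: 1}
        permuted = FoldAssignment(
            n=n, k=4, fold_of=tuple(relabel[f] for f in folds.fold_of), seed=folds.seed
        )
        fitter = refit_fitter(["x"])
        assert rmsecv(fitter, y, X, folds) == pytest.approx(
            rmsecv(fitter, y, X, permuted), abs=1e-12
        )

    def test_fitter_errors_annotated_with_fold(self, rng):
        def broken(y_tr, X_tr, X_te):
            raise ValueError("boom")

        folds = make_folds(10, 2, seed=1)
        with pytest.raises(RuntimeError, match="fold 0"):
            rmsecv(broken, np.zeros(10), np.zeros((10, 1)), folds)


class TestEvaluateModels:
    @staticmethod
    def _table(n, seed, with_vivo=True):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            lkw = rng.normal()
            y = 0.5 + 0.8 * lkw + 0.1 * rng.normal()
            records.append(
                CompoundRecord(
                    id=f"m{i}",
                    log_kw_iam=lkw,
                    log_bcf_epi=y,
                    log_bcf_vivo=(y + 0.05 * rng.normal()) if with_vivo and i % 3 == 0 else None,
                )
            )
        return CompoundTable(records=records)

    def test_perfect_fixed_model(self):
        table = self._table(30, seed=1, with_vivo=False)
        y = table.column("log_bcf_epi")
        lkw = table.column("log_kw_iam")
        beta = np.polyfit(lkw, y, 1)
        exact = LinearModel(
            name="exact",
            intercept=float(beta[1]),
            coefficients={"log_kw_iam": float(beta[0])},
        )
        # replace response with the exact model output → all errors vanish
        for rec in table.records:
            rec.log_bcf_epi = exact.intercept + exact.coefficients["log_kw_iam"] * rec.log_kw_iam
        report = evaluate_models({"exact": exact}, table, external=table)
        assert report["exact"]["rmsep_ext"] == pytest.approx(0.0, abs=1e-12)
        assert report["exact"]["r2_train"] == pytest.approx(1.0, abs=1e-12)
        assert report["exact"]["rmsecv"] < 1e-10

    def test_metric_ordering_preserved(self):
        table = self._table(60, seed=2)
        good = LinearModel(name="good", intercept=0.5, coefficients={"log_kw_iam": 0.8})
        bad = LinearModel(name="bad", intercept=2.5, coefficients={"log_kw_iam": 0.8})
        report = evaluate_models({"good": good, "bad": bad}, table, external=table)
        for metric in ("rmsep_ext", "rmsep_vivo"):
            assert report["good"][metric] < report["bad"][metric]

    def test_missing_reference_column_reported_missing(self):
        table = self._table(30, seed=3, with_vivo=False)
        model = LinearModel(name="m", intercept=0.0, coefficients={"log_kw_iam": 1.0})
        report = evaluate_models({"m": model}, table, external=table)
        assert report["m"]["rmsep_vivo"] is None
        assert report["m"]["r2_vivo"] is None

    def test_report_carries_fold_seed(self):
        table = self._table(30, seed=4)
        model = LinearModel(name="m", intercept=0.0, coefficients={"log_kw_iam": 1.0})
        report = evaluate_models({"m": model}, table, seed=123)
        assert report["m"]["fold_seed"] == 123
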