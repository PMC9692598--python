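"""K-fold cross-validation and external-set evaluation.

The k-fold procedure splits the n training compounds into k near-equal
folds, refits on k−1 folds and scores the held-out fold with the RMSE

    RMSE_j = sqrt( Σ_i (y_i^pred − y_i^ref)² / N_j ),

then aggregates per-fold errors quadratically,

    RMSECV = sqrt( Σ_j RMSE_j² / k ).

With equal fold sizes this equals the pooled RMSE over all held-out
residuals; with unequal folds the two differ (the quadratic-mean
aggregate weights folds equally, not observations) and the aggregate
form is the one returned.

External evaluation reports RMSEP on an independent compound table
against the EPI-estimated reference, and RMSEP/R² against in-vivo
measurements where available.  R²_vivo is the squared Pearson
correlation between predictions and measurements, since the evaluated
models were never fitted to the vivo data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .compound_data import CompoundTable
from .model_zoo import LinearModel
from .qsar_fit import fit_ols

#: Default fold-assignment seed, recorded in every report.
DEFAULT_FOLD_SEED = 20221111


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic assignment of n indices to k near-equal folds."""

    n: int
    k: int
    fold_of: tuple[int, ...]
    seed: int

    def indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_of) == j)


def make_folds(n: int, k: int, seed: int = DEFAULT_FOLD_SEED) -> FoldAssignment:
    """Seeded uniform shuffle, then contiguous split into k folds whose
    sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n (k={k}, n={n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for j, chunk in enumerate(np.array_split(order, k)):
        fold_of[chunk] = j
    return FoldAssignment(n=n, k=k, fold_of=tuple(int(f) for f in fold_of), seed=seed)


def rmse(pred: Sequence[float], ref: Sequence[float]) -> float:
    """Root mean squared error between predictions and reference values."""
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError(f"length mismatch or empty input ({p.shape} vs {r.shape})")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def rmsecv(
    fitter: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    y: Sequence[float],
    X: np.ndarray,
    folds: FoldAssignment,
) -> float:
    """Quadratic-mean aggregate of per-fold held-out RMSEs.

    ``fitter(y_train, X_train, X_test)`` must return predictions for the
    test rows.  Fitter errors are re-raised annotated with the fold index.
    """
    y_arr = np.asarray(y, dtype=float)
    X_arr = np.asarray(X, dtype=float)
    if X_arr.ndim == 1:
        X_arr = X_arr[:, None]
    if y_arr.size != folds.n or X_arr.shape[0] != folds.n:
        raise ValueError("data length does not match the fold assignment")
    fold_rmse = np.empty(folds.k)
    for j in range(folds.k):
        test = folds.indices(j)
        train = np.setdiff1d(np.arange(folds.n), test)
        try:
            pred = fitter(y_arr[train], X_arr[train], X_arr[test])
        except Exception as exc:  # annotate with fold for diagnosis
            raise RuntimeError(f"fitter failed on fold {j}: {exc}") from exc
        fold_rmse[j] = rmse(pred, y_arr[test])
    return float(np.sqrt(np.mean(fold_rmse**2)))


def pooled_cv_rmse(
    fitter: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    y: Sequence[float],
    X: np.ndarray,
    folds: FoldAssignment,
) -> float:
    """Pooled RMSE over all held-out residuals (observation-weighted
    alternative to the quadratic-mean aggregate)."""
    y_arr = np.asarray(y, dtype=float)
    X_arr = np.asarray(X, dtype=float)
    if X_arr.ndim == 1:
        X_arr = X_arr[:, None]
    sq = np.empty(folds.n)
    for j in range(folds.k):
        test = folds.indices(j)
        train = np.setdiff1d(np.arange(folds.n), test)
        pred = fitter(y_arr[train], X_arr[train], X_arr[test])
        sq[test] = (np.asarray(pred) - y_arr[test]) ** 2
    return float(np.sqrt(np.mean(sq)))


def refit_fitter(variables: Sequence[str]) -> Callable:
    """Fitter that refits OLS on a fixed variable set each fold (how the
    published fixed-coefficient models are cross-validated)."""
    names = list(variables)

    def fit(y_tr: np.ndarray, X_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
        cols = {n: X_tr[:, j] for j, n in enumerate(names)}
        res = fit_ols(y_tr, cols)
        beta = np.array([res.model.coefficients[n] for n in names])
        return res.model.intercept + X_te @ beta

    return fit


def _squared_pearson(pred: np.ndarray, ref: np.ndarray) -> float:
    return float(sps.pearsonr(pred, ref).statistic ** 2)


def evaluate_models(
    models: Mapping[str, LinearModel],
    train: CompoundTable,
    external: CompoundTable | None = None,
    k: int = 5,
    seed: int = DEFAULT_FOLD_SEED,
) -> dict[str, dict[str, float | None]]:
    """Per-model validation summary (RMSECV, RMSEP_ext, RMSEP_vivo, R²_vivo).

    RMSECV refits each model's variable set per fold on the training
    table; the external table is scored with the fixed published
    coefficients against ``log_bcf_epi``, and against ``log_bcf_vivo``
    on the subset where in-vivo values exist.  Metrics whose reference
    column is absent are reported as ``None``.
    """
    report: dict[str, dict[str, float | None]] = {}
    y_train = train.column("log_bcf_epi")
    for label, model in models.items():
        row: dict[str, float | None] = {
            "rmsecv": None,
            "rmsep_ext": None,
            "rmsep_vivo": None,
            "r2_vivo": None,
            "r2_train": None,
            "fold_seed": float(seed),
        }
        names = model.variables
        X_train = train.matrix(names)
        train_ok = ~np.isnan(y_train) & ~np.isnan(X_train).any(axis=1)
        if train_ok.sum() > len(names) + 1:
            y_t, X_t = y_train[train_ok], X_train[train_ok]
            folds = make_folds(int(train_ok.sum()), k, seed)
            row["rmsecv"] = rmsecv(refit_fitter(names), y_t, X_t, folds)
            pred_t = model.intercept + X_t @ np.array(
                [model.coefficients[n] for n in names]
            )
            ss_res = float(np.sum((y_t - pred_t) ** 2))
            ss_tot = float(np.sum((y_t - y_t.mean()) ** 2))
            row["r2_train"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else None

        table = external if external is not None else train
        beta = np.array([model.coefficients[n] for n in names])
        X_ext = table.matrix(names)
        pred_ext = model.intercept + X_ext @ beta
        y_epi = table.column("log_bcf_epi")
        ok = ~np.isnan(y_epi) & ~np.isnan(X_ext).any(axis=1)
        if ok.any():
            row["rmsep_ext"] = rmse(pred_ext[ok], y_epi[ok])
        y_vivo = table.column("log_bcf_vivo")
        ok_v = ~np.isnan(y_vivo) & ~np.isnan(X_ext).any(axis=1)
        if ok_v.any():
            row["rmsep_vivo"] = rmse(pred_ext[ok_v], y_vivo[ok_v])
            if ok_v.sum() >= 3:
                row["r2_vivo"] = _squared_pearson(pred_ext[ok_v], y_vivo[ok_v])
        report[label] = row
    return report
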