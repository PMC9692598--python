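"""OLS core and forward stepwise variable selection.

The MLR models are ordinary least-squares regressions of log BCF on a
small set of descriptors chosen by forward stepwise selection: starting
from an (optionally forced) base set, the candidate whose addition has
the smallest partial-F p-value enters the model as long as that p-value
is below ``alpha_enter``; there is no removal step.  The partial F-test
for a single added variable is equivalent to the t-test on its
coefficient in the enlarged model, which is how it is computed here.

Coefficients are reported on the raw descriptor scales (no
standardisation), matching how the published equations are written.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .model_zoo import LinearModel


@dataclass(frozen=True)
class FitResult:
    """An OLS fit packaged as a reusable :class:`LinearModel`."""

    model: LinearModel
    residuals: np.ndarray
    r2: float
    r2_adj: float
    f_statistic: float
    p_value: float
    entry_order: tuple[str, ...] = ()


def _as_matrix(predictors: Mapping[str, Sequence[float]]) -> tuple[list[str], np.ndarray]:
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[n], dtype=float) for n in names])
    return names, X


def _collinear_columns(names: list[str], X: np.ndarray) -> list[str]:
    """Columns involved in exact linear dependence, found by greedy QR check."""
    bad: list[str] = []
    kept: list[int] = []
    Xc = np.column_stack([np.ones(X.shape[0]), X])
    base_rank = 1
    for j in range(X.shape[1]):
        cols = [0] + [k + 1 for k in kept] + [j + 1]
        if np.linalg.matrix_rank(Xc[:, cols]) > base_rank:
            kept.append(j)
            base_rank += 1
        else:
            bad.append(names[j])
    return bad


def _constant_response_result(
    y_arr: np.ndarray, names: list[str], name: str
) -> FitResult:
    model = LinearModel(
        name=name,
        intercept=float(y_arr[0]),
        coefficients={n: 0.0 for n in names},
        coefficient_se={n: 0.0 for n in names},
        intercept_se=0.0,
        n_train=len(y_arr),
        stats={"r2": 0.0, "r2_adj": 0.0, "F": float("nan")},
    )
    return FitResult(
        model=model,
        residuals=np.zeros_like(y_arr),
        r2=0.0,
        r2_adj=0.0,
        f_statistic=float("nan"),
        p_value=float("nan"),
    )


def fit_ols(
    y: Sequence[float],
    predictors: Mapping[str, Sequence[float]],
    name: str = "ols",
) -> FitResult:
    """Least squares of y on named predictor columns, with an intercept.

    Raises
    ------
    ValueError
        On missing values, on n ≤ p + 1, or on a rank-deficient design
        (the error names the collinear columns).
    """
    names, X = _as_matrix(predictors)
    y_arr = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.isnan(y_arr).any() or np.isnan(X).any():
        raise ValueError("fit_ols does not accept missing values")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError(
            f"rank-deficient design; collinear columns: {_collinear_columns(names, X)}"
        )
    fit = sm.OLS(y_arr, design).fit()
    if np.ptp(y_arr) == 0.0:
        # constant response: define R^2 = 0 (no variance to explain)
        return _constant_response_result(y_arr, names, name)

    coefficients = dict(zip(names, fit.params[1:]))
    ses = dict(zip(names, fit.bse[1:]))
    model = LinearModel(
        name=name,
        intercept=float(fit.params[0]),
        coefficients={k: float(v) for k, v in coefficients.items()},
        coefficient_se={k: float(v) for k, v in ses.items()},
        intercept_se=float(fit.bse[0]),
        n_train=int(n),
        stats={
            "r2": float(fit.rsquared),
            "r2_adj": float(fit.rsquared_adj),
            "F": float(fit.fvalue) if p > 0 else float("nan"),
        },
    )
    return FitResult(
        model=model,
        residuals=np.asarray(fit.resid),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue) if p > 0 else float("nan"),
        p_value=float(fit.f_pvalue) if p > 0 else float("nan"),
    )


def _entry_p_and_t(
    y: np.ndarray, current: dict[str, np.ndarray], candidate: str, col: np.ndarray
) -> tuple[float, float]:
    """Partial-F p-value (= coefficient t-test p) and |t| for adding one column."""
    X = np.column_stack(list(current.values()) + [col])
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return np.inf, 0.0  # candidate adds no new information
    fit = sm.OLS(y, design).fit()
    t = float(fit.tvalues[-1])
    return float(fit.pvalues[-1]), abs(t)


def stepwise_forward(
    y: Sequence[float],
    candidates: Mapping[str, Sequence[float]],
    alpha_enter: float = 0.05,
    forced: Sequence[str] = (),
    name: str = "stepwise",
) -> FitResult:
    """Forward stepwise OLS selection.

    At each step the remaining candidate with the smallest partial-F
    p-value enters if that p-value is below ``alpha_enter``; ties are
    broken by larger |t|, then by candidate order.  Returns the OLS fit
    of the final variable set with the entry order recorded (forced
    variables first).
    """
    y_arr = np.asarray(y, dtype=float)
    pool = {n: np.asarray(v, dtype=float) for n, v in candidates.items()}
    order = list(pool)
    selected: dict[str, np.ndarray] = {}
    entry: list[str] = []
    for f in forced:
        if f not in pool:
            raise ValueError(f"forced variable {f!r} not among candidates")
        selected[f] = pool.pop(f)
        entry.append(f)

    while pool:
        best_key: tuple[float, float, int] | None = None
        best_cand: str | None = None
        for cand, col in pool.items():
            p, abs_t = _entry_p_and_t(y_arr, selected, cand, col)
            key = (p, -abs_t, order.index(cand))
            if best_key is None or key < best_key:
                best_key, best_cand = key, cand
        assert best_key is not None and best_cand is not None
        if best_key[0] >= alpha_enter:
            break
        selected[best_cand] = pool.pop(best_cand)
        entry.append(best_cand)

    if not selected:
        # intercept-only model
        mean = float(np.mean(y_arr))
        model = LinearModel(name=name, intercept=mean, coefficients={}, n_train=len(y_arr))
        resid = y_arr - mean
        return FitResult(
            model=model,
            residuals=resid,
            r2=0.0,
            r2_adj=0.0,
            f_statistic=float("nan"),
            p_value=float("nan"),
            entry_order=(),
        )

    result = fit_ols(y_arr, selected, name=name)
    return FitResult(
        model=result.model,
        residuals=result.residuals,
        r2=result.r2,
        r2_adj=result.r2_adj,
        f_statistic=result.f_statistic,
        p_value=result.p_value,
        entry_order=tuple(entry),
    )
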