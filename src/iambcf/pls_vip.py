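"""NIPALS partial least squares, VIP scores and VIP-based pruning.

PLS replaces a collinear descriptor block with a small number of
orthogonal components (linear combinations chosen for covariance with
the response) and regresses the response on those.  Both X and y are
autoscaled (mean 0, unit sample standard deviation, n−1 denominator)
before extraction; predictions are returned on the original y scale.

For a single response the NIPALS weight vector per component has the
closed form w ∝ X'y, so each component is extracted directly:

    w = X'y / ‖X'y‖,   t = Xw,   p = X't / t't,   q = y't / t't,

followed by deflation X ← X − t p'.  An iterative NIPALS loop (the
multi-response algorithm) is retained for robustness and convergence
checking; for one response it converges in a single pass to the same
solution.

Variable importance in the projection (VIP) summarises how much each
descriptor contributes to the explained response variance:

    VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ),  SSY_a = q_a² t_a't_a.

The squared VIPs average to one, so VIP < 1 marks a below-average
contributor; the pruning loop refits after dropping all such variables
until every survivor scores at least the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class PLSModel:
    """Fitted single-response PLS model (autoscaled internally)."""

    x_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    n_components: int
    weights: np.ndarray     # W, (p, A), unit-norm columns
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # q, (A,)
    scores: np.ndarray      # T, (n, A)
    vip: np.ndarray         # (p,)

    def regression_vector(self) -> np.ndarray:
        """PLS regression coefficients on the autoscaled space:
        b = W (P'W)^{-1} q."""
        W, P, q = self.weights, self.x_loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: Mapping[str, Sequence[float]] | np.ndarray) -> np.ndarray:
        """Predict the response on its original scale."""
        if isinstance(X, Mapping):
            mat = np.column_stack(
                [np.asarray(X[n], dtype=float) for n in self.x_names]
            )
        else:
            mat = np.asarray(X, dtype=float)
        Z = (mat - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Z @ self.regression_vector())


@dataclass(frozen=True)
class PruneTrace:
    """One VIP-pruning run: per round, the retained variable names, their
    VIP vector, the component count used and the cross-validated RMSE."""

    rounds: tuple[tuple[tuple[str, ...], np.ndarray, int, float], ...]

    @property
    def retained(self) -> tuple[str, ...]:
        return self.rounds[-1][0]


def _columns(X: Mapping[str, Sequence[float]]) -> tuple[list[str], np.ndarray]:
    names = list(X)
    return names, np.column_stack([np.asarray(X[n], dtype=float) for n in names])


def _nipals_component(Xa: np.ndarray, ya: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS weight/score extraction (iterative form; single pass is
    exact for one response)."""
    w = Xa.T @ ya
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValueError("response is orthogonal to the residual X block")
    w = w / norm
    t = Xa @ w
    for _ in range(_NIPALS_MAX_ITER):
        # multi-response NIPALS inner loop, kept for generality; with a
        # single y the first update already reproduces w exactly
        u = ya  # single response: u-score is y itself
        w_new = Xa.T @ u
        w_new = w_new / np.linalg.norm(w_new)
        t_new = Xa @ w_new
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            return w_new, t_new
        w, t = w_new, t_new
    return w, t


def fit_pls(
    y: Sequence[float],
    X: Mapping[str, Sequence[float]],
    n_components: int,
) -> PLSModel:
    """Fit a single-response NIPALS-PLS model with autoscaling.

    Raises
    ------
    ValueError
        On a constant column (named), or when ``n_components`` exceeds
        min(p, n − 1).
    """
    names, mat = _columns(X)
    y_arr = np.asarray(y, dtype=float)
    n, p = mat.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} outside [1, min(p, n-1)={min(p, n - 1)}]"
        )
    x_sd = mat.std(axis=0, ddof=1)
    constant = [names[j] for j in range(p) if x_sd[j] == 0.0]
    if constant:
        raise ValueError(f"constant columns cannot be autoscaled: {constant}")
    x_mean = mat.mean(axis=0)
    y_mean = float(y_arr.mean())
    y_sd = float(y_arr.std(ddof=1))
    if y_sd == 0.0:
        y_sd = 1.0  # constant response: keep centring well-defined
    Xa = (mat - x_mean) / x_sd
    ya = (y_arr - y_mean) / y_sd

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    Xres = Xa.copy()
    for a in range(n_components):
        w, t = _nipals_component(Xres, ya)
        tt = float(t @ t)
        if tt == 0.0:
            raise ValueError(f"degenerate component {a + 1}: zero score variance")
        p_a = Xres.T @ t / tt
        q_a = float(ya @ t / tt)
        Xres = Xres - np.outer(t, p_a)
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t

    model = PLSModel(
        x_names=tuple(names),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        vip=np.empty(0),
    )
    object.__setattr__(model, "vip", vip_scores(model))
    return model


def vip_scores(model: PLSModel) -> np.ndarray:
    """VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a), SSY_a = q_a² t_a't_a."""
    W, q, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total == 0.0:
        return np.zeros(p)
    return np.sqrt(p * (W**2 @ ssy) / total)


def select_components(
    y: Sequence[float],
    X: Mapping[str, Sequence[float]],
    max_components: int,
    folds,
) -> tuple[int, np.ndarray]:
    """Pick the component count minimising k-fold cross-validated RMSE.

    Returns ``(A_opt, curve)`` where ``curve[a-1]`` is the CV-RMSE with
    ``a`` components; ties go to the smaller count.  A component count
    that cannot be extracted on some training split (rank-deficient
    residual) scores infinity.
    """
    from .validation import rmsecv  # local import to avoid a cycle

    names, mat = _columns(X)
    curve = np.empty(max_components)
    for a in range(1, max_components + 1):
        def fitter(y_tr, X_tr, X_te, a=a):
            cols = {n: X_tr[:, j] for j, n in enumerate(names)}
            limit = min(a, X_tr.shape[1], len(y_tr) - 1)
            m = fit_pls(y_tr, cols, limit)
            return m.predict(X_te)

        try:
            curve[a - 1] = rmsecv(fitter, y, mat, folds)
        except RuntimeError:
            curve[a - 1] = np.inf
    a_opt = int(np.argmin(curve)) + 1
    return a_opt, curve


def prune_by_vip(
    y: Sequence[float],
    X: Mapping[str, Sequence[float]],
    component_selector: Callable[[Sequence[float], Mapping[str, Sequence[float]]], int],
    threshold: float = 1.0,
) -> PruneTrace:
    """Iteratively drop all variables with VIP below ``threshold``.

    Each round refits PLS on the surviving variables with a component
    count chosen by ``component_selector``, which may return either the
    count alone or ``(count, cv_rmse)``; when no CV-RMSE is supplied the
    trace records NaN for that round.  Stops when no variable falls
    below the threshold or when dropping would leave fewer than two
    variables (the drop is then not applied).
    """
    current = {n: np.asarray(v, dtype=float) for n, v in X.items()}
    if len(current) < 2:
        raise ValueError("pruning requires at least two starting variables")
    rounds: list[tuple[tuple[str, ...], np.ndarray, int, float]] = []
    while True:
        selection = component_selector(y, current)
        if isinstance(selection, tuple):
            n_comp, cv_rmse = int(selection[0]), float(selection[1])
        else:
            n_comp, cv_rmse = int(selection), float("nan")
        model = fit_pls(y, current, n_comp)
        rounds.append((tuple(current), model.vip.copy(), n_comp, cv_rmse))
        below = [n for n, v in zip(current, model.vip) if v < threshold]
        survivors = [n for n in current if n not in below]
        if not below or len(survivors) <= 1:
            break
        current = {n: current[n] for n in survivors}
    return PruneTrace(rounds=tuple(rounds))
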