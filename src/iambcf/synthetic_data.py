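"""Synthetic compound tables with a realistic descriptor correlation
structure.

The generator draws multivariate-Gaussian descriptor vectors whose
correlation matrix defaults to the published pairwise correlations among
log kw^IAM and the 16 calculated descriptors of the 120-compound IAM
study (e.g. corr(log kw^IAM, log Kow) = 0.84), then builds the response

    log BCF_EPI = b0 + Σ b_j · descriptor_j + ε,   ε ~ N(0, noise_sd²),

from a configurable generative linear model (default: the published
four-variable IAM model MLR2).  Count-valued descriptors are rounded to
non-negative integers and F_Csp3 is clipped to [0, 1] *before* the
response is computed, so refitting the generative variable set on a
noiseless table recovers the generative coefficients exactly.

Because the printed source gives correlations but not marginal
distributions, marginals default to mean 0 and sd 1 and are
user-overridable.  A correlation matrix printed to two decimals can be
slightly indefinite; it is repaired to the nearest unit-diagonal PSD
matrix by eigenvalue clipping before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compound_data import CompoundRecord, CompoundTable
from .model_zoo import MLR2, LinearModel
from .registry import COUNT_DESCRIPTORS, MODEL_VARIABLES

#: Published pairwise correlations among the 17 modelling variables,
#: in MODEL_VARIABLES order (log_kw_iam, Mw, HvAt, ArHvAt, F_Csp3, FRB,
#: HA, HD, MR, TPSA, Et, EHOMO, ELUMO, DipPCh, DipH, DipS, logKow).
DESCRIPTOR_CORRELATION: np.ndarray = np.array([
    # lkw   Mw   HvAt ArHv  FC3  FRB   HA   HD   MR  TPSA   Et  HOMO LUMO  DPCh DipH DipS  Kow
    [1.00, 0.51, 0.51, 0.39,-0.07, 0.34, 0.09,-0.15, 0.57,-0.08,-0.44, 0.38,-0.17,-0.09, 0.05,-0.04, 0.84],
    [0.51, 1.00, 0.98, 0.50, 0.07, 0.62, 0.78, 0.38, 0.98, 0.64,-0.86, 0.49,-0.42, 0.45, 0.52, 0.49, 0.32],
    [0.51, 0.98, 1.00, 0.52, 0.06, 0.63, 0.78, 0.37, 0.99, 0.64,-0.87, 0.53,-0.39, 0.46, 0.52, 0.49, 0.32],
    [0.39, 0.50, 0.52, 1.00,-0.58, 0.16, 0.27, 0.02, 0.53, 0.17,-0.44, 0.56,-0.52, 0.13, 0.40, 0.16, 0.29],
    [-0.07, 0.07, 0.06,-0.58, 1.00, 0.27, 0.09, 0.06, 0.08, 0.00,-0.01,-0.29, 0.59,-0.01,-0.07,-0.01,-0.04],
    [0.34, 0.62, 0.63, 0.16, 0.27, 1.00, 0.59, 0.31, 0.63, 0.45,-0.52, 0.31,-0.06, 0.26, 0.33, 0.31, 0.25],
    [0.09, 0.78, 0.78, 0.27, 0.09, 0.59, 1.00, 0.53, 0.70, 0.86,-0.75, 0.25,-0.39, 0.61, 0.54, 0.61,-0.11],
    [-0.15, 0.38, 0.37, 0.02, 0.06, 0.31, 0.53, 1.00, 0.33, 0.67,-0.35, 0.26,-0.14, 0.26, 0.52, 0.28,-0.27],
    [0.57, 0.98, 0.99, 0.53, 0.08, 0.63, 0.70, 0.33, 1.00, 0.57,-0.84, 0.56,-0.36, 0.41, 0.51, 0.44, 0.38],
    [-0.08, 0.64, 0.64, 0.17, 0.00, 0.45, 0.86, 0.67, 0.57, 1.00,-0.63, 0.21,-0.43, 0.67, 0.55, 0.68,-0.28],
    [-0.44,-0.86,-0.87,-0.44,-0.01,-0.52,-0.75,-0.35,-0.84,-0.63, 1.00,-0.43, 0.42,-0.48,-0.42,-0.49,-0.25],
    [0.38, 0.49, 0.53, 0.56,-0.29, 0.31, 0.25, 0.26, 0.56, 0.21,-0.43, 1.00,-0.23, 0.13, 0.44, 0.19, 0.26],
    [-0.17,-0.42,-0.39,-0.52, 0.59,-0.06,-0.39,-0.14,-0.36,-0.43, 0.42,-0.23, 1.00,-0.39,-0.27,-0.38,-0.05],
    [-0.09, 0.45, 0.46, 0.13,-0.01, 0.26, 0.61, 0.26, 0.41, 0.67,-0.48, 0.13,-0.39, 1.00, 0.33, 0.97,-0.28],
    [0.05, 0.52, 0.52, 0.40,-0.07, 0.33, 0.54, 0.52, 0.51, 0.55,-0.42, 0.44,-0.27, 0.33, 1.00, 0.44,-0.11],
    [-0.04, 0.49, 0.49, 0.16,-0.01, 0.31, 0.61, 0.28, 0.44, 0.68,-0.49, 0.19,-0.38, 0.97, 0.44, 1.00,-0.25],
    [0.84, 0.32, 0.32, 0.29,-0.04, 0.25,-0.11,-0.27, 0.38,-0.28,-0.25, 0.26,-0.05,-0.28,-0.11,-0.25, 1.00],
])


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic compound table."""

    n: int = 120
    seed: int = 0
    descriptor_names: tuple[str, ...] = MODEL_VARIABLES
    correlation: np.ndarray = field(
        default_factory=lambda: DESCRIPTOR_CORRELATION.copy()
    )
    marginal_mean: np.ndarray | None = None  # default zeros
    marginal_sd: np.ndarray | None = None    # default ones
    generative_model: LinearModel = MLR2
    noise_sd: float = 0.35

    def __post_init__(self) -> None:
        p = len(self.descriptor_names)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (p, p):
            raise ValueError(f"correlation must be {p}x{p}")
        if not np.allclose(self.correlation, self.correlation.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.correlation) > 1.0 + 1e-12):
            raise ValueError("correlation entries must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.marginal_mean is None:
            self.marginal_mean = np.zeros(p)
        if self.marginal_sd is None:
            self.marginal_sd = np.ones(p)
        self.marginal_mean = np.asarray(self.marginal_mean, dtype=float)
        self.marginal_sd = np.asarray(self.marginal_sd, dtype=float)


def repair_correlation(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest-PSD adjustment of a rounded correlation matrix.

    Eigenvalues are clipped from below at 1e-8 and the diagonal is
    rescaled back to one.  Idempotent on matrices that are already PSD
    with unit diagonal.  Returns ``(repaired, max_change)``.
    """
    mat = np.asarray(matrix, dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("correlation matrix must be symmetric")
    eigval, eigvec = np.linalg.eigh(mat)
    if eigval.min() >= 0.0:  # already PSD: exact no-op (idempotence)
        return mat.copy(), 0.0
    clipped = np.clip(eigval, 1e-8, None)
    fixed = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    fixed = 0.5 * (fixed + fixed.T)
    return fixed, float(np.max(np.abs(fixed - mat)))


def generate(spec: SyntheticSpec) -> CompoundTable:
    """Draw a synthetic compound table (deterministic given the seed)."""
    names = list(spec.descriptor_names)
    p = len(names)
    target, _ = repair_correlation(spec.correlation)
    root = np.linalg.cholesky(target + 1e-12 * np.eye(p))
    rng = np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n, p)) @ root.T
    values = spec.marginal_mean + spec.marginal_sd * Z

    # discretise counts / clip fractions BEFORE computing the response
    cols = {name: values[:, j].copy() for j, name in enumerate(names)}
    for name in names:
        if name in COUNT_DESCRIPTORS:
            cols[name] = np.maximum(np.rint(cols[name]), 0.0)
        elif name == "F_Csp3":
            cols[name] = np.clip(cols[name], 0.0, 1.0)

    gen = spec.generative_model
    signal = np.full(spec.n, gen.intercept)
    for var, coef in gen.coefficients.items():
        if var not in cols:
            raise ValueError(f"generative model needs variable {var!r}")
        signal = signal + coef * cols[var]
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else 0.0
    log_bcf = signal + noise

    records = []
    for i in range(spec.n):
        descriptors = {
            name: float(cols[name][i]) for name in names if name != "log_kw_iam"
        }
        records.append(
            CompoundRecord(
                id=f"synth-{i + 1:05d}",
                log_kw_iam=float(cols["log_kw_iam"][i]) if "log_kw_iam" in cols else None,
                descriptors=descriptors,
                log_bcf_epi=float(log_bcf[i]),
            )
        )
    return CompoundTable(records=records)
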