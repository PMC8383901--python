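"""Downstream analyses of coalescence-rate estimates.

Pairwise rate matrices for chosen epochs, column standardization and
principal components for visualizing population structure, and
directional-migration mixture fitting: the integrated (0–50k YBP)
coalescence-rate profile of a recently coalesced lineage set against a
panel of individuals is decomposed as a non-negative mixture of the
profiles of surrogate source individuals, with entry-bootstrap confidence
intervals (default 1000 replicates, 2.5/97.5 percentiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .em import CoalRateEstimate
from .timegrid import DEFAULT_GENERATION_TIME

__all__ = [
    "RateMatrix",
    "MixtureProblem",
    "integrate_rates",
    "standardize_columns",
    "principal_components",
    "nnls_fit",
    "nnls_bootstrap",
]


@dataclass
class RateMatrix:
    """Integrated pairwise coalescence rates: rows = targets, columns =
    references, for one epoch window (years).  Directed: target→reference
    and reference→target entries are kept distinct; NaN marks missing."""

    values: pd.DataFrame
    window_years: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.window_years
        if not lo < hi:
            raise ValueError("window start must precede end")
        v = self.values.to_numpy(float)
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("integrated rates must be >= 0")

    def symmetrized(self) -> "RateMatrix":
        """Arithmetic mean of the two directions (labels must match)."""
        v = self.values
        return RateMatrix(0.5 * (v + v.T), self.window_years)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="target")

    @classmethod
    def from_tsv(cls, path, window_years: tuple[float, float]) -> "RateMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, window_years)


def integrate_rates(
    est: CoalRateEstimate,
    window_years: tuple[float, float],
    generation_time: float = DEFAULT_GENERATION_TIME,
) -> float:
    """∫ λ(t) dt over a year-denominated window: the expected number of
    coalescences over the window.  Additive over disjoint windows and
    linear in the rates."""
    lo, hi = window_years[0] / generation_time, window_years[1] / generation_time
    if not lo < hi:
        raise ValueError("window start must precede end")
    b = est.grid.boundaries
    if lo < b[0] - 1e-9 or hi > b[-1] * (1 + 1e-12):
        raise ValueError("window outside the grid span")
    overlap = np.clip(np.minimum(b[1:], hi) - np.maximum(b[:-1], lo), 0.0, None)
    return float(overlap @ est.rates)


def standardize_columns(matrix) -> pd.DataFrame:
    """Column-standardize a rate matrix for PCA: missing entries are
    mean-imputed (reported), constant columns dropped with a warning, then
    each column is centered and scaled to unit sample standard deviation."""
    df = matrix.values if isinstance(matrix, RateMatrix) else pd.DataFrame(matrix)
    df = df.astype(float).copy()
    if (df.notna().sum(axis=0) < 2).any():
        raise ValueError("every column needs >= 2 present entries")
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(f"mean-imputed {n_missing} missing entries")
        df = df.fillna(df.mean(axis=0))
    sd = df.std(axis=0, ddof=1)
    constant = sd <= 0
    if constant.any():
        warnings.warn(f"dropped {int(constant.sum())} constant columns")
        df = df.loc[:, ~constant]
        sd = sd[~constant]
    return (df - df.mean(axis=0)) / sd


def principal_components(matrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of the rows via centered SVD.

    Returns ``(scores, explained_variance_fractions)`` with ``scores =
    U_k S_k``; the fractions sum to at most 1.
    """
    X = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix, float
    )
    if k < 1 or k > min(X.shape):
        raise ValueError(f"k must be in 1..{min(X.shape)}")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return U[:, :k] * s[:k], evr[:k]


@dataclass
class MixtureProblem:
    """NNLS design: ``y`` (N,) integrated rates of the focal lineage set to
    N panel individuals; ``X`` (N, k) the same quantity for k surrogate
    sources; fit ``β ≥ 0`` minimizing ``‖y − Xβ‖₂``."""

    y: np.ndarray
    X: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, float).ravel()
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        N, k = self.X.shape
        if not (N > k >= 1):
            raise ValueError("need N > k >= 1")
        if self.y.shape != (N,):
            raise ValueError("y length must match rows of X")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.X))):
            raise ValueError("entries must be finite")


def nnls_fit(p: MixtureProblem) -> np.ndarray:
    """Non-negative least squares coefficients β̂ = argmin_{β≥0} ‖y − Xβ‖₂.

    At the solution the KKT conditions hold: the gradient component
    ``(Xᵀ(Xβ − y))_j`` is ~0 where ``β_j > 0`` and >= 0 where ``β_j = 0``.
    """
    norms = np.linalg.norm(p.X, axis=0)
    if np.any(norms == 0):
        raise ValueError("X contains an all-zero column")
    beta, _ = scipy.optimize.nnls(p.X, p.y)
    return beta


def nnls_bootstrap(
    p: MixtureProblem,
    n_reps: int = 1000,
    seed: int | None = None,
    max_redraws: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Entry bootstrap for the mixture coefficients.

    Resamples the N panel entries (rows of y and X jointly) with
    replacement and refits; degenerate resamples (a zero column in X) are
    redrawn and counted.  Returns ``(ci_lower, ci_upper, replicate_betas,
    n_redrawn)`` at the 2.5/97.5 percentiles; deterministic given ``seed``.
    """
    if p.y.size < 10:
        raise ValueError("entry bootstrap needs N >= 10")
    rng = np.random.default_rng(seed)
    N, k = p.X.shape
    betas = np.empty((n_reps, k))
    n_redrawn = 0
    for r in range(n_reps):
        for _ in range(max_redraws):
            idx = rng.integers(0, N, N)
            Xb = p.X[idx]
            if np.all(np.linalg.norm(Xb, axis=0) > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate resample")
        betas[r], _ = scipy.optimize.nnls(Xb, p.y[idx])
    lo = np.percentile(betas, 2.5, axis=0)
    hi = np.percentile(betas, 97.5, axis=0)
    return lo, hi, betas, n_redrawn
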