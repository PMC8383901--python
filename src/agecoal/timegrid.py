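"""Time axis and piecewise-constant coalescence-rate primitives.

Everything downstream — binning of mutation ages, the EM over sharing
counts, rate integration — works on a :class:`TimeGrid`: an ordered set of
epoch boundaries partitioning ``[0, t_out]``, where ``t_out`` is a hard cap
on mutation age given by the TMRCA to an outgroup (10 million years for
human–chimpanzee, the shipped default).

Internal time unit is *generations* throughout the package; user-facing
I/O in years is converted with a configurable generation time (default
28 years per generation, so that per-generation mutation rates and
year-denominated epochs coexist).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_GENERATION_TIME",
    "DEFAULT_T_OUT_YEARS",
    "TimeGrid",
    "PiecewiseRate",
    "build_log_grid",
    "cumulative_rate",
    "sharing_probability",
    "parse_grid_spec",
]

#: Years per generation used for all year<->generation conversions.
DEFAULT_GENERATION_TIME = 28.0

#: Hard cap on mutation age: TMRCA to the outgroup, in years
#: (human–chimpanzee).
DEFAULT_T_OUT_YEARS = 1.0e7


@dataclass(frozen=True)
class TimeGrid:
    """Ordered epoch boundaries partitioning ``[0, t_out]`` in generations.

    ``boundaries`` must be strictly increasing, start at 0 and end at the
    finite outgroup cap ``t_out``.  Bin ``e`` is ``[boundaries[e],
    boundaries[e+1])``.
    """

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("grid needs at least two boundaries")
        if b[0] != 0.0:
            raise ValueError("first boundary must be 0")
        if not np.all(np.isfinite(b)):
            raise ValueError("boundaries must be finite (t_out is a hard cap)")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_bins(self) -> int:
        return self.boundaries.size - 1

    @property
    def t_out(self) -> float:
        return float(self.boundaries[-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def bin_index(self, t: float) -> int:
        """Index of the bin containing ``t`` (``t_out`` maps to the last bin)."""
        if t < 0 or t > self.t_out:
            raise ValueError(f"time {t} outside grid span [0, {self.t_out}]")
        idx = int(np.searchsorted(self.boundaries, t, side="right")) - 1
        return min(idx, self.n_bins - 1)

    def representative_ages(self, t0: float = 0.0) -> np.ndarray:
        """Per-bin representative age used by the binned EM.

        Log-spaced bins use the geometric mean of their boundaries; a bin
        whose (possibly ``t0``-clamped) lower edge is 0 uses the arithmetic
        midpoint.  Bins entirely below ``t0`` return NaN (they can carry no
        observations).
        """
        lo = np.maximum(self.boundaries[:-1], t0)
        hi = self.boundaries[1:]
        rep = np.where(lo > 0, np.sqrt(lo * hi), 0.5 * (lo + hi))
        rep = np.where(hi <= t0, np.nan, rep)
        return rep

    def refine(self, factor: int) -> "TimeGrid":
        """Split every bin into ``factor`` equal-width sub-bins."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        b = self.boundaries
        parts = [
            np.linspace(b[i], b[i + 1], factor + 1)[:-1] for i in range(self.n_bins)
        ]
        return TimeGrid(np.append(np.concatenate(parts), b[-1]))

    def to_years(self, generation_time: float = DEFAULT_GENERATION_TIME) -> np.ndarray:
        return self.boundaries * generation_time


def build_log_grid(t_first: float, t_out: float, n_log_bins: int) -> TimeGrid:
    """One linear bin ``[0, t_first)`` followed by ``n_log_bins`` log10-spaced
    bins up to the outgroup cap ``t_out`` (all in generations)."""
    if not (0 < t_first < t_out):
        raise ValueError("need 0 < t_first < t_out")
    if n_log_bins < 1:
        raise ValueError("n_log_bins must be >= 1")
    logs = np.logspace(np.log10(t_first), np.log10(t_out), n_log_bins + 1)
    boundaries = np.concatenate([[0.0], logs])
    boundaries[-1] = t_out  # exact cap, immune to round-off
    return TimeGrid(boundaries)


def default_grid(
    generation_time: float = DEFAULT_GENERATION_TIME,
    t_out_years: float = DEFAULT_T_OUT_YEARS,
    n_log_bins: int = 28,
    t_first: float = 1000.0,
) -> TimeGrid:
    """Shipped default: one linear bin to 1000 generations, then 28 log bins
    to the outgroup cap (10 My converted to generations)."""
    return build_log_grid(t_first, t_out_years / generation_time, n_log_bins)


def parse_grid_spec(
    spec: str, generation_time: float = DEFAULT_GENERATION_TIME
) -> TimeGrid:
    """Parse a CLI grid specification ``log:<t_first>:<t_out>:<n_log_bins>``
    with times in *years*."""
    parts = spec.split(":")
    if len(parts) != 4 or parts[0] != "log":
        raise ValueError(
            f"bad grid spec {spec!r}; expected log:<t_first>:<t_out>:<n_log_bins>"
        )
    t_first, t_out = float(parts[1]), float(parts[2])
    return build_log_grid(
        t_first / generation_time, t_out / generation_time, int(parts[3])
    )


@dataclass(frozen=True)
class PiecewiseRate:
    """Piecewise-constant coalescence rate λ(t), one value per grid bin,
    in units of per generation."""

    grid: TimeGrid
    rates: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.shape != (self.grid.n_bins,):
            raise ValueError(
                f"need {self.grid.n_bins} rates, got shape {r.shape}"
            )
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("rates must be finite and >= 0")
        object.__setattr__(self, "rates", r)

    @classmethod
    def constant(cls, grid: TimeGrid, rate: float) -> "PiecewiseRate":
        return cls(grid, np.full(grid.n_bins, float(rate)))

    def cumulative(self, t0: float, t) -> float | np.ndarray:
        """Integrated rate Λ = ∫_{t0}^{t} λ(s) ds; ``t`` may be an array."""
        return cumulative_rate(self, t0, t)

    def sharing_probability(self, t0: float, a) -> float | np.ndarray:
        return sharing_probability(self, t0, a)

    def value_at(self, t) -> np.ndarray:
        """λ evaluated at times ``t`` (cap time maps to the last bin)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(
            np.searchsorted(self.grid.boundaries, t, side="right") - 1,
            0,
            self.grid.n_bins - 1,
        )
        return self.rates[idx]


def _overlap_lengths(grid: TimeGrid, t0, t) -> np.ndarray:
    """|bin_e ∩ [t0, t]| for every bin; broadcasts over trailing axis of t."""
    lo = grid.boundaries[:-1]
    hi = grid.boundaries[1:]
    t = np.asarray(t, dtype=float)
    return np.clip(
        np.minimum(hi, t[..., None]) - np.maximum(lo, t0), 0.0, None
    )


def cumulative_rate(rate: PiecewiseRate, t0: float, t) -> float | np.ndarray:
    """Λ(t0, t) = Σ_e λ_e · |bin_e ∩ [t0, t]| (dimensionless).

    Additive in ``t`` and zero at ``t == t0``.  ``t`` may be scalar or array;
    all times must satisfy ``0 <= t0 <= t <= t_out``.
    """
    t_arr = np.asarray(t, dtype=float)
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if np.any(t_arr < t0):
        raise ValueError("t must be >= t0")
    if np.any(t_arr > rate.grid.t_out * (1 + 1e-12)):
        raise ValueError("t beyond the grid cap t_out")
    out = _overlap_lengths(rate.grid, t0, t_arr) @ rate.rates
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def sharing_probability(rate: PiecewiseRate, t0: float, a) -> float | np.ndarray:
    """P(mutation of age ``a`` is shared) = P(T < a) = 1 − exp(−Λ(t0, a)).

    ``T`` is the pair coalescence time, constrained to ``T >= t0`` (the older
    of the two sample ages): a derived allele on a reference chromosome is
    carried by the target iff the pair coalesced more recently than the
    mutation arose.
    """
    lam = cumulative_rate(rate, t0, a)
    return -np.expm1(-lam) if not np.isscalar(lam) else float(-np.expm1(-lam))
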