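"""Trinucleotide mutation-spectrum statistics and the TCC/TTC pulse.

Single-base substitutions in their immediate flanking context are collapsed
by strand into 96 canonical classes (central base a pyrimidine; 4 left
flanks x 2 central pyrimidines x 3 derived alleles x 4 right flanks / 2
strands).  Excluding CpG-context classes — prone to deamination-driven
hypermutability — retains 76 of the 96.  Per-individual relative
mutation-rate curves through time, their Integrated Mutation Intensity
(IMI: area between the scaled curve and the constant baseline over
14 ky – 1 My BP in log10 time), and a read-count-thresholded TCC>TTC
proportion estimator for low-coverage genomes quantify the well-known but
unexplained European TCC→TTC rate elevation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mutations import DatedMutationTable
from .observations import Pileup, ReadFilter, _bin_mass_batch
from .timegrid import TimeGrid

__all__ = [
    "TripletClass",
    "RateCurve",
    "canonical_class",
    "enumerate_classes",
    "relative_rate_curve",
    "imi",
    "tcc_proportion_lowcov",
    "transversion_rate",
    "CPG_RULES",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass(frozen=True)
class TripletClass:
    """Strand-collapsed substitution class ``XYZ>XY'Z`` with central
    pyrimidine Y."""

    left: str
    anc: str
    der: str
    right: str

    def __post_init__(self):
        if self.anc not in "CT":
            raise ValueError("canonical central ancestral base must be a pyrimidine")
        if self.der == self.anc or any(
            b not in _BASES for b in (self.left, self.anc, self.der, self.right)
        ):
            raise ValueError("invalid class bases")

    @property
    def label(self) -> str:
        return (
            f"{self.left}{self.anc}{self.right}>{self.left}{self.der}{self.right}"
        )

    @property
    def is_transition(self) -> bool:
        return {self.anc, self.der} in ({"C", "T"}, {"A", "G"})

    def cpg_context(self, rule: str = "pulse20") -> bool:
        return CPG_RULES[rule](self) if rule in CPG_RULES else _unknown_rule(rule)

    def __str__(self) -> str:
        return self.label


def _unknown_rule(rule: str):
    raise ValueError(f"unknown CpG rule {rule!r}; available: {sorted(CPG_RULES)}")


def _is_cpg_pulse20(c: TripletClass) -> bool:
    """Shipped CpG-context rule, constrained to exclude exactly 20 of the
    96 classes: the ancestral triplet carries a CG dinucleotide at the
    mutating site (central C followed by G; 12 classes), or the derived
    allele creates one (T>C with right flank G; 4 classes), or creates one
    on the opposite strand (T>G with left flank C; 4 classes).
    """
    if c.anc == "C" and c.right == "G":
        return True
    if c.anc == "T" and c.der == "C" and c.right == "G":
        return True
    if c.anc == "T" and c.der == "G" and c.left == "C":
        return True
    return False


CPG_RULES = {"pulse20": _is_cpg_pulse20}


def canonical_class(left: str, anc: str, der: str, right: str) -> TripletClass:
    """Canonicalize a contextual substitution by strand.

    If the ancestral central base is a purine the whole triplet and both
    alleles are reverse-complemented (flanks swap and complement), so a
    substitution and its reverse-complement map to the same class;
    idempotent on already-canonical input.
    """
    for b in (left, anc, der, right):
        if b not in _BASES:
            raise ValueError(f"invalid base {b!r}")
    if anc == der:
        raise ValueError("ancestral and derived alleles must differ")
    if anc in "AG":
        left, right = _COMP[right], _COMP[left]
        anc, der = _COMP[anc], _COMP[der]
    return TripletClass(left, anc, der, right)


def enumerate_classes(
    exclude_cpg: bool = False, cpg_rule: str = "pulse20"
) -> list[TripletClass]:
    """All 96 canonical classes, or the subset outside CpG context (76
    under the shipped rule, which flags exactly 20)."""
    if cpg_rule not in CPG_RULES:
        _unknown_rule(cpg_rule)
    out = []
    for left in _BASES:
        for anc in "CT":
            for der in _BASES:
                if der == anc:
                    continue
                for right in _BASES:
                    cls = TripletClass(left, anc, der, right)
                    if exclude_cpg and cls.cpg_context(cpg_rule):
                        continue
                    out.append(cls)
    return out


@dataclass
class RateCurve:
    """Relative mutation-rate of one triplet class through epochs.

    ``boundaries_years`` are increasing epoch edges in years; ``values``
    are dimensionless relative rates (NaN = epoch with no data).  The
    scaling window (default [1e5, 1e6] YBP, predating the TCC/TTC pulse)
    is where :func:`imi` normalizes the curve to mean 1.
    """

    boundaries_years: np.ndarray
    values: np.ndarray
    scaling_window: tuple[float, float] = (1e5, 1e6)

    def __post_init__(self):
        b = np.asarray(self.boundaries_years, float)
        v = np.asarray(self.values, float)
        if b.ndim != 1 or not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        if v.shape != (b.size - 1,):
            raise ValueError("need one value per epoch")
        if np.any(v[np.isfinite(v)] < 0):
            raise ValueError("relative rates must be >= 0")
        self.boundaries_years, self.values = b, v


def relative_rate_curve(
    table: DatedMutationTable,
    opportunities: dict[str, float] | float,
    boundaries_years: np.ndarray,
    focal: str = "TCC>TTC",
    exclude_cpg: bool = True,
    cpg_rule: str = "pulse20",
) -> RateCurve:
    """Relative mutation-rate curve of a focal triplet class.

    Per epoch ``e`` and retained class ``c``, the class's binned mutation
    mass ``M_c(e)`` (uniform age mass over each mutation's branch interval)
    is turned into a density ``d_c(e) = M_c(e) / L_c`` using the genomic
    opportunity ``L_c`` (context count in the ancestral genome; a scalar
    means flat opportunities).  The curve is ``d_focal(e)`` divided by the
    mean of ``d_c(e)`` over the retained classes, so shared temporal trends
    cancel; invariant to rescaling all ``L_c`` jointly.

    Singleton and terminal-branch mutations are excluded (the
    ``is_terminal`` column when present, otherwise ``carrier_count == 1``
    as a proxy, with a warning).  Epochs with zero total density are NaN.
    """
    df = table.df
    if "left_base" not in df.columns or "right_base" not in df.columns:
        raise ValueError("table lacks flanking-context columns")
    if "is_terminal" in df.columns:
        keep = ~df["is_terminal"].to_numpy(bool) & ~table.is_singleton
    else:
        warnings.warn(
            "no is_terminal column; using carrier_count==1 as the "
            "terminal-branch proxy"
        )
        keep = ~table.is_singleton

    classes = enumerate_classes(exclude_cpg=exclude_cpg, cpg_rule=cpg_rule)
    labels = [c.label for c in classes]
    if focal not in labels:
        raise ValueError(f"focal class {focal} not among the retained classes")
    if np.isscalar(opportunities):
        L = {lab: float(opportunities) for lab in labels}
    else:
        L = dict(opportunities)
    missing_L = [lab for lab in labels if lab not in L or L[lab] <= 0]
    if missing_L:
        raise ValueError(f"non-positive or missing opportunities for {missing_L[:3]}...")

    b_years = np.asarray(boundaries_years, float)
    n_epochs = b_years.size - 1
    sub = df[keep]
    lab_per_mut = np.array(
        [
            canonical_class(l, a, d, r).label
            for l, a, d, r in zip(
                sub["left_base"], sub["anc"], sub["der"], sub["right_base"]
            )
        ]
    )
    # bin each mutation's age mass on the year grid
    grid_like = np.concatenate([[0.0], b_years[b_years > 0]])
    grid = TimeGrid(grid_like)
    mass, _ = _bin_mass_batch(
        sub["age_lower_years"].to_numpy(float).clip(max=grid.t_out),
        sub["age_upper_years"].to_numpy(float).clip(max=grid.t_out),
        grid,
        0.0,
    )
    # map grid bins back onto requested epochs (drop the padding bin if any)
    offset = grid.n_bins - n_epochs
    M = np.zeros((len(labels), n_epochs))
    index = {lab: i for i, lab in enumerate(labels)}
    for lab in np.unique(lab_per_mut):
        if lab not in index:  # excluded (e.g. CpG) class
            continue
        rows = lab_per_mut == lab
        M[index[lab]] = mass[rows, offset:].sum(axis=0)
    dens = M / np.array([L[lab] for lab in labels])[:, None]
    mean_dens = dens.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(mean_dens > 0, dens[index[focal]] / mean_dens, np.nan)
    return RateCurve(b_years, curve)


def imi(
    curve: RateCurve,
    integration_window: tuple[float, float] = (14e3, 1e6),
    prescaled: bool = False,
) -> float:
    """Integrated Mutation Intensity: area between the scaled curve and the
    constant baseline over the integration window, in log10 time.

    The curve is first scaled to mean 1 (log10-time-weighted) over its
    scaling window — set ``prescaled=True`` to bypass.  Epochs missing at
    the recent end take the earliest available value (constant
    extrapolation back to the window start); interior gaps take the nearest
    older value.  A constant curve yields exactly 0.
    """
    b = curve.boundaries_years
    vals = curve.values.copy()
    # fill NaN epochs from the nearest older, then younger, neighbour
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("curve has no data")
    for i in range(vals.size - 2, -1, -1):
        if not np.isfinite(vals[i]):
            vals[i] = vals[i + 1]
    for i in range(1, vals.size):
        if not np.isfinite(vals[i]):
            vals[i] = vals[i - 1]

    lo_int, hi_int = integration_window
    if b[0] > lo_int:
        # constant extrapolation of the earliest value to the window start
        b = np.concatenate([[lo_int], b])
        vals = np.concatenate([[vals[0]], vals])
    if b[-1] < hi_int:
        raise ValueError("curve does not reach the end of the integration window")

    def log_overlap(window):
        w_lo, w_hi = np.log10(window[0]), np.log10(window[1])
        e_lo = np.log10(np.maximum(b[:-1], window[0] * 1e-12))
        e_hi = np.log10(np.maximum(b[1:], window[0] * 1e-12))
        return np.clip(np.minimum(e_hi, w_hi) - np.maximum(e_lo, w_lo), 0.0, None)

    if not prescaled:
        w_scale = log_overlap(curve.scaling_window)
        if w_scale.sum() <= 0:
            raise ValueError("no epochs intersect the scaling window")
        if np.ptp(vals) == 0:  # constant curve: the mean is exact
            scale = float(vals[0])
        else:
            scale = float(np.sum(w_scale * vals) / np.sum(w_scale))
        if scale <= 0:
            raise ValueError("scaling window has zero mean rate")
        vals = vals / scale

    w_int = log_overlap(integration_window)
    return float(np.sum(w_int * (vals - 1.0)))


def tcc_proportion_lowcov(
    pileup: Pileup,
    table: DatedMutationTable,
    min_depth: int = 4,
    min_derived: int = 4,
    age_cap_years: float = 1e5,
    block_size: int = 10_000_000,
    n_reps: int = 100,
    seed: int | None = None,
    filters: ReadFilter | None = None,
    cpg_rule: str = "pulse20",
) -> tuple[float, float, float]:
    """TCC>TTC proportion among non-CpG C>T transitions in a low-coverage
    individual.

    A table site qualifies when at least ``min_depth`` passing reads map,
    at least ``min_derived`` of them support the derived allele (strong
    evidence of a het or hom-derived genotype) and the branch's upper
    coalescence age is below ``age_cap_years``.  The statistic is the
    fraction of qualifying non-CpG C>T-transition sites whose canonical
    class is TCC>TTC; the CI is a 10-Mb block bootstrap (2.5/97.5
    percentiles).  Returns ``(proportion, ci_low, ci_high)``.
    """
    df = table.df
    if "left_base" not in df.columns or "right_base" not in df.columns:
        raise ValueError("table lacks flanking-context columns")
    ok = pileup.passing(filters)
    sidx = pileup.site_index[ok]
    base = pileup.base[ok]
    n = len(table)
    depth = np.bincount(sidx, minlength=n)
    der = df["der"].to_numpy(dtype="U1")
    n_der = np.bincount(sidx[base == der[sidx]], minlength=n)
    qualifying = (
        (depth >= min_depth)
        & (n_der >= min_derived)
        & (df["age_upper_years"].to_numpy(float) < age_cap_years)
    )
    labels = np.array(
        [
            canonical_class(l, a, d, r).label
            for l, a, d, r in zip(
                df["left_base"], df["anc"], df["der"], df["right_base"]
            )
        ]
    )
    ct_labels = {
        c.label
        for c in enumerate_classes(exclude_cpg=True, cpg_rule=cpg_rule)
        if c.anc == "C" and c.der == "T"
    }
    denom_mask = qualifying & np.isin(labels, sorted(ct_labels))
    num_mask = denom_mask & (labels == "TCC>TTC")
    if denom_mask.sum() == 0:
        raise ValueError(
            f"no qualifying C>T transition sites "
            f"({qualifying.sum()} qualifying sites overall)"
        )
    prop = num_mask.sum() / denom_mask.sum()

    pos = df["pos"].to_numpy()
    chroms = df["chrom"].to_numpy()
    chrom_ids = {c: i for i, c in enumerate(np.unique(chroms))}
    block_of = np.array([chrom_ids[c] for c in chroms]) * 10**9 + pos // block_size
    uniq = np.unique(block_of[denom_mask])
    rng = np.random.default_rng(seed)
    num_per = np.array([num_mask[block_of == b].sum() for b in uniq], float)
    den_per = np.array([denom_mask[block_of == b].sum() for b in uniq], float)
    props = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, uniq.size, uniq.size)
        d = den_per[idx].sum()
        props[r] = num_per[idx].sum() / d if d > 0 else np.nan
    props = props[np.isfinite(props)]
    return float(prop), float(np.percentile(props, 2.5)), float(np.percentile(props, 97.5))


def transversion_rate(total_rate: float = 1.25e-8, ts_tv_ratio: float = 2.0) -> float:
    """Transversion-only mutation rate implied by a total rate and a
    transition:transversion ratio: ``total / (1 + ratio)`` (e.g. 1.25e-8
    with Ts:Tv = 2 gives ~4e-9 per base per generation)."""
    if total_rate <= 0 or ts_tv_ratio < 0:
        raise ValueError("need total_rate > 0 and ts_tv_ratio >= 0")
    return total_rate / (1.0 + ts_tv_ratio)
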