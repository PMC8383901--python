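"""From genotypes or reads at dated sites to shared/not-shared counts.

The EM consumes only *sharing counts*: per genomic block and per time-grid
bin, fractional counts of shared and not-shared observations.  For every
derived mutation carried by a reference chromosome we record whether the
target carries it too; the mutation's (uniform) age mass over its branch
interval is distributed onto the grid with :func:`bin_mutation_mass`.
Compiling these counts is linear in data size, after which EM run time is
independent of sample size and genome length.

Read-level input applies the standard ancient-DNA filters: mapping quality
> 30, read length > 34 bp, fewer than 3 mismatches, 2 bp trimmed at each
read end, and at most two distinct alleles observed per site.  Accessibility
masks keep sites with >= 5x depth and below twice the mean coverage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mutations import DatedMutationTable
from .timegrid import DEFAULT_GENERATION_TIME, TimeGrid

__all__ = [
    "ReadRecord",
    "ReadFilter",
    "Pileup",
    "SharingCounts",
    "polarize_alleles",
    "filter_read",
    "build_coverage_mask",
    "bin_mutation_mass",
    "genotype_observations",
    "read_observations",
    "make_blocks",
]

logger = logging.getLogger(__name__)

#: Default genomic block length (bp) for sufficient statistics; matches the
#: 20-Mb block bootstrap.
DEFAULT_BLOCK_SIZE = 20_000_000

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def polarize_alleles(
    ref_allele: str, alt_allele: str, ancestral_base: str
) -> tuple[str, str] | None:
    """Orient a biallelic site so the first allele is ancestral.

    Returns ``(anc, der)`` or ``None`` when the site cannot be polarized
    (ancestral base unknown or matching neither allele).
    """
    if ancestral_base == ref_allele:
        return ref_allele, alt_allele
    if ancestral_base == alt_allele:
        return alt_allele, ref_allele
    return None


@dataclass(frozen=True)
class ReadRecord:
    """Per-read fields relevant to the acceptance filter, for one site."""

    mapping_quality: int
    read_length: int
    mismatch_count: int
    base: str
    offset: int  # distance of the site from the nearer read end, >= 0


@dataclass(frozen=True)
class ReadFilter:
    """Read acceptance thresholds.  Defaults follow the ancient-DNA
    protocol: MQ strictly above 30, length strictly above 34, mismatches
    strictly below 3, 2 bp excluded at each read end."""

    min_mapping_quality: int = 30  # exclusive
    min_read_length: int = 34  # exclusive
    max_mismatches: int = 3  # exclusive
    end_trim: int = 2


def filter_read(r: ReadRecord, end_trim: int = 2, filters: ReadFilter | None = None) -> bool:
    """True iff the read passes all thresholds (all comparisons strict)."""
    f = filters or ReadFilter(end_trim=end_trim)
    return (
        r.mapping_quality > f.min_mapping_quality
        and r.read_length > f.min_read_length
        and r.mismatch_count < f.max_mismatches
        and r.offset >= (f.end_trim if filters else end_trim)
    )


def build_coverage_mask(
    depth_track: np.ndarray, mean_coverage: float, start: int = 0
) -> list[tuple[int, int]]:
    """Accessibility mask from a per-base depth track.

    A site passes iff ``depth >= 5`` and ``depth < 2 * mean_coverage``.
    Returns merged half-open 0-based intervals (BED convention), offset by
    ``start``.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    depth = np.asarray(depth_track)
    passing = (depth >= 5) & (depth < 2 * mean_coverage)
    return _runs_to_intervals(passing, start)


def _runs_to_intervals(passing: np.ndarray, start: int = 0) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], passing.view(np.int8), [0]])))
    return [
        (int(edges[i]) + start, int(edges[i + 1]) + start)
        for i in range(0, edges.size, 2)
    ]


class GenomicMask:
    """Merged per-chromosome intervals; 0-based half-open (BED)."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged])
            self._ends[chrom] = np.array([m[1] for m in merged])

    def contains(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """Vectorized membership for 1-based positions."""
        p0 = np.asarray(pos_1based) - 1
        if chrom not in self._starts:
            return np.zeros(p0.shape, dtype=bool)
        idx = np.searchsorted(self._starts[chrom], p0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(p0.shape, dtype=bool)
        out[ok] = p0[ok] < self._ends[chrom][idx[ok]]
        return out


def bin_mutation_mass(
    age_lower: float, age_upper: float, grid: TimeGrid, t0: float = 0.0
) -> np.ndarray:
    """Distribute a mutation's uniform age mass onto the grid bins.

    The interval is clamped to ``[max(age_lower, t0), age_upper]``; a point
    age gets full mass in its containing bin.  Returns all-zero weights when
    the interval lies entirely below ``t0`` (an observation inconsistent
    with the sample ages) — callers should treat that as a diagnostic.
    Otherwise weights sum to 1.
    """
    w, n_bad = _bin_mass_batch(
        np.atleast_1d(float(age_lower)), np.atleast_1d(float(age_upper)), grid, t0
    )
    return w[0]


def _bin_mass_batch(
    lower: np.ndarray, upper: np.ndarray, grid: TimeGrid, t0: float
) -> tuple[np.ndarray, int]:
    """Vectorized :func:`bin_mutation_mass`: (n, n_bins) weights and the
    number of inconsistent (all-zero) rows."""
    if np.any(lower > upper):
        raise ValueError("need age_lower <= age_upper")
    lo = np.clip(np.maximum(lower, t0), None, grid.t_out)
    hi = np.clip(upper, None, grid.t_out)
    b_lo = grid.boundaries[:-1]
    b_hi = grid.boundaries[1:]
    width = hi - lo
    point = (width <= 0) & (upper >= t0)
    bad = upper < t0
    out = np.zeros((lower.size, grid.n_bins))
    span = np.flatnonzero(~point & ~bad)
    if span.size:
        ov = np.clip(
            np.minimum(b_hi, hi[span, None]) - np.maximum(b_lo, lo[span, None]),
            0.0,
            None,
        )
        out[span] = ov / width[span, None]
    pt = np.flatnonzero(point)
    if pt.size:
        idx = np.clip(
            np.searchsorted(grid.boundaries, hi[pt], side="right") - 1,
            0,
            grid.n_bins - 1,
        )
        out[pt, idx] = 1.0
    return out, int(bad.sum())


@dataclass
class SharingCounts:
    """Per-block, per-bin fractional counts of shared / not-shared
    observations: the EM's sufficient statistics.

    ``blocks`` are ``(chrom, start, end)`` with 1-based start and exclusive
    end, tiling each chromosome without overlap.  ``singletons`` optionally
    carries, per block, an ``(m, 3)`` array of (age_lower, age_upper,
    weight) rows for shared singleton observations whose age mass the EM
    re-tilts each iteration (see the em module).
    """

    grid: TimeGrid
    t0: float
    blocks: list[tuple[str, int, int]]
    shared: np.ndarray  # (n_blocks, n_bins)
    notshared: np.ndarray  # (n_blocks, n_bins)
    singletons: list[np.ndarray] | None = None
    generation_time: float = DEFAULT_GENERATION_TIME
    n_inconsistent: int = 0

    def __post_init__(self):
        nb, ne = len(self.blocks), self.grid.n_bins
        self.shared = np.asarray(self.shared, dtype=float).reshape(nb, ne)
        self.notshared = np.asarray(self.notshared, dtype=float).reshape(nb, ne)
        for arr in (self.shared, self.notshared):
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError("counts must be finite and >= 0")
        below = self.grid.boundaries[1:] <= self.t0
        if np.any((self.shared[:, below] > 0) | (self.notshared[:, below] > 0)):
            raise ValueError("bins entirely below t0 must carry zero counts")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def total(self) -> tuple[np.ndarray, np.ndarray]:
        return self.shared.sum(axis=0), self.notshared.sum(axis=0)

    def resample_blocks(self, indices: np.ndarray) -> "SharingCounts":
        """Counts for a with-replacement resample of block indices."""
        sing = None
        if self.singletons is not None:
            sing = [self.singletons[i] for i in indices]
        return SharingCounts(
            grid=self.grid,
            t0=self.t0,
            blocks=[self.blocks[i] for i in indices],
            shared=self.shared[indices],
            notshared=self.notshared[indices],
            singletons=sing,
            generation_time=self.generation_time,
        )

    # ---- JSON serialization (boundaries and t0 in years) ---------------
    def to_json(self) -> str:
        payload = {
            "format": "agecoal-counts v1",
            "grid_boundaries_years": (self.grid.boundaries * self.generation_time).tolist(),
            "t0_years": self.t0 * self.generation_time,
            "generation_time": self.generation_time,
            "blocks": [[c, int(s), int(e)] for c, s, e in self.blocks],
            "shared": self.shared.tolist(),
            "notshared": self.notshared.tolist(),
            "singletons": None
            if self.singletons is None
            else [s.tolist() for s in self.singletons],
            "n_inconsistent": self.n_inconsistent,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SharingCounts":
        d = json.loads(text)
        gt = d["generation_time"]
        grid = TimeGrid(np.asarray(d["grid_boundaries_years"]) / gt)
        sing = d.get("singletons")
        return cls(
            grid=grid,
            t0=d["t0_years"] / gt,
            blocks=[(c, s, e) for c, s, e in d["blocks"]],
            shared=np.asarray(d["shared"]),
            notshared=np.asarray(d["notshared"]),
            singletons=None if sing is None else [np.asarray(s).reshape(-1, 3) for s in sing],
            generation_time=gt,
            n_inconsistent=d.get("n_inconsistent", 0),
        )


def make_blocks(
    chrom_lengths: dict[str, int], block_size: int = DEFAULT_BLOCK_SIZE
) -> list[tuple[str, int, int]]:
    """Tile chromosomes with non-overlapping blocks of ``block_size`` bp
    (1-based start, exclusive end; last block absorbs the remainder up to
    half a block)."""
    blocks = []
    for chrom, length in chrom_lengths.items():
        edges = list(range(1, length + 2, block_size))
        if edges[-1] != length + 1:
            edges.append(length + 1)
        if len(edges) > 2 and edges[-1] - edges[-2] < block_size / 2:
            edges.pop(-2)
        for s, e in zip(edges[:-1], edges[1:]):
            blocks.append((chrom, s, e))
    return blocks


def _block_index(
    table: DatedMutationTable, blocks: list[tuple[str, int, int]]
) -> np.ndarray:
    """Block index per table row (-1 when not covered)."""
    idx = np.full(len(table), -1, dtype=np.int64)
    chroms = table.df["chrom"].to_numpy()
    pos = table.df["pos"].to_numpy()
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for b, (c, s, e) in enumerate(blocks):
        by_chrom.setdefault(c, []).append((s, e, b))
    for c, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _, _ in ivs])
        ends = np.array([e for _, e, _ in ivs])
        ids = np.array([b for _, _, b in ivs])
        sel = np.flatnonzero(chroms == c)
        j = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (j >= 0) & (pos[sel] < ends[np.clip(j, 0, None)])
        idx[sel[ok]] = ids[j[ok]]
    return idx


def _accumulate_counts(
    table: DatedMutationTable,
    shared_w: np.ndarray,
    notshared_w: np.ndarray,
    grid: TimeGrid,
    t0: float,
    blocks: list[tuple[str, int, int]],
    drop_shared_singletons: bool = False,
    generation_time: float | None = None,
) -> SharingCounts:
    """Bin per-site shared/not-shared weights into block x bin counts.

    Shared weight on singleton mutations (carrier_count == 1) is routed to
    the per-block singleton list for age re-tilting during EM (or dropped
    when requested); its uniform-age binning would understate its age.
    """
    gt = generation_time if generation_time is not None else table.generation_time
    bidx = _block_index(table, blocks)
    lower, upper = table.age_lower, table.age_upper
    keep = bidx >= 0
    mass, _ = _bin_mass_batch(lower, upper, grid, t0)
    consistent = mass.sum(axis=1) > 0
    n_inconsistent = int(np.sum(keep & ~consistent & ((shared_w > 0) | (notshared_w > 0))))
    use = keep & consistent
    singleton = table.is_singleton & (shared_w > 0)

    nb = len(blocks)
    shared = np.zeros((nb, grid.n_bins))
    notshared = np.zeros((nb, grid.n_bins))
    for b in range(grid.n_bins):
        m = mass[:, b]
        sel = use & (m > 0)
        if not np.any(sel):
            continue
        shared[:, b] += np.bincount(
            bidx[sel], weights=shared_w[sel] * m[sel] * ~singleton[sel], minlength=nb
        )
        notshared[:, b] += np.bincount(
            bidx[sel], weights=notshared_w[sel] * m[sel], minlength=nb
        )
    singletons = None
    if not drop_shared_singletons:
        singletons = []
        for b in range(nb):
            sel = use & singleton & (bidx == b)
            singletons.append(
                np.column_stack([lower[sel], upper[sel], shared_w[sel]])
            )
    return SharingCounts(
        grid=grid,
        t0=t0,
        blocks=blocks,
        shared=shared,
        notshared=notshared,
        singletons=singletons,
        generation_time=gt,
        n_inconsistent=n_inconsistent,
    )


def _prepare_table(
    table: DatedMutationTable,
    transversions_only: bool,
    masks: list[GenomicMask | None],
) -> tuple[DatedMutationTable, np.ndarray]:
    keep = np.ones(len(table), dtype=bool)
    if transversions_only:
        keep &= table.is_transversion
    for mask in masks:
        if mask is None:
            continue
        for chrom in table.df["chrom"].unique():
            sel = (table.df["chrom"] == chrom).to_numpy()
            keep[sel] &= mask.contains(chrom, table.df["pos"].to_numpy()[sel])
    return table.subset(keep), keep


def _default_blocks(table: DatedMutationTable, block_size: int):
    lengths = table.df.groupby("chrom", sort=True)["pos"].max().to_dict()
    return make_blocks({c: int(p) for c, p in lengths.items()}, block_size)


def genotype_observations(
    table: DatedMutationTable,
    target_gts: np.ndarray,
    reference_gts: np.ndarray | None,
    grid: TimeGrid,
    mode: str = "cross",
    t_target: float = 0.0,
    t_reference: float = 0.0,
    seed: int | None = None,
    blocks: list[tuple[str, int, int]] | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    ploidy: int = 2,
    transversions_only: bool = False,
    target_mask: GenomicMask | None = None,
    reference_mask: GenomicMask | None = None,
    drop_shared_singletons: bool = False,
) -> SharingCounts:
    """Sharing counts from unphased genotype dosages at the table's sites.

    ``target_gts``/``reference_gts`` are derived-allele dosages aligned to
    table rows, shape ``(n_sites,)`` or ``(n_sites, n_individuals)``, with
    NaN marking missing genotypes.  In ``cross`` mode every carried derived
    copy in the reference is compared against every target chromosome:
    shared weight ``w_r * (target derived copies)``, not-shared weight
    ``w_r * (target ancestral copies)`` — multiplication over chromosomes
    needs no phase.  In ``within`` mode (single diploid individual,
    ``target_gts`` only) each heterozygous site assigns one allele to each
    category uniformly at random (seeded); homozygous-derived sites
    contribute one carried copy on each side.
    """
    table, kept = _prepare_table(table, transversions_only, [target_mask, reference_mask])
    if blocks is None:
        blocks = _default_blocks(table, block_size)
    t0 = max(t_target, t_reference)
    n = len(table)

    def _as2d(g):
        g = np.asarray(g, dtype=float)
        return g[:, None] if g.ndim == 1 else g

    if mode == "cross":
        if reference_gts is None:
            raise ValueError("cross mode needs reference genotypes")
        tg = _as2d(target_gts)[kept]
        rg = _as2d(reference_gts)[kept]
        for g in (tg, rg):
            vals = g[~np.isnan(g)]
            if np.any((vals < 0) | (vals > ploidy) | (vals != np.round(vals))):
                raise ValueError(f"dosages must be in 0..{ploidy} or NaN")
        w_r = np.nansum(rg, axis=1)
        der_t = np.nansum(tg, axis=1)
        anc_t = np.sum(~np.isnan(tg), axis=1) * ploidy - der_t
        shared_w = w_r * der_t
        notshared_w = w_r * anc_t
    elif mode == "within":
        g = np.asarray(target_gts, dtype=float)[kept]
        if g.ndim != 1:
            raise ValueError("within mode expects a single individual's dosages")
        rng = np.random.default_rng(seed)
        het = g == 1
        to_reference = np.zeros(n, dtype=bool)
        to_reference[het] = rng.random(int(het.sum())) < 0.5
        shared_w = np.where(g == 2, 1.0, 0.0)
        notshared_w = np.where(het & to_reference, 1.0, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return _accumulate_counts(
        table, shared_w, notshared_w, grid, t0, blocks,
        drop_shared_singletons=drop_shared_singletons,
    )


@dataclass
class Pileup:
    """Flat per-read records at dated sites.

    ``site_index`` maps each read to a row of the mutation table the pileup
    was extracted against; remaining arrays are per-read fields.
    """

    site_index: np.ndarray
    base: np.ndarray  # unicode '<U1'
    mapping_quality: np.ndarray
    read_length: np.ndarray
    mismatch_count: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.site_index = np.asarray(self.site_index, dtype=np.int64)
        self.base = np.asarray(self.base, dtype="U1")

    def passing(self, filters: ReadFilter | None = None) -> np.ndarray:
        f = filters or ReadFilter()
        return (
            (self.mapping_quality > f.min_mapping_quality)
            & (self.read_length > f.min_read_length)
            & (self.mismatch_count < f.max_mismatches)
            & (self.offset >= f.end_trim)
        )


def _pileup_site_stats(
    pileup: Pileup,
    table: DatedMutationTable,
    filters: ReadFilter | None,
    max_reads_per_site: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_derived, n_ancestral, n_distinct_alleles) per table site from
    passing reads, optionally keeping only the first ``max_reads_per_site``
    passing reads at each site."""
    n = len(table)
    ok = pileup.passing(filters)
    sidx = pileup.site_index[ok]
    base = pileup.base[ok]
    if max_reads_per_site is not None and sidx.size:
        order = np.argsort(sidx, kind="stable")
        s_sorted = sidx[order]
        new_group = np.concatenate([[True], np.diff(s_sorted) > 0])
        starts = np.flatnonzero(new_group)
        sizes = np.diff(np.append(starts, s_sorted.size))
        rank = np.arange(s_sorted.size) - np.repeat(starts, sizes)
        keep = np.zeros(sidx.size, dtype=bool)
        keep[order[rank < max_reads_per_site]] = True
        sidx, base = sidx[keep], base[keep]
    anc = table.df["anc"].to_numpy(dtype="U1")
    der = table.df["der"].to_numpy(dtype="U1")
    n_der = np.bincount(sidx[base == der[sidx]], minlength=n).astype(float)
    n_anc = np.bincount(sidx[base == anc[sidx]], minlength=n).astype(float)
    distinct = np.zeros(n)
    for b in "ACGT":
        distinct += np.bincount(sidx[base == b], minlength=n) > 0
    return n_der, n_anc, distinct


def read_observations(
    table: DatedMutationTable,
    target_pileup: Pileup,
    reference: Pileup | np.ndarray,
    grid: TimeGrid,
    t_target: float = 0.0,
    t_reference: float = 0.0,
    filters: ReadFilter | None = None,
    blocks: list[tuple[str, int, int]] | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    transversions_only: bool = False,
    target_mask: GenomicMask | None = None,
    reference_mask: GenomicMask | None = None,
    drop_shared_singletons: bool = False,
    max_reads_per_site: int | None = None,
) -> SharingCounts:
    """Sharing counts from a target read pileup.

    ``reference`` is either a pileup (carried-copy weight per site = number
    of derived-supporting passing reads) or a genotype dosage array (weight
    = summed derived dosage).  Each passing target read matching the derived
    allele adds ``w_r`` shared weight, matching the ancestral allele adds
    ``w_r`` not-shared weight; reads with any other base are skipped, and a
    site showing more than two distinct alleles is skipped entirely.
    Multiplying across reads treats overlapping reads as independent, which
    overweights deep sites; ``max_reads_per_site`` optionally caps the reads
    used per site (default: no cap).
    """
    full_n = len(table)
    table_f, kept = _prepare_table(
        table, transversions_only, [target_mask, reference_mask]
    )
    if blocks is None:
        blocks = _default_blocks(table_f, block_size)
    t0 = max(t_target, t_reference)

    n_der_t, n_anc_t, distinct_t = _pileup_site_stats(
        target_pileup, table, filters, max_reads_per_site
    )
    if isinstance(reference, Pileup):
        w_r, _, distinct_r = _pileup_site_stats(
            reference, table, filters, max_reads_per_site
        )
        biallelic = (distinct_t <= 2) & (distinct_r <= 2)
    else:
        rg = np.asarray(reference, dtype=float)
        rg = rg[:, None] if rg.ndim == 1 else rg
        w_r = np.nansum(rg, axis=1)
        biallelic = distinct_t <= 2
    shared_w = np.where(biallelic, w_r * n_der_t, 0.0)
    notshared_w = np.where(biallelic, w_r * n_anc_t, 0.0)
    if full_n and np.any(~biallelic):
        logger.debug("skipped %d sites with >2 observed alleles", int((~biallelic).sum()))
    return _accumulate_counts(
        table_f, shared_w[kept], notshared_w[kept], grid, t0, blocks,
        drop_shared_singletons=drop_shared_singletons,
    )
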