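"""Synthetic data with known ground truth for every pipeline stage.

The built-in pair simulator is self-contained: it draws a pair coalescence
time from a piecewise-exponential, lays Poisson numbers of dated mutations
on the reference-private lineage (not shared) and on the shared ancestral
lineage up to the outgroup cap (shared), and can emit genotypes and
error-prone read pileups at arbitrary mean coverage.  Independent segments
emulate free recombination.  A tree-sequence adapter
(:func:`import_tree_sequence`) extracts dated mutations and pairwise
coalescence times from coalescent simulators such as msprime for richer
multi-population tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mutations import DatedMutationTable
from .observations import Pileup, SharingCounts, _accumulate_counts, make_blocks
from .timegrid import DEFAULT_GENERATION_TIME, PiecewiseRate, TimeGrid

__all__ = [
    "PairSimConfig",
    "ReadSimConfig",
    "simulate_pair",
    "simulate_genome",
    "simulate_reads",
    "sample_pair_times",
    "counts_from_truth",
    "import_tree_sequence",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PairSimConfig:
    """Study conditions for one simulated target/reference chromosome pair.

    Defaults mirror the human setting: mutation rate 1.25e-8 per base per
    generation, contemporary samples, exact mutation ages
    (``interval_halfwidth=0``).  ``t_out`` defaults to the rate grid's cap.
    """

    rate: PiecewiseRate
    mu: float = 1.25e-8
    L: int = 1_000_000
    t_target: float = 0.0
    t_reference: float = 0.0
    t_out: float | None = None
    interval_halfwidth: float = 0.0
    seed: int | None = None
    generation_time: float = DEFAULT_GENERATION_TIME

    def __post_init__(self):
        if self.mu <= 0 or self.L <= 0:
            raise ValueError("need mu > 0 and L > 0")
        if self.t_target < 0 or self.t_reference < 0:
            raise ValueError("sample ages must be >= 0")
        if not (0 <= self.interval_halfwidth < 1):
            raise ValueError("interval_halfwidth must be in [0, 1)")
        self.L = int(self.L)
        self.t_out = self.rate.grid.t_out if self.t_out is None else float(self.t_out)


@dataclass
class ReadSimConfig:
    """Sequencing emulation: Poisson depth at ``mean_coverage``, uniform
    base-error rate, fixed read geometry set to filter-passing values."""

    mean_coverage: float = 4.0
    error_rate: float = 0.0
    read_length: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


def sample_pair_times(
    rate: PiecewiseRate, t0: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw coalescence times from the piecewise-exponential with hazard
    λ(t) on ``t >= t0`` by inverting the cumulative hazard.  The final
    epoch's rate is extended beyond the grid cap; a zero final rate leaves
    never-coalescing pairs at +inf."""
    b = rate.grid.boundaries
    u = np.clip(b[:-1], t0, None)
    w = np.clip(b[1:] - u, 0.0, None)
    hazard = rate.rates * w
    cumH = np.concatenate([[0.0], np.cumsum(hazard)])
    target = rng.exponential(size=n)
    T = np.full(n, np.inf)
    inside = target < cumH[-1]
    if np.any(inside):
        e = np.searchsorted(cumH, target[inside], side="right") - 1
        T[inside] = u[e] + (target[inside] - cumH[e]) / rate.rates[e]
    beyond = ~inside
    if np.any(beyond) and rate.rates[-1] > 0:
        T[beyond] = rate.grid.t_out + (target[beyond] - cumH[-1]) / rate.rates[-1]
    return T


@dataclass
class PairSimResult:
    T: float
    table: DatedMutationTable
    shared: np.ndarray  # truth label per table row


def simulate_pair(
    cfg: PairSimConfig,
    rng: np.random.Generator | None = None,
    chrom: str = "1",
    start: int = 1,
) -> PairSimResult:
    """Simulate one target/reference pair under the infinite-sites model.

    Coalescence time ``T`` starts at ``t0 = max(t_target, t_reference)``.
    Mutations private to the reference lineage number Poisson(μ·L·(T −
    t_reference)) with true ages Uniform(t_reference, T) (not shared);
    ancestral-lineage mutations number Poisson(μ·L·(t_out − T)) with ages
    Uniform(T, t_out) (shared), none when ``T >= t_out``.  Emitted age
    intervals are ``[a(1−h), a(1+h)]`` clipped to ``[0, t_out]`` (``h=0``
    gives exact ages); positions are uniform without collision.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    t0 = max(cfg.t_target, cfg.t_reference)
    T = float(sample_pair_times(cfg.rate, t0, 1, rng)[0])
    T_capped = min(T, cfg.t_out)

    n_priv = rng.poisson(cfg.mu * cfg.L * max(T_capped - cfg.t_reference, 0.0))
    n_shared = rng.poisson(cfg.mu * cfg.L * max(cfg.t_out - T, 0.0))
    ages = np.concatenate(
        [
            rng.uniform(cfg.t_reference, T_capped, n_priv),
            rng.uniform(T, cfg.t_out, n_shared) if n_shared else np.empty(0),
        ]
    )
    shared = np.concatenate(
        [np.zeros(n_priv, dtype=bool), np.ones(n_shared, dtype=bool)]
    )
    n = ages.size
    pos = start + rng.choice(cfg.L, size=n, replace=False)
    h = cfg.interval_halfwidth
    lower = np.clip(ages * (1 - h), 0.0, cfg.t_out)
    upper = np.clip(ages * (1 + h), 0.0, cfg.t_out)
    anc_idx = rng.integers(0, 4, n)
    der_idx = (anc_idx + rng.integers(1, 4, n)) % 4
    gt = cfg.generation_time
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "anc": _BASES[anc_idx],
            "der": _BASES[der_idx],
            "age_lower_years": lower * gt,
            "age_upper_years": upper * gt,
            "carrier_count": 2,
            "is_fixed": False,
            "left_base": _BASES[rng.integers(0, 4, n)],
            "right_base": _BASES[rng.integers(0, 4, n)],
        }
    )
    order = np.argsort(pos, kind="mergesort")
    table = DatedMutationTable(
        df.iloc[order],
        t_out_years=cfg.t_out * gt,
        generation_time=gt,
        source="agecoal pair simulator",
    )
    return PairSimResult(T=T, table=table, shared=shared[order])


@dataclass
class GenomeSimResult:
    table: DatedMutationTable
    shared: np.ndarray
    segment_times: np.ndarray
    chrom_length: int
    t0: float


def simulate_genome(
    cfg: PairSimConfig,
    n_segments: int,
    chrom: str = "1",
) -> GenomeSimResult:
    """Tile ``n_segments`` independent pair coalescences along one
    chromosome (segment length ``cfg.L``), emulating free recombination
    between segments.  Same per-segment model as :func:`simulate_pair`,
    drawn in bulk; rare position collisions within a segment are dropped
    (infinite sites).  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    t0 = max(cfg.t_target, cfg.t_reference)
    T = sample_pair_times(cfg.rate, t0, n_segments, rng)
    Tc = np.minimum(T, cfg.t_out)
    n_priv = rng.poisson(cfg.mu * cfg.L * np.maximum(Tc - cfg.t_reference, 0.0))
    n_shared = rng.poisson(cfg.mu * cfg.L * np.maximum(cfg.t_out - T, 0.0))

    def _ages(lo: np.ndarray, hi: np.ndarray, n: np.ndarray) -> np.ndarray:
        return rng.uniform(np.repeat(lo, n), np.repeat(hi, n))

    seg = np.concatenate(
        [np.repeat(np.arange(n_segments), n_priv),
         np.repeat(np.arange(n_segments), n_shared)]
    )
    ages = np.concatenate(
        [_ages(np.full(n_segments, float(cfg.t_reference)), Tc, n_priv),
         _ages(Tc, np.full(n_segments, cfg.t_out), n_shared)]
    )
    shared = np.concatenate(
        [np.zeros(n_priv.sum(), dtype=bool), np.ones(n_shared.sum(), dtype=bool)]
    )
    pos = 1 + seg * cfg.L + rng.integers(0, cfg.L, seg.size)
    order = np.argsort(pos, kind="mergesort")
    keep = np.concatenate([[True], np.diff(pos[order]) > 0])
    order = order[keep]
    ages, shared, pos = ages[order], shared[order], pos[order]

    n = ages.size
    h = cfg.interval_halfwidth
    anc_idx = rng.integers(0, 4, n)
    der_idx = (anc_idx + rng.integers(1, 4, n)) % 4
    gt = cfg.generation_time
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "anc": _BASES[anc_idx],
            "der": _BASES[der_idx],
            "age_lower_years": np.clip(ages * (1 - h), 0.0, cfg.t_out) * gt,
            "age_upper_years": np.clip(ages * (1 + h), 0.0, cfg.t_out) * gt,
            "carrier_count": 2,
            "is_fixed": False,
            "left_base": _BASES[rng.integers(0, 4, n)],
            "right_base": _BASES[rng.integers(0, 4, n)],
        }
    )
    table = DatedMutationTable(
        df,
        t_out_years=cfg.t_out * gt,
        generation_time=gt,
        source="agecoal genome simulator",
    )
    return GenomeSimResult(
        table=table,
        shared=shared,
        segment_times=T,
        chrom_length=n_segments * cfg.L,
        t0=t0,
    )


def counts_from_truth(
    sim: GenomeSimResult,
    grid: TimeGrid,
    block_size: int = 20_000_000,
) -> SharingCounts:
    """Sharing counts from perfectly observed haploid sharing labels
    (weight 1 per mutation), the noise-free end of the pipeline."""
    blocks = make_blocks({sim.table.df["chrom"].iloc[0]: sim.chrom_length}, block_size)
    shared_w = sim.shared.astype(float)
    return _accumulate_counts(
        sim.table, shared_w, 1.0 - shared_w, grid, sim.t0, blocks
    )


def genotypes_from_truth(sim: GenomeSimResult, ploidy: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Homozygous diploid dosages implied by the haploid truth labels:
    reference carries every table mutation (dosage ``ploidy``), the target
    carries the shared ones."""
    ref = np.full(len(sim.table), float(ploidy))
    tgt = np.where(sim.shared, float(ploidy), 0.0)
    return tgt, ref


def simulate_reads(
    genotypes: np.ndarray,
    cfg: ReadSimConfig,
    rng: np.random.Generator | None = None,
    anc: np.ndarray | None = None,
    der: np.ndarray | None = None,
    ploidy: int = 2,
) -> Pileup:
    """Emulate reference-aligned reads at dated sites.

    ``genotypes`` are derived dosages per site (0..ploidy).  Per site the
    depth is Poisson(mean_coverage); each read samples one of the
    individual's alleles uniformly and is flipped to a uniformly chosen
    different base with probability ``error_rate``.  Read geometry fields
    are set to filter-passing values.  Deterministic given the RNG.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    g = np.asarray(genotypes, dtype=float)
    n_sites = g.size
    depth = rng.poisson(cfg.mean_coverage, n_sites)
    site_idx = np.repeat(np.arange(n_sites), depth)
    n_reads = site_idx.size
    derived = rng.random(n_reads) < (g[site_idx] / ploidy)
    if anc is None:
        anc = np.full(n_sites, "A")
    if der is None:
        der = np.full(n_sites, "G")
    base = np.where(derived, np.asarray(der, dtype="U1")[site_idx],
                    np.asarray(anc, dtype="U1")[site_idx]).astype("U1")
    if cfg.error_rate > 0:
        err = rng.random(n_reads) < cfg.error_rate
        if np.any(err):
            base_idx = np.searchsorted(_BASES, base[err])
            shift = rng.integers(1, 4, int(err.sum()))
            base[err] = _BASES[(base_idx + shift) % 4]
    return Pileup(
        site_index=site_idx,
        base=base,
        mapping_quality=np.full(n_reads, 60),
        read_length=np.full(n_reads, cfg.read_length),
        mismatch_count=np.zeros(n_reads, dtype=int),
        offset=np.full(n_reads, cfg.read_length // 2),
    )


def import_tree_sequence(
    ts,
    pairs: list[tuple[int, int]],
    generation_time: float = DEFAULT_GENERATION_TIME,
    t_out: float | None = None,
    chrom: str = "1",
):
    """Extract dated mutations and pairwise coalescence times from a tree
    sequence with dated nodes (e.g. msprime output).

    Each mapped mutation yields the age interval [time of the node below,
    time of the node above the branch] in generations and a carrier count
    from the number of samples below; unmapped or undated mutations are
    skipped and counted.  For every requested sample pair the per-tree
    TMRCA is returned with its genomic span weight, suitable for
    :func:`agecoal.em.direct_mle_from_times`.

    Returns ``(table, pair_times, n_skipped)`` where ``pair_times`` maps
    each pair to ``(times, spans)`` arrays.
    """
    if isinstance(ts, (str, bytes)):
        import tskit

        ts = tskit.load(ts)
    node_time = ts.tables.nodes.time
    rows = []
    n_skipped = 0
    for tree in ts.trees():
        for site in tree.sites():
            if len(site.mutations) != 1:
                n_skipped += len(site.mutations)
                continue
            mut = site.mutations[0]
            node = mut.node
            parent = tree.parent(node)
            if parent == -1:
                n_skipped += 1
                continue
            lo, hi = float(node_time[node]), float(node_time[parent])
            if not np.isfinite(hi) or hi <= 0:
                n_skipped += 1
                continue
            rows.append(
                (
                    int(site.position) + 1,
                    site.ancestral_state,
                    mut.derived_state,
                    lo,
                    hi,
                    tree.num_samples(node),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["pos", "anc", "der", "age_lower", "age_upper", "carrier_count"],
    )
    df = df.drop_duplicates(subset="pos", keep="first")
    cap = float(node_time.max()) if t_out is None else float(t_out)
    df["age_upper"] = df["age_upper"].clip(upper=cap)
    df["age_lower"] = df["age_lower"].clip(upper=cap)
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": df["pos"].astype(np.int64),
            "anc": df["anc"],
            "der": df["der"],
            "age_lower_years": df["age_lower"] * generation_time,
            "age_upper_years": df["age_upper"] * generation_time,
            "carrier_count": df["carrier_count"].astype(np.int64),
            "is_fixed": False,
        }
    )
    table = DatedMutationTable(
        out,
        t_out_years=cap * generation_time,
        generation_time=generation_time,
        source="tree-sequence import",
    )
    pair_times = {}
    for u, v in pairs:
        times, spans = [], []
        for tree in ts.trees():
            times.append(tree.tmrca(u, v))
            spans.append(tree.span)
        pair_times[(u, v)] = (np.asarray(times), np.asarray(spans))
    return table, pair_times, n_skipped
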