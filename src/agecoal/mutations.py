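"""Dated-mutation tables: the anchor for all sharing observations.

A dated mutation is a polarized variant (ancestral → derived) whose age is
known only up to the branch of a genome-wide genealogy it maps onto: its
true age is modelled as uniform on ``[age_lower, age_upper]``.  Tables are
stored as a TSV dialect ("agecoal-mut v1") with ages in years; internally
ages are exposed in generations.

Fixed sites — derived in every sample of the dating genealogy — must also
be included, because target/reference lineages can coalesce into the root
branch; their age is capped at the TMRCA to an outgroup (``t_out``).
:func:`augment_fixed_sites` adds such sites to a table with Poisson counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

from .timegrid import DEFAULT_GENERATION_TIME, DEFAULT_T_OUT_YEARS

__all__ = [
    "DatedMutationTable",
    "read_mutation_table",
    "write_mutation_table",
    "augment_fixed_sites",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = [
    "chrom",
    "pos",
    "anc",
    "der",
    "age_lower_years",
    "age_upper_years",
    "carrier_count",
    "is_fixed",
]
_OPTIONAL_COLUMNS = ["left_base", "right_base", "is_terminal"]
_BASES = ("A", "C", "G", "T")


@dataclass
class DatedMutationTable:
    """Sorted collection of dated, polarized mutations.

    Backed by a :class:`pandas.DataFrame` with columns ``chrom, pos, anc,
    der, age_lower_years, age_upper_years, carrier_count, is_fixed`` and
    optionally ``left_base, right_base`` (flanking ancestral bases) and
    ``is_terminal`` (mutation maps to a terminal branch).

    Invariants: sorted by (chrom, pos); positions unique per chromosome
    (two-state / infinite-sites assumption); ``0 <= age_lower <= age_upper
    <= t_out``; fixed sites have ``age_upper == t_out``.  A point age
    (``age_lower == age_upper``) represents an exactly dated mutation.
    """

    df: pd.DataFrame
    t_out_years: float = DEFAULT_T_OUT_YEARS
    generation_time: float = DEFAULT_GENERATION_TIME
    source: str = ""

    def __post_init__(self):
        df = self.df
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(subset=["chrom", "pos"]).any():
            dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
            raise ValueError(
                f"duplicate position {dup['chrom']}:{dup['pos']} violates the "
                "two-state (infinite-sites) assumption"
            )
        lo = df["age_lower_years"].to_numpy(float)
        hi = df["age_upper_years"].to_numpy(float)
        if np.any(lo < 0) or np.any(lo > hi):
            raise ValueError("need 0 <= age_lower <= age_upper")
        if np.any(hi > self.t_out_years * (1 + 1e-9)):
            raise ValueError("age_upper exceeds t_out")
        bad = ~(df["anc"].isin(_BASES) & df["der"].isin(_BASES))
        if bad.any() or (df["anc"] == df["der"]).any():
            raise ValueError("alleles must be distinct bases in {A,C,G,T}")
        fixed = df["is_fixed"].to_numpy(bool)
        off = fixed & (hi != self.t_out_years)
        if off.any():
            warnings.warn(
                f"{off.sum()} fixed sites had age_upper != t_out; overwritten"
            )
            df.loc[off, "age_upper_years"] = self.t_out_years
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    # -- generation-denominated views ------------------------------------
    @property
    def age_lower(self) -> np.ndarray:
        return self.df["age_lower_years"].to_numpy(float) / self.generation_time

    @property
    def age_upper(self) -> np.ndarray:
        return self.df["age_upper_years"].to_numpy(float) / self.generation_time

    @property
    def t_out(self) -> float:
        return self.t_out_years / self.generation_time

    @property
    def is_singleton(self) -> np.ndarray:
        return self.df["carrier_count"].to_numpy(int) == 1

    @property
    def is_transversion(self) -> np.ndarray:
        """True where the allele pair is a purine<->pyrimidine change."""
        pair = self.df["anc"] + self.df["der"]
        transitions = {"AG", "GA", "CT", "TC"}
        return ~pair.isin(transitions).to_numpy()

    def subset(self, mask: np.ndarray) -> "DatedMutationTable":
        return DatedMutationTable(
            self.df[mask].reset_index(drop=True),
            t_out_years=self.t_out_years,
            generation_time=self.generation_time,
            source=self.source,
        )


def read_mutation_table(
    path_or_stream,
    generation_time: float = DEFAULT_GENERATION_TIME,
    t_out_years: float = DEFAULT_T_OUT_YEARS,
) -> DatedMutationTable:
    """Read an agecoal-mut v1 TSV (tab-separated, '#'-prefixed header row,
    ages in years).

    Rows with ``age_lower > age_upper`` are rejected with a logged warning;
    malformed rows raise with the offending line number; duplicate positions
    raise (infinite-sites violation).
    """
    close = False
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
        fh: IO[str] = open(path_or_stream)
        close = True
    else:
        fh = path_or_stream
    try:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("agecoal-mut header row must start with '#'")
        columns = header.lstrip("#").strip().split("\t")
        missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
        if missing:
            raise ValueError(f"header missing required columns: {missing}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"line {lineno}: expected {len(columns)} fields, got {len(fields)}"
                )
            rows.append(fields)
    finally:
        if close:
            fh.close()

    df = pd.DataFrame(rows, columns=columns)
    try:
        df["pos"] = df["pos"].astype(np.int64)
        df["age_lower_years"] = df["age_lower_years"].astype(float)
        df["age_upper_years"] = df["age_upper_years"].astype(float)
        df["carrier_count"] = df["carrier_count"].astype(np.int64)
        df["is_fixed"] = df["is_fixed"].astype(np.int64).astype(bool)
        if "is_terminal" in df.columns:
            df["is_terminal"] = df["is_terminal"].astype(np.int64).astype(bool)
    except ValueError as exc:
        raise ValueError(f"malformed numeric field: {exc}") from exc

    bad = df["age_lower_years"] > df["age_upper_years"]
    if bad.any():
        logger.warning(
            "rejected %d rows with age_lower > age_upper", int(bad.sum())
        )
        df = df[~bad].reset_index(drop=True)
    return DatedMutationTable(
        df, t_out_years=t_out_years, generation_time=generation_time
    )


def write_mutation_table(table: DatedMutationTable, path_or_stream) -> None:
    """Write agecoal-mut v1 TSV.  Float ages use shortest-round-trip
    formatting so that write-then-read reproduces the table bit-identically."""
    close = False
    if isinstance(path_or_stream, (str, bytes)) or hasattr(path_or_stream, "__fspath__"):
        fh: IO[str] = open(path_or_stream, "w")
        close = True
    else:
        fh = path_or_stream
    try:
        cols = [c for c in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS if c in table.df.columns]
        fh.write("#" + "\t".join(cols) + "\n")
        for row in table.df[cols].itertuples(index=False):
            out = []
            for col, val in zip(cols, row):
                if col in ("age_lower_years", "age_upper_years"):
                    out.append(repr(float(val)))
                elif col in ("is_fixed", "is_terminal"):
                    out.append(str(int(val)))
                else:
                    out.append(str(val))
            fh.write("\t".join(out) + "\n")
    finally:
        if close:
            fh.close()


def augment_fixed_sites(
    table: DatedMutationTable,
    mu: float,
    region: tuple[str, int, int, float],
    seed: int,
    t_out: float | None = None,
    carrier_count: int = 2,
) -> DatedMutationTable:
    """Append fixed derived sites for a genomic region.

    The number of fixed mutations in a region of ``l`` base pairs whose
    sample TMRCA is ``t_sample`` is Poisson with mean ``mu * l *
    (t_out - t_sample)`` — all times in generations, ``mu`` per base per
    generation.  If ``t_sample >= t_out`` no fixed mutations are added.
    Positions are drawn uniformly at random with replacement and repeat
    draws are collapsed to a single record (two-state model: the state is
    observed derived either way); positions colliding with existing records
    are likewise skipped.

    ``region`` is ``(chrom, start, end, t_sample)`` with 1-based inclusive
    ``start``, exclusive ``end`` and ``t_sample`` in generations.
    Deterministic given ``seed``.
    """
    chrom, start, end, t_sample = region
    length = end - start
    if mu <= 0 or length <= 0:
        raise ValueError("need mu > 0 and a non-empty region")
    t_out = table.t_out if t_out is None else t_out
    rng = np.random.default_rng(seed)
    if t_sample >= t_out:
        return table
    n = rng.poisson(mu * length * (t_out - t_sample))
    if n == 0:
        return table
    pos = np.unique(rng.integers(start, end, size=n))
    existing = table.df.loc[table.df["chrom"] == chrom, "pos"].to_numpy()
    pos = pos[~np.isin(pos, existing)]
    anc = rng.choice(list(_BASES), size=pos.size)
    shift = rng.integers(1, 4, size=pos.size)
    base_idx = np.array([_BASES.index(b) for b in anc])
    der = np.array(_BASES)[(base_idx + shift) % 4]
    gt = table.generation_time
    new = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "anc": anc,
            "der": der,
            "age_lower_years": t_sample * gt,
            "age_upper_years": t_out * gt,
            "carrier_count": carrier_count,
            "is_fixed": True,
        }
    )
    for col in _OPTIONAL_COLUMNS:
        if col in table.df.columns:
            if col == "is_terminal":
                new[col] = False
            else:
                new[col] = rng.choice(list(_BASES), size=pos.size)
    df = pd.concat([table.df, new], ignore_index=True)
    return DatedMutationTable(
        df,
        t_out_years=table.t_out_years,
        generation_time=table.generation_time,
        source=table.source,
    )
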