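"""Readers for the standard genomic formats the pipeline consumes.

VCF genotypes are read with cyvcf2, reference-aligned reads (SAM/BAM/CRAM)
with pysam, accessibility masks as BED.  All readers align their output to
the rows of a :class:`~agecoal.mutations.DatedMutationTable`, which is the
coordinate frame of every downstream computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mutations import DatedMutationTable
from .observations import GenomicMask, Pileup

__all__ = [
    "read_bed_mask",
    "write_bed_mask",
    "read_genotypes_vcf",
    "pileup_from_alignments",
    "write_vcf",
]


def read_bed_mask(path) -> GenomicMask:
    """BED accessibility mask (0-based half-open intervals)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    intervals: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in df.itertuples(index=False):
        intervals.setdefault(chrom, []).append((int(start), int(end)))
    return GenomicMask(intervals)


def write_bed_mask(intervals: dict[str, list[tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_genotypes_vcf(
    path, table: DatedMutationTable, samples: list[str] | None = None
) -> np.ndarray:
    """Derived-allele dosages at the table's sites from a VCF/BCF.

    Returns an ``(n_sites, n_samples)`` float array with NaN for missing
    genotypes and for table sites absent from the VCF.  Sites whose VCF
    alleles cannot be oriented to the table's ancestral/derived pair are
    left missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), samples=samples)
    n_samples = len(vcf.samples)
    key_to_row = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(table.df["chrom"], table.df["pos"]))
    }
    out = np.full((len(table), n_samples), np.nan)
    anc = table.df["anc"].to_numpy()
    der = table.df["der"].to_numpy()
    for var in vcf:
        row = key_to_row.get((var.CHROM, var.POS))
        if row is None or len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if {ref, alt} != {anc[row], der[row]}:
            continue
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan  # missing calls
        derived = gts == (1.0 if alt == der[row] else 0.0)
        dosage = np.where(np.isnan(gts), np.nan, derived.astype(float)).sum(axis=1)
        out[row] = dosage
    return out


def pileup_from_alignments(path, table: DatedMutationTable, mode: str = "r") -> Pileup:
    """Extract a per-site read pileup at the table's sites from a SAM/BAM.

    Iterates reads (no index required), records the base each read carries
    at every overlapping table site, together with the filter-relevant
    fields: mapping quality, read length, mismatch count (NM tag, 0 when
    absent) and the distance of the site from the nearer read end.
    """
    import pysam

    sites: dict[str, dict[int, int]] = {}
    for i, (c, p) in enumerate(zip(table.df["chrom"], table.df["pos"])):
        sites.setdefault(str(c), {})[int(p)] = i
    cols: dict[str, list] = {
        "site_index": [], "base": [], "mapping_quality": [],
        "read_length": [], "mismatch_count": [], "offset": [],
    }
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            chrom_sites = sites.get(read.reference_name)
            if not chrom_sites:
                continue
            nm = read.get_tag("NM") if read.has_tag("NM") else 0
            rlen = read.query_length
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                row = chrom_sites.get(rpos + 1)  # SAM pos is 0-based here
                if row is None:
                    continue
                cols["site_index"].append(row)
                cols["base"].append(read.query_sequence[qpos].upper())
                cols["mapping_quality"].append(read.mapping_quality)
                cols["read_length"].append(rlen)
                cols["mismatch_count"].append(nm)
                cols["offset"].append(min(qpos, rlen - 1 - qpos))
    return Pileup(
        site_index=np.asarray(cols["site_index"], dtype=np.int64),
        base=np.asarray(cols["base"], dtype="U1"),
        mapping_quality=np.asarray(cols["mapping_quality"], dtype=int),
        read_length=np.asarray(cols["read_length"], dtype=int),
        mismatch_count=np.asarray(cols["mismatch_count"], dtype=int),
        offset=np.asarray(cols["offset"], dtype=int),
    )


def write_vcf(
    table: DatedMutationTable,
    dosages: np.ndarray,
    sample_names: list[str],
    path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write unphased diploid genotypes (derived dosage 0/1/2, NaN missing)
    as a minimal VCF, with the ancestral base as REF."""
    dosages = np.asarray(dosages, float)
    dosages = dosages[:, None] if dosages.ndim == 1 else dosages
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        df = table.df
        for i, row in enumerate(df.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[float(d)] for d in dosages[i]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.anc}\t{row.der}\t.\tPASS\t.\tGT\t{gts}\n"
            )
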