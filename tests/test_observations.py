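import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agecoal import (
    DatedMutationTable,
    GenomicMask,
    Pileup,
    ReadRecord,
    SharingCounts,
    TimeGrid,
    bin_mutation_mass,
    build_coverage_mask,
    filter_read,
    genotype_observations,
    make_blocks,
    polarize_alleles,
    read_observations,
)


def table_from(pos, lo, hi, carrier=2, anc="C", der="A", chrom="1"):
    n = len(pos)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "anc": [anc] * n if isinstance(anc, str) else anc,
            "der": [der] * n if isinstance(der, str) else der,
            "age_lower_years": np.asarray(lo, float) * 28.0,
            "age_upper_years": np.asarray(hi, float) * 28.0,
            "carrier_count": carrier,
            "is_fixed": False,
        }
    )
    return DatedMutationTable(df)


class TestPolarize:
    @pytest.mark.parametrize(
        "ref,alt,anc,expected",
        [
            ("C", "T", "C", ("C", "T")),
            ("C", "T", "T", ("T", "C")),
            ("C", "T", "N", None),
            ("C", "T", "G", None),
        ],
    )
    def test_orientation(self, ref, alt, anc, expected):
        assert polarize_alleles(ref, alt, anc) == expected


class TestReadFilter:
    @pytest.mark.parametrize(
        "mq,length,mm,offset,expected",
        [
            (30, 50, 0, 10, False),  # MQ threshold is strict
            (31, 35, 2, 2, True),
            (60, 100, 3, 10, False),  # fewer than three mismatches
            (60, 34, 0, 10, False),  # length strictly above 34
            (60, 100, 0, 1, False),  # 2 bp end trim
        ],
    )
    def test_thresholds(self, mq, length, mm, offset, expected):
        r = ReadRecord(mq, length, mm, "A", offset)
        assert filter_read(r) is expected


class TestCoverageMask:
    def test_thresholds(self):
        depth = np.array([4, 5, 10, 19, 20, 25, 5])
        intervals = build_coverage_mask(depth, mean_coverage=10.0)
        # pass iff depth >= 5 and depth < 20
        assert intervals == [(1, 4), (6, 7)]

    def test_mask_membership(self):
        mask = GenomicMask({"1": [(10, 20), (15, 30)]})  # merges to (10, 30)
        pos = np.array([10, 11, 30, 31])  # 1-based
        np.testing.assert_array_equal(
            mask.contains("1", pos), [False, True, True, False]
        )
        assert not mask.contains("2", np.array([15]))[0]


class TestBinMutationMass:
    def test_split_across_bins(self):
        grid = TimeGrid(np.array([0.0, 200.0, 400.0, 600.0]))
        w = bin_mutation_mass(100.0, 300.0, grid)
        np.testing.assert_allclose(w, [0.5, 0.5, 0.0])

    def test_inside_one_bin(self):
        grid = TimeGrid(np.array([0.0, 200.0, 400.0]))
        np.testing.assert_allclose(bin_mutation_mass(210.0, 290.0, grid), [0, 1])

    def test_clamped_to_t0(self):
        grid = TimeGrid(np.array([0.0, 200.0, 400.0]))
        w = bin_mutation_mass(100.0, 300.0, grid, t0=150.0)
        np.testing.assert_allclose(w, [1 / 3, 2 / 3])

    def test_interval_below_t0_is_flagged_empty(self):
        grid = TimeGrid(np.array([0.0, 200.0, 400.0]))
        np.testing.assert_allclose(bin_mutation_mass(10.0, 90.0, grid, t0=100.0), [0, 0])

    def test_point_age(self):
        grid = TimeGrid(np.array([0.0, 200.0, 400.0]))
        np.testing.assert_allclose(bin_mutation_mass(250.0, 250.0, grid), [0, 1])

    @given(
        lo=st.floats(0, 500),
        width=st.floats(0.001, 500),
        t0=st.floats(0, 300),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_sums_to_one(self, lo, width, t0):
        grid = TimeGrid(np.array([0.0, 100.0, 250.0, 600.0]))
        hi = min(lo + width, 600.0)
        lo = min(lo, hi)
        w = bin_mutation_mass(lo, hi, grid, t0=t0)
        if hi >= t0:
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
        else:
            assert w.sum() == 0.0


class TestGenotypeObservations:
    grid = TimeGrid(np.array([0.0, 1000.0]))

    def counts(self, tgt, ref, **kw):
        t = table_from([100, 200, 300], [10, 10, 10], [20, 20, 20])
        return genotype_observations(t, np.array(tgt), np.array(ref), self.grid, **kw)

    def test_het_het(self):
        c = self.counts([1, np.nan, np.nan], [1, np.nan, np.nan])
        assert c.total()[0].sum() == 1 and c.total()[1].sum() == 1

    def test_hom_ref_target(self):
        c = self.counts([0, np.nan, np.nan], [2, np.nan, np.nan])
        assert c.total()[0].sum() == 0 and c.total()[1].sum() == 4

    def test_missing_target_contributes_nothing(self):
        # a missing target genotype means no target chromosomes observed
        c = self.counts([np.nan] * 3, [1, 1, 1])
        assert c.total()[0].sum() == 0 and c.total()[1].sum() == 0

    def test_invalid_dosage(self):
        with pytest.raises(ValueError, match="dosage"):
            self.counts([3, 0, 0], [1, 1, 1])

    def test_within_mode_random_split(self):
        t = table_from(np.arange(1, 2001) * 10, [10] * 2000, [20] * 2000)
        c = genotype_observations(
            t, np.array([1.0] * 1000 + [2.0] * 1000), None, self.grid,
            mode="within", seed=0,
        )
        shared, notshared = c.total()
        assert shared.sum() == 1000  # hom-derived sites
        # het sites put the derived allele reference-side half the time
        assert abs(notshared.sum() - 500) < 3 * np.sqrt(250)

    def test_transversions_only_removes_transitions(self):
        t = table_from([100, 200], [10, 10], [20, 20], anc=["C", "C"], der=["T", "A"])
        c = genotype_observations(
            t, np.array([1.0, 1.0]), np.array([1.0, 1.0]), self.grid,
            transversions_only=True,
        )
        assert c.total()[0].sum() == 1  # only the C>A site remains

    def test_mask_application(self):
        t = table_from([100, 200], [10, 10], [20, 20])
        mask = GenomicMask({"1": [(150, 250)]})
        c = genotype_observations(
            t, np.array([1.0, 1.0]), np.array([1.0, 1.0]), self.grid,
            target_mask=mask,
        )
        assert c.total()[0].sum() == 1


class TestReadObservations:
    grid = TimeGrid(np.array([0.0, 1000.0]))

    def pileup(self, bases, site=0, mq=60, length=100, mm=0, offset=50):
        n = len(bases)
        return Pileup(
            site_index=np.full(n, site),
            base=np.array(bases),
            mapping_quality=np.full(n, mq),
            read_length=np.full(n, length),
            mismatch_count=np.full(n, mm),
            offset=np.full(n, offset),
        )

    def test_multiply_across_reads(self):
        t = table_from([100], [10], [20])
        c = read_observations(t, self.pileup(["A", "C", "A"]), np.array([1.0]), self.grid)
        shared, notshared = c.total()
        assert shared.sum() == 2 and notshared.sum() == 1

    def test_triallelic_site_skipped(self):
        t = table_from([100], [10], [20])
        c = read_observations(
            t, self.pileup(["A", "C", "G"]), np.array([1.0]), self.grid
        )
        assert c.total()[0].sum() == 0 and c.total()[1].sum() == 0

    def test_third_allele_read_skipped(self):
        t = table_from([100], [10], [20])
        c = read_observations(
            t, self.pileup(["A", "G", "A"]), np.array([1.0]), self.grid
        )
        # two alleles observed (A, G): site kept, G-read ignored
        assert c.total()[0].sum() == 2 and c.total()[1].sum() == 0

    def test_failing_reads_excluded(self):
        t = table_from([100], [10], [20])
        c = read_observations(
            t, self.pileup(["A", "A"], mq=20), np.array([1.0]), self.grid
        )
        assert c.total()[0].sum() == 0

    def test_no_reads_no_counts(self):
        t = table_from([100], [10], [20])
        empty = self.pileup([])
        c = read_observations(t, empty, np.array([2.0]), self.grid)
        assert c.total()[0].sum() == 0 and c.total()[1].sum() == 0

    def test_max_reads_per_site_cap(self):
        t = table_from([100], [10], [20])
        c = read_observations(
            t, self.pileup(["A", "A", "A", "A", "C"]), np.array([1.0]),
            self.grid, max_reads_per_site=3,
        )
        # only the first three reads at the site are used
        assert c.total()[0].sum() + c.total()[1].sum() == 3

    def test_reference_pileup_weighting(self):
        t = table_from([100], [10], [20])
        c = read_observations(
            t, self.pileup(["A", "C"]), self.pileup(["A", "A", "C"]), self.grid
        )
        # w_r = 2 derived-supporting reference reads
        assert c.total()[0].sum() == 2 and c.total()[1].sum() == 2


class TestBlocks:
    def test_blocks_tile_without_overlap(self):
        blocks = make_blocks({"1": 55_000_000}, 20_000_000)
        assert blocks[0] == ("1", 1, 20_000_001)
        assert blocks[-1][2] == 55_000_001
        spans = [(s, e) for _, s, e in blocks]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 == s2

    def test_counts_additive_over_blocks(self):
        rng = np.random.default_rng(0)
        n = 500
        pos = np.sort(rng.choice(10**8, n, replace=False)) + 1
        lo = rng.uniform(0, 5e4, n)
        t = table_from(pos, lo, lo + rng.uniform(1, 1e4, n))
        grid = TimeGrid(np.array([0.0, 1000.0, 10000.0, 400000.0]))
        tgt = rng.integers(0, 3, n).astype(float)
        ref = rng.integers(0, 3, n).astype(float)
        fine = genotype_observations(t, tgt, ref, grid, block_size=20_000_000)
        coarse = genotype_observations(t, tgt, ref, grid, block_size=10**9)
        assert fine.n_blocks > 1 and coarse.n_blocks == 1
        np.testing.assert_allclose(
            fine.total()[0] + _singleton_mass(fine),
            coarse.total()[0] + _singleton_mass(coarse),
        )
        np.testing.assert_allclose(fine.total()[1], coarse.total()[1])

    def test_json_round_trip(self):
        t = table_from([100, 200, 300], [10, 10, 10], [20, 20, 20], carrier=1)
        grid = TimeGrid(np.array([0.0, 1000.0]))
        c = genotype_observations(t, np.array([1.0, 2.0, 0.0]), np.array([1.0, 1.0, 1.0]), grid)
        c2 = SharingCounts.from_json(c.to_json())
        np.testing.assert_allclose(c2.shared, c.shared)
        np.testing.assert_allclose(c2.notshared, c.notshared)
        np.testing.assert_allclose(c2.grid.boundaries, c.grid.boundaries)
        assert c2.blocks == c.blocks
        assert len(c2.singletons) == len(c.singletons)
        for a, b in zip(c2.singletons, c.singletons):
            np.testing.assert_allclose(a, b)


def _singleton_mass(counts):
    if counts.singletons is None:
        return 0.0
    return sum(s[:, 2].sum() for s in counts.singletons if s.size)


class TestSingletonRouting:
    def test_shared_singletons_set_aside(self):
        t = table_from([100, 200], [10, 10], [20, 20], carrier=1)
        grid = TimeGrid(np.array([0.0, 1000.0]))
        c = genotype_observations(t, np.array([1.0, 0.0]), np.array([1.0, 1.0]), grid)
        # site 1 shared (goes to singleton list), site 2 not shared (binned)
        assert c.total()[0].sum() == 0
        assert _singleton_mass(c) == 1.0
        assert c.total()[1].sum() == 3.0

    def test_drop_shared_singletons(self):
        t = table_from([100], [10], [20], carrier=1)
        grid = TimeGrid(np.array([0.0, 1000.0]))
        c = genotype_observations(
            t, np.array([2.0]), np.array([2.0]), grid, drop_shared_singletons=True
        )
        assert c.singletons is None
        assert c.total()[0].sum() == 0
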