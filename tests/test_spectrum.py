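import itertools

import numpy as np
import pandas as pd
import pytest

from agecoal import (
    DatedMutationTable,
    Pileup,
    RateCurve,
    canonical_class,
    enumerate_classes,
    imi,
    relative_rate_curve,
    tcc_proportion_lowcov,
    transversion_rate,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestCanonicalClass:
    def test_already_canonical(self):
        assert canonical_class("T", "C", "T", "C").label == "TCC>TTC"

    def test_reverse_complement_collapse(self):
        # GGA with G>A on the other strand is TCC>TTC
        assert canonical_class("G", "G", "A", "A").label == "TCC>TTC"

    def test_strand_symmetry_exhaustive(self):
        for left, anc, der, right in itertools.product("ACGT", repeat=4):
            if anc == der:
                continue
            rc = (COMP[right], COMP[anc], COMP[der], COMP[left])
            assert canonical_class(left, anc, der, right) == canonical_class(*rc)

    def test_idempotent(self):
        c = canonical_class("G", "G", "A", "A")
        assert canonical_class(c.left, c.anc, c.der, c.right) == c

    def test_invalid_bases(self):
        with pytest.raises(ValueError):
            canonical_class("N", "C", "T", "A")
        with pytest.raises(ValueError):
            canonical_class("A", "C", "C", "A")


class TestEnumerateClasses:
    def test_counts(self):
        all_classes = enumerate_classes()
        retained = enumerate_classes(exclude_cpg=True)
        assert len(all_classes) == 96
        assert len(retained) == 76
        assert len(all_classes) - len(retained) == 20

    def test_partition(self):
        all_classes = set(c.label for c in enumerate_classes())
        retained = set(c.label for c in enumerate_classes(exclude_cpg=True))
        excluded = all_classes - retained
        assert len(excluded) == 20
        assert "ACG>ATG" in excluded  # central C followed by G

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="pulse20"):
            enumerate_classes(exclude_cpg=True, cpg_rule="nope")


def context_table(labels_and_counts, age_lo=2e4, age_hi=3e4, carrier=3):
    """One mutation row per (class, epoch placement) occurrence."""
    rows = []
    pos = 1
    for (left, anc, der, right), n, lo, hi in labels_and_counts:
        for _ in range(n):
            rows.append(("1", pos, anc, der, lo, hi, carrier, False, left, right))
            pos += 10
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "anc", "der", "age_lower_years", "age_upper_years",
            "carrier_count", "is_fixed", "left_base", "right_base",
        ],
    )
    return DatedMutationTable(df)


class TestRelativeRateCurve:
    boundaries = np.array([1e3, 1e4, 1e5, 1e6, 1e7])

    def uniform_spec(self, extra_focal=0):
        spec = []
        for c in enumerate_classes(exclude_cpg=True):
            for lo, hi in zip(self.boundaries[:-1], self.boundaries[1:]):
                n = 1 + (extra_focal if c.label == "TCC>TTC" and lo == 1e4 else 0)
                spec.append(((c.left, c.anc, c.der, c.right), n, lo * 1.01, hi * 0.99))
        return spec

    def test_uniform_composition_gives_flat_curve(self):
        table = context_table(self.uniform_spec())
        curve = relative_rate_curve(table, 1.0, self.boundaries)
        np.testing.assert_allclose(curve.values, 1.0, rtol=1e-9)

    def test_doubled_focal_epoch(self):
        table = context_table(self.uniform_spec(extra_focal=1))
        curve = relative_rate_curve(table, 1.0, self.boundaries)
        # doubling the focal class also lifts the 76-class mean
        assert curve.values[1] == pytest.approx(2 / (1 + 1 / 76), rel=1e-9)
        assert curve.values[1] == pytest.approx(1.9741, abs=1e-4)

    def test_singletons_excluded(self):
        spec = self.uniform_spec()
        table = context_table(spec)
        extra = context_table(
            [(("T", "C", "T", "C"), 50, 1.2e4, 9e4)], carrier=1
        )
        merged = DatedMutationTable(
            pd.concat(
                [table.df, extra.df.assign(pos=extra.df["pos"] + 10**7)],
                ignore_index=True,
            )
        )
        with pytest.warns(UserWarning, match="terminal"):
            curve = relative_rate_curve(merged, 1.0, self.boundaries)
        np.testing.assert_allclose(curve.values, 1.0, rtol=1e-9)

    def test_opportunity_scaling_invariance(self):
        table = context_table(self.uniform_spec(extra_focal=2))
        L1 = {c.label: 1.0 for c in enumerate_classes(exclude_cpg=True)}
        L2 = {k: 7.5 * v for k, v in L1.items()}
        c1 = relative_rate_curve(table, L1, self.boundaries)
        c2 = relative_rate_curve(table, L2, self.boundaries)
        np.testing.assert_allclose(c1.values, c2.values, rtol=1e-12)

    def test_missing_context_rejected(self):
        df = context_table(self.uniform_spec()).df.drop(columns=["left_base"])
        table = DatedMutationTable(df)
        with pytest.raises(ValueError, match="context"):
            relative_rate_curve(table, 1.0, self.boundaries)


class TestIMI:
    boundaries = np.array([1e3, 1e4, 1e5, 1e6, 1e7])

    def test_constant_curve_is_exactly_zero(self):
        curve = RateCurve(self.boundaries, np.full(4, 1.7))
        assert imi(curve) == 0.0

    def test_uniform_elevation_rectangle_area(self):
        c = 0.4
        curve = RateCurve(self.boundaries, np.full(4, 1.0 + c))
        val = imi(curve, prescaled=True)
        assert val == pytest.approx(c * (np.log10(1e6) - np.log10(14e3)), rel=1e-9)
        assert val == pytest.approx(c * 1.853872, abs=1e-5)

    def test_recent_extrapolation(self):
        # no epochs younger than 30k: earliest value extends back to 14k
        boundaries = np.array([3e4, 1e5, 1e6, 1e7])
        curve = RateCurve(boundaries, np.array([2.0, 1.0, 1.0]))
        val = imi(curve, prescaled=True)
        assert val == pytest.approx(np.log10(1e5) - np.log10(14e3), rel=1e-9)

    def test_scaling_window_normalization(self):
        # doubling the whole curve changes nothing after scaling
        a = RateCurve(self.boundaries, np.array([3.0, 2.0, 1.0, 1.0]))
        b = RateCurve(self.boundaries, 2 * np.array([3.0, 2.0, 1.0, 1.0]))
        assert imi(a) == pytest.approx(imi(b), rel=1e-12)

    def test_linearity_in_excess(self):
        base = np.array([1.0, 1.0, 1.0, 1.0])
        bump = np.array([0.8, 0.4, 0.0, 0.0])
        v1 = imi(RateCurve(self.boundaries, base + bump), prescaled=True)
        v2 = imi(RateCurve(self.boundaries, base + 2 * bump), prescaled=True)
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_no_scaling_epochs_is_an_error(self):
        curve = RateCurve(self.boundaries, np.ones(4), scaling_window=(2e7, 3e7))
        with pytest.raises(ValueError, match="scaling"):
            imi(curve)


class TestTransversionRate:
    def test_printed_value_at_one_significant_figure(self):
        rate = transversion_rate(1.25e-8, 2.0)
        assert rate == pytest.approx(1.25e-8 / 3)
        # rounded to one significant figure: 4e-9 per base per generation
        rounded = float(f"{rate:.0e}")
        assert rounded == 4e-9


class TestTccProportionLowcov:
    def make_pileup(self, table, depths, derived):
        site_idx, bases = [], []
        der = table.df["der"].to_numpy()
        anc = table.df["anc"].to_numpy()
        for i, (d, nd) in enumerate(zip(depths, derived)):
            site_idx += [i] * d
            bases += [der[i]] * nd + [anc[i]] * (d - nd)
        n = len(site_idx)
        return Pileup(
            site_index=np.array(site_idx, dtype=int),
            base=np.array(bases),
            mapping_quality=np.full(n, 60),
            read_length=np.full(n, 100),
            mismatch_count=np.zeros(n, dtype=int),
            offset=np.full(n, 50),
        )

    def ct_table(self, n, tcc_first, seed=0, age=5e4):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            if i < tcc_first:
                left, right = "T", "C"  # TCC>TTC
            else:
                left, right = "A", "A"  # ACA>ATA, a non-CpG C>T
            rows.append(
                ("1", 1 + i * 1000, "C", "T", age * 0.9, age, 3, False, left, right)
            )
        df = pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "anc", "der", "age_lower_years", "age_upper_years",
                "carrier_count", "is_fixed", "left_base", "right_base",
            ],
        )
        return DatedMutationTable(df)

    def test_read_support_threshold(self):
        table = self.ct_table(2, 1)
        pu = self.make_pileup(table, depths=[5, 5], derived=[3, 4])
        # first site has only 3 derived reads: not counted
        prop, lo, hi = tcc_proportion_lowcov(pu, table, n_reps=20, seed=0)
        assert prop == 0.0

    def test_all_tcc_gives_one(self):
        table = self.ct_table(30, 30)
        pu = self.make_pileup(table, depths=[6] * 30, derived=[5] * 30)
        prop, lo, hi = tcc_proportion_lowcov(pu, table, n_reps=20, seed=0)
        assert prop == 1.0 and lo == 1.0 and hi == 1.0

    def test_age_cap_ascertainment(self):
        table = self.ct_table(10, 10, age=2e5)  # above the 100k cap
        pu = self.make_pileup(table, depths=[6] * 10, derived=[6] * 10)
        with pytest.raises(ValueError, match="qualifying"):
            tcc_proportion_lowcov(pu, table, n_reps=10, seed=0)

    def test_binomial_share_recovered(self):
        rng = np.random.default_rng(4)
        n = 2000
        k = int(0.3 * n)
        # scatter TCC and non-TCC sites randomly along the chromosome
        table = self.ct_table(n, k)
        depths = rng.poisson(8, n)
        derived = np.minimum(depths, rng.poisson(6, n))
        pu = self.make_pileup(table, depths=depths, derived=derived)
        prop, lo, hi = tcc_proportion_lowcov(pu, table, n_reps=50, seed=1)
        q = sum(1 for d, nd in zip(depths, derived) if d >= 4 and nd >= 4)
        se = np.sqrt(0.3 * 0.7 / q)
        assert abs(prop - 0.3) < 3 * se

    def test_high_coverage_limit_equals_genotype_proportion(self):
        table = self.ct_table(50, 20)
        pu = self.make_pileup(table, depths=[200] * 50, derived=[200] * 50)
        prop, _, _ = tcc_proportion_lowcov(pu, table, n_reps=10, seed=0)
        assert prop == pytest.approx(20 / 50)
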