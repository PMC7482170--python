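"""Spectrum classes, length bins, rates, fold changes and zygosity stats."""

import math

import numpy as np
import pytest

from radmut.events import Category, MutationEvent, classify_event, merge_into_events
from radmut.spectra import (
    GENOME_LENGTH_BP,
    classify_sbs,
    fold_change,
    indel_length_bin,
    is_transition,
    per_bp_rate,
    per_gy,
    summarize_strain,
    welch_t,
    zygosity_ratio,
)

from conftest import deletion, insertion, sbs


class TestSbsClasses:
    @pytest.mark.parametrize(
        "ref,alt,label,transition",
        [
            ("A", "G", "A/T>G/C", True),
            ("T", "C", "A/T>G/C", True),   # strand collapse
            ("G", "T", "G/C>T/A", False),
            ("C", "A", "G/C>T/A", False),
            ("A", "T", "A/T>T/A", False),
            ("G", "A", "G/C>A/T", True),
        ],
    )
    def test_collapse_and_transition_flag(self, ref, alt, label, transition):
        cls = classify_sbs(ref, alt)
        assert cls == label
        assert is_transition(cls) is transition

    def test_equal_or_invalid_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_sbs("A", "A")
        with pytest.raises(ValueError):
            classify_sbs("N", "A")


def event_of(call):
    (e,) = merge_into_events([call])
    return classify_event(e)


class TestIndelBins:
    @pytest.mark.parametrize(
        "call,label",
        [
            (deletion(100, "A" * 15), "11-30"),
            (insertion(100, "T"), "1"),
            (deletion(100, "A" * 250), ">100"),
            (deletion(100, "AC"), "2-10"),
            (insertion(100, "ACGTACGTACG" * 5), "31-100"),
        ],
    )
    def test_bin_edges(self, call, label):
        assert indel_length_bin(event_of(call)) == label

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError):
            indel_length_bin(event_of(sbs(100, "A", "G")))


class TestRates:
    def test_single_plant_rate(self):
        r = per_bp_rate([10])
        assert r.mean == pytest.approx(10 / GENOME_LENGTH_BP)
        assert r.se == 0.0 and not r.se_defined

    def test_closed_form_mean_and_se(self):
        r = per_bp_rate([10, 12, 14], genome_length_bp=1000)
        assert r.mean == pytest.approx(12 / 1000)
        assert r.se == pytest.approx((2 / math.sqrt(3)) / 1000)

    def test_all_zero(self):
        r = per_bp_rate([0, 0, 0])
        assert (r.mean, r.se) == (0.0, 0.0)

    def test_per_gy_divides_mean_and_se(self):
        r = per_gy(per_bp_rate([10, 12, 14], 1000), 100.0)
        assert r.mean == pytest.approx(12 / 1000 / 100)
        assert r.se == pytest.approx((2 / math.sqrt(3)) / 1000 / 100)

    def test_per_gy_identity_at_one_gray(self):
        r = per_bp_rate([3, 4, 5])
        assert per_gy(r, 1.0) == r

    def test_zero_plants_and_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            per_bp_rate([])
        with pytest.raises(ValueError):
            per_gy(per_bp_rate([1]), 0.0)


class TestWelch:
    def test_matches_textbook_formula(self):
        a = [30.1, 28.4, 33.0, 29.5]
        b = [10.2, 12.8, 11.1]
        t, df, p = welch_t(a, b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
        df_expected = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        assert t == pytest.approx(t_expected, abs=1e-12)
        assert df == pytest.approx(df_expected, abs=1e-12)
        assert 0 < p < 1


def labelled_events(n_hom, n_het):
    events = []
    for i in range(n_hom + n_het):
        e = event_of(sbs(100 + 20 * i, "A", "G"))
        e.zygosity = "homozygous" if i < n_hom else "heterozygous"
        events.append(e)
    return events


class TestZygosityRatio:
    def test_expected_ratio_consistent(self):
        zr = zygosity_ratio(labelled_events(10, 20))
        assert zr.ratio == pytest.approx(0.5)
        assert zr.p_value > 0.5

    def test_no_homozygous_small_p(self):
        zr = zygosity_ratio(labelled_events(0, 20))
        assert zr.ratio == 0.0
        # exact binomial tail: P(X = 0 | n = 20, p = 1/3) summed two-sided
        assert zr.p_value < 0.01

    def test_equal_counts(self):
        assert zygosity_ratio(labelled_events(15, 15)).ratio == pytest.approx(1.0)

    def test_zero_het_undefined_ratio(self):
        zr = zygosity_ratio(labelled_events(5, 0))
        assert zr.ratio is None
        assert zr.n_homozygous == 5


class TestStrainSummary:
    def make_summary(self, counts_by_plant, dose=100.0, genome=1_000_000):
        events_by_plant = {}
        for plant, n_by_cat in counts_by_plant.items():
            events = []
            pos = 100
            for cat, n in n_by_cat.items():
                for _ in range(n):
                    e = MutationEvent(
                        sample_id=plant, chrom="c", start=pos, end=pos,
                        members=[sbs(pos, "A", "G", sample=plant)],
                        category=cat, zygosity="heterozygous",
                    )
                    events.append(e)
                    pos += 50
            events_by_plant[plant] = events
        return summarize_strain(events_by_plant, "test", dose, genome)

    def test_one_event_per_type_fractions(self):
        s = self.make_summary({"p1": {c: 1 for c in Category}})
        for c in Category:
            assert s.fractions[c.value] == pytest.approx(1 / 7)

    def test_per_type_rates_sum_to_total(self):
        s = self.make_summary(
            {
                "p1": {Category.SBS: 5, Category.DEL_GE2: 2},
                "p2": {Category.SBS: 3, Category.COMPLEX: 1},
            }
        )
        total = sum(s.rate_per_bp[c.value].mean for c in Category)
        assert total == pytest.approx(s.rate_per_bp["Total"].mean)
        assert s.counts["Total"].tolist() == [7, 4]

    def test_per_gy_commutes_with_averaging(self):
        s = self.make_summary(
            {"p1": {Category.SBS: 4}, "p2": {Category.SBS: 8}}, dose=200.0
        )
        direct = s.rate_per_bp["SBS"].mean / 200.0
        assert s.rate_per_bp_per_gy["SBS"].mean == pytest.approx(direct)


class TestFoldChange:
    def test_identical_rates_give_one(self):
        wt = TestStrainSummary().make_summary({"p1": {Category.SBS: 5}})
        assert fold_change([wt], wt, "SBS") == pytest.approx(1.0)

    def test_zero_wt_rate_undefined(self):
        wt = TestStrainSummary().make_summary({"p1": {Category.SBS: 5}})
        mut = TestStrainSummary().make_summary({"p1": {Category.SBS: 5}})
        assert math.isnan(fold_change([mut], wt, "SV"))
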