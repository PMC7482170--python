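"""Mutation spectra, length distributions, rates and zygosity ratios.

Rates are expressed per base pair of the haploid reference (the golden
path of chromosomes 1-5, 119,146,348 bp, is the default denominator) and
optionally per gray of absorbed dose. Per-strain values are means with
standard errors across the sequenced M2 plants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import Category, MutationEvent

GENOME_LENGTH_BP = 119_146_348

SBS_CLASSES = (
    "A/T>G/C",  # transition
    "G/C>A/T",  # transition
    "A/T>T/A",
    "A/T>C/G",
    "G/C>T/A",
    "G/C>C/G",
)
TRANSITIONS = frozenset({"A/T>G/C", "G/C>A/T"})

INDEL_BINS = ("1", "2-10", "11-30", "31-100", ">100")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_sbs(ref_base: str, alt_base: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    The pair is folded so the reference base reads A or G; e.g. T>C and
    A>G are both "A/T>G/C".
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("ref and alt bases are equal")
    if ref_base not in _COMPLEMENT or alt_base not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in {ref_base}>{alt_base}")
    if ref_base in "TC":
        ref_base, alt_base = _COMPLEMENT[ref_base], _COMPLEMENT[alt_base]
    label = f"{ref_base}/{_COMPLEMENT[ref_base]}>{alt_base}/{_COMPLEMENT[alt_base]}"
    assert label in SBS_CLASSES
    return label


def is_transition(sbs_class: str) -> bool:
    return sbs_class in TRANSITIONS


def indel_length_bin(event: MutationEvent) -> str:
    """Length bin {1, 2-10, 11-30, 31-100, >100} of an InDel event."""
    if event.category not in (
        Category.DEL1,
        Category.INS1,
        Category.DEL_GE2,
        Category.INS_GE2,
    ):
        raise ValueError(f"not an InDel event: {event.category}")
    n = event.length
    if n == 1:
        return "1"
    if n <= 10:
        return "2-10"
    if n <= 30:
        return "11-30"
    if n <= 100:
        return "31-100"
    return ">100"


@dataclass(frozen=True)
class RateEstimate:
    """Mean +/- SE of a per-plant quantity; SE is 0 (flagged) for n = 1."""

    mean: float
    se: float
    n: int

    @property
    def se_defined(self) -> bool:
        return self.n > 1

    def scaled(self, factor: float) -> "RateEstimate":
        return RateEstimate(self.mean * factor, self.se * factor, self.n)


def per_bp_rate(
    counts_per_plant: list[float], genome_length_bp: int = GENOME_LENGTH_BP
) -> RateEstimate:
    """Mean and standard error of per-plant counts divided by genome length."""
    if len(counts_per_plant) < 1:
        raise ValueError("at least one plant required")
    rates = np.asarray(counts_per_plant, dtype=float) / genome_length_bp
    n = len(rates)
    se = float(np.std(rates, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return RateEstimate(float(np.mean(rates)), se, n)


def per_gy(rate: RateEstimate, dose_gy: float) -> RateEstimate:
    """Divide a rate (and its SE) by the absorbed dose."""
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    return RateEstimate(rate.mean / dose_gy, rate.se / dose_gy, rate.n)


def welch_t(a: list[float], b: list[float]) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t statistic, degrees of freedom, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ZygosityRatio:
    n_homozygous: int
    n_heterozygous: int
    ratio: float | None  # hom / het; None when no heterozygous events
    p_value: float  # exact binomial test of hom count vs expected 1/3

    @property
    def n(self) -> int:
        return self.n_homozygous + self.n_heterozygous


def zygosity_ratio(
    events: list[MutationEvent], expected_hom_fraction: float = 1.0 / 3.0
) -> ZygosityRatio:
    """Homozygous:heterozygous ratio with an exact binomial test.

    Under Mendelian segregation of M1-heterozygous mutations, a sampled
    M2 plant carries a detected mutation as homozygous with probability
    1/3 and heterozygous with 2/3, so hom:het is expected at 0.5.
    """
    n_hom = sum(1 for e in events if e.zygosity == "homozygous")
    n_het = sum(1 for e in events if e.zygosity == "heterozygous")
    total = n_hom + n_het
    ratio = (n_hom / n_het) if n_het else None
    p = (
        stats.binomtest(n_hom, total, expected_hom_fraction).pvalue
        if total
        else float("nan")
    )
    return ZygosityRatio(n_hom, n_het, ratio, p)


CATEGORY_ORDER = [
    Category.SBS,
    Category.DEL1,
    Category.INS1,
    Category.DEL_GE2,
    Category.INS_GE2,
    Category.COMPLEX,
    Category.SV,
]


@dataclass
class StrainSummary:
    """Per-strain mutation-type table (counts, rates, fractions)."""

    strain: str
    dose_gy: float
    n_plants: int
    genome_length_bp: int
    counts: pd.DataFrame  # plants x categories (+ Total column)
    rate_per_bp: dict[str, RateEstimate] = field(default_factory=dict)
    rate_per_bp_per_gy: dict[str, RateEstimate] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Two-block table: per-bp rates (x1e-8) and per-Gy rates (x1e-10)."""
        cols = [c.value for c in CATEGORY_ORDER] + ["Total"]
        rows = {
            "rate_per_bp_x1e8": [self.rate_per_bp[c].mean * 1e8 for c in cols],
            "se_per_bp_x1e8": [self.rate_per_bp[c].se * 1e8 for c in cols],
            "rate_per_bp_per_gy_x1e10": [
                self.rate_per_bp_per_gy[c].mean * 1e10 for c in cols
            ],
            "se_per_bp_per_gy_x1e10": [
                self.rate_per_bp_per_gy[c].se * 1e10 for c in cols
            ],
            "fraction_of_total": [
                self.fractions.get(c, float("nan")) for c in cols
            ],
        }
        return pd.DataFrame(rows, index=cols)


def summarize_strain(
    events_by_plant: dict[str, list[MutationEvent]],
    strain: str,
    dose_gy: float,
    genome_length_bp: int = GENOME_LENGTH_BP,
) -> StrainSummary:
    """Tabulate per-plant category counts and per-bp / per-Gy rates.

    Complex events count once; homozygous events count once (zygosity
    does not weight the rate).
    """
    plants = sorted(events_by_plant)
    cols = [c.value for c in CATEGORY_ORDER]
    data = []
    for p in plants:
        row = {c: 0 for c in cols}
        for e in events_by_plant[p]:
            row[e.category.value] += 1
        data.append(row)
    counts = pd.DataFrame(data, index=plants, columns=cols)
    counts["Total"] = counts.sum(axis=1)

    rate_bp: dict[str, RateEstimate] = {}
    rate_gy: dict[str, RateEstimate] = {}
    for c in counts.columns:
        r = per_bp_rate(counts[c].tolist(), genome_length_bp)
        rate_bp[c] = r
        rate_gy[c] = per_gy(r, dose_gy)

    total = rate_bp["Total"].mean
    fractions = {
        c: (rate_bp[c].mean / total if total else float("nan")) for c in cols
    }
    return StrainSummary(
        strain=strain,
        dose_gy=dose_gy,
        n_plants=len(plants),
        genome_length_bp=genome_length_bp,
        counts=counts,
        rate_per_bp=rate_bp,
        rate_per_bp_per_gy=rate_gy,
        fractions=fractions,
    )


def fold_change(
    mutant_summaries: list[StrainSummary],
    wt_summary: StrainSummary,
    category: str,
) -> float:
    """Mean mutant per-Gy rate for a category over the wild-type rate."""
    wt = wt_summary.rate_per_bp_per_gy[category].mean
    if wt == 0:
        return float("nan")
    mutant = float(
        np.mean([s.rate_per_bp_per_gy[category].mean for s in mutant_summaries])
    )
    return mutant / wt


def sbs_spectrum(events: list[MutationEvent]) -> dict[str, int]:
    """Counts over the 6 strand-collapsed SBS classes (simple SBS events)."""
    counts = {c: 0 for c in SBS_CLASSES}
    for e in events:
        if e.category is Category.SBS:
            m = e.members[0]
            counts[classify_sbs(m.ref_allele, m.alt_allele)] += 1
    return counts


def indel_length_distribution(
    events: list[MutationEvent],
) -> pd.DataFrame:
    """Counts per length bin, deletions and insertions separately."""
    out = pd.DataFrame(0, index=list(INDEL_BINS), columns=["deletion", "insertion"])
    for e in events:
        if e.category in (Category.DEL1, Category.DEL_GE2):
            out.loc[indel_length_bin(e), "deletion"] += 1
        elif e.category in (Category.INS1, Category.INS_GE2):
            out.loc[indel_length_bin(e), "insertion"] += 1
    return out
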