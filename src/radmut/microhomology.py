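"""Apparent microhomology at the rejoined sites of deletions >= 2 bp.

When the two sides of a deletion junction share sequence, the breakpoint
placement is ambiguous: several equal-length deletions yield the same
derived chromosome. The apparent microhomology length is that placement
ambiguity,

    mh = (number of distinct equivalent placements) - 1
       = mh_left + mh_right,

where ``mh_right`` is the longest k such that the first k deleted bases
equal the k reference bases just right of the deletion, and ``mh_left``
symmetrically for the deleted suffix against the left flank. Matching
truncates at chromosome ends; tandem-repeat deletions can therefore have
mh greater than the deletion length and are reported uncapped.

Junctions whose flank windows (one deletion length each side, clipped to
the chromosome) contain N have undefined microhomology and are excluded
from distributions but counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome import ReferenceGenome

MH_BINS = ("0", "1", "2", "3-4", "5-9", ">=10")
FLANK_REPORT_BP = 30


@dataclass(frozen=True)
class DeletionJunction:
    chrom: str
    del_start: int
    del_end: int
    deleted_seq: str
    left_flank: str
    right_flank: str
    mh_length: int | None  # None: undefined (N in flank window)

    @property
    def length(self) -> int:
        return self.del_end - self.del_start + 1

    @property
    def bin(self) -> str | None:
        return None if self.mh_length is None else bin_microhomology(self.mh_length)


def compute_microhomology(
    ref: ReferenceGenome, chrom: str, del_start: int, del_end: int
) -> int | None:
    """Microhomology length of the deletion [del_start, del_end] (1-based).

    Returns None when an N base falls in the deleted segment or in the
    flank windows of one deletion length on either side.
    """
    if del_end < del_start:
        raise ValueError("del_end < del_start")
    n = del_end - del_start + 1
    if n < 2:
        raise ValueError("microhomology is defined for deletions >= 2 bp")
    deleted = ref.fetch(chrom, del_start, del_end)
    left = ref.fetch_clipped(chrom, del_start - n, del_start - 1)
    right = ref.fetch_clipped(chrom, del_end + 1, del_end + n)
    if "N" in deleted or "N" in left or "N" in right:
        return None

    length = ref.chrom_length(chrom)
    # a right shift by k yields the same derived sequence iff
    # ref[s+i] == ref[e+1+i] for all i < k; the condition is
    # prefix-extendable, so extend base by base (uncapped, so tandem
    # repeats can exceed the deletion length); stop at N or chromosome end
    mh_right = 0
    while del_end + 1 + mh_right <= length:
        a = ref.base(chrom, del_start + mh_right)
        b = ref.base(chrom, del_end + 1 + mh_right)
        if a != b or a == "N":
            break
        mh_right += 1
    mh_left = 0
    while del_start - 1 - mh_left >= 1:
        a = ref.base(chrom, del_end - mh_left)
        b = ref.base(chrom, del_start - 1 - mh_left)
        if a != b or a == "N":
            break
        mh_left += 1
    return mh_left + mh_right


def junction_from_deletion(
    ref: ReferenceGenome,
    chrom: str,
    del_start: int,
    del_end: int,
    flank_bp: int = FLANK_REPORT_BP,
) -> DeletionJunction:
    return DeletionJunction(
        chrom=chrom,
        del_start=del_start,
        del_end=del_end,
        deleted_seq=ref.fetch(chrom, del_start, del_end),
        left_flank=ref.fetch_clipped(chrom, del_start - flank_bp, del_start - 1),
        right_flank=ref.fetch_clipped(chrom, del_end + 1, del_end + flank_bp),
        mh_length=compute_microhomology(ref, chrom, del_start, del_end),
    )


def bin_microhomology(mh_length: int) -> str:
    """Bin a microhomology length into {0, 1, 2, 3-4, 5-9, >=10}."""
    if mh_length < 0:
        raise ValueError("microhomology length must be >= 0")
    if mh_length <= 2:
        return str(mh_length)
    if mh_length <= 4:
        return "3-4"
    if mh_length <= 9:
        return "5-9"
    return ">=10"


@dataclass
class MicrohomologyDistribution:
    counts: dict[str, int]          # per bin, defined junctions only
    fractions: dict[str, float]     # counts / n_defined
    n_defined: int
    n_undefined: int
    zero_fraction: float | None     # fraction of defined junctions with mh 0


def microhomology_distribution(
    junctions: list[DeletionJunction],
) -> MicrohomologyDistribution:
    """Per-bin counts and fractions over defined-microhomology junctions."""
    defined = [j for j in junctions if j.mh_length is not None]
    n_undef = len(junctions) - len(defined)
    counter = Counter(j.bin for j in defined)
    counts = {b: counter.get(b, 0) for b in MH_BINS}
    n = len(defined)
    fractions = {b: (c / n if n else 0.0) for b, c in counts.items()}
    zero_fraction = (counts["0"] / n) if n else None
    return MicrohomologyDistribution(
        counts=counts,
        fractions=fractions,
        n_defined=n,
        n_undefined=n_undef,
        zero_fraction=zero_fraction,
    )
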