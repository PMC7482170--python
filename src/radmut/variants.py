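"""Candidate variant calls and their normalization.

A :class:`CandidateCall` is one caller-reported variant in one sample,
stored in a minimal internal representation:

* substitution  -- ``pos`` is the substituted base, ``ref_allele`` and
  ``alt_allele`` are single bases (multi-base substitutions are
  decomposed at the I/O boundary);
* deletion      -- ``pos`` is the first deleted base, ``ref_allele`` the
  deleted sequence, ``alt_allele`` empty;
* insertion     -- the inserted sequence ``alt_allele`` sits between
  ``pos`` and ``pos + 1`` (``ref_allele`` empty);
* inversion / translocation -- breakpoint coordinates in ``pos`` /
  ``end``; alleles empty.

``normalize_variant`` shifts insertions and deletions to their leftmost
equivalent placement, the canonical representative of the set of
placements that yield the same derived sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .genome import ReferenceGenome


class VariantClass(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    INVERSION = "inversion"
    TRANSLOCATION = "translocation"


SV_CLASSES = frozenset({VariantClass.INVERSION, VariantClass.TRANSLOCATION})


@dataclass(frozen=True)
class CandidateCall:
    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    allele_frequency: float
    source: str = ""
    end: int | None = None  # SV second breakpoint

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"allele_frequency {self.allele_frequency} not in [0, 1]")
        if self.variant_class is VariantClass.SUBSTITUTION and len(
            self.ref_allele
        ) != len(self.alt_allele):
            raise ValueError("substitution requires |ref| == |alt|")

    @property
    def is_sv(self) -> bool:
        return self.variant_class in SV_CLASSES

    @property
    def length(self) -> int:
        """Number of bases gained, lost or substituted (SVs: span length)."""
        if self.variant_class is VariantClass.DELETION:
            return len(self.ref_allele)
        if self.variant_class is VariantClass.INSERTION:
            return len(self.alt_allele)
        if self.is_sv:
            return (self.end or self.pos) - self.pos + 1
        return len(self.ref_allele)

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive reference span.

        Insertions occupy a zero-length interval between ``pos`` and
        ``pos + 1``, encoded as ``(pos + 1, pos)`` so that the count of
        intervening reference bases between two variants is always
        ``start_b - end_a - 1``.
        """
        if self.variant_class is VariantClass.INSERTION:
            return (self.pos + 1, self.pos)
        if self.is_sv:
            return (self.pos, self.end if self.end is not None else self.pos)
        return (self.pos, self.pos + len(self.ref_allele) - 1)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Site identity used for cross-sample comparisons."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class FilteredCall(CandidateCall):
    """A candidate call that survived filtering, with assigned zygosity."""

    zygosity: str = "heterozygous"  # or "homozygous"


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared prefix then suffix bases, returning minimal alleles.

    Prefix-first trimming removes the VCF anchor base without shifting
    the caller's reported indel placement (left-alignment is a separate,
    explicit step). The returned ``pos`` is the 1-based position of the
    first remaining reference base (for a pure insertion: the base
    before the insertion point).
    """
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if not ref:  # insertion: anchor on the base before the gap
        pos -= 1
    return pos, ref, alt


def normalize_variant(call: CandidateCall, ref: ReferenceGenome) -> CandidateCall:
    """Shift an insertion or deletion to its leftmost equivalent placement.

    Substitutions and SVs are returned unchanged. Raises ValueError when
    the stored ref_allele disagrees with the reference genome.
    """
    if call.variant_class is VariantClass.DELETION:
        n = len(call.ref_allele)
        observed = ref.fetch(call.chrom, call.pos, call.pos + n - 1)
        if observed != call.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {call.chrom}:{call.pos}: "
                f"call says {call.ref_allele!r}, genome has {observed!r}"
            )
        pos, seq = call.pos, call.ref_allele
        while pos > 1 and ref.base(call.chrom, pos - 1) == seq[-1]:
            seq = ref.base(call.chrom, pos - 1) + seq[:-1]
            pos -= 1
        if pos == call.pos:
            return call
        return replace(call, pos=pos, ref_allele=seq)

    if call.variant_class is VariantClass.INSERTION:
        pos, seq = call.pos, call.alt_allele
        while pos >= 1 and ref.base(call.chrom, pos) == seq[-1]:
            seq = ref.base(call.chrom, pos) + seq[:-1]
            pos -= 1
        if pos == call.pos:
            return call
        return replace(call, pos=pos, alt_allele=seq)

    if call.variant_class is VariantClass.SUBSTITUTION:
        observed = ref.fetch(
            call.chrom, call.pos, call.pos + len(call.ref_allele) - 1
        )
        if observed != call.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {call.chrom}:{call.pos}: "
                f"call says {call.ref_allele!r}, genome has {observed!r}"
            )
    return call


def normalize_calls(
    calls: list[CandidateCall], ref: ReferenceGenome
) -> list[CandidateCall]:
    """Left-align every small variant; SV calls pass through unchanged."""
    return [c if c.is_sv else normalize_variant(c, ref) for c in calls]


def apply_variants(
    ref: ReferenceGenome,
    chrom: str,
    calls: list[CandidateCall],
    start: int,
    end: int,
) -> str:
    """Apply non-overlapping small variants to reference[start, end].

    Used for round-trip checks and for deriving the mutant sequence of a
    clustered (complex) event. SV calls are not supported here.
    """
    calls = sorted(calls, key=lambda c: c.span)
    out: list[str] = []
    cursor = start
    for c in calls:
        if c.is_sv:
            raise ValueError("apply_variants does not handle SV calls")
        s, e = c.span
        if c.variant_class is VariantClass.INSERTION:
            out.append(ref.fetch(chrom, cursor, c.pos))
            out.append(c.alt_allele)
            cursor = c.pos + 1
        else:
            out.append(ref.fetch(chrom, cursor, s - 1))
            out.append(c.alt_allele)
            cursor = e + 1
    out.append(ref.fetch(chrom, cursor, end))
    return "".join(out)
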