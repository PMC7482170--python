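"""Merging nearby variants into mutation events and 7-way classification.

Detected mutations fall into seven categories: SBS, single-base deletion
(Del1, "-1"), single-base insertion (Ins1, "+1"), deletion of >= 2 bp
(DelGE2), insertion of >= 2 bp (InsGE2), complex-type and structural
variant (SV). Two or more variants whose spans are separated by fewer
than ``merge_window_bp`` intervening reference bases are considered one
mutational event (complex type); SVs are tallied separately and never
merge with small variants.

Within a complex event, maximal runs of two or more reference-matching
bases are treated as non-mutated spacers delimiting change blocks; a
single matching base between two changes is absorbed into one block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .genome import ReferenceGenome
from .variants import CandidateCall, FilteredCall, VariantClass, apply_variants

MERGE_WINDOW_BP = 10
SPACER_MIN_MATCH = 2


class Category(str, Enum):
    SBS = "SBS"
    DEL1 = "Del1"
    INS1 = "Ins1"
    DEL_GE2 = "DelGE2"
    INS_GE2 = "InsGE2"
    COMPLEX = "Complex"
    SV = "SV"


@dataclass(frozen=True)
class ChangeBlock:
    """One contiguous changed segment of a complex event."""

    kind: str  # substitution-run | deletion | insertion | mixed
    start: int
    end: int
    ref_seq: str
    alt_seq: str


@dataclass
class MutationEvent:
    sample_id: str
    chrom: str
    start: int
    end: int
    members: list[FilteredCall]
    category: Category | None = None
    zygosity: str | None = None
    mixed_zygosity: bool = False
    composition: list[ChangeBlock] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Affected length: the single member's length, or span width."""
        if len(self.members) == 1:
            return self.members[0].length
        return self.end - self.start + 1

    def describe_members(self) -> str:
        return ";".join(
            f"{m.variant_class.value}:{m.pos}"
            + (f"-{m.end}" if m.is_sv and m.end is not None else "")
            + f":{m.ref_allele or '-'}>{m.alt_allele or '-'}"
            for m in self.members
        )


def _gap(a: CandidateCall, b: CandidateCall) -> int:
    """Intervening reference bases between two variants (b after a)."""
    return b.span[0] - a.span[1] - 1


def _event_zygosity(members: list[FilteredCall]) -> tuple[str | None, bool]:
    zygs = [getattr(m, "zygosity", None) for m in members]
    zygs = [z for z in zygs if z is not None]
    if not zygs:
        return None, False
    if len(set(zygs)) == 1:
        return zygs[0], False
    # mixed-zygosity cluster: majority label, heterozygous on ties
    n_hom = sum(z == "homozygous" for z in zygs)
    label = "homozygous" if n_hom > len(zygs) - n_hom else "heterozygous"
    return label, True


def merge_into_events(
    calls: list[FilteredCall], window_bp: int = MERGE_WINDOW_BP
) -> list[MutationEvent]:
    """Group one sample's normalized calls into (uncategorized) events.

    Two small variants are linked when fewer than ``window_bp`` reference
    bases lie between their spans; events are the connected components of
    that linkage. SVs always form singleton events.
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(samples)}")

    events: list[MutationEvent] = []
    sv_calls = [c for c in calls if c.is_sv]
    small = sorted(
        (c for c in calls if not c.is_sv), key=lambda c: (c.chrom, c.span)
    )

    cluster: list[FilteredCall] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(c.span[0] for c in cluster)
        end = max(c.span[1] for c in cluster)
        zyg, mixed = _event_zygosity(cluster)
        events.append(
            MutationEvent(
                sample_id=cluster[0].sample_id,
                chrom=cluster[0].chrom,
                start=start,
                end=end,
                members=list(cluster),
                zygosity=zyg,
                mixed_zygosity=mixed,
            )
        )
        cluster.clear()

    max_end = None
    for c in small:
        if (
            cluster
            and c.chrom == cluster[0].chrom
            and c.span[0] - max_end - 1 < window_bp
        ):
            cluster.append(c)
            max_end = max(max_end, c.span[1])
        else:
            flush()
            cluster.append(c)
            max_end = c.span[1]
    flush()

    for c in sorted(sv_calls, key=lambda x: (x.chrom, x.span)):
        zyg, mixed = _event_zygosity([c])
        events.append(
            MutationEvent(
                sample_id=c.sample_id,
                chrom=c.chrom,
                start=c.span[0],
                end=c.span[1],
                members=[c],
                zygosity=zyg,
                mixed_zygosity=mixed,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.start, e.end))
    return events


def classify_event(event: MutationEvent) -> MutationEvent:
    """Assign one of the seven categories in place (and return the event)."""
    if len(event.members) >= 2:
        event.category = Category.COMPLEX
        return event
    m = event.members[0]
    if m.is_sv:
        event.category = Category.SV
    elif m.variant_class is VariantClass.SUBSTITUTION:
        event.category = Category.SBS
    elif m.variant_class is VariantClass.DELETION:
        event.category = Category.DEL1 if m.length == 1 else Category.DEL_GE2
    elif m.variant_class is VariantClass.INSERTION:
        event.category = Category.INS1 if m.length == 1 else Category.INS_GE2
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unclassifiable variant class {m.variant_class}")
    return event


def describe_complex(
    event: MutationEvent,
    ref: ReferenceGenome,
    spacer_min_match: int = SPACER_MIN_MATCH,
) -> list[ChangeBlock]:
    """Decompose a complex event into change blocks.

    Members separated by at least ``spacer_min_match`` reference-matching
    bases start a new block; members closer than that (including a single
    matching base) are absorbed into one block.
    """
    members = sorted(event.members, key=lambda m: m.span)
    groups: list[list[FilteredCall]] = [[members[0]]]
    for m in members[1:]:
        if _gap(groups[-1][-1], m) < spacer_min_match:
            groups[-1].append(m)
        else:
            groups.append([m])

    blocks: list[ChangeBlock] = []
    for grp in groups:
        start = min(m.span[0] for m in grp)
        end = max(m.span[1] for m in grp)
        classes = {m.variant_class for m in grp}
        if classes == {VariantClass.SUBSTITUTION}:
            kind = "substitution-run"
        elif len(grp) == 1 and classes == {VariantClass.DELETION}:
            kind = "deletion"
        elif len(grp) == 1 and classes == {VariantClass.INSERTION}:
            kind = "insertion"
        else:
            kind = "mixed"
        ref_seq = ref.fetch(event.chrom, start, end) if end >= start else ""
        fetch_start = min(start, end + 1)
        alt_seq = apply_variants(ref, event.chrom, grp, fetch_start, end)
        blocks.append(
            ChangeBlock(kind=kind, start=start, end=end, ref_seq=ref_seq, alt_seq=alt_seq)
        )
    event.composition = blocks
    return blocks


def build_events(
    calls: list[FilteredCall],
    ref: ReferenceGenome | None = None,
    window_bp: int = MERGE_WINDOW_BP,
    spacer_min_match: int = SPACER_MIN_MATCH,
) -> list[MutationEvent]:
    """Merge, classify and (where complex) decompose one sample's calls."""
    events = [classify_event(e) for e in merge_into_events(calls, window_bp)]
    if ref is not None:
        for e in events:
            if e.category is Category.COMPLEX:
                describe_complex(e, ref, spacer_min_match)
    return events
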