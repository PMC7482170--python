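"""Reference genome container with 1-based inclusive coordinates.

All positional lookups in this package are 1-based and inclusive at both
ends, matching the base-pair phrasing used throughout the analysis; the
VCF anchor-base convention exists only at the I/O boundary (see
:mod:`radmut.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_VALID = set("ACGTN")


@dataclass
class ReferenceGenome:
    """Named chromosome sequences, uppercase, alphabet {A,C,G,T,N}.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> DNA string. Lowercase input is folded
        to uppercase; any character outside {A,C,G,T,N} raises ValueError.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return reference bases on [start, end], 1-based inclusive.

        Coordinates outside the chromosome raise IndexError; use
        :meth:`fetch_clipped` when truncation at the ends is wanted.
        """
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(
                f"[{start}, {end}] outside {chrom} (length {len(seq)})"
            )
        if end < start:
            return ""
        return seq[start - 1 : end]

    def fetch_clipped(self, chrom: str, start: int, end: int) -> str:
        """Like :meth:`fetch` but silently clipped to the chromosome."""
        seq = self.sequences[chrom]
        start = max(start, 1)
        end = min(end, len(seq))
        if end < start:
            return ""
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)
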