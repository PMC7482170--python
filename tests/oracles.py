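"""Brute-force oracles, independent of the implementation paths they check."""

from __future__ import annotations


def derived_after_deletion(seq: str, start: int, end: int) -> str:
    """Chromosome string after deleting [start, end] (1-based inclusive)."""
    return seq[: start - 1] + seq[end:]


def equivalent_deletion_placements(seq: str, start: int, end: int) -> list[int]:
    """All start positions of equal-length deletions with the same result."""
    n = end - start + 1
    target = derived_after_deletion(seq, start, end)
    return [
        s
        for s in range(1, len(seq) - n + 2)
        if derived_after_deletion(seq, s, s + n - 1) == target
    ]


def brute_force_microhomology(seq: str, start: int, end: int) -> int:
    return len(equivalent_deletion_placements(seq, start, end)) - 1


def leftmost_deletion_placement(seq: str, start: int, end: int) -> int:
    return min(equivalent_deletion_placements(seq, start, end))


def derived_after_insertion(seq: str, pos: int, ins: str) -> str:
    """Chromosome string after inserting ``ins`` between pos and pos+1."""
    return seq[:pos] + ins + seq[pos:]


def leftmost_insertion_placement(seq: str, pos: int, ins: str) -> tuple[int, str]:
    """Leftmost (pos, inserted-seq) giving the same derived sequence.

    Enumerates every placement and every rotation of the inserted string.
    """
    target = derived_after_insertion(seq, pos, ins)
    best = (pos, ins)
    for p in range(0, pos + 1):
        for r in range(len(ins)):
            rot = ins[r:] + ins[:r]
            if derived_after_insertion(seq, p, rot) == target and p < best[0]:
                best = (p, rot)
    return best


def union_find_events(spans: list[tuple[int, int]], window: int) -> list[set[int]]:
    """Connected components of the '< window intervening bases' relation."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            gap = max(s1, s2) - min(e1, e2) - 1
            if gap < window:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=min)
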