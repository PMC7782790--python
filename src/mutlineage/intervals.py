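"""Half-open genomic interval arithmetic.

Intervals are 0-based, half-open ``(start, end)`` tuples grouped per
chromosome in a plain ``dict``.  Only the operations the lineage caller
needs are provided: normalisation (sort + merge), pairwise intersection,
total length, and point membership.
"""

from __future__ import annotations

from bisect import bisect_right

IntervalMap = dict[str, list[tuple[int, int]]]


def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Intersection of two merged interval lists (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def contains(intervals: list[tuple[int, int]], pos: int) -> bool:
    """Membership test on a merged, sorted interval list."""
    idx = bisect_right(intervals, (pos, float("inf"))) - 1
    return idx >= 0 and intervals[idx][0] <= pos < intervals[idx][1]


def normalize_map(ivmap: IntervalMap) -> IntervalMap:
    return {chrom: merge(ivs) for chrom, ivs in ivmap.items() if ivs}


def intersect_maps(maps: list[IntervalMap]) -> IntervalMap:
    """Intersect a list of per-chromosome interval maps."""
    if not maps:
        raise ValueError("need at least one interval map")
    out = normalize_map(maps[0])
    for other in maps[1:]:
        other = normalize_map(other)
        out = {
            chrom: intersect(out[chrom], other[chrom])
            for chrom in out.keys() & other.keys()
        }
        out = {c: ivs for c, ivs in out.items() if ivs}
    return out
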