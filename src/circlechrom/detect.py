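"""Circle (ecDNA) detection from split long-read alignments.

A read that traverses the head-to-tail junction of a circular template aligns
as two segments with a characteristic geometry.  A segment pair supports a
circle iff all four criteria hold:

1. both segments are longer than ``min_seg_len`` (strictly, default 1 kb);
2. both map to the same chromosome;
3. both map to the same strand;
4. the pair is in *outward* orientation: the segment later in read order maps
   strictly upstream (+ strand) / strictly downstream (- strand) of the
   earlier one, i.e. the read runs off the circle's reference end and
   re-enters at its reference start.

Per-read candidates are then clustered (single linkage within a breakpoint
tolerance) into circle records with read support.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SegmentAlignment

DEFAULT_MIN_SEG_LEN = 1000
DEFAULT_SIZE_RANGE = (50, 100_000)
DEFAULT_READ_OVERLAP_SLACK = 100
DEFAULT_CLUSTER_TOLERANCE = 50


@dataclass(frozen=True)
class JunctionCandidate:
    """One read's evidence for a circle: the two breakpoints it implies."""

    read_id: str
    chrom: str
    strand: str
    circle_start: int
    circle_end: int

    def __post_init__(self):
        if self.circle_start >= self.circle_end:
            raise ValueError("circle_start must be < circle_end")

    @property
    def size(self) -> int:
        return self.circle_end - self.circle_start


@dataclass
class EcDNARecord:
    """A clustered circular-DNA locus with its supporting reads."""

    chrom: str
    start: int
    end: int
    support: int
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("start must be < end")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def size(self) -> int:
        return self.end - self.start


def classify_pair(
    a: SegmentAlignment,
    b: SegmentAlignment,
    min_seg_len: int = DEFAULT_MIN_SEG_LEN,
    read_overlap_slack: int = DEFAULT_READ_OVERLAP_SLACK,
) -> JunctionCandidate | None:
    """Classify a read-ordered segment pair; return a candidate iff it is a
    head-to-tail junction pair under the four criteria.

    ``a`` must precede ``b`` on the read (abutting or gapped is fine; overlap
    on the read beyond ``read_overlap_slack`` rejects the pair).
    """
    if a.read_id != b.read_id:
        raise ValueError(f"segments from different reads: {a.read_id!r} vs {b.read_id!r}")
    if a.read_start > b.read_start:
        raise ValueError("pair must be given in read order (a before b)")
    if a.read_end - b.read_start > read_overlap_slack:
        return None
    if a.read_len <= min_seg_len or b.read_len <= min_seg_len:
        return None  # criterion 1, strict
    if a.chrom != b.chrom:
        return None  # criterion 2
    if a.strand != b.strand:
        return None  # criterion 3
    # criterion 4: outward orientation
    if a.strand == "+":
        outward = b.ref_end <= a.ref_start
    else:
        outward = b.ref_start >= a.ref_end
    if not outward:
        return None
    circle_start = min(a.ref_start, b.ref_start)
    circle_end = max(a.ref_end, b.ref_end)
    return JunctionCandidate(a.read_id, a.chrom, a.strand, circle_start, circle_end)


def _segments_from_frame(segments: pd.DataFrame) -> dict[str, list[SegmentAlignment]]:
    by_read: dict[str, list[SegmentAlignment]] = defaultdict(list)
    for row in segments.itertuples(index=False):
        by_read[row.read_id].append(
            SegmentAlignment(
                row.read_id,
                int(row.read_start),
                int(row.read_end),
                row.chrom,
                int(row.ref_start),
                int(row.ref_end),
                row.strand,
            )
        )
    return by_read


def detect_junctions(
    segments: pd.DataFrame,
    min_seg_len: int = DEFAULT_MIN_SEG_LEN,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
    read_overlap_slack: int = DEFAULT_READ_OVERLAP_SLACK,
) -> list[JunctionCandidate]:
    """Scan all reads' consecutive segment pairs for junction geometry.

    At most one candidate is emitted per read: the qualifying pair with the
    largest combined segment length (ties to the smaller circle_start), then
    the size filter is applied.
    """
    lo, hi = size_range
    out: list[JunctionCandidate] = []
    for read_id, segs in _segments_from_frame(segments).items():
        segs.sort(key=lambda s: (s.read_start, s.read_end))
        best = None  # (combined_len, -circle_start) maximised
        for a, b in zip(segs, segs[1:]):
            cand = classify_pair(a, b, min_seg_len, read_overlap_slack)
            if cand is None:
                continue
            key = (a.read_len + b.read_len, -cand.circle_start)
            if best is None or key > best[0]:
                best = (key, cand)
        if best is not None and lo <= best[1].size <= hi:
            out.append(best[1])
    out.sort(key=lambda c: (c.chrom, c.circle_start, c.circle_end, c.read_id))
    return out


def _lower_median(values: list[int]) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def cluster_junctions(
    candidates: list[JunctionCandidate],
    tolerance: int = DEFAULT_CLUSTER_TOLERANCE,
) -> list[EcDNARecord]:
    """Single-linkage clustering of junction candidates into circle records.

    Two candidates are linked when they share a chromosome and both
    breakpoints differ by at most ``tolerance`` bp.  Record breakpoints are
    the lower medians of member breakpoints; support counts distinct reads.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    by_chrom: dict[str, list[JunctionCandidate]] = defaultdict(list)
    for c in candidates:
        by_chrom[c.chrom].append(c)

    records: list[EcDNARecord] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: (c.circle_start, c.circle_end))
        n = len(group)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

        for i in range(n):
            for j in range(i + 1, n):
                if group[j].circle_start - group[i].circle_start > tolerance:
                    break  # sorted by start
                if abs(group[i].circle_end - group[j].circle_end) <= tolerance:
                    union(i, j)

        members: dict[int, list[JunctionCandidate]] = defaultdict(list)
        for i in range(n):
            members[find(i)].append(group[i])
        for _, cands in sorted(members.items(), key=lambda kv: min(c.circle_start for c in kv[1])):
            start = _lower_median([c.circle_start for c in cands])
            end = _lower_median([c.circle_end for c in cands])
            read_ids = sorted({c.read_id for c in cands})
            records.append(EcDNARecord(chrom, start, end, len(read_ids), read_ids))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records
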