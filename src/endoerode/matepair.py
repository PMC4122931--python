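"""Discordant mate-pair screen for intrapopulation rearrangements.

A large-insert mate-pair library sequenced outward maps in RF orientation
(coordinate-leftmost mate on the reverse strand) at the library insert
size; anything else is discordant and potentially evidence of a structural
variant segregating in the population. The screen classifies each mapped
pair by orientation and outer-distance insert size, applies the filter
cascade — concordant pairs discarded, pairs touching mobile regions
discarded, different-contig pairs set aside, mate-overlapping pairs
discarded — then summarizes the retained orientation mixture and looks for
clusters of discordant pairs supporting a common junction. FR pairs in a
mate-pair library are short-insert paired-end contamination, and scattered
FF/RR pairs are library errors; real rearrangement junctions announce
themselves as *clusters* of co-locating discordant pairs.

Orientation convention: the mate with the smaller start is "left". FR =
left forward, right reverse (innie); RF = left reverse, right forward
(outie, the mate-pair norm); FF/RR = both on one strand. Insert size is
the outer distance, right.end - left.start. Classification is invariant
to swapping the mate labels.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MatePairRecord",
    "ClassifiedPair",
    "ScreenSummary",
    "JunctionCluster",
    "classify_orientation",
    "filter_cascade",
    "orientation_summary",
    "junction_evidence",
    "read_matepair_tsv",
    "write_matepair_tsv",
    "CONCORDANT_WINDOW",
]

#: Insert-size window (bp, inclusive) of a concordant RF mate-pair.
CONCORDANT_WINDOW = (2_211, 3_651)

Mate = tuple[str, int, int, str]  # contig, start, end, strand


@dataclass(frozen=True)
class MatePairRecord:
    """One read pair's mapped positions and strands."""

    pair_id: str
    mate1: Mate
    mate2: Mate
    mobile1: bool = False
    mobile2: bool = False

    def __post_init__(self) -> None:
        for contig, start, end, strand in (self.mate1, self.mate2):
            if start >= end:
                raise ValueError(f"pair {self.pair_id!r}: mate start >= end")
            if strand not in "+-":
                raise ValueError(f"pair {self.pair_id!r}: bad strand {strand!r}")


@dataclass(frozen=True)
class ClassifiedPair:
    record: MatePairRecord
    same_contig: bool
    orientation: Optional[str]  # FF | RR | RF | FR, same-contig only
    insert_size: Optional[int]
    disposition: str  # concordant_discarded | mobile_discarded |
    #                   overlap_discarded | intercontig | retained


def classify_orientation(record: MatePairRecord) -> tuple[Optional[str], Optional[int]]:
    """(orientation, insert size) for a same-contig pair, else (None, None)."""
    (c1, s1, e1, st1), (c2, s2, e2, st2) = record.mate1, record.mate2
    if c1 != c2:
        return None, None
    if (s1, e1, st1) <= (s2, e2, st2):
        left, right = (s1, e1, st1), (s2, e2, st2)
    else:
        left, right = (s2, e2, st2), (s1, e1, st1)
    ls, rs = left[2], right[2]
    if ls == "+" and rs == "-":
        orientation = "FR"
    elif ls == "-" and rs == "+":
        orientation = "RF"
    elif ls == "+":
        orientation = "FF"
    else:
        orientation = "RR"
    return orientation, right[1] - left[0]


def _mates_overlap(record: MatePairRecord) -> bool:
    (c1, s1, e1, _), (c2, s2, e2, _) = record.mate1, record.mate2
    return c1 == c2 and s1 < e2 and s2 < e1


def _in_mobile(mate: Mate, mobile_regions: Mapping[str, Sequence[tuple[int, int]]]) -> bool:
    contig, start, end, _ = mate
    return any(s < end and start < e for s, e in mobile_regions.get(contig, ()))


def filter_cascade(
    records: Iterable[MatePairRecord],
    concordant_window: tuple[int, int] = CONCORDANT_WINDOW,
    mobile_regions: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> list[ClassifiedPair]:
    """Classify every pair through the screen's filter cascade, in order:

    1. concordant pairs (same contig, RF, insert inside the window) out;
    2. pairs with a mate in a mobile region (given intervals or record
       flags) out;
    3. different-contig pairs set aside (no orientation defined);
    4. pairs whose mates overlap each other, partly or entirely, out.

    Each pair receives exactly one disposition; retained pairs have a
    defined orientation and disjoint mates.
    """
    lo, hi = concordant_window
    mobile_regions = mobile_regions or {}
    out: list[ClassifiedPair] = []
    for rec in records:
        orientation, insert = classify_orientation(rec)
        same = orientation is not None
        if same and orientation == "RF" and lo <= insert <= hi:
            disposition = "concordant_discarded"
        elif (
            rec.mobile1
            or rec.mobile2
            or _in_mobile(rec.mate1, mobile_regions)
            or _in_mobile(rec.mate2, mobile_regions)
        ):
            disposition = "mobile_discarded"
        elif not same:
            disposition = "intercontig"
        elif _mates_overlap(rec):
            disposition = "overlap_discarded"
        else:
            disposition = "retained"
        out.append(ClassifiedPair(rec, same, orientation, insert, disposition))
    return out


@dataclass
class ScreenSummary:
    """Disposition and retained-orientation tallies of one screen run."""

    disposition_counts: dict[str, int]
    orientation_counts: dict[str, int]
    retained_total: int
    percent: dict[str, Optional[float]]  # per orientation, of retained; NA -> None

    @property
    def total(self) -> int:
        return sum(self.disposition_counts.values())


def orientation_summary(
    classified: Optional[Iterable[ClassifiedPair]] = None,
    retained_counts: Optional[Mapping[str, int]] = None,
) -> ScreenSummary:
    """Orientation mixture of the retained pairs, as percentages.

    Accepts either classified pairs from :func:`filter_cascade` or, for
    checking published tallies, the retained per-orientation counts
    directly. Percentages are count/retained_total to two decimals; with
    nothing retained they are reported as None.
    """
    dispositions: dict[str, int] = defaultdict(int)
    orient: dict[str, int] = {o: 0 for o in ("FF", "RR", "RF", "FR")}
    if retained_counts is not None:
        for o, c in retained_counts.items():
            orient[o] = int(c)
        dispositions["retained"] = sum(orient.values())
    else:
        for cp in classified or ():
            dispositions[cp.disposition] += 1
            if cp.disposition == "retained":
                orient[cp.orientation] += 1
    retained_total = sum(orient.values())
    assert retained_total == dispositions.get("retained", 0)
    percent: dict[str, Optional[float]] = {
        o: (round(100.0 * c / retained_total, 2) if retained_total else None)
        for o, c in orient.items()
    }
    return ScreenSummary(dict(dispositions), orient, retained_total, percent)


@dataclass
class JunctionCluster:
    contig: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    support: int
    pair_ids: list[str]


def junction_evidence(
    classified: Iterable[ClassifiedPair],
    min_support: int = 10,
    window: int = 1_000,
) -> list[JunctionCluster]:
    """Clusters of retained non-FR pairs supporting a common junction.

    Single-linkage: two pairs link when they sit on one contig and both
    their left-mate and right-mate starts lie within ``window`` bp of each
    other. Components with support >= ``min_support`` are reported as
    candidate rearrangement junctions — a rearrangement-free library
    yields none, matching the screen's expected negative result. FR pairs
    are excluded as paired-end contamination.
    """
    pairs = [
        cp
        for cp in classified
        if cp.disposition == "retained" and cp.orientation != "FR"
    ]
    by_contig: dict[str, list[ClassifiedPair]] = defaultdict(list)
    for cp in pairs:
        by_contig[cp.record.mate1[0]].append(cp)

    clusters: list[JunctionCluster] = []
    for contig in sorted(by_contig):
        group = by_contig[contig]
        coords = []
        for cp in group:
            m1, m2 = cp.record.mate1, cp.record.mate2
            left, right = (m1, m2) if m1[1] <= m2[1] else (m2, m1)
            coords.append((left[1], right[1], cp))
        coords.sort(key=lambda t: (t[0], t[1]))
        n = len(coords)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if coords[j][0] - coords[i][0] > window:
                    break
                if abs(coords[j][1] - coords[i][1]) <= window:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comps: dict[int, list[int]] = defaultdict(list)
        for i in range(n):
            comps[find(i)].append(i)
        for root in sorted(comps):
            idxs = comps[root]
            if len(idxs) < min_support:
                continue
            lefts = [coords[i][0] for i in idxs]
            rights = [coords[i][1] for i in idxs]
            clusters.append(
                JunctionCluster(
                    contig=contig,
                    left_interval=(min(lefts), max(lefts)),
                    right_interval=(min(rights), max(rights)),
                    support=len(idxs),
                    pair_ids=sorted(coords[i][2].record.pair_id for i in idxs),
                )
            )
    clusters.sort(key=lambda c: (c.contig, c.left_interval))
    return clusters


# -- TSV interface -----------------------------------------------------------

_TSV_HEADER = (
    "pair_id\tcontig1\tstart1\tend1\tstrand1\tcontig2\tstart2\tend2\tstrand2"
)


def write_matepair_tsv(records: Iterable[MatePairRecord], path) -> None:
    """Write pairs to the tab-delimited exchange format (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for r in records:
            c1, s1, e1, st1 = r.mate1
            c2, s2, e2, st2 = r.mate2
            fh.write(f"{r.pair_id}\t{c1}\t{s1}\t{e1}\t{st1}\t{c2}\t{s2}\t{e2}\t{st2}\n")


def read_matepair_tsv(path) -> list[MatePairRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected mate-pair TSV header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            pid, c1, s1, e1, st1, c2, s2, e2, st2 = line.rstrip("\n").split("\t")
            records.append(
                MatePairRecord(
                    pair_id=pid,
                    mate1=(c1, int(s1), int(e1), st1),
                    mate2=(c2, int(s2), int(e2), st2),
                )
            )
    return records
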