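"""Signed gene orders, synteny clusters and breakpoint distances.

Two genomes sharing a set of nonmobile single-copy orthologs induce a
signed permutation: genes are indexed 1..n along genome A, and genome B's
order lists those indices with a sign recording whether the gene kept or
flipped its strand relative to A. Syntenic clusters are maximal runs of
genes colinear in both genomes (same order and signs, or fully reversed
with flipped signs); the breakpoint distance — non-conserved adjacencies in
the 0/(n+1)-framed permutation — is an exact, cheap lower-bound proxy for
the number of inversions separating the genomes (each inversion disrupts
at most two adjacencies, so planted inversions >= distance/2 always).

An exact minimal inversion distance (Hannenhalli-Pevzner) is deliberately
out of scope; :func:`greedy_reversal_count` gives a clearly-labelled
heuristic upper bound instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core_io import GeneFeature, MOBILE_CLASSES

__all__ = [
    "SignedGeneOrder",
    "SyntenyCluster",
    "shared_signed_orders",
    "synteny_clusters",
    "breakpoint_distance",
    "pairwise_distance_matrix",
    "greedy_reversal_count",
    "cluster_spans",
    "flanking_element_tally",
]


@dataclass
class SignedGeneOrder:
    """A strain's gene order as a signed permutation of ortholog indices."""

    strain_id: str
    order: list[int]
    index_to_group: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = sorted(abs(x) for x in self.order)
        n = len(self.order)
        if seen != list(range(1, n + 1)):
            raise ValueError(
                f"order of {self.strain_id!r} is not a signed permutation of 1..{n}"
            )


@dataclass
class SyntenyCluster:
    """A maximal colinear run of shared genes; members in genome-A order."""

    members: list[str]
    indices: list[int]
    orientation: str  # "same" or "reversed" in B
    spans: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    flank_categories: set[str] = field(default_factory=set)


def shared_signed_orders(
    features_a: Sequence[GeneFeature],
    features_b: Sequence[GeneFeature],
    ortholog_of: Optional[Mapping[str, str]] = None,
    strain_a: str = "A",
    strain_b: str = "B",
) -> tuple[SignedGeneOrder, SignedGeneOrder, int]:
    """Signed orders over the nonmobile single-copy orthologs shared by both.

    ``ortholog_of`` maps feature_id to ortholog group; when omitted the
    features' own ``ortho_group`` is used. Mobile-class features are
    excluded before indexing; orthologs duplicated within a strain are
    dropped (their count is returned as the third element). Genome A's
    order is 1..n with positive signs by construction; B's entry for a
    gene is +index when the gene kept A's strand and -index otherwise.
    """

    def _groups(feats: Sequence[GeneFeature]) -> dict[str, list[GeneFeature]]:
        out: dict[str, list[GeneFeature]] = {}
        for f in feats:
            if f.is_mobile:
                continue
            grp = ortholog_of.get(f.feature_id) if ortholog_of else f.ortho_group
            if grp:
                out.setdefault(grp, []).append(f)
        return out

    ga, gb = _groups(features_a), _groups(features_b)
    dup = {g for g, fl in ga.items() if len(fl) > 1} | {
        g for g, fl in gb.items() if len(fl) > 1
    }
    shared = sorted((set(ga) & set(gb)) - dup)
    picked = [(g, ga[g][0], gb[g][0]) for g in shared]
    picked.sort(key=lambda t: (t[1].scaffold_id, t[1].start))

    index_to_group = {i + 1: g for i, (g, _, _) in enumerate(picked)}
    order_a = list(range(1, len(picked) + 1))
    b_entries = []
    for i, (g, fa, fb) in enumerate(picked, 1):
        sign = 1 if fa.strand == fb.strand else -1
        b_entries.append((fb.scaffold_id, fb.start, sign * i))
    b_entries.sort(key=lambda t: (t[0], t[1]))
    order_b = [e[2] for e in b_entries]
    return (
        SignedGeneOrder(strain_a, order_a, index_to_group),
        SignedGeneOrder(strain_b, order_b, dict(index_to_group)),
        len(dup),
    )


def synteny_clusters(
    order_a: SignedGeneOrder, order_b: SignedGeneOrder
) -> list[SyntenyCluster]:
    """Maximal runs of A colinear in B, partitioning the shared gene set.

    A run i..j of A's indices forms a cluster when the same genes sit
    consecutively in B either in identical order with identical signs, or
    in fully reversed order with flipped signs. Equivalently the run is
    chained through conserved signed adjacencies, which is how it is
    computed; tests compare against a brute-force enumeration of the
    definition.
    """
    a = order_a.order
    b = order_b.order
    n = len(a)
    if n == 0:
        return []
    pos_b = {abs(x): i for i, x in enumerate(b)}
    sign_b = {abs(x): (1 if x > 0 else -1) for x in b}

    def conserved(x: int, y: int) -> bool:
        """Signed adjacency (x, y) of A survives in B."""
        px, py = pos_b[abs(x)], pos_b[abs(y)]
        sx = sign_b[abs(x)] * (1 if x > 0 else -1)
        sy = sign_b[abs(y)] * (1 if y > 0 else -1)
        if py == px + 1 and sx == 1 and sy == 1:
            return True
        if px == py + 1 and sx == -1 and sy == -1:
            return True
        return False

    clusters: list[SyntenyCluster] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or not conserved(a[i - 1], a[i]):
            indices = [abs(x) for x in a[start:i]]
            if len(indices) == 1:
                orientation = "same" if sign_b[indices[0]] > 0 else "reversed"
            else:
                orientation = (
                    "same" if pos_b[indices[0]] < pos_b[indices[-1]] else "reversed"
                )
            clusters.append(
                SyntenyCluster(
                    members=[order_a.index_to_group.get(k, str(k)) for k in indices],
                    indices=indices,
                    orientation=orientation,
                )
            )
            start = i
    return clusters


def breakpoint_distance(order: Sequence[int], circular: bool = False) -> int:
    """Non-conserved adjacencies of a signed permutation framed by 0 and n+1.

    An adjacency (a, b) is conserved iff b - a == 1 on the signed values.
    Linear framing prepends 0 and appends n+1; circular framing closes the
    permutation on itself instead, comparing successive signed pairs
    around the circle.
    """
    perm = list(order)
    n = len(perm)
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValueError("not a signed permutation of 1..n")
    if n == 0:
        return 0

    def conserved(a: int, b: int) -> bool:
        if b - a == 1:
            return True
        # circular wrap: n followed by 1 (or -1 followed by -n) closes the circle
        return circular and ((a == n and b == 1) or (a == -1 and b == -n))

    if circular:
        pairs = list(zip(perm, perm[1:] + [perm[0]]))
    else:
        framed = [0] + perm + [n + 1]
        pairs = list(zip(framed, framed[1:]))
    return sum(1 for a, b in pairs if not conserved(a, b))


def pairwise_distance_matrix(
    orders: Mapping[str, Sequence[int]], circular: bool = False
) -> tuple[list[str], np.ndarray]:
    """Symmetric breakpoint-distance matrix between strains.

    Each strain's order must be a signed permutation over the same 1..n
    index set. The distance between strains is the breakpoint distance of
    one order expressed in the coordinates of the other; the diagonal is
    zero and the matrix symmetric (breakpoint distance of a permutation
    equals that of its inverse). Triangle inequality is not asserted.
    """
    names = sorted(orders)
    n_strains = len(names)
    mat = np.zeros((n_strains, n_strains), dtype=int)
    for i, j in combinations(range(n_strains), 2):
        rel = _relative_order(orders[names[i]], orders[names[j]])
        d = breakpoint_distance(rel, circular=circular)
        mat[i, j] = mat[j, i] = d
    return names, mat


def _relative_order(ref: Sequence[int], other: Sequence[int]) -> list[int]:
    """Express ``other`` in coordinates where ``ref`` is the identity."""
    rank = {}
    for i, x in enumerate(ref, 1):
        rank[abs(x)] = (i, 1 if x > 0 else -1)
    out = []
    for x in other:
        i, s = rank[abs(x)]
        out.append(i * s * (1 if x > 0 else -1))
    return out


def greedy_reversal_count(order: Sequence[int]) -> int:
    """Heuristic upper bound on the inversion count sorting ``order``.

    Greedy sorting-by-reversals: bring each index home left to right,
    then fix residual negative signs by single-element flips. Always an
    upper bound on the true inversion distance, never a substitute for it.
    """
    perm = list(order)
    n = len(perm)
    count = 0
    for i in range(n):
        target = i + 1
        j = next(k for k in range(i, n) if abs(perm[k]) == target)
        if j != i:
            perm[i : j + 1] = [-x for x in reversed(perm[i : j + 1])]
            count += 1
        if perm[i] == -target:
            perm[i] = target
            count += 1
    return count


def cluster_spans(
    clusters: Iterable[SyntenyCluster],
    features_by_strain: Mapping[str, Sequence[GeneFeature]],
) -> list[SyntenyCluster]:
    """Attach per-strain genomic spans (scaffold, min start, max end)."""
    by_group: dict[str, dict[str, GeneFeature]] = {}
    for strain, feats in features_by_strain.items():
        by_group[strain] = {f.ortho_group: f for f in feats if f.ortho_group}
    for cl in clusters:
        for strain, groups in by_group.items():
            members = [groups[m] for m in cl.members if m in groups]
            if not members:
                continue
            sid = members[0].scaffold_id
            if any(f.scaffold_id != sid for f in members):
                continue  # cluster split over scaffolds: no single span
            cl.spans[strain] = (
                sid,
                min(f.start for f in members),
                max(f.end for f in members),
            )
    return list(clusters)


def flanking_element_tally(
    clusters: Iterable[SyntenyCluster],
    features: Sequence[GeneFeature],
    strain: str,
    window: int = 3_000,
) -> dict[str, int]:
    """How many clusters have a mobile element within ±window of a boundary.

    A cluster counts for category c when any feature of class c starts or
    ends within ``window`` bp of either of its span boundaries on the same
    scaffold; one cluster may count in several categories, and clusters
    with no mobile neighbour count as "none". Clusters lacking a span for
    ``strain`` are skipped.
    """
    mobile = [f for f in features if f.is_mobile]
    tally = {c: 0 for c in sorted(MOBILE_CLASSES)}
    tally["none"] = 0
    for cl in clusters:
        if strain not in cl.spans:
            continue
        sid, s, e = cl.spans[strain]
        near = set()
        for f in mobile:
            if f.scaffold_id != sid:
                continue
            for boundary in (s, e):
                if (
                    abs(f.start - boundary) <= window
                    or abs(f.end - boundary) <= window
                ):
                    near.add(f.klass)
        if near:
            for c in near:
                tally[c] += 1
        else:
            tally["none"] += 1
    return tally
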