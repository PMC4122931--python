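"""COG category frequency profiles and degradation divergence.

A strain's functional profile is the relative frequency of each COG
category among its COG-assigned CDSs. Hits against the COG database arrive
as a precomputed table (running the homology search is out of scope); per
CDS, hits passing the e-value cutoff are reduced to a maximum-total-score
set of mutually nonoverlapping intervals (weighted interval scheduling). A
CDS with accepted hits in m distinct categories contributes 1/m to each,
keeping frequencies on the simplex. Degradation divergence is the profile
minus the mean profile of a designated set of free-living relatives,
zero-filled over the union category set so the subtraction is defined
everywhere.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HitRecord",
    "CategoryProfile",
    "DivergenceProfile",
    "select_nonoverlapping_hits",
    "category_frequencies",
    "degradation_divergence",
]

EVALUE_CUTOFF = 1e-3


@dataclass(frozen=True)
class HitRecord:
    """One database hit on a CDS: query interval, category, score, e-value."""

    cds_id: str
    start: int
    end: int
    category: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")


@dataclass
class CategoryProfile:
    strain_id: str
    freq: dict[str, float] = field(default_factory=dict)
    n_assigned: int = 0


@dataclass
class DivergenceProfile:
    strain_id: str
    delta: dict[str, float] = field(default_factory=dict)


def select_nonoverlapping_hits(
    hits: Sequence[HitRecord], evalue_cutoff: float = EVALUE_CUTOFF
) -> list[HitRecord]:
    """Best nonoverlapping hit set per CDS (max total score).

    Hits with evalue above the cutoff are dropped; the rest are solved per
    CDS by weighted interval scheduling. Among equal-score optima the
    deterministic preference is lower evalue, then leftmost start
    (encoded in the DP's secondary key). Intervals are half-open, so
    touching hits do not conflict.
    """
    by_cds: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.evalue <= evalue_cutoff:
            by_cds[h.cds_id].append(h)
    out: list[HitRecord] = []
    for cds in sorted(by_cds):
        out.extend(_schedule(by_cds[cds]))
    return out


def _schedule(hits: list[HitRecord]) -> list[HitRecord]:
    # weighted interval scheduling; dp entries carry the chosen index set
    hits = sorted(hits, key=lambda h: (h.end, h.start, h.evalue))
    n = len(hits)
    ends = [h.end for h in hits]
    best: list[tuple[float, tuple[int, ...]]] = [(0.0, ())]  # (score, indices)
    for i in range(n):
        h = hits[i]
        p = bisect_right(ends, h.start, 0, i)
        skip = best[i]
        take = (best[p][0] + h.score, best[p][1] + (i,))
        if take[0] > skip[0]:
            chosen = take
        elif take[0] < skip[0]:
            chosen = skip
        else:  # equal score: lower evalues, then leftmost starts
            def _key(t: tuple[float, tuple[int, ...]]):
                members = [hits[j] for j in t[1]]
                return (
                    sorted(m.evalue for m in members),
                    sorted((m.start, m.end) for m in members),
                )

            chosen = min(take, skip, key=_key)
        best.append(chosen)
    return [hits[j] for j in sorted(best[n][1])]


def category_frequencies(
    accepted_hits: Sequence[HitRecord], strain_id: str
) -> CategoryProfile:
    """Relative COG category frequencies over COG-assigned CDSs.

    Absolute category counts are divided by the number of COG-assigned
    CDSs; a CDS whose accepted hits span m distinct categories contributes
    1/m to each, so the frequencies sum to one. An empty hit set yields an
    empty profile with ``n_assigned`` 0 (no division by zero).
    """
    cats_by_cds: dict[str, set[str]] = defaultdict(set)
    for h in accepted_hits:
        cats_by_cds[h.cds_id].add(h.category)
    profile = CategoryProfile(strain_id=strain_id, n_assigned=len(cats_by_cds))
    if not cats_by_cds:
        return profile
    counts: dict[str, float] = defaultdict(float)
    for cats in cats_by_cds.values():
        for c in cats:
            counts[c] += 1.0 / len(cats)
    profile.freq = {c: counts[c] / profile.n_assigned for c in sorted(counts)}
    return profile


def degradation_divergence(
    profiles: Mapping[str, CategoryProfile], free_living_ids: Iterable[str]
) -> dict[str, DivergenceProfile]:
    """Per-category deviation of every strain from the free-living mean.

    The mean per-category frequency over the free-living strains is
    subtracted from every strain's frequency (free-living strains
    included, so their deltas average to zero per category). Categories
    missing from a strain are zero-filled over the union category set.
    """
    free = list(free_living_ids)
    if not free:
        raise ValueError("free_living_ids must be nonempty")
    missing = [s for s in free if s not in profiles]
    if missing:
        raise ValueError(f"free-living strains missing from profiles: {missing}")
    categories = sorted({c for p in profiles.values() for c in p.freq})
    mean = {
        c: sum(profiles[s].freq.get(c, 0.0) for s in free) / len(free)
        for c in categories
    }
    return {
        sid: DivergenceProfile(
            strain_id=sid,
            delta={c: p.freq.get(c, 0.0) - mean[c] for c in categories},
        )
        for sid, p in profiles.items()
    }
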