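"""Synthetic genomes, scaffolds, protein sets and mate-pair libraries.

Every analysis stage in this package is exercised against data with known
ground truth: a single chromosome with non-overlapping genes, derived
strains related by block inversions (optionally with IS elements planted at
the breakpoints), N-gapped scaffolds, planted repeat families, proteins
degraded by truncation/internal stops/frameshifts, and a mate-pair library
that is a mixture of concordant RF pairs, short-insert FR paired-end
contamination, and rare FF/RR orientation errors.

Determinism: one global seed fans out to per-stage child generators via
``numpy.random.SeedSequence(seed, spawn_key=(STAGE,))`` where STAGE is a
fixed per-operation integer (documented next to each operation). Identical
configs therefore give byte-identical outputs, and stages are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_io import GeneFeature, ScaffoldSet

__all__ = [
    "SimulationConfig",
    "MatePairConfig",
    "TruthSet",
    "generate_genome",
    "apply_inversions",
    "scaffoldize",
    "plant_repeats",
    "random_proteins",
    "pseudogenize",
    "simulate_matepairs",
    "simulate_strain_set",
]

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# per-stage spawn keys for the global-seed fan-out
_STAGE_GENOME = 1
_STAGE_INVERSIONS = 2
_STAGE_SCAFFOLDIZE = 3
_STAGE_REPEATS = 4
_STAGE_PSEUDO = 5
_STAGE_MATEPAIRS = 6
_STAGE_STRAINS = 7


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class MatePairConfig:
    """Mixture and insert-size model of a simulated mate-pair library.

    The insert size is the outer distance (leftmost start to rightmost
    end). Concordant pairs are RF with insert ~ Normal(insert_mu,
    insert_sd) truncated to more than twice the read length; FR
    contamination mimics a short-insert paired-end library; FF/RR pairs
    land at random positions. Fractions must sum to 1.
    """

    n_pairs: int = 50_000
    insert_mu: float = 2931.0  # midpoint of the 2,211-3,651 bp concordance window
    insert_sd: float = 240.0  # window spans mu +/- 3 sd
    read_len: int = 100
    frac_concordant_rf: float = 0.95
    frac_fr_contam: float = 0.04
    frac_ff_err: float = 0.005
    frac_rr_err: float = 0.005
    fr_insert_range: tuple[int, int] = (200, 500)

    def __post_init__(self) -> None:
        total = (
            self.frac_concordant_rf
            + self.frac_fr_contam
            + self.frac_ff_err
            + self.frac_rr_err
        )
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mate-pair class fractions sum to {total}, not 1")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    genome_length: int = 200_000
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (300, 1200)
    min_intergenic: int = 200
    gc_content: float = 0.50
    n_repeat_families: int = 3
    repeat_length: int = 400
    repeat_copies: int = 3
    n_gaps: int = 10
    gap_size_range: tuple[int, int] = (100, 500)
    n_inversions: int = 5
    pseudogenize_fraction: float = 0.3
    matepair: MatePairConfig = field(default_factory=MatePairConfig)

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_genes", "n_repeat_families",
                     "repeat_copies", "n_gaps", "n_inversions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.pseudogenize_fraction <= 1.0):
            raise ValueError("pseudogenize_fraction must be in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth planted by the generators, keyed by artifact ids."""

    gaps: list[tuple[str, int, int, str]] = field(default_factory=list)  # +removed seq
    repeats: list[tuple[str, int, int, int]] = field(default_factory=list)  # +family
    inversion_breakpoints: list[int] = field(default_factory=list)
    signed_order: list[int] = field(default_factory=list)
    protein_states: dict[str, dict] = field(default_factory=dict)
    pair_classes: dict[str, str] = field(default_factory=dict)


# -- genome ------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig,
) -> tuple[ScaffoldSet, list[GeneFeature], TruthSet]:
    """One chromosome of i.i.d. background with non-overlapping genes.

    Gene lengths are uniform over ``gene_length_range``; the remaining
    slack is spread over the ``n_genes + 1`` intergenic segments on top of
    ``min_intergenic``, so no gene touches another. Strands are random.
    Stage key 1 of the seed fan-out.
    """
    rng = _rng(config.seed, _STAGE_GENOME)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(_BASES, size=config.genome_length, p=probs))

    n = config.n_genes
    if n == 0:
        scaff = ScaffoldSet(records={"chr1": seq})
        return scaff, [], TruthSet()

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    reserved = int(lengths.sum()) + (n + 1) * config.min_intergenic
    slack = config.genome_length - reserved
    if slack < 0:
        raise ValueError(
            f"cannot place {n} genes of total span {int(lengths.sum())} bp with "
            f"{config.min_intergenic} bp spacing into {config.genome_length} bp; "
            "reduce n_genes or gene lengths"
        )
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    features: list[GeneFeature] = []
    pos = 0
    for i in range(n):
        pos += config.min_intergenic + int(extra[i])
        start, end = pos, pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GeneFeature(
                feature_id=f"g{i + 1:04d}",
                scaffold_id="chr1",
                start=start,
                end=end,
                strand=strand,
                klass="CDS",
                ortho_group=f"og{i + 1:04d}",
            )
        )
        pos = end
    scaff = ScaffoldSet(records={"chr1": seq})
    return scaff, features, TruthSet()


# -- inversions --------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def apply_inversions(
    genome: ScaffoldSet,
    features: Sequence[GeneFeature],
    n_inversions: int,
    seed: int,
    plant_is: bool = False,
    is_length: int = 60,
) -> tuple[ScaffoldSet, list[GeneFeature], TruthSet]:
    """Derive a rearranged strain by inverting random gene blocks.

    Each inversion picks a contiguous block of genes (in the *current*
    order) and reverses the enclosed sequence between two intergenic
    breakpoints; no gene is ever cut. The truth signed permutation tracks
    block flips: genes are numbered 1..n in the source order, and an
    inverted block reverses and negates its entries. With ``plant_is``,
    an IS feature is annotated over the background at each breakpoint
    (deduplicated when inversions share a breakpoint). Stage key 2.
    """
    if n_inversions < 0:
        raise ValueError("n_inversions must be >= 0")
    rng = _rng(seed, _STAGE_INVERSIONS)
    sid = next(iter(genome.records))
    seq = genome.records[sid]
    feats = sorted(features, key=lambda f: f.start)
    n = len(feats)
    order = list(range(1, n + 1))  # signed permutation truth
    breakpoints: list[int] = []

    for _ in range(n_inversions):
        if n < 2:
            break
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i + 1, n))  # invert genes i..j inclusive
        left_gap_lo = feats[i - 1].end if i > 0 else 0
        left_gap_hi = feats[i].start
        right_gap_lo = feats[j].end
        right_gap_hi = feats[j + 1].start if j + 1 < n else len(seq)
        b1 = int(rng.integers(left_gap_lo + 1, left_gap_hi)) if left_gap_hi > left_gap_lo + 1 else left_gap_lo
        b2 = int(rng.integers(right_gap_lo + 1, right_gap_hi)) if right_gap_hi > right_gap_lo + 1 else right_gap_hi

        seq = seq[:b1] + _revcomp(seq[b1:b2]) + seq[b2:]
        new_feats: list[GeneFeature] = []
        for f in feats:
            if b1 <= f.start and f.end <= b2:
                new_feats.append(
                    replace(
                        f,
                        start=b1 + (b2 - f.end),
                        end=b1 + (b2 - f.start),
                        strand="-" if f.strand == "+" else "+",
                    )
                )
            else:
                new_feats.append(f)
        feats = sorted(new_feats, key=lambda f: f.start)
        order[i : j + 1] = [-x for x in reversed(order[i : j + 1])]
        breakpoints = [b1 + (b2 - p) if b1 <= p <= b2 else p for p in breakpoints]
        breakpoints.extend([b1, b2])

    derived = ScaffoldSet(records={sid: seq})
    truth = TruthSet(signed_order=order, inversion_breakpoints=sorted(set(breakpoints)))
    out_feats = list(feats)
    if plant_is:
        occupied = sorted((f.start, f.end) for f in feats)
        k = 0
        for bp in truth.inversion_breakpoints:
            s = max(0, bp - is_length // 2)
            e = min(len(seq), s + is_length)
            # clip against neighbouring genes; skip if no room
            for gs, ge in occupied:
                if gs < e and s < ge:
                    if bp <= gs:
                        e = min(e, gs)
                    else:
                        s = max(s, ge)
            if e - s >= 10:
                k += 1
                out_feats.append(
                    GeneFeature(
                        feature_id=f"is{k:03d}",
                        scaffold_id=sid,
                        start=s,
                        end=e,
                        strand="+",
                        klass="IS",
                    )
                )
        out_feats.sort(key=lambda f: f.start)
    return derived, out_feats, truth


# -- scaffold gaps -----------------------------------------------------------

def _intergenic_segments(
    seq_len: int, features: Sequence[GeneFeature], margin: int = 1
) -> list[tuple[int, int]]:
    """Intervals not covered by any feature, shrunk by ``margin`` per side."""
    segs = []
    pos = 0
    for f in sorted(features, key=lambda f: f.start):
        if f.start - pos > 2 * margin:
            segs.append((pos + margin, f.start - margin))
        pos = max(pos, f.end)
    if seq_len - pos > 2 * margin:
        segs.append((pos + margin, seq_len - margin))
    return segs


def scaffoldize(
    genome: ScaffoldSet,
    features: Sequence[GeneFeature],
    n_gaps: int,
    gap_size_range: tuple[int, int],
    seed: int,
) -> tuple[ScaffoldSet, TruthSet]:
    """Replace inter-gene segments with N-runs, emulating assembly gaps.

    Gap lengths are sampled uniformly from ``gap_size_range`` and clipped
    to fit their segment; each chosen segment hosts at most one gap, with
    at least one non-N base on both sides so the run stays maximal.
    Replacement (not insertion) keeps all other coordinates stable; the
    truth records the overwritten sequence. Stage key 3.
    """
    rng = _rng(seed, _STAGE_SCAFFOLDIZE)
    sid = next(iter(genome.records))
    seq = genome.records[sid]
    lo, hi = gap_size_range
    segs = [s for s in _intergenic_segments(len(seq), features, margin=2) if s[1] - s[0] >= lo]
    if n_gaps > len(segs):
        raise ValueError(
            f"n_gaps={n_gaps} exceeds the {len(segs)} intergenic sites that can "
            f"host a gap of >= {lo} bp"
        )
    chosen = sorted(rng.choice(len(segs), size=n_gaps, replace=False).tolist())
    truth = TruthSet()
    chars = list(seq)
    for ci in chosen:
        s, e = segs[ci]
        size = min(int(rng.integers(lo, hi + 1)), e - s)
        start = s + int(rng.integers(0, (e - s) - size + 1))
        truth.gaps.append((sid, start, start + size, seq[start : start + size]))
        chars[start : start + size] = "N" * size
    truth.gaps.sort(key=lambda g: g[1])
    return ScaffoldSet(records={sid: "".join(chars)}), truth


# -- repeats -----------------------------------------------------------------

def plant_repeats(
    scaffolds: ScaffoldSet,
    features: Sequence[GeneFeature],
    n_families: int,
    copies: int,
    length: int,
    seed: int,
    gap_flank_fraction: float = 0.5,
) -> tuple[ScaffoldSet, TruthSet]:
    """Overwrite inter-gene background with repeat-family copies.

    Each family is one random core sequence copied ``copies`` times,
    forward or reverse-complement; about ``gap_flank_fraction`` of the
    copies are placed immediately against an N-run flank (repeats crowd
    assembly gaps in real fragmented genomes). Copies never overlap genes,
    gaps, or each other. Stage key 4.
    """
    rng = _rng(seed, _STAGE_REPEATS)
    sid = next(iter(scaffolds.records))
    seq = scaffolds.records[sid]
    chars = list(seq)
    import re as _re

    n_runs = [(m.start(), m.end()) for m in _re.finditer(r"N+", seq)]
    blocked = sorted(
        [(f.start, f.end) for f in features] + [(s, e) for s, e in n_runs]
    )
    placed: list[tuple[int, int]] = []
    truth = TruthSet()

    def _free(s: int, e: int) -> bool:
        if s < 0 or e > len(seq):
            return False
        for bs, be in blocked + placed:
            if bs < e and s < be:
                return False
        return True

    for fam in range(n_families):
        core = "".join(rng.choice(_BASES, size=length))
        want_flank = rng.random(copies) < gap_flank_fraction
        for c in range(copies):
            pos = -1
            if want_flank[c] and n_runs:
                gs, ge = n_runs[int(rng.integers(0, len(n_runs)))]
                for cand in ((gs - length, gs), (ge, ge + length)):
                    if _free(*cand):
                        pos = cand[0]
                        break
            if pos < 0:
                for _ in range(200):
                    s = int(rng.integers(0, len(seq) - length + 1))
                    if _free(s, s + length):
                        pos = s
                        break
            if pos < 0:
                raise ValueError(
                    "could not place repeat copy; genome too crowded for "
                    f"{n_families}x{copies} repeats of {length} bp"
                )
            copy = core if rng.random() < 0.5 else _revcomp(core)
            chars[pos : pos + length] = copy
            placed.append((pos, pos + length))
            truth.repeats.append((sid, pos, pos + length, fam))
    truth.repeats.sort(key=lambda r: r[1])
    return ScaffoldSet(records={sid: "".join(chars)}), truth


# -- proteins ----------------------------------------------------------------

def random_proteins(
    n: int, length_range: tuple[int, int], rng: np.random.Generator, prefix: str = "p"
) -> dict[str, str]:
    """Random amino-acid sequences over the 20-letter alphabet."""
    lo, hi = length_range
    out = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        out[f"{prefix}{i + 1:04d}"] = "".join(rng.choice(_AA, size=length))
    return out


def pseudogenize(
    proteins: dict[str, str],
    fraction: float,
    seed: int,
    modes: tuple[str, ...] = ("truncate",),
    retained_range: tuple[float, float] = (0.05, 0.90),
) -> tuple[dict[str, str], TruthSet]:
    """Degrade a fraction of proteins, recording state and retained fraction.

    Modes: ``truncate`` keeps an N-terminal prefix; ``internal_stop``
    truncates at a premature stop codon (equivalent product, distinct
    provenance); ``frameshift`` keeps the prefix and garbles the remainder
    with random residues, as a shifted reading frame would. The retained
    fraction is sampled uniformly from ``retained_range``. Stage key 5.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    bad = set(modes) - {"truncate", "internal_stop", "frameshift"}
    if bad:
        raise ValueError(f"unknown pseudogenization modes: {sorted(bad)}")
    rng = _rng(seed, _STAGE_PSEUDO)
    ids = sorted(proteins)
    n_hit = int(round(fraction * len(ids)))
    hit = set(rng.choice(ids, size=n_hit, replace=False).tolist()) if n_hit else set()
    out: dict[str, str] = {}
    truth = TruthSet()
    for pid in ids:
        seq = proteins[pid]
        if pid not in hit:
            out[pid] = seq
            truth.protein_states[pid] = {"state": "intact", "retained_fraction": 1.0}
            continue
        mode = modes[int(rng.integers(0, len(modes)))]
        retained = float(rng.uniform(*retained_range))
        cut = max(1, int(round(retained * len(seq))))
        if mode == "frameshift":
            tail = "".join(rng.choice(_AA, size=len(seq) - cut))
            out[pid] = seq[:cut] + tail
        else:
            out[pid] = seq[:cut]
        truth.protein_states[pid] = {
            "state": "pseudo",
            "retained_fraction": cut / len(seq),
            "mode": mode,
        }
    return out, truth


# -- mate pairs --------------------------------------------------------------

def simulate_matepairs(
    contigs: ScaffoldSet,
    config: MatePairConfig,
    seed: int,
) -> tuple[list, TruthSet]:
    """Simulate a mapped mate-pair library as position/strand records.

    Read-level sequence is never generated; records carry only the mapped
    intervals and strands the downstream screen consumes. FF/RR pairs are
    redrawn until the two reads do not overlap, so the planted class is
    recoverable exactly per record. Stage key 6.
    """
    from .matepair import MatePairRecord

    rng = _rng(seed, _STAGE_MATEPAIRS)
    rl = config.read_len
    names = sorted(contigs.records)
    lens = np.array([contigs.length_of(s) for s in names], dtype=float)
    max_insert = config.insert_mu + 4 * config.insert_sd
    if lens.max() < max_insert:
        raise ValueError(
            f"longest contig ({int(lens.max())} bp) shorter than the maximum "
            f"insert (~{int(max_insert)} bp)"
        )
    usable = lens >= max_insert
    weights = np.where(usable, lens, 0.0)
    weights /= weights.sum()

    classes = ("concordant_RF", "FR_contam", "FF_err", "RR_err")
    fracs = np.array(
        [
            config.frac_concordant_rf,
            config.frac_fr_contam,
            config.frac_ff_err,
            config.frac_rr_err,
        ]
    )
    records: list[MatePairRecord] = []
    truth = TruthSet()
    draws = rng.choice(len(classes), size=config.n_pairs, p=fracs)
    for idx in range(config.n_pairs):
        cls = classes[draws[idx]]
        ci = int(rng.choice(len(names), p=weights))
        contig, clen = names[ci], int(lens[ci])
        pid = f"mp{idx + 1:07d}"
        if cls == "concordant_RF":
            insert = 0
            while insert <= 2 * rl:
                insert = int(round(rng.normal(config.insert_mu, config.insert_sd)))
            s = int(rng.integers(0, clen - insert + 1))
            m1 = (contig, s, s + rl, "-")
            m2 = (contig, s + insert - rl, s + insert, "+")
        elif cls == "FR_contam":
            insert = int(rng.integers(config.fr_insert_range[0], config.fr_insert_range[1] + 1))
            s = int(rng.integers(0, clen - insert + 1))
            m1 = (contig, s, s + rl, "+")
            m2 = (contig, s + insert - rl, s + insert, "-")
        else:
            strand = "+" if cls == "FF_err" else "-"
            while True:
                a = int(rng.integers(0, clen - rl + 1))
                b = int(rng.integers(0, clen - rl + 1))
                if abs(a - b) >= rl:
                    break
            m1 = (contig, min(a, b), min(a, b) + rl, strand)
            m2 = (contig, max(a, b), max(a, b) + rl, strand)
        if rng.random() < 0.5:  # classification must not depend on mate labels
            m1, m2 = m2, m1
        records.append(MatePairRecord(pair_id=pid, mate1=m1, mate2=m2))
        truth.pair_classes[pid] = cls
    return records, truth


# -- multi-strain ortholog sets ---------------------------------------------

def simulate_strain_set(
    n_groups: int,
    seed: int,
    strains: tuple[str, ...] = ("SAp", "SCt", "SCc"),
    length_range: tuple[int, int] = (120, 400),
    state_probs: tuple[float, float, float] = (0.6, 0.25, 0.15),
    retained_range: tuple[float, float] = (0.40, 0.90),
    mobile_group_fraction: float = 0.0,
) -> tuple[dict, dict, list[tuple[str, str, str]], dict]:
    """Ortholog groups across strains with planted intact/pseudo/absent states.

    Returns ``(proteins_by_strain, klass_by_strain, ortholog_rows, truth)``
    where ``proteins_by_strain[strain][fid]`` is a sequence,
    ``klass_by_strain[strain][fid]`` is CDS/pseudogene/IS, ortholog_rows
    are (group_id, strain, feature_id), and truth maps group_id to planted
    per-strain states plus a mobile flag. States are drawn from
    ``state_probs`` per strain, re-drawn until the group has at least two
    non-absent members and one intact one (groups are seeded from shared
    CDSs, so an intact representative always exists). Pseudogene retained
    fractions are sampled from ``retained_range``, whose default sits
    safely above the gray zone around the 30% relative-score cutoff so the
    rule can recover the planted state exactly. ``mobile_group_fraction``
    gives that share of groups an IS member (such groups must be filtered
    out downstream). Stage key 7.
    """
    rng = _rng(seed, _STAGE_STRAINS)
    proteins: dict[str, dict[str, str]] = {s: {} for s in strains}
    klasses: dict[str, dict[str, str]] = {s: {} for s in strains}
    rows: list[tuple[str, str, str]] = []
    truth: dict[str, dict] = {}
    states = ("intact", "pseudo", "absent")
    for g in range(n_groups):
        gid = f"og{g + 1:04d}"
        ref = "".join(rng.choice(_AA, size=int(rng.integers(*length_range))))
        while True:
            drawn = [states[i] for i in rng.choice(3, size=len(strains), p=state_probs)]
            if sum(s != "absent" for s in drawn) >= 2 and "intact" in drawn:
                break
        is_mobile_group = rng.random() < mobile_group_fraction
        truth[gid] = {"states": dict(zip(strains, drawn)), "mobile": is_mobile_group}
        for strain, state in zip(strains, drawn):
            if state == "absent":
                continue
            fid = f"{strain}_{gid}"
            rows.append((gid, strain, fid))
            if state == "intact":
                # light neutral divergence: a few substitutions
                seq = list(ref)
                for _ in range(max(1, len(ref) // 50)):
                    p = int(rng.integers(0, len(seq)))
                    seq[p] = str(rng.choice(_AA))
                proteins[strain][fid] = "".join(seq)
                klasses[strain][fid] = "CDS"
            else:
                retained = float(rng.uniform(*retained_range))
                cut = max(1, int(round(retained * len(ref))))
                proteins[strain][fid] = ref[:cut]
                klasses[strain][fid] = "pseudogene"
        if is_mobile_group:
            strain = strains[int(rng.integers(0, len(strains)))]
            fid = f"{strain}_{gid}_is"
            rows.append((gid, strain, fid))
            proteins[strain][fid] = "".join(rng.choice(_AA, size=100))
            klasses[strain][fid] = "IS"
            truth[gid]["mobile_member"] = fid
    return proteins, klasses, rows, truth
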