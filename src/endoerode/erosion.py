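"""Pseudogene state matrices under the relative alignment-score rule.

Genome erosion in endosymbionts is read from a per-strain gene-state matrix
over shared ortholog groups: a gene is *intact* when an annotated CDS
member exists, *pseudo* when only a degraded fragment remains whose local
alignment score against an intact representative reaches at least 30% of
the representative's self-alignment score, and *absent* otherwise. Groups
touched by mobile elements are excluded, as are groups seen in fewer than
two strains. Inactivation events are then placed on the branches of a
fixed rooted species topology under Dollo parsimony (a lost gene is never
regained: intact -> pseudo -> absent is the only admissible order along
any root-to-leaf path).

The score is a raw Smith-Waterman local alignment score under BLOSUM62
with affine gaps (a gap of length L costs 11 + L). Raw score rather than
bitscore: the ratio to the self-score cancels any affine bitscore
constants, and the raw optimum is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import MOBILE_CLASSES

__all__ = [
    "local_align_score",
    "relative_score",
    "assign_state",
    "build_state_matrix",
    "assign_loss_branches",
    "OrthoStateMatrix",
    "BranchEvents",
    "RELATIVE_SCORE_CUTOFF",
]

#: Fraction of the self-alignment score below which a fragment no longer
#: counts as a (pseudo)gene.
RELATIVE_SCORE_CUTOFF = 0.30

_STATE_ORDER = {"intact": 0, "pseudo": 1, "absent": 2}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.load("BLOSUM62")
    arr = matrix.copy()
    if "X" in matrix.alphabet:
        xi = matrix.alphabet.index("X")
        for i in range(len(matrix.alphabet)):
            arr[xi, i] = 0.0
            arr[i, xi] = 0.0
    aligner.substitution_matrix = arr
    # gap of length L costs 11 + L
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def local_align_score(a: str, b: str) -> float:
    """Optimal local alignment raw score of two protein sequences.

    BLOSUM62, gap open 11 / extend 1 (length-L gap costs 11 + L); X is
    tolerated and scores 0 against everything. Symmetric in its
    arguments; >= 0 by the local-alignment empty-alignment floor.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    for name, s in (("first", a), ("second", b)):
        bad = set(s) - _ALPHABET
        if bad:
            raise ValueError(f"{name} sequence has non-amino-acid characters {sorted(bad)}")
    return float(_ALIGNER.score(a, b))


def relative_score(query: str, ref: str) -> float:
    """Alignment score of query against ref, relative to ref's self-score."""
    self_score = local_align_score(ref, ref)
    if self_score <= 0:
        raise ValueError("reference self-score is 0; cannot form a ratio")
    return local_align_score(query, ref) / self_score


@dataclass(frozen=True)
class GeneEvidence:
    """What one strain shows for one ortholog group."""

    has_intact_cds: bool
    fragments: tuple[str, ...] = ()


def assign_state(evidence: GeneEvidence, ref: Optional[str]) -> str:
    """intact / pseudo / absent for one strain-by-group cell.

    An annotated CDS wins outright. Failing that, the best fragment must
    reach the 30% relative-score cutoff against the intact representative
    to count as a pseudogene; below the cutoff the gene is scored absent —
    eroded past recognition is indistinguishable from lost.
    """
    if evidence.has_intact_cds:
        return "intact"
    if ref and evidence.fragments:
        best = max(relative_score(f, ref) for f in evidence.fragments if f)
        if best >= RELATIVE_SCORE_CUTOFF:
            return "pseudo"
    return "absent"


@dataclass
class OrthoStateMatrix:
    """Rows: ortholog groups (lexicographic); columns: strains.

    ``cells[group][strain]`` is intact/pseudo/absent; ``provenance``
    holds the evidence behind each call (feature id or relative score).
    ``dropped`` records filtered groups with the reason.
    """

    strains: tuple[str, ...]
    cells: dict[str, dict[str, str]]
    provenance: dict[str, dict[str, str]]
    dropped: dict[str, str]

    @property
    def groups(self) -> list[str]:
        return sorted(self.cells)

    def to_rows(self) -> list[dict]:
        return [
            {"group": g, **{s: self.cells[g][s] for s in self.strains}}
            for g in self.groups
        ]


def build_state_matrix(
    proteins_by_strain: Mapping[str, Mapping[str, str]],
    klass_by_strain: Mapping[str, Mapping[str, str]],
    ortholog_rows: Iterable[tuple[str, str, str]],
) -> OrthoStateMatrix:
    """Build the strain-by-group state matrix from ortholog membership.

    ``ortholog_rows`` are (group_id, strain, feature_id). Per group the
    intact representative is the longest member annotated as CDS. Groups
    with any mobile-class member are removed, as are groups non-absent in
    fewer than two strains. Row order is lexicographic by group id.
    """
    strains = tuple(sorted(proteins_by_strain))
    rows = list(ortholog_rows)
    for gid, strain, fid in rows:
        if strain not in proteins_by_strain:
            raise ValueError(f"ortholog table references unknown strain {strain!r}")

    members: dict[str, dict[str, list[str]]] = {}
    for gid, strain, fid in rows:
        members.setdefault(gid, {}).setdefault(strain, []).append(fid)

    cells: dict[str, dict[str, str]] = {}
    provenance: dict[str, dict[str, str]] = {}
    dropped: dict[str, str] = {}
    for gid in sorted(members):
        by_strain = members[gid]
        all_fids = [(s, f) for s, fl in by_strain.items() for f in fl]
        if any(klass_by_strain[s].get(f) in MOBILE_CLASSES for s, f in all_fids):
            dropped[gid] = "mobile_member"
            continue
        # intact representative: longest CDS member across strains
        cds = [
            (s, f)
            for s, f in all_fids
            if klass_by_strain[s].get(f) == "CDS" and proteins_by_strain[s].get(f)
        ]
        ref = None
        if cds:
            s, f = max(cds, key=lambda sf: (len(proteins_by_strain[sf[0]][sf[1]]), sf))
            ref = proteins_by_strain[s][f]
        row: dict[str, str] = {}
        prov: dict[str, str] = {}
        for strain in strains:
            fids = by_strain.get(strain, [])
            has_cds = any(klass_by_strain[strain].get(f) == "CDS" for f in fids)
            fragments = tuple(
                proteins_by_strain[strain][f]
                for f in fids
                if klass_by_strain[strain].get(f) != "CDS"
                and proteins_by_strain[strain].get(f)
            )
            state = assign_state(GeneEvidence(has_cds, fragments), ref)
            row[strain] = state
            if state == "intact":
                prov[strain] = "cds:" + next(
                    f for f in fids if klass_by_strain[strain].get(f) == "CDS"
                )
            elif state == "pseudo":
                best = max(relative_score(f, ref) for f in fragments)
                prov[strain] = f"fragment_relative_score:{best:.3f}"
            else:
                prov[strain] = "no_evidence"
        if sum(s != "absent" for s in row.values()) < 2:
            dropped[gid] = "fewer_than_two_strains"
            continue
        cells[gid] = row
        provenance[gid] = prov
    return OrthoStateMatrix(strains, cells, provenance, dropped)


# -- Dollo event placement ---------------------------------------------------

@dataclass(frozen=True)
class BranchEvents:
    """Per-branch event counts for one gene on the fixed 3-leaf topology.

    Branches of ((left, right), out) rooted with an intact outgroup state:
    ``root_internal`` (root to the ancestor of the ingroup pair), the
    three terminal branches, and a total. ``ambiguous`` flags patterns
    whose minimal labeling puts an event on the internal branch, where
    independent terminal events could equally produce the leaf states.
    """

    pseudogenization: dict
    loss: dict
    total_events: int
    ambiguous: bool


def _branch_events(parent: str, child: str) -> tuple[int, int]:
    """(pseudogenization, loss) transitions along one branch."""
    p, c = _STATE_ORDER[parent], _STATE_ORDER[child]
    if c < p:
        raise ValueError("Dollo violation: state regained along a branch")
    pseudo = 1 if p < 1 <= c else 0
    loss = 1 if p < 2 <= c else 0
    return pseudo, loss


def assign_loss_branches(
    pattern: Mapping[str, str],
    topology: tuple[tuple[str, str], str] = (("SAp", "SCt"), "SCc"),
) -> BranchEvents:
    """Place inactivation events on a 3-leaf rooted tree by Dollo parsimony.

    The root is assumed intact (outgroup state). The only free labeling is
    the internal node; all admissible labelings are enumerated and the one
    with the fewest events wins. A branch where a gene passes intact to
    absent carries both a pseudogenization and a loss event (the pseudo
    stage is obligatory under Dollo, merely unobserved).
    """
    (left, right), out = topology
    for leaf in (left, right, out):
        if pattern[leaf] not in _STATE_ORDER:
            raise ValueError(f"bad state {pattern[leaf]!r} for leaf {leaf!r}")

    best: Optional[tuple[int, dict, dict]] = None
    for internal in ("intact", "pseudo", "absent"):
        if _STATE_ORDER[internal] > min(
            _STATE_ORDER[pattern[left]], _STATE_ORDER[pattern[right]]
        ):
            continue  # Dollo: children cannot regain
        try:
            branches = {
                "root_internal": _branch_events("intact", internal),
                left: _branch_events(internal, pattern[left]),
                right: _branch_events(internal, pattern[right]),
                out: _branch_events("intact", pattern[out]),
            }
        except ValueError:
            continue
        total = sum(p + l for p, l in branches.values())
        if best is None or total < best[0]:
            pseudo = {b: pl[0] for b, pl in branches.items()}
            loss = {b: pl[1] for b, pl in branches.items()}
            best = (total, pseudo, loss)
    assert best is not None  # internal="intact" is always admissible
    total, pseudo, loss = best
    on_internal = pseudo["root_internal"] + loss["root_internal"] > 0
    return BranchEvents(
        pseudogenization=pseudo, loss=loss, total_events=total, ambiguous=on_internal
    )


def branch_event_table(
    matrix: OrthoStateMatrix,
    topology: tuple[tuple[str, str], str] = (("SAp", "SCt"), "SCc"),
) -> dict:
    """Aggregate per-branch event counts over every row of the matrix."""
    (left, right), out = topology
    branches = ["root_internal", left, right, out]
    agg = {
        "pseudogenization": {b: 0 for b in branches},
        "loss": {b: 0 for b in branches},
        "ambiguous_rows": 0,
        "rows": 0,
    }
    for gid in matrix.groups:
        ev = assign_loss_branches(matrix.cells[gid], topology)
        for b in branches:
            agg["pseudogenization"][b] += ev.pseudogenization[b]
            agg["loss"][b] += ev.loss[b]
        agg["ambiguous_rows"] += int(ev.ambiguous)
        agg["rows"] += 1
    return agg
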