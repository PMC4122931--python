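"""Shared domain types and readers/writers for the formats every stage touches.

Coordinate convention: everything in memory is 0-based half-open; GFF3 on
disk is 1-based inclusive. The conversion happens in exactly two places
(:func:`read_feature_table` and :func:`write_primer_gff`) so off-by-one
drift cannot creep in elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "ScaffoldSet",
    "GeneFeature",
    "MOBILE_CLASSES",
    "FEATURE_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "write_primer_gff",
]

#: Closed vocabulary of feature classes. Mobile classes are the four
#: element types that mediate rearrangement and inactivation in young
#: endosymbiont genomes: insertion sequences, prophage genes, group II
#: intron mobile elements, and the TnTIR transposon-like quorum-sensing
#: element.
FEATURE_CLASSES = frozenset(
    {"CDS", "pseudogene", "IS", "phage", "GIIME", "TnTIR", "RNA"}
    # annotation classes used by the primer-design GFF3 output
    | {"gap", "repeat_region", "primer"}
)
MOBILE_CLASSES = frozenset({"IS", "phage", "GIIME", "TnTIR"})

_VALID_CHARS = set("ACGTNacgtn")
_STRANDS = {"+", "-", "."}


class FastaFormatError(ValueError):
    """Raised for FASTA records violating the scaffold-set invariants."""


@dataclass
class ScaffoldSet:
    """Named nucleotide sequences, the substrate of gap closure.

    ``records`` maps scaffold id to an uppercase sequence over {A,C,G,T,N}.
    Soft-masking is never applied destructively: lowercase runs found on
    read (or produced by repeat detection) live in ``masked`` as 0-based
    half-open intervals per scaffold.
    """

    records: dict[str, str] = field(default_factory=dict)
    masked: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, seq in self.records.items():
            if not sid:
                raise FastaFormatError("empty scaffold id")
            if not seq:
                raise FastaFormatError(f"scaffold {sid!r} has empty sequence")
            for i, c in enumerate(seq):
                if c not in "ACGTN":
                    raise FastaFormatError(
                        f"scaffold {sid!r}: illegal character {c!r} at offset {i}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.records

    def __getitem__(self, scaffold_id: str) -> str:
        return self.records[scaffold_id]

    def length_of(self, scaffold_id: str) -> int:
        return len(self.records[scaffold_id])

    def masked_intervals(self, scaffold_id: str) -> list[tuple[int, int]]:
        return self.masked.get(scaffold_id, [])


@dataclass(frozen=True)
class GeneFeature:
    """A located, stranded, classed genome feature.

    Coordinates are 0-based half-open. ``klass`` comes from
    :data:`FEATURE_CLASSES`; the raw annotation token (e.g. an IS family
    name like ``IS481``) is preserved in ``attributes['family']``.
    """

    feature_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    klass: str
    cog_category: Optional[str] = None
    ortho_group: Optional[str] = None
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.klass not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.feature_id!r}: unknown class {self.klass!r}; "
                f"accepted: {sorted(FEATURE_CLASSES)}"
            )

    @property
    def is_mobile(self) -> bool:
        return self.klass in MOBILE_CLASSES

    @property
    def length(self) -> int:
        return self.end - self.start

    def attr(self, key: str) -> Optional[str]:
        for k, v in self.attributes:
            if k == key:
                return v
        return None


def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a multi-record FASTA into a :class:`ScaffoldSet`.

    Sequences are uppercased; lowercase (soft-masked) runs are recorded
    as intervals in ``masked``. Duplicate ids, empty records and
    characters outside {A,C,G,T,N} are hard errors.
    """
    records: dict[str, str] = {}
    masked: dict[str, list[tuple[int, int]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        seq = str(rec.seq)
        if sid in records:
            raise FastaFormatError(f"duplicate scaffold id {sid!r}")
        if not seq:
            raise FastaFormatError(f"scaffold {sid!r} has empty sequence")
        for i, c in enumerate(seq):
            if c not in _VALID_CHARS:
                raise FastaFormatError(
                    f"scaffold {sid!r}: illegal character {c!r} at offset {i}"
                )
        runs = [(m.start(), m.end()) for m in re.finditer(r"[acgtn]+", seq)]
        if runs:
            masked[sid] = runs
        records[sid] = seq.upper()
    return ScaffoldSet(records=records, masked=masked)


def write_fasta(scaffolds: ScaffoldSet, path: str | Path, width: int = 70) -> None:
    """Write scaffolds as wrapped FASTA, lowercasing soft-masked intervals."""
    with open(path, "w") as fh:
        for sid, seq in scaffolds.records.items():
            chars = list(seq)
            for s, e in scaffolds.masked_intervals(sid):
                for i in range(s, e):
                    chars[i] = chars[i].lower()
            out = "".join(chars)
            fh.write(f">{sid}\n")
            for i in range(0, len(out), width):
                fh.write(out[i : i + width] + "\n")


# -- feature tables ----------------------------------------------------------

#: Maps raw annotation tokens onto the internal class vocabulary. IS family
#: names (IS481, IS3, ...) collapse onto "IS" with the family retained.
_TOKEN_MAP = {
    "CDS": "CDS",
    "gene": "CDS",
    "pseudogene": "pseudogene",
    "pseudo": "pseudogene",
    "phage": "phage",
    "prophage": "phage",
    "GIIME": "GIIME",
    "group_II_intron": "GIIME",
    "TnTIR": "TnTIR",
    "RNA": "RNA",
    "tRNA": "RNA",
    "rRNA": "RNA",
    "tmRNA": "RNA",
    "IS": "IS",
    "gap": "gap",
    "repeat_region": "repeat_region",
    "primer": "primer",
}


def _map_klass(token: str) -> tuple[str, Optional[str]]:
    if token in _TOKEN_MAP:
        return _TOKEN_MAP[token], None
    if re.fullmatch(r"IS\w+", token):
        return "IS", token
    raise ValueError(
        f"unknown feature class token {token!r}; accepted: "
        f"{sorted(_TOKEN_MAP)} or an IS family name (ISxxx)"
    )


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[_unescape_gff3(k)] = _unescape_gff3(v)
    return attrs


_GFF3_ESCAPES = {"%3B": ";", "%3D": "=", "%26": "&", "%2C": ",", "%25": "%", "%09": "\t"}


def _escape_gff3(value: str) -> str:
    value = value.replace("%", "%25")
    for esc, raw in _GFF3_ESCAPES.items():
        if raw != "%":
            value = value.replace(raw, esc)
    return value


def _unescape_gff3(value: str) -> str:
    for esc, raw in _GFF3_ESCAPES.items():
        value = value.replace(esc, raw)
    return value


def read_feature_table(path: str | Path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or the TSV dialect.

    On-disk coordinates are 1-based inclusive; the returned features are
    0-based half-open. The TSV dialect has a header line with columns
    ``feature_id scaffold_id start end strand klass`` and optionally
    ``cog_category ortho_group``.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "tsv":
        return _read_feature_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'gff3' or 'tsv'")


def _convert_coords(start_1based: int, end_inclusive: int, where: str) -> tuple[int, int]:
    if end_inclusive < start_1based:
        raise ValueError(f"{where}: end {end_inclusive} < start {start_1based}")
    return start_1based - 1, end_inclusive


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            sid, _src, ftype, start, end, _score, strand, _phase, attr_text = cols
            s0, e0 = _convert_coords(int(start), int(end), f"{path}:{lineno}")
            klass, family = _map_klass(ftype)
            attrs = _parse_gff3_attributes(attr_text)
            fid = attrs.pop("ID", f"feat{lineno}")
            cog = attrs.pop("cog_category", None)
            grp = attrs.pop("ortho_group", None)
            if family and "family" not in attrs:
                attrs["family"] = family
            feats.append(
                GeneFeature(
                    feature_id=fid,
                    scaffold_id=sid,
                    start=s0,
                    end=e0,
                    strand=strand,
                    klass=klass,
                    cog_category=cog,
                    ortho_group=grp,
                    attributes=tuple(sorted(attrs.items())),
                )
            )
    return feats


def _read_feature_tsv(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ("feature_id", "scaffold_id", "start", "end", "strand", "klass")
        for col in required:
            if col not in idx:
                raise ValueError(f"{path}: missing required TSV column {col!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            s0, e0 = _convert_coords(
                int(cols[idx["start"]]), int(cols[idx["end"]]), f"{path}:{lineno}"
            )
            klass, family = _map_klass(cols[idx["klass"]])

            def _opt(name: str) -> Optional[str]:
                if name in idx and idx[name] < len(cols) and cols[idx[name]]:
                    return cols[idx[name]]
                return None

            attrs = (("family", family),) if family else ()
            feats.append(
                GeneFeature(
                    feature_id=cols[idx["feature_id"]],
                    scaffold_id=cols[idx["scaffold_id"]],
                    start=s0,
                    end=e0,
                    strand=cols[idx["strand"]],
                    klass=klass,
                    cog_category=_opt("cog_category"),
                    ortho_group=_opt("ortho_group"),
                    attributes=attrs,
                )
            )
    return feats


def write_feature_table(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features to the TSV dialect (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("feature_id\tscaffold_id\tstart\tend\tstrand\tklass\tcog_category\tortho_group\n")
        for f in features:
            klass = f.attr("family") or f.klass
            fh.write(
                f"{f.feature_id}\t{f.scaffold_id}\t{f.start + 1}\t{f.end}\t"
                f"{f.strand}\t{klass}\t{f.cog_category or ''}\t{f.ortho_group or ''}\n"
            )


# -- primer annotation output ------------------------------------------------

def write_primer_gff(
    gaps: Iterable,
    repeats: Iterable,
    pairs: Iterable,
    gff_path: str | Path,
    fasta_path: str | Path,
    scaffolds: Optional[ScaffoldSet] = None,
) -> None:
    """Write gap/repeat/primer annotations as GFF3 plus a primer FASTA.

    ``gaps`` are :class:`~endoerode.gap_primer.GapInterval`, ``repeats``
    :class:`~endoerode.gap_primer.RepeatInterval`, and ``pairs``
    :class:`~endoerode.gap_primer.PrimerPair`. Coordinates are emitted
    1-based inclusive; the file round-trips through
    :func:`read_feature_table` (primer/gap/repeat lines map onto the
    generic feature classes on re-read).
    """
    def _check_bounds(sid: str, start: int, end: int, what: str) -> None:
        if scaffolds is not None:
            if sid not in scaffolds:
                raise ValueError(f"{what} references unknown scaffold {sid!r}")
            if not (0 <= start < end <= scaffolds.length_of(sid)):
                raise ValueError(
                    f"{what} [{start},{end}) outside scaffold {sid!r} bounds"
                )

    lines = ["##gff-version 3"]
    fasta_records: list[tuple[str, str]] = []
    for i, g in enumerate(gaps, 1):
        _check_bounds(g.scaffold_id, g.start, g.end, "gap")
        lines.append(
            f"{g.scaffold_id}\tendoerode\tgap\t{g.start + 1}\t{g.end}\t.\t.\t.\t"
            f"ID=gap{i};estimated_size={g.estimated_size}"
        )
    for i, r in enumerate(repeats, 1):
        _check_bounds(r.scaffold_id, r.start, r.end, "repeat")
        lines.append(
            f"{r.scaffold_id}\tendoerode\trepeat_region\t{r.start + 1}\t{r.end}\t.\t.\t.\t"
            f"ID=repeat{i};family={_escape_gff3(str(r.family_id))}"
        )
    for i, p in enumerate(pairs, 1):
        for side, cand in (("left", p.left), ("right", p.right)):
            _check_bounds(cand.scaffold_id, cand.start, cand.end, f"primer {side}")
            pid = f"primer{i}_{side}"
            lines.append(
                f"{cand.scaffold_id}\tendoerode\tprimer\t{cand.start + 1}\t{cand.end}\t"
                f"{cand.penalty:.3f}\t{cand.strand}\t.\t"
                f"ID={pid};tm={cand.tm:.2f};gc={cand.gc_fraction:.3f};"
                f"product_size={p.product_size}"
            )
            fasta_records.append((pid, cand.sequence))
    with open(gff_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(fasta_path, "w") as fh:
        for pid, seq in fasta_records:
            fh.write(f">{pid}\n{seq}\n")
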