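"""Germline V-segment allele database: loading, translation, operational grouping.

Short-read genotyping cannot distinguish gene segments whose sequences are
nearly identical (e.g. tandem-duplicated genes). Segments whose closest allele
pair exceeds a global-alignment identity threshold are therefore merged into
*operational groups* and genotyped as one unit; all downstream copy-number and
allele calls are made per group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .align import Scoring, global_identity, nucleotide_scoring

_ALLELE_NAME_RE = re.compile(r"^([A-Za-z][A-Za-z0-9().\-/]*)\*([0-9][A-Za-z0-9]*)$")
_VALID_NT = set("ACGTN")


class ParseError(ValueError):
    """Malformed allele database record."""


def translate_allele(nt_seq: str, frame_offset: int = 0) -> str:
    """Standard-code translation; stop codons render as "_".

    The trailing partial codon is dropped; a sequence shorter than one codon
    translates to the empty string.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1, or 2")
    trimmed = nt_seq[frame_offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate()).replace("*", "_")


@dataclass
class Allele:
    """One named germline allele of a V-gene segment."""

    segment_name: str
    allele_id: str
    nt_seq: str
    functional: bool = True

    def __post_init__(self):
        self.nt_seq = self.nt_seq.upper()
        if not self.nt_seq:
            raise ValueError(f"empty sequence for {self.full_name}")
        bad = set(self.nt_seq) - _VALID_NT
        if bad:
            raise ValueError(f"{self.full_name}: invalid nucleotides {sorted(bad)}")

    @property
    def full_name(self) -> str:
        return f"{self.segment_name}*{self.allele_id}"

    @property
    def aa_seq(self) -> str:
        return translate_allele(self.nt_seq, 0)


@dataclass
class OperationalGroup:
    """Set of segments genotyped as a single unit."""

    group_id: str
    member_segments: frozenset
    representative_seq: str

    def __contains__(self, segment: str) -> bool:
        return segment in self.member_segments


@dataclass
class AlleleDatabase:
    """Germline allele reference for one locus (IGHV or TRBV)."""

    alleles: list[Allele]
    locus: str
    groups: list[OperationalGroup] = field(default_factory=list)

    def __post_init__(self):
        if self.locus not in ("IGHV", "TRBV"):
            raise ValueError("locus must be IGHV or TRBV")
        seen = set()
        for al in self.alleles:
            if al.full_name in seen:
                raise ParseError(f"duplicate allele name {al.full_name}")
            seen.add(al.full_name)
        self._by_name = {al.full_name: al for al in self.alleles}

    # --- lookups ----------------------------------------------------------
    def get(self, full_name: str) -> Allele:
        return self._by_name[full_name]

    def __contains__(self, full_name: str) -> bool:
        return full_name in self._by_name

    @property
    def segments(self) -> list[str]:
        return sorted({al.segment_name for al in self.alleles})

    @property
    def functional_alleles(self) -> list[Allele]:
        return [al for al in self.alleles if al.functional]

    @property
    def functional_segments(self) -> list[str]:
        return sorted({al.segment_name for al in self.functional_alleles})

    def alleles_for_segment(self, segment: str) -> list[Allele]:
        return [al for al in self.alleles if al.segment_name == segment]

    def group_for_segment(self, segment: str) -> OperationalGroup:
        for g in self.groups:
            if segment in g:
                return g
        raise KeyError(f"segment {segment} not in any operational group")

    def group_by_id(self, group_id: str) -> OperationalGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def group_alleles(self, group_id: str, functional_only: bool = True) -> list[Allele]:
        g = self.group_by_id(group_id)
        pool = self.functional_alleles if functional_only else self.alleles
        return sorted((al for al in pool if al.segment_name in g.member_segments),
                      key=lambda al: al.full_name)


def _parse_header(description: str) -> tuple[str, str, bool]:
    """Extract (segment, allele_id, functional) from an IMGT-dialect header.

    Headers are '|'-separated; the field matching SEGMENT*NN is the allele
    name and an optional field among {F, P, ORF} (parentheses tolerated) is
    the functionality call. Plain ">SEGMENT*NN" headers are accepted.
    """
    fields = [f.strip() for f in description.split("|")]
    name_match = None
    for f in fields:
        m = _ALLELE_NAME_RE.match(f)
        if m:
            name_match = m
            break
    if name_match is None:
        raise ParseError(f"no SEGMENT*NN allele name in header: {description!r}")
    functional = True
    for f in fields:
        tag = f.strip("()[] ").upper()
        if tag in ("P", "ORF", "PSEUDO", "PSEUDOGENE"):
            functional = False
        elif tag == "F":
            functional = True
    return name_match.group(1), name_match.group(2), functional


def load_allele_fasta(path: str | Path, locus: str) -> AlleleDatabase:
    """Read an IMGT-dialect germline FASTA into an :class:`AlleleDatabase`.

    Non-functional (pseudogene/ORF) records are retained but flagged; they are
    excluded from grouping and all downstream statistics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            segment, allele_id, functional = _parse_header(rec.description)
            alleles.append(Allele(segment_name=segment, allele_id=allele_id,
                                  nt_seq=str(rec.seq), functional=functional))
        except ValueError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
    if not alleles:
        raise ParseError(f"no FASTA records in {path}")
    return AlleleDatabase(alleles=alleles, locus=locus)


def write_allele_fasta(db: AlleleDatabase, path: str | Path) -> None:
    with open(path, "w") as fh:
        for al in db.alleles:
            tag = "F" if al.functional else "P"
            fh.write(f">{al.full_name}|{db.locus}|{tag}\n{al.nt_seq}\n")


def group_operational_segments(db: AlleleDatabase,
                               identity_threshold: float = 0.95,
                               scoring: Scoring | None = None) -> list[OperationalGroup]:
    """Partition functional segments into operational groups by single linkage.

    Two segments join one group when *any* allele pair across them reaches the
    global-alignment identity threshold; merging is transitive, so chained
    near-duplicates (e.g. a four-member tandem family) collapse into a single
    group. The group id is the lexicographically smallest member plus "^".
    The resulting groups are stored on ``db.groups`` and returned.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    segments = db.functional_segments
    if not segments:
        raise ValueError("database has no functional segments")
    scoring = scoring or nucleotide_scoring()
    parent = {s: s for s in segments}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    seqs = {s: [al.nt_seq for al in db.alleles_for_segment(s) if al.functional]
            for s in segments}
    for s1, s2 in combinations(segments, 2):
        if find(s1) == find(s2):
            continue
        joined = False
        for a in seqs[s1]:
            for b in seqs[s2]:
                # cheap exact/equal-length lower bound before full alignment
                if a == b:
                    joined = True
                elif len(a) == len(b):
                    ham = sum(x == y for x, y in zip(a, b)) / len(a)
                    joined = ham >= identity_threshold or (
                        global_identity(a, b, scoring) >= identity_threshold)
                else:
                    joined = global_identity(a, b, scoring) >= identity_threshold
                if joined:
                    break
            if joined:
                break
        if joined:
            union(s1, s2)

    clusters: dict[str, set] = {}
    for s in segments:
        clusters.setdefault(find(s), set()).add(s)
    groups = []
    for members in clusters.values():
        head = min(members)
        rep = sorted(seqs[head])[0] if seqs[head] else ""
        groups.append(OperationalGroup(group_id=head + "^",
                                       member_segments=frozenset(members),
                                       representative_seq=rep))
    groups.sort(key=lambda g: g.group_id)
    db.groups = groups
    return groups
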