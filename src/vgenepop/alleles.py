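"""Simplified diploid phasing, allele matching, and novel-allele nomenclature.

Two-copy segments (diploid copy number 2 in essentially every individual) can
be analysed for allelic variation without copy-number confounding. Reads for
one segment are piled up on the group reference, heterozygous sites are
detected, and the two haplotype sequences are reconstructed by greedy
read-linkage phasing. Each haplotype is matched to the closest database
allele; imperfect matches become putatively novel alleles named by the closest
allele plus "_"-separated mutation suffixes
({ref base}{alt base}{position}{ref aa}{alt aa}, 0-based positions, reading
frame from base 0). An allele or SNV is only called when observed in at least
two individuals.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_db import Allele, AlleleDatabase, translate_allele

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class PhasingError(ValueError):
    pass


class AmbiguityError(PhasingError):
    """More than two base states pass the heterozygosity threshold."""


@dataclass
class Read:
    """A (simulated or pre-aligned) read over a segment reference.

    ``start`` is the 0-based reference offset when known (aligned input);
    unknown offsets are located by minimum-mismatch scanning. Reads sharing a
    ``fragment`` id are mates of one sequenced fragment and phase together.
    """

    seq: str
    start: int | None = None
    truncated: bool = False
    fragment: int | None = None


@dataclass
class PhasedSegment:
    individual_id: str
    group_id: str
    hap1_seq: str
    hap2_seq: str
    truncated: bool = False
    phase_ambiguous: bool = False
    het_positions: list = field(default_factory=list)


@dataclass(frozen=True)
class Mutation:
    """One substitution relative to the matched reference allele."""

    ref_base: str  # lowercase
    alt_base: str
    position: int  # 0-based on the reference allele
    ref_aa: str  # "_" denotes a stop codon
    alt_aa: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("reference and alternative base are identical")
        if self.position < 0:
            raise ValueError("negative position")

    @property
    def token(self) -> str:
        return f"{self.ref_base}{self.alt_base}{self.position}{self.ref_aa}{self.alt_aa}"


@dataclass
class AlleleCall:
    individual_id: str
    group_id: str
    hap_index: int  # 1 or 2
    allele_name: str  # database name or novel name
    base_allele: str  # closest database allele
    novel: bool
    mutations: tuple
    truncated: bool = False
    tie: bool = False
    called: bool = True  # False once dropped by the >=2-individual rule


def _locate_read(seq: str, reference: str) -> int:
    """Best ungapped offset of a read on the reference (minimum mismatches,
    smallest offset on ties). Synthetic regime: no indels."""
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    r = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(r) >= len(ref):
        return 0
    best, best_off = len(r) + 1, 0
    for off in range(len(ref) - len(r) + 1):
        mism = int(np.count_nonzero(ref[off:off + len(r)] != r))
        if mism < best:
            best, best_off = mism, off
            if mism == 0:
                break
    return best_off


def phase_segment_reads(reads: list[Read], reference: str,
                        min_het_frac: float = 0.2,
                        individual_id: str = "", group_id: str = "") -> PhasedSegment:
    """Reconstruct the two haplotype sequences of a two-copy segment.

    Sites where two base states each hold at least ``min_het_frac`` of the
    covering reads are heterozygous; more than two such states raise
    :class:`AmbiguityError`. Heterozygous sites are phased greedily: reads
    covering two sites vote for the co-occurring state pairing; sites without
    any link to previously phased sites get a deterministic (alphabetical)
    phase and the segment is flagged ``phase_ambiguous``. Mate reads (same
    ``fragment`` id) contribute linkage jointly, as a paired-end fragment does.
    """
    if not reads:
        raise PhasingError("no reads to phase")
    L = len(reference)
    counts = np.zeros((4, L), dtype=np.int64)
    placed = []  # (offset, encoded read, fragment key)
    for n, read in enumerate(reads):
        seq = read.seq.upper()
        off = read.start if read.start is not None else _locate_read(seq, reference)
        seq = seq[: L - off]
        enc = np.full(len(seq), -1, dtype=np.int64)
        for i, b in enumerate(seq):
            enc[i] = _BASE_INDEX.get(b, -1)
        valid = enc >= 0
        np.add.at(counts, (enc[valid], off + np.nonzero(valid)[0]), 1)
        key = ("f", read.fragment) if read.fragment is not None else ("r", n)
        placed.append((off, enc, key))

    coverage = counts.sum(axis=0)
    consensus = np.full(L, "N", dtype="<U1")
    het_states: dict[int, tuple[str, str]] = {}
    for pos in np.nonzero(coverage > 0)[0]:
        col = counts[:, pos]
        cov = coverage[pos]
        states = [b for b in range(4) if col[b] >= min_het_frac * cov and col[b] > 0]
        if len(states) > 2:
            raise AmbiguityError(
                f"{individual_id}/{group_id}: >2 base states at position {int(pos)}")
        if len(states) == 2:
            s = sorted(states)
            het_states[int(pos)] = (_BASES[s[0]], _BASES[s[1]])
            consensus[pos] = _BASES[int(np.argmax(col))]
        else:
            consensus[pos] = _BASES[states[0]]

    het_positions = sorted(het_states)
    hap1 = consensus.copy()
    hap2 = consensus.copy()
    ambiguous = False

    if het_positions:
        # linkage votes from fragments spanning pairs of het sites
        votes: dict[tuple[int, int], dict[tuple[str, str], int]] = defaultdict(
            lambda: defaultdict(int))
        fragments: dict = defaultdict(dict)  # key -> {het pos: base}
        for off, enc, key in placed:
            for p in het_positions:
                if off <= p < off + len(enc) and enc[p - off] >= 0:
                    base = _BASES[enc[p - off]]
                    if fragments[key].get(p, base) == base:
                        fragments[key][p] = base
                    else:  # mates disagree (error); drop the site
                        fragments[key][p] = None
        for sites in fragments.values():
            covered = sorted(p for p, b in sites.items() if b is not None)
            for i, p in enumerate(covered):
                for q in covered[i + 1:]:
                    votes[(p, q)][(sites[p], sites[q])] += 1

        assignment: dict[int, tuple[str, str]] = {}
        p0 = het_positions[0]
        assignment[p0] = het_states[p0]  # alphabetically smaller state on hap1
        for q in het_positions[1:]:
            b1, b2 = het_states[q]
            keep_score = flip_score = 0
            for p in assignment:
                key = (p, q) if p < q else (q, p)
                for (bp, bq), c in votes.get(key, {}).items():
                    if p < q:
                        sp, sq = bp, bq
                    else:
                        sp, sq = bq, bp
                    if sq not in (b1, b2) or sp not in assignment[p]:
                        continue  # sequencing-error state
                    on_hap1 = sp == assignment[p][0]
                    if (sq == b1) == on_hap1:
                        keep_score += c
                    else:
                        flip_score += c
            if keep_score == 0 and flip_score == 0:
                ambiguous = True
                assignment[q] = (b1, b2)
            elif keep_score == flip_score:
                ambiguous = True
                assignment[q] = (b1, b2)
            else:
                assignment[q] = (b1, b2) if keep_score > flip_score else (b2, b1)
        for p, (a, b) in assignment.items():
            hap1[p] = a
            hap2[p] = b

    truncated = bool((coverage == 0).any())
    return PhasedSegment(individual_id=individual_id, group_id=group_id,
                         hap1_seq="".join(hap1), hap2_seq="".join(hap2),
                         truncated=truncated, phase_ambiguous=ambiguous,
                         het_positions=het_positions)


# ---------------------------------------------------------------------------
# Allele matching and nomenclature


def _codon_aas(ref_seq: str, position: int, alt_base: str) -> tuple[str, str]:
    """Amino acids of the reference codon and of the codon with only this
    substitution applied (frame from base 0; incomplete codon -> X)."""
    c = 3 * (position // 3)
    codon = ref_seq[c:c + 3]
    if len(codon) < 3:
        return "X", "X"
    ref_aa = translate_allele(codon) or "X"
    alt_codon = list(codon)
    alt_codon[position % 3] = alt_base.upper()
    alt_aa = translate_allele("".join(alt_codon)) or "X"
    return ref_aa, alt_aa


@dataclass
class MatchResult:
    allele: Allele
    mutations: tuple
    truncated: bool
    tie: bool = False


def match_allele(hap_seq: str, db: AlleleDatabase, group_id: str) -> MatchResult:
    """Closest database allele of the group by substitution count.

    Comparison runs over the aligned prefix (positions both sequences cover);
    'N' bases in the haplotype (uncovered positions) never count as mutations.
    Equidistant alleles resolve to the lexicographically smallest name with the
    tie recorded.
    """
    hap = hap_seq.upper()
    if not hap:
        raise ValueError("empty haplotype sequence")
    candidates = db.group_alleles(group_id)
    if not candidates:
        raise KeyError(f"no alleles for group {group_id}")
    scored = []
    for al in candidates:
        L = min(len(hap), len(al.nt_seq))
        mism = sum(1 for i in range(L)
                   if hap[i] in _BASES and hap[i] != al.nt_seq[i])
        scored.append((mism, al.full_name, al))
    scored.sort(key=lambda t: (t[0], t[1]))
    best_mism, _, best = scored[0]
    tie = len(scored) > 1 and scored[1][0] == best_mism
    muts = []
    L = min(len(hap), len(best.nt_seq))
    for i in range(L):
        if hap[i] in _BASES and hap[i] != best.nt_seq[i]:
            ref_aa, alt_aa = _codon_aas(best.nt_seq, i, hap[i])
            muts.append(Mutation(ref_base=best.nt_seq[i].lower(),
                                 alt_base=hap[i].lower(), position=i,
                                 ref_aa=ref_aa, alt_aa=alt_aa))
    truncated = len(hap) < len(best.nt_seq)
    return MatchResult(allele=best, mutations=tuple(muts),
                       truncated=truncated, tie=tie)


def name_novel_allele(base_allele_name: str, mutations: tuple,
                      truncated: bool = False) -> str:
    """Render the novel-allele name: base name plus "_"-joined mutation tokens.

    A premature stop among the alternative amino acids appends "(P)"; a
    truncated reconstruction appends "(T)". With no mutations and no
    truncation the name is the base name itself.
    """
    positions = [m.position for m in mutations]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError("mutations must be sorted by strictly ascending position")
    name = base_allele_name + "".join("_" + m.token for m in mutations)
    if any(m.alt_aa == "_" for m in mutations):
        name += "(P)"
    if truncated:
        name += "(T)"
    return name


_MUT_TOKEN_RE = re.compile(r"_([acgt])([acgt])(\d+)([A-Z_])([A-Z_])")


def parse_novel_name(name: str) -> tuple[str, list[tuple], bool, bool]:
    """Inverse of :func:`name_novel_allele`.

    Returns (base name, [(ref, alt, position, ref_aa, alt_aa)], stop flag,
    truncated flag).
    """
    p_flag = t_flag = False
    core = name
    for _ in range(2):
        if core.endswith("(T)"):
            t_flag, core = True, core[:-3]
        elif core.endswith("(P)"):
            p_flag, core = True, core[:-3]
    matches = list(_MUT_TOKEN_RE.finditer(core))
    if not matches:
        return core, [], p_flag, t_flag
    base = core[: matches[0].start()]
    muts = []
    end = matches[0].start()
    for m in matches:
        if m.start() != end:
            raise ValueError(f"unparseable allele name {name!r}")
        muts.append((m.group(1), m.group(2), int(m.group(3)), m.group(4), m.group(5)))
        end = m.end()
    if end != len(core):
        raise ValueError(f"unparseable allele name {name!r}")
    return base, muts, p_flag, t_flag


def apply_mutations(base_seq: str, mutations) -> str:
    """Apply substitution mutations to a reference allele sequence."""
    seq = list(base_seq.upper())
    for m in mutations:
        ref, alt, pos = m.ref_base, m.alt_base, m.position
        if pos >= len(seq):
            raise ValueError(f"mutation position {pos} beyond sequence end")
        if seq[pos] != ref.upper():
            raise ValueError(f"reference base mismatch at {pos}")
        seq[pos] = alt.upper()
    return "".join(seq)


# ---------------------------------------------------------------------------
# Cohort-level calling


def call_alleles_cohort(phased: list[PhasedSegment], db: AlleleDatabase,
                        min_individuals: int = 2,
                        two_copy_groups: list[str] | None = None,
                        regions: pd.Series | None = None,
                        drop_ambiguous: bool = True,
                        ) -> tuple[pd.DataFrame, list[AlleleCall]]:
    """Match and name every haplotype, then apply the >=2-individual rule.

    Alleles observed in fewer than ``min_individuals`` distinct individuals
    are dropped from the frequency table and their haplotypes marked uncalled
    (a homozygote contributes two haplotype counts but one individual).
    Segments whose phase could not be anchored by read linkage are excluded
    by default (``drop_ambiguous``): their arbitrary phase would fabricate
    recurring chimeric haplotypes that the two-individual rule cannot filter.
    Returns the allele frequency table (per group: name, counts, frequency,
    regions observed) and the full call list.
    """
    if two_copy_groups is not None:
        bad = {p.group_id for p in phased} - set(two_copy_groups)
        if bad:
            raise ValueError(f"groups not designated two-copy: {sorted(bad)}")
    if drop_ambiguous:
        phased = [p for p in phased if not p.phase_ambiguous]
    calls: list[AlleleCall] = []
    for seg in phased:
        for idx, hap in ((1, seg.hap1_seq), (2, seg.hap2_seq)):
            m = match_allele(hap, db, seg.group_id)
            truncated = m.truncated or seg.truncated
            novel = bool(m.mutations) or truncated
            name = (name_novel_allele(m.allele.full_name, m.mutations, truncated)
                    if novel else m.allele.full_name)
            calls.append(AlleleCall(individual_id=seg.individual_id,
                                    group_id=seg.group_id, hap_index=idx,
                                    allele_name=name, base_allele=m.allele.full_name,
                                    novel=novel, mutations=m.mutations,
                                    truncated=truncated, tie=m.tie))

    by_allele: dict[tuple[str, str], list[AlleleCall]] = defaultdict(list)
    for c in calls:
        by_allele[(c.group_id, c.allele_name)].append(c)

    rows = []
    for (group_id, name), obs in sorted(by_allele.items()):
        individuals = {c.individual_id for c in obs}
        if len(individuals) < min_individuals:
            for c in obs:
                c.called = False
            continue
        row = {"group_id": group_id, "allele_name": name,
               "novel": obs[0].novel, "haplotype_count": len(obs),
               "n_individuals": len(individuals)}
        if regions is not None:
            row["regions"] = ",".join(sorted({str(regions[c.individual_id])
                                              for c in obs
                                              if c.individual_id in regions.index}))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        totals = table.groupby("group_id")["haplotype_count"].transform("sum")
        table["frequency"] = table["haplotype_count"] / totals
    return table, calls


def identify_snps(calls: list[AlleleCall], db: AlleleDatabase,
                  min_individuals: int = 2) -> pd.DataFrame:
    """Polymorphic positions across the cohort's reconstructed haplotypes.

    A base state counts only when carried by at least ``min_individuals``
    distinct individuals; a position is a SNP when at least two states pass.
    Returns one row per (group, position, state) of each SNP.
    """
    inds = {c.individual_id for c in calls}
    if len(inds) < min_individuals:
        raise ValueError("need calls from at least two individuals")
    by_group: dict[str, list[AlleleCall]] = defaultdict(list)
    for c in calls:
        by_group[c.group_id].append(c)

    rows = []
    for group_id, group_calls in sorted(by_group.items()):
        seqs = []
        for c in group_calls:
            base = db.get(c.base_allele).nt_seq
            seqs.append((c.individual_id, apply_mutations(base, c.mutations)))
        L = min(len(s) for _, s in seqs)
        for pos in range(L):
            carriers: dict[str, set] = defaultdict(set)
            hapcount: dict[str, int] = defaultdict(int)
            for ind, s in seqs:
                carriers[s[pos]].add(ind)
                hapcount[s[pos]] += 1
            valid = {b for b, inds_ in carriers.items() if len(inds_) >= min_individuals}
            if len(valid) >= 2:
                for b in sorted(valid):
                    rows.append({"group_id": group_id, "position": pos, "state": b,
                                 "haplotype_count": hapcount[b],
                                 "n_individuals": len(carriers[b])})
    return pd.DataFrame(rows, columns=["group_id", "position", "state",
                                       "haplotype_count", "n_individuals"])


def calls_to_frame(calls: list[AlleleCall]) -> pd.DataFrame:
    """Flatten calls to a table; mutations are implicit in the allele name."""
    return pd.DataFrame([{
        "individual_id": c.individual_id, "group_id": c.group_id,
        "hap_index": c.hap_index, "allele_name": c.allele_name,
        "base_allele": c.base_allele, "novel": c.novel,
        "truncated": c.truncated, "called": c.called} for c in calls])


def calls_from_frame(frame: pd.DataFrame) -> list[AlleleCall]:
    """Rebuild calls from :func:`calls_to_frame` output (round-trips names)."""
    calls = []
    for row in frame.itertuples(index=False):
        _, tokens, _, _ = parse_novel_name(str(row.allele_name))
        muts = tuple(Mutation(ref_base=r, alt_base=a, position=p,
                              ref_aa=ra, alt_aa=aa)
                     for r, a, p, ra, aa in tokens)
        calls.append(AlleleCall(
            individual_id=str(row.individual_id), group_id=str(row.group_id),
            hap_index=int(row.hap_index), allele_name=str(row.allele_name),
            base_allele=str(row.base_allele), novel=bool(row.novel),
            mutations=muts, truncated=bool(row.truncated),
            called=bool(row.called)))
    return calls


def snp_count_per_group(snp_table: pd.DataFrame) -> pd.Series:
    """Number of SNP positions per group (zero-SNP groups absent)."""
    if len(snp_table) == 0:
        return pd.Series(dtype=int)
    return snp_table.groupby("group_id")["position"].nunique()
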