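"""Built-in synthetic study conditions.

Programmatic construction of (1) synthetic IGHV/TRBV germline allele
databases whose structure mirrors a real locus — near-identical duplicated
segments that collapse into operational groups, multi-allele two-copy
segments, a pseudogene, and planted codons that make specific novel-allele
names checkable by hand — and (2) cohort configurations shaped like a
worldwide sequencing panel: seven geographic regions totalling 286
individuals, ~38% blood/saliva DNA, 42x mean genome coverage with 100-bp
reads and 21-mers, region-structured CNV and allele frequencies including
region-private and novel alleles.

The high-copy polymorphism carries haploid variants of 1..7 copies and the
second one 1..4, so the common-polymorphism haplotype product is
2 x 2 x 2 x 7 x 4 for IGHV and 2 x 2 for TRBV.
"""

from __future__ import annotations

from math import cos, pi

import numpy as np

from .alleles import Mutation, _codon_aas, name_novel_allele
from .cnv import CnvPolymorphism
from .reference_db import Allele, AlleleDatabase, group_operational_segments
from .simulate import SimulationConfig

REGIONS = ("Africa", "WestEurasia", "CentralAsiaSiberia", "EastAsia",
           "SouthAsia", "Oceania", "America")

#: full-panel regional sizes (sums to 286)
COHORT_286 = {"Africa": 44, "WestEurasia": 73, "CentralAsiaSiberia": 27,
              "EastAsia": 45, "SouthAsia": 49, "Oceania": 22, "America": 26}

_STOPS = {"TAA", "TAG", "TGA"}
_SEG_CODONS = 99  # 297 bp, a typical V-exon length


def _random_codon_seq(rng: np.random.Generator, n_codons: int = _SEG_CODONS) -> str:
    codons = []
    while len(codons) < n_codons:
        c = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _mutate(seq: str, rng: np.random.Generator, n: int,
            frozen: set | None = None) -> str:
    """Apply n random substitutions, avoiding frozen positions and new stops."""
    frozen = frozen or set()
    chars = list(seq)
    done = 0
    while done < n:
        pos = int(rng.integers(0, len(chars)))
        if pos in frozen:
            continue
        old = chars[pos]
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == old:
            continue
        c0 = 3 * (pos // 3)
        codon = chars[c0:c0 + 3]
        codon[pos % 3] = new
        if "".join(codon) in _STOPS:
            continue
        chars[pos] = new
        done += 1
    return "".join(chars)


def _plant(seq: str, pos: int, codon: str) -> str:
    assert pos % 3 == 0 and len(codon) == 3
    return seq[:pos] + codon + seq[pos + 3:]


def synthetic_reference(locus: str, seed: int = 0) -> AlleleDatabase:
    """Build a synthetic germline allele database for one locus.

    IGHV: 11 two-copy segments, the duplicated/polymorphic families (a
    four-member tandem family, three near-identical duplicate pairs), and one
    pseudogene. TRBV: 45 two-copy groups (one a merged duplicate pair) plus
    two insertion/deletion families. Planted codons: IGHV1-18*01 carries AAC
    at 168 (so a->g there reads N->D), IGHV1-45*02 GGA at 123 (g->a: G->R),
    TRBV10-1*02 GAA at 234 (g->t: E->stop), TRBV12-5*01 CAC at 27 (c->g:
    H->D). Grouping is NOT yet applied.
    """
    if locus not in ("IGHV", "TRBV"):
        raise ValueError("locus must be IGHV or TRBV")
    rng = np.random.default_rng(seed * 2 + (0 if locus == "IGHV" else 1))
    alleles: list[Allele] = []

    def add(seg: str, aid: str, seq: str, functional: bool = True) -> str:
        alleles.append(Allele(segment_name=seg, allele_id=aid, nt_seq=seq,
                              functional=functional))
        return seq

    if locus == "IGHV":
        two_copy = ["IGHV1-18", "IGHV6-1", "IGHV1-45", "IGHV3-7", "IGHV4-34",
                    "IGHV1-2", "IGHV3-15", "IGHV3-21", "IGHV5-51", "IGHV3-48",
                    "IGHV1-46"]
        for seg in two_copy:
            s1 = _random_codon_seq(rng)
            frozen: set = set()
            if seg == "IGHV1-18":
                s1 = _plant(s1, 168, "AAC")
                frozen = {168, 169, 170}
            add(seg, "01", s1)
            s2 = _mutate(s1, rng, 3, frozen)
            if seg == "IGHV1-45":
                s2 = _plant(s2, 123, "GGA")
            add(seg, "02", s2)
        # insertion/deletion families (each segment one allele)
        for seg in ["IGHV1-8", "IGHV3-9", "IGHV5-10-1", "IGHV4-38-2",
                    "IGHV1-69-2"]:
            add(seg, "01", _random_codon_seq(rng))
        s364 = add("IGHV3-64", "01", _random_codon_seq(rng))
        add("IGHV3-64D", "01", s364)  # exact duplicate
        s343 = add("IGHV3-43", "01", _random_codon_seq(rng))
        add("IGHV3-43D", "01", _mutate(s343, rng, 1))
        s169 = add("IGHV1-69", "01", _random_codon_seq(rng))
        add("IGHV1-69", "02", _mutate(s169, rng, 2))
        add("IGHV1-69D", "01", s169)
        s270 = add("IGHV2-70", "01", _random_codon_seq(rng))
        add("IGHV2-70D", "01", _mutate(s270, rng, 2))
        # four-member tandem family, chained ~99% identity
        s330 = add("IGHV3-30", "01", _random_codon_seq(rng))
        s3303 = add("IGHV3-30-3", "01", _mutate(s330, rng, 3))
        s3305 = add("IGHV3-30-5", "01", _mutate(s3303, rng, 3))
        add("IGHV3-33", "01", _mutate(s3305, rng, 3))
        s323 = add("IGHV3-23", "01", _random_codon_seq(rng))
        add("IGHV3-23D", "01", s323)
        add("IGHV7-40", "01", _random_codon_seq(rng), functional=False)
    else:
        singles = ["TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV5-3",
                   "TRBV5-4", "TRBV5-5", "TRBV5-6", "TRBV6-1", "TRBV6-4",
                   "TRBV6-5", "TRBV6-6", "TRBV7-2", "TRBV7-3", "TRBV7-4",
                   "TRBV7-6", "TRBV7-7", "TRBV7-9", "TRBV9", "TRBV10-1",
                   "TRBV10-2", "TRBV10-3", "TRBV11-1", "TRBV11-2", "TRBV11-3",
                   "TRBV12-5", "TRBV13", "TRBV14", "TRBV15", "TRBV16",
                   "TRBV17", "TRBV18", "TRBV19", "TRBV20-1", "TRBV23-1",
                   "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1",
                   "TRBV30", "TRBV5-7", "TRBV6-7", "TRBV6-8"]
        for seg in singles:
            s1 = _random_codon_seq(rng)
            if seg == "TRBV12-5":
                s1 = _plant(s1, 27, "CAC")
            add(seg, "01", s1)
            if seg in ("TRBV9", "TRBV10-1", "TRBV28", "TRBV6-1", "TRBV19",
                       "TRBV5-1", "TRBV7-2", "TRBV11-2", "TRBV14", "TRBV30"):
                s2 = _mutate(s1, rng, 3, frozen={27, 28, 29})
                if seg == "TRBV10-1":
                    s2 = _plant(s2, 234, "GAA")
                add(seg, "02", s2)
        s123 = add("TRBV12-3", "01", _random_codon_seq(rng))
        add("TRBV12-4", "01", _mutate(s123, rng, 1))  # merged two-copy pair
        # insertion/deletion families
        s42 = add("TRBV4-2", "01", _random_codon_seq(rng))
        add("TRBV4-3", "01", _mutate(s42, rng, 2))
        s62 = add("TRBV6-2", "01", _random_codon_seq(rng))
        add("TRBV6-3", "01", _mutate(s62, rng, 1))
        for seg in ["TRBV5-8", "TRBV6-9", "TRBV7-8"]:
            add(seg, "01", _random_codon_seq(rng))
        add("TRBVA", "01", _random_codon_seq(rng), functional=False)
    return AlleleDatabase(alleles=alleles, locus=locus)


def study_polymorphisms(locus: str) -> list[CnvPolymorphism]:
    """The locus's common copy-number polymorphisms (group ids carry "^")."""
    if locus == "IGHV":
        return [
            CnvPolymorphism("IGHV1-8.region", ["IGHV1-8^", "IGHV3-9^",
                                               "IGHV5-10-1^", "IGHV3-64^"],
                            [("ins", (1, 1, 0, 1)), ("alt", (0, 0, 1, 1))]),
            CnvPolymorphism("IGHV4-38-2.region", ["IGHV4-38-2^", "IGHV3-43^"],
                            [("ins", (1, 1)), ("del", (0, 1))]),
            CnvPolymorphism("IGHV1-69.region", ["IGHV1-69^", "IGHV1-69-2^",
                                                "IGHV2-70^"],
                            [("single", (1, 0, 1)), ("dup", (2, 1, 1))]),
            CnvPolymorphism("IGHV3-30.cn", ["IGHV3-30^"],
                            [(str(c), (c,)) for c in range(1, 8)],
                            call_method="round"),
            CnvPolymorphism("IGHV3-23.cn", ["IGHV3-23^"],
                            [(str(c), (c,)) for c in range(1, 5)],
                            call_method="round"),
        ]
    if locus == "TRBV":
        return [
            CnvPolymorphism("TRBV4-2.ins", ["TRBV4-2^", "TRBV6-2^"],
                            [("ins", (1, 1)), ("del", (0, 0))]),
            CnvPolymorphism("TRBV5-8.del", ["TRBV5-8^", "TRBV6-9^", "TRBV7-8^"],
                            [("pres", (1, 1, 1)), ("del", (0, 0, 0))]),
        ]
    raise ValueError("locus must be IGHV or TRBV")


# per-region frequency of the FIRST haploid variant of each 2-variant
# polymorphism (region order as in REGIONS)
_TWO_VARIANT_FREQS = {
    "IGHV1-8.region": (0.55, 0.35, 0.40, 0.30, 0.45, 0.25, 0.30),
    "IGHV4-38-2.region": (0.60, 0.70, 0.65, 0.75, 0.70, 0.80, 0.72),
    "IGHV1-69.region": (0.70, 0.75, 0.80, 0.65, 0.70, 0.85, 0.80),
    "TRBV4-2.ins": (0.50, 0.35, 0.40, 0.45, 0.40, 0.30, 0.35),
    "TRBV5-8.del": (0.88, 0.85, 0.82, 0.86, 0.84, 0.80, 0.83),
}
# multi-variant polymorphisms: base vector, mildly tilted by region
_MULTI_VARIANT_BASE = {
    "IGHV3-30.cn": (0.24, 0.20, 0.16, 0.13, 0.10, 0.09, 0.08),
    "IGHV3-23.cn": (0.45, 0.30, 0.15, 0.10),
}


def _variant_freqs(locus: str) -> dict:
    polys = study_polymorphisms(locus)
    out: dict = {}
    for r_idx, region in enumerate(REGIONS):
        out[region] = {}
        for poly in polys:
            pid = poly.polymorphism_id
            if pid in _TWO_VARIANT_FREQS:
                p1 = _TWO_VARIANT_FREQS[pid][r_idx]
                out[region][pid] = (p1, 1.0 - p1)
            else:
                base = np.asarray(_MULTI_VARIANT_BASE[pid], float)
                tilt = 1.0 + 0.15 * np.cos(
                    2 * pi * (r_idx + np.arange(len(base))) / len(REGIONS))
                v = base * tilt
                out[region][pid] = tuple(v / v.sum())
    return out


def _novel_entry(db: AlleleDatabase, base_name: str, pos: int,
                 alt: str | None = None) -> tuple[str, tuple]:
    """Novel-allele spec (name, (base, ((pos, alt),))) for one substitution.

    Without an explicit alternative base, the first base that avoids creating
    a premature stop is chosen.
    """
    seq = db.get(base_name).nt_seq
    ref = seq[pos]
    if alt is None:
        for cand in "ACGT":
            if cand != ref and _codon_aas(seq, pos, cand)[1] != "_":
                alt = cand
                break
    ref_aa, alt_aa = _codon_aas(seq, pos, alt)
    mut = Mutation(ref_base=ref.lower(), alt_base=alt.lower(), position=pos,
                   ref_aa=ref_aa, alt_aa=alt_aa)
    return name_novel_allele(base_name, (mut,)), (base_name, ((pos, alt),))


def _base_allele_freqs(db: AlleleDatabase, two_copy_groups: list[str]) -> dict:
    """Region-tilted frequencies over each group's database alleles."""
    weights = {1: (1.0,), 2: (0.65, 0.35), 3: (0.55, 0.30, 0.15)}
    out: dict = {region: {} for region in REGIONS}
    for r_idx, region in enumerate(REGIONS):
        for g_idx, gid in enumerate(sorted(two_copy_groups)):
            names = [al.full_name for al in db.group_alleles(gid)]
            w = np.asarray(weights[min(len(names), 3)][:len(names)], float)
            if len(names) > 3:
                w = np.full(len(names), 1.0 / len(names))
            tilt = 1.0 + 0.2 * np.cos(2 * pi * (r_idx + g_idx
                                                + np.arange(len(w))) / len(REGIONS))
            v = w * tilt
            v /= v.sum()
            out[region][gid] = {nm: float(f) for nm, f in zip(names, v)}
    return out


def _inject_allele(freqs: dict, group: str, name: str, per_region: dict) -> None:
    """Set an allele to given regional frequencies, shrinking the others."""
    for region, f in per_region.items():
        g = freqs[region][group]
        rest = 1.0 - g.pop(name, 0.0)
        scale = (1.0 - f) / rest
        for nm in g:
            g[nm] *= scale
        g[name] = f


def study_config(locus: str, db: AlleleDatabase, seed: int = 0,
                 n_individuals_per_region: dict | None = None,
                 coverage_noise_cv: float = 0.05,
                 with_novel: bool = True) -> SimulationConfig:
    """Default SGDP-shaped cohort configuration for a grouped database.

    Plants high-frequency cosmopolitan novel alleles (the hand-checkable
    IGHV1-18*01 a->g at 168 and the TRBV10-1*02 stop / TRBV12-5*01 H->D pair)
    plus one Africa-private novel allele and one Africa-private database
    allele per locus.
    """
    if not db.groups:
        group_operational_segments(db)
    polys = study_polymorphisms(locus)
    poly_groups = {gid for p in polys for gid in p.group_ids}
    known = {g.group_id for g in db.groups}
    missing = poly_groups - known
    if missing:
        raise ValueError(f"polymorphism groups absent from database: {missing}")
    two_copy = sorted(known - poly_groups)
    allele_freqs = _base_allele_freqs(db, two_copy)
    novel: dict = {}
    if with_novel:
        if locus == "IGHV":
            plan = [("IGHV1-18^", "IGHV1-18*01", 168, "G",
                     {r: 0.15 for r in REGIONS}),
                    ("IGHV3-21^", "IGHV3-21*01", 60, None, {"Africa": 0.25})]
            private_known = ("IGHV3-7^", "IGHV3-7*02", {"Africa": 0.30})
        else:
            plan = [("TRBV10-1^", "TRBV10-1*02", 234, "T",
                     {r: 0.12 for r in REGIONS}),
                    ("TRBV12-5^", "TRBV12-5*01", 27, "G",
                     {r: 0.20 for r in REGIONS}),
                    ("TRBV28^", "TRBV28*01", 90, None, {"Africa": 0.20})]
            private_known = ("TRBV9^", "TRBV9*02", {"Africa": 0.35})
        for group, base, pos, alt, per_region in plan:
            name, entry = _novel_entry(db, base, pos, alt)
            novel[name] = entry
            _inject_allele(allele_freqs, group, name, per_region)
        # make one database allele region-private: zero it outside the region
        group, name, per_region = private_known
        for region in REGIONS:
            g = allele_freqs[region][group]
            if name in g and region not in per_region:
                rest = 1.0 - g.pop(name)
                for nm in g:
                    g[nm] /= rest
        _inject_allele(allele_freqs, group, name, per_region)
    return SimulationConfig(
        n_individuals_per_region=dict(n_individuals_per_region or COHORT_286),
        polymorphisms=polys,
        variant_freqs=_variant_freqs(locus),
        allele_freqs=allele_freqs,
        novel_alleles=novel,
        coverage_noise_cv=coverage_noise_cv,
        seed=seed,
    )
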