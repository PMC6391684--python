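"""Phasing, allele matching, novel-allele nomenclature, cohort calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vgenepop.alleles import (AmbiguityError, Mutation, PhasedSegment,
                              PhasingError, Read, apply_mutations,
                              call_alleles_cohort, identify_snps, match_allele,
                              name_novel_allele, parse_novel_name,
                              phase_segment_reads)
from vgenepop.reference_db import Allele, AlleleDatabase, \
    group_operational_segments, translate_allele

REF = "ATGGATAAACCCGGGTTTACAAGAGCTGCA"  # 30 bp toy reference


def _reads_from(seq, read_len=12, step=3, fragment_base=None):
    reads = []
    for k, start in enumerate(range(0, len(seq) - read_len + 1, step)):
        frag = None if fragment_base is None else fragment_base + k
        reads.append(Read(seq=seq[start:start + read_len], start=start,
                          fragment=frag))
    return reads


class TestPhasing:
    def test_homozygous_consensus(self):
        seg = phase_segment_reads(_reads_from(REF), REF)
        assert seg.hap1_seq == seg.hap2_seq == REF
        assert not seg.phase_ambiguous and not seg.truncated

    def test_two_linked_het_sites_recovered(self):
        hapA = REF
        hapB = REF[:5] + "C" + REF[6:13] + "T" + REF[14:]  # sites 5 and 13
        reads = _reads_from(hapA) + _reads_from(hapB)
        seg = phase_segment_reads(reads, REF, min_het_frac=0.2)
        assert {seg.hap1_seq, seg.hap2_seq} == {hapA, hapB}
        assert not seg.phase_ambiguous

    def test_mate_pairs_link_distant_sites(self):
        # het sites at 2 and 26 are farther apart than one 10-bp read but a
        # fragment's mates cover both
        hapA = REF
        hapB = REF[:2] + "C" + REF[3:26] + "C" + REF[27:]
        reads = []
        for f, hap in enumerate([hapA, hapB] * 6):
            reads.append(Read(seq=hap[0:10], start=0, fragment=f))
            reads.append(Read(seq=hap[20:30], start=20, fragment=f))
            reads.append(Read(seq=hap[8:22], start=8, fragment=1000 + f))
        seg = phase_segment_reads(reads, REF)
        assert {seg.hap1_seq, seg.hap2_seq} == {hapA, hapB}

    def test_unlinkable_sites_flagged_and_deterministic(self):
        hapA = REF
        hapB = REF[:2] + "C" + REF[3:26] + "C" + REF[27:]
        reads = []
        for hap in [hapA, hapB] * 5:
            reads.append(Read(seq=hap[0:8], start=0))
            reads.append(Read(seq=hap[22:30], start=22))
        seg1 = phase_segment_reads(reads, REF)
        seg2 = phase_segment_reads(reads, REF)
        assert seg1.phase_ambiguous
        assert (seg1.hap1_seq, seg1.hap2_seq) == (seg2.hap1_seq, seg2.hap2_seq)

    def test_three_states_raise_ambiguity(self):
        reads = [Read(seq=b + REF[1:10], start=0) for b in "ACG" for _ in range(4)]
        with pytest.raises(AmbiguityError):
            phase_segment_reads(reads, REF)

    def test_zero_reads_rejected(self):
        with pytest.raises(PhasingError):
            phase_segment_reads([], REF)

    def test_unaligned_reads_are_located(self):
        reads = [Read(seq=REF[6:18]), Read(seq=REF[0:12]), Read(seq=REF[18:30])]
        seg = phase_segment_reads(reads, REF)
        assert seg.hap1_seq == REF

    def test_uncovered_positions_flag_truncated(self):
        seg = phase_segment_reads([Read(seq=REF[:15], start=0)], REF)
        assert seg.truncated and seg.hap1_seq.endswith("N" * 5)


@pytest.fixture()
def match_db():
    a01 = REF
    a02 = REF[:9] + "T" + REF[10:]  # differs at position 9
    db = AlleleDatabase(alleles=[Allele("IGHV1-18", "01", a01),
                                 Allele("IGHV1-18", "02", a02)], locus="IGHV")
    group_operational_segments(db)
    return db


class TestMatchAllele:
    def test_exact_match(self, match_db):
        m = match_allele(REF, match_db, "IGHV1-18^")
        assert m.allele.full_name == "IGHV1-18*01"
        assert m.mutations == () and not m.truncated

    def test_planted_substitution_recovered(self, match_db):
        hap = REF[:14] + "A" + REF[15:]  # G->A at 14
        m = match_allele(hap, match_db, "IGHV1-18^")
        assert m.allele.full_name == "IGHV1-18*01"
        assert len(m.mutations) == 1
        mut = m.mutations[0]
        assert (mut.ref_base, mut.alt_base, mut.position) == ("g", "a", 14)

    def test_equidistant_tie_breaks_lexicographically(self, match_db):
        # one mismatch against *01 (pos 20) and one against *02 (pos 9 + 20 - 9...)
        hap = REF[:9] + "T" + REF[10:]  # exactly *02
        hap = hap[:20] + ("C" if hap[20] != "C" else "G") + hap[21:]
        # now 2 mismatches to *01, 1 to *02 -> *02 wins; build a true tie instead
        tie_hap = REF[:9] + "G" + REF[10:]  # pos 9: A in *01, T in *02, G in hap
        m = match_allele(tie_hap, match_db, "IGHV1-18^")
        assert m.allele.full_name == "IGHV1-18*01"
        assert m.tie

    def test_truncated_haplotype_flagged(self, match_db):
        m = match_allele(REF[:20], match_db, "IGHV1-18^")
        assert m.truncated

    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            n_alleles = int(rng.integers(2, 10))
            L = int(rng.integers(9, 60))
            base = "".join(rng.choice(list("ACGT"), L))
            alleles = []
            for k in range(n_alleles):
                s = list(base)
                for pos in rng.choice(L, size=int(rng.integers(0, 5)),
                                      replace=False):
                    s[pos] = "ACGT"[int(rng.integers(0, 4))]
                alleles.append(Allele("SEG1", f"{k + 1:02d}", "".join(s)))
            try:
                db = AlleleDatabase(alleles=alleles, locus="IGHV")
            except ValueError:  # duplicated sequence is fine, duplicated name not
                continue
            group_operational_segments(db, 0.5)
            gid = db.groups[0].group_id
            hap = "".join(rng.choice(list("ACGT"), L))
            m = match_allele(hap, db, gid)
            best = min(sum(h != a for h, a in zip(hap, al.nt_seq))
                       for al in alleles)
            assert len(m.mutations) == best


class TestNaming:
    def test_printed_example_name(self):
        mut = Mutation(ref_base="a", alt_base="g", position=168,
                       ref_aa="N", alt_aa="D")
        assert name_novel_allele("IGHV1-18*01", (mut,)) == "IGHV1-18*01_ag168ND"

    def test_no_mutations_returns_base_name(self):
        assert name_novel_allele("TRBV12-5*01", ()) == "TRBV12-5*01"

    def test_premature_stop_annotated(self):
        mut = Mutation(ref_base="g", alt_base="t", position=234,
                       ref_aa="E", alt_aa="_")
        assert name_novel_allele("TRBV10-1*02", (mut,)) == \
            "TRBV10-1*02_gt234E_(P)"

    def test_truncation_annotated(self):
        assert name_novel_allele("IGHV6-1*01", (), truncated=True) == \
            "IGHV6-1*01(T)"

    def test_unsorted_mutations_rejected(self):
        m1 = Mutation("a", "g", 10, "K", "R")
        m2 = Mutation("c", "t", 4, "H", "Y")
        with pytest.raises(ValueError):
            name_novel_allele("X*01", (m1, m2))

    def test_parse_inverts_rendering(self):
        base, muts, p, t = parse_novel_name("TRBV10-1*02_gt234E_(P)")
        assert base == "TRBV10-1*02" and p and not t
        assert muts == [("g", "t", 234, "E", "_")]

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_roundtrip_reconstructs_sequence(self, data):
        """name -> parse -> apply reproduces the mutated haplotype exactly."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
        L = 3 * int(rng.integers(4, 40))
        base_seq = "".join(rng.choice(list("ACGT"), L))
        positions = sorted(rng.choice(L, size=int(rng.integers(1, 6)),
                                      replace=False))
        muts = []
        hap = list(base_seq)
        for pos in positions:
            alt = rng.choice([b for b in "ACGT" if b != base_seq[pos]])
            c0 = 3 * (pos // 3)
            ref_codon = base_seq[c0:c0 + 3]
            alt_codon = ref_codon[:pos % 3] + alt + ref_codon[pos % 3 + 1:]
            muts.append(Mutation(
                ref_base=base_seq[pos].lower(), alt_base=alt.lower(),
                position=int(pos),
                ref_aa=translate_allele(ref_codon) or "X",
                alt_aa=translate_allele(alt_codon) or "X"))
            hap[pos] = alt
        name = name_novel_allele("SEG*01", tuple(muts))
        _, tokens, _, _ = parse_novel_name(name)
        rebuilt = apply_mutations(base_seq,
                                  [Mutation(r, a, p_, ra, aa)
                                   for r, a, p_, ra, aa in tokens])
        assert rebuilt == "".join(hap)


def _phased(ind, hap1, hap2, group="IGHV1-18^"):
    return PhasedSegment(individual_id=ind, group_id=group,
                         hap1_seq=hap1, hap2_seq=hap2)


class TestCohortCalling:
    def test_singleton_novel_allele_dropped(self, match_db):
        novel = REF[:14] + "A" + REF[15:]
        phased = [_phased("i1", REF, novel)] + \
            [_phased(f"j{k}", REF, REF) for k in range(3)]
        table, calls = call_alleles_cohort(phased, match_db)
        assert "IGHV1-18*01_ga14FY" not in set(table["allele_name"])
        dropped = [c for c in calls if c.novel]
        assert dropped and not dropped[0].called

    def test_novel_allele_in_two_individuals_kept(self, match_db):
        novel = REF[:14] + "A" + REF[15:]
        phased = [_phased("i1", REF, novel), _phased("i2", novel, REF),
                  _phased("i3", REF, REF)]
        table, _ = call_alleles_cohort(phased, match_db)
        row = table[table["novel"]].iloc[0]
        assert row["haplotype_count"] == 2 and row["n_individuals"] == 2

    def test_homozygote_counts_two_haplotypes_one_individual(self, match_db):
        novel = REF[:14] + "A" + REF[15:]
        table, _ = call_alleles_cohort(
            [_phased("i1", novel, novel), _phased("i2", REF, REF),
             _phased("i3", REF, REF)], match_db)
        assert not table["novel"].any()  # 2 novel haplotypes but 1 individual

    def test_threshold_monotone(self, match_db):
        novel = REF[:14] + "A" + REF[15:]
        phased = [_phased("i1", REF, novel), _phased("i2", novel, REF),
                  _phased("i3", REF, REF)]
        t2, _ = call_alleles_cohort(phased, match_db, min_individuals=2)
        t3, _ = call_alleles_cohort(phased, match_db, min_individuals=3)
        assert set(t3["allele_name"]) <= set(t2["allele_name"])

    def test_frequencies_sum_to_one_per_group(self, match_db):
        a02 = match_db.get("IGHV1-18*02").nt_seq
        phased = [_phased("i1", REF, a02), _phased("i2", a02, a02),
                  _phased("i3", REF, REF)]
        table, _ = call_alleles_cohort(phased, match_db)
        assert table.groupby("group_id")["frequency"].sum().iloc[0] == \
            pytest.approx(1.0)

    def test_undesignated_group_rejected(self, match_db):
        with pytest.raises(ValueError, match="two-copy"):
            call_alleles_cohort([_phased("i1", REF, REF)], match_db,
                                two_copy_groups=["OTHER^"])


class TestIdentifySnps:
    def test_monomorphic_cohort_empty(self, match_db):
        _, calls = call_alleles_cohort(
            [_phased(f"i{k}", REF, REF) for k in range(4)], match_db)
        assert len(identify_snps(calls, match_db)) == 0

    def test_two_state_site_counted(self, match_db):
        a02 = match_db.get("IGHV1-18*02").nt_seq
        phased = [_phased(f"i{k}", REF, REF) for k in range(5)] + \
            [_phased(f"j{k}", a02, a02) for k in range(3)]
        _, calls = call_alleles_cohort(phased, match_db)
        snps = identify_snps(calls, match_db)
        assert snps["position"].nunique() == 1
        assert set(snps["state"]) == {REF[9], a02[9]}
        counts = snps.set_index("state")["n_individuals"]
        assert counts[REF[9]] == 5 and counts[a02[9]] == 3

    def test_single_individual_state_not_a_snp(self, match_db):
        novel = REF[:14] + "A" + REF[15:]
        phased = [_phased(f"i{k}", REF, REF) for k in range(4)] + \
            [_phased("solo", novel, REF)]
        _, calls = call_alleles_cohort(phased, match_db)
        assert len(identify_snps(calls, match_db)) == 0
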