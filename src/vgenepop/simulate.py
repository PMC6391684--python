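"""Synthetic cohort generation with known ground truth.

Emulates a worldwide short-read cohort (region-structured CNV haplotype and
allele frequencies, diploid copy numbers driving noisy per-segment coverage,
blood/saliva/cell-line DNA sources) so that every downstream stage —
copy-number estimation, CNV genotype clustering, phasing, allele discovery,
population statistics — can be validated against planted truth.

Model: for each individual, each polymorphism's two haploid variants are drawn
independently from that region's variant frequencies; the diploid copy number
of a group is the sum of the two draws. Two-copy groups carry two alleles
drawn from regional allele frequencies (which may include designated novel
alleles, simulated by mutating database alleles at configured positions).
Observed per-group coverage is (CN/2) x the individual's genome coverage times
multiplicative Gaussian noise (coefficient of variation ``coverage_noise_cv``),
truncated at zero, and is reported in k-mer units so the estimation chain is
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alleles import Read, apply_mutations
from .cnv import CnvPolymorphism
from .reference_db import AlleleDatabase

_DNA_SOURCES = ("blood", "saliva", "cell_line")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``variant_freqs``: region -> polymorphism_id -> frequency vector over the
    polymorphism's haploid variants. ``allele_freqs``: region -> group_id ->
    {allele name: frequency}; names absent from the database must appear in
    ``novel_alleles`` (name -> (base allele, ((position, alt base), ...))).
    """

    n_individuals_per_region: dict
    polymorphisms: list
    variant_freqs: dict
    allele_freqs: dict
    novel_alleles: dict = field(default_factory=dict)
    genome_coverage_mean: float = 42.0
    genome_coverage_sd: float = 5.0
    coverage_noise_cv: float = 0.05
    read_length: int = 100
    kmer_size: int = 21
    dna_source_probs: dict = field(
        default_factory=lambda: {"blood": 0.25, "saliva": 0.13, "cell_line": 0.62})
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_individuals_per_region.values()):
            raise ConfigError("negative individual count")
        if sum(self.n_individuals_per_region.values()) == 0:
            raise ConfigError("empty cohort")
        if not (self.read_length > self.kmer_size >= 1):
            raise ConfigError("need read_length > kmer_size >= 1")
        if self.coverage_noise_cv < 0:
            raise ConfigError("negative coverage noise")
        if abs(sum(self.dna_source_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("DNA source probabilities must sum to 1")
        if set(self.dna_source_probs) - set(_DNA_SOURCES):
            raise ConfigError(f"unknown DNA source in {self.dna_source_probs}")
        poly_ids = {p.polymorphism_id for p in self.polymorphisms}
        for region in self.n_individuals_per_region:
            vf = self.variant_freqs.get(region, {})
            if set(vf) != poly_ids:
                raise ConfigError(f"region {region}: variant frequencies must "
                                  "cover every polymorphism")
            for p in self.polymorphisms:
                v = np.asarray(vf[p.polymorphism_id], float)
                if len(v) != len(p.haploid_variants):
                    raise ConfigError(f"{region}/{p.polymorphism_id}: frequency "
                                      "vector length mismatch")
                if (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                    raise ConfigError(f"{region}/{p.polymorphism_id}: frequencies "
                                      "must be non-negative and sum to 1")
            for group, freqs in self.allele_freqs.get(region, {}).items():
                tot = sum(freqs.values())
                if any(f < 0 for f in freqs.values()) or abs(tot - 1.0) > 1e-9:
                    raise ConfigError(f"{region}/{group}: allele frequencies "
                                      "must be non-negative and sum to 1")


@dataclass
class TrueGenotype:
    """Planted ground truth for one individual."""

    individual_id: str
    region: str
    dna_source: str
    genome_coverage: float
    cn: dict  # group_id -> diploid copy number
    variant_pairs: dict  # polymorphism_id -> (hap1 label, hap2 label)
    alleles: dict  # group_id -> (hap1 allele name, hap2 allele name)
    allele_seqs: dict  # group_id -> (hap1 seq, hap2 seq)


@dataclass
class Cohort:
    """Simulated cohort: genotypes plus the tables downstream stages consume."""

    config: SimulationConfig
    db: AlleleDatabase
    genotypes: list
    metadata: pd.DataFrame  # individual_id, region, dna_source, genome_coverage
    coverage: pd.DataFrame  # long format, k-mer units
    truth: pd.DataFrame  # individual_id, group_id, true_cn, hap1/hap2 allele

    @property
    def regions(self) -> pd.Series:
        return self.metadata.set_index("individual_id")["region"]

    def genotype(self, individual_id: str) -> TrueGenotype:
        for g in self.genotypes:
            if g.individual_id == individual_id:
                return g
        raise KeyError(individual_id)

    def presence_sets(self) -> dict:
        """individual -> set of groups present (CN > 0), from planted truth."""
        return {g.individual_id: {gid for gid, cn in g.cn.items() if cn > 0}
                for g in self.genotypes}


def resolve_allele_sequence(name: str, db: AlleleDatabase, novel_alleles: dict) -> str:
    """Sequence of a database allele or a configured novel allele."""
    if name in db:
        return db.get(name).nt_seq
    if name in novel_alleles:
        base, muts = novel_alleles[name]
        seq = list(db.get(base).nt_seq)
        for pos, alt in muts:
            seq[pos] = alt.upper()
        return "".join(seq)
    raise KeyError(f"unknown allele {name}")


def simulate_population(config: SimulationConfig, db: AlleleDatabase) -> Cohort:
    """Draw a cohort under the configured study conditions (seed-reproducible)."""
    config.validate()
    if not db.groups:
        raise ConfigError("database has no operational groups; group it first")
    rng = np.random.default_rng(config.seed)
    group_ids = [g.group_id for g in db.groups]
    poly_groups = {gid for p in config.polymorphisms for gid in p.group_ids}
    rep_len = {g.group_id: max(len(g.representative_seq), config.read_length)
               for g in db.groups}
    sources = sorted(config.dna_source_probs)
    source_p = np.array([config.dna_source_probs[s] for s in sources])
    r, k = config.read_length, config.kmer_size

    genotypes: list[TrueGenotype] = []
    meta_rows, cov_rows, truth_rows = [], [], []
    for region in sorted(config.n_individuals_per_region):
        n = config.n_individuals_per_region[region]
        region_alleles = config.allele_freqs.get(region, {})
        for i in range(n):
            ind = f"{region}-{i:03d}"
            dna = sources[rng.choice(len(sources), p=source_p)]
            gcov = float(max(1.0, rng.normal(config.genome_coverage_mean,
                                             config.genome_coverage_sd)))
            cn = {gid: 2 for gid in group_ids}
            for gid in poly_groups:
                cn[gid] = 0
            variant_pairs = {}
            for poly in config.polymorphisms:
                freqs = np.asarray(config.variant_freqs[region][poly.polymorphism_id],
                                   float)
                picks = rng.choice(len(freqs), size=2, p=freqs / freqs.sum())
                labels = tuple(poly.variant_labels[p] for p in picks)
                variant_pairs[poly.polymorphism_id] = labels
                for lab in labels:
                    vec = poly.variant_vector(lab)
                    for gid, c in zip(poly.group_ids, vec):
                        cn[gid] += int(c)
            alleles, allele_seqs = {}, {}
            for gid in sorted(region_alleles):
                freqs = region_alleles[gid]
                names = sorted(freqs)
                p = np.array([freqs[nm] for nm in names])
                picks = rng.choice(len(names), size=2, p=p / p.sum())
                pair = tuple(names[j] for j in picks)
                alleles[gid] = pair
                allele_seqs[gid] = tuple(
                    resolve_allele_sequence(nm, db, config.novel_alleles)
                    for nm in pair)
            geno = TrueGenotype(individual_id=ind, region=region, dna_source=dna,
                                genome_coverage=gcov, cn=cn,
                                variant_pairs=variant_pairs, alleles=alleles,
                                allele_seqs=allele_seqs)
            genotypes.append(geno)
            meta_rows.append({"individual_id": ind, "region": region,
                              "dna_source": dna, "genome_coverage": gcov})
            for gid in group_ids:
                L = rep_len[gid]
                expected = cn[gid] / 2.0 * gcov
                if config.coverage_noise_cv > 0:
                    expected *= 1.0 + rng.normal(0.0, config.coverage_noise_cv)
                base_cov = max(0.0, expected)
                kmer_cov = base_cov * (L - r + 1) / L * (r - k + 1) / r
                cov_rows.append({"individual_id": ind, "group_id": gid,
                                 "kmer_coverage": kmer_cov, "contig_length": L,
                                 "read_length": r, "kmer_size": k,
                                 "genome_coverage": gcov})
                a1, a2 = alleles.get(gid, (None, None))
                truth_rows.append({"individual_id": ind, "group_id": gid,
                                   "true_cn": cn[gid], "hap1_allele": a1,
                                   "hap2_allele": a2})
    return Cohort(config=config, db=db, genotypes=genotypes,
                  metadata=pd.DataFrame(meta_rows),
                  coverage=pd.DataFrame(cov_rows),
                  truth=pd.DataFrame(truth_rows))


def _with_errors(sub: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return sub
    n_err = rng.binomial(len(sub), error_rate)
    if not n_err:
        return sub
    chars = list(sub)
    for pos in rng.choice(len(sub), size=n_err, replace=False):
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_segment_reads(genotype: TrueGenotype, group_id: str,
                           db: AlleleDatabase, read_length: int = 100,
                           depth_per_copy: float = 15.0,
                           error_rate: float = 0.0,
                           rng: np.random.Generator | int = 0,
                           paired: bool = True,
                           insert_mean: float = 250.0,
                           insert_sd: float = 60.0) -> list[Read]:
    """Uniform (paired-end by default) reads from every haploid copy of a group.

    Fragment starts are uniform on the template; fragment lengths are Gaussian
    (``insert_mean``/``insert_sd``) clipped to [read length, template length],
    and each fragment yields two mate reads (its two ends, sharing a
    ``fragment`` id) so distant heterozygous sites stay linkable, as with real
    paired-end data. Read counts are Poisson with per-copy per-base depth
    ``depth_per_copy``; base errors are i.i.d. substitutions at ``error_rate``.
    A group at copy number 0 yields no reads; reads longer than the template
    are truncated and flagged.
    """
    if depth_per_copy <= 0:
        raise ValueError("depth must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if group_id in genotype.allele_seqs:
        templates = list(genotype.allele_seqs[group_id])
    else:
        n_copies = genotype.cn.get(group_id, 0)
        rep = db.group_by_id(group_id).representative_seq
        templates = [rep] * n_copies
    reads: list[Read] = []
    frag_id = 0
    for seq in templates:
        if not seq:
            continue
        L = len(seq)
        if read_length >= L:
            n_reads = int(rng.poisson(depth_per_copy))
            for _ in range(n_reads):
                reads.append(Read(seq=_with_errors(seq, error_rate, rng),
                                  start=0, truncated=True))
            continue
        per_fragment = 2 * read_length if paired else read_length
        n_frags = int(rng.poisson(depth_per_copy * L / per_fragment))
        for _ in range(n_frags):
            if paired:
                flen = int(np.clip(rng.normal(insert_mean, insert_sd),
                                   read_length, L))
            else:
                flen = read_length
            start = int(rng.integers(0, L - flen + 1))
            reads.append(Read(seq=_with_errors(seq[start:start + read_length],
                                               error_rate, rng),
                              start=start, fragment=frag_id))
            if paired and flen > read_length:
                s2 = start + flen - read_length
                reads.append(Read(seq=_with_errors(seq[s2:s2 + read_length],
                                                   error_rate, rng),
                                  start=s2, fragment=frag_id))
            frag_id += 1
    return reads


def select_cohort(metadata: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Restrict the cohort by DNA source for the locus under analysis.

    Cell-line DNA comes from immortalized B cells whose heavy-chain locus is
    truncated by VDJ recombination, so IGHV analysis keeps blood and saliva
    sources only; TRBV keeps every individual.
    """
    if locus not in ("IGHV", "TRBV"):
        raise ValueError("locus must be IGHV or TRBV")
    unknown = set(metadata["dna_source"]) - set(_DNA_SOURCES)
    if unknown:
        raise ValueError(f"unknown DNA source values {sorted(unknown)}")
    if locus == "TRBV":
        return metadata.copy()
    return metadata[metadata["dna_source"].isin(("blood", "saliva"))].copy()
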