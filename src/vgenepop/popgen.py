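"""Summary statistics of allelic and nucleotide variation.

Covers the cohort-level descriptors of V-segment diversity: average pairwise
base-pair difference between a segment's alleles, SNPs per segment, the
fraction of novel alleles, variants private to a geographic region, the
Weir & Cockerham (1984) fixation index over haplotype allele counts, and a
two-sample Kolmogorov-Smirnov comparison of per-segment allele-count
distributions.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class DiversitySummary:
    avg_pairwise_bp_diff_pct: float
    avg_snps_per_segment: float
    novel_count: int
    total_count: int

    @property
    def novel_fraction(self) -> float:
        return self.novel_count / self.total_count if self.total_count else 0.0


@dataclass
class PrivateVariant:
    kind: str  # "allele" or "SNV"
    identifier: str
    region: str
    carrier_haplotypes: int
    regional_frequency: float


@dataclass
class FstResult:
    overall: float | None
    per_locus: dict = field(default_factory=dict)
    regions: tuple = ()


def avg_pairwise_bp_difference(allele_seqs: dict, weights: dict | None = None) -> float:
    """Mean percent base-pair difference between a segment's alleles, averaged
    unweighted over segments.

    ``allele_seqs`` maps group -> {allele name: sequence}; pairs are compared
    over their shared prefix length. Groups with fewer than two alleles are
    skipped with a warning. ``weights`` (group -> {allele: haplotype count})
    switches to frequency-weighted pair sampling.
    """
    per_segment = []
    for group in sorted(allele_seqs):
        seqs = allele_seqs[group]
        if len(seqs) < 2:
            warnings.warn(f"group {group} has <2 alleles; skipped")
            continue
        names = sorted(seqs)
        diffs, wsum = [], []
        for a, b in combinations(names, 2):
            sa, sb = seqs[a].upper(), seqs[b].upper()
            L = min(len(sa), len(sb))
            d = 100.0 * sum(x != y for x, y in zip(sa[:L], sb[:L])) / L
            w = (weights[group][a] * weights[group][b]) if weights else 1.0
            diffs.append(d * w)
            wsum.append(w)
        per_segment.append(sum(diffs) / sum(wsum))
    if not per_segment:
        raise ValueError("no group with at least two alleles")
    return float(np.mean(per_segment))


def snps_per_segment(snp_table: pd.DataFrame, segment_groups: list[str]) -> float:
    """Total SNP positions divided by the number of designated two-copy
    groups (zero-SNP groups included in the denominator)."""
    if not segment_groups:
        raise ValueError("empty segment list")
    if len(snp_table) == 0:
        return 0.0
    n_snps = int(snp_table.groupby("group_id")["position"].nunique().sum())
    return n_snps / len(segment_groups)


def novel_fraction(allele_table: pd.DataFrame) -> tuple[int, int, float]:
    """(novel, total, fraction) over distinct called alleles."""
    if len(allele_table) == 0:
        raise ValueError("empty allele table")
    total = len(allele_table)
    novel = int(allele_table["novel"].sum())
    return novel, total, novel / total


def private_alleles(calls, regions: pd.Series,
                    only_called: bool = True) -> list[PrivateVariant]:
    """Alleles whose every carrier belongs to a single region.

    Regional frequency is carrier haplotypes over 2 x region size.
    """
    region_sizes = regions.value_counts()
    carriers: dict[tuple, list] = defaultdict(list)
    for c in calls:
        if only_called and not c.called:
            continue
        carriers[(c.group_id, c.allele_name)].append(c.individual_id)
    out = []
    for (group, name), inds in sorted(carriers.items()):
        regs = {str(regions[i]) for i in inds}
        if len(regs) == 1:
            region = regs.pop()
            out.append(PrivateVariant(
                kind="allele", identifier=f"{group}:{name}", region=region,
                carrier_haplotypes=len(inds),
                regional_frequency=len(inds) / (2 * int(region_sizes[region]))))
    return out


def private_snvs(snp_table: pd.DataFrame, calls, db, regions: pd.Series,
                 ) -> list[PrivateVariant]:
    """SNV states carried exclusively by individuals of one region.

    A state at a polymorphic site is private to region R when every haplotype
    carrying it belongs to an individual from R and at least one other state
    exists at the site. Identifiers follow segment_position+base.
    """
    from .alleles import apply_mutations

    region_sizes = regions.value_counts()
    by_group = defaultdict(list)
    for c in calls:
        by_group[c.group_id].append(c)
    out = []
    for _, row in snp_table.iterrows():
        group, pos, state = row["group_id"], int(row["position"]), row["state"]
        carriers = []
        for c in by_group[group]:
            seq = apply_mutations(db.get(c.base_allele).nt_seq, c.mutations)
            if pos < len(seq) and seq[pos] == state:
                carriers.append(c.individual_id)
        regs = {str(regions[i]) for i in carriers}
        if len(regs) == 1 and carriers:
            region = regs.pop()
            out.append(PrivateVariant(
                kind="SNV", identifier=f"{group}_{pos}{state.lower()}",
                region=region, carrier_haplotypes=len(carriers),
                regional_frequency=len(carriers) / (2 * int(region_sizes[region]))))
    return out


def fst_weir_cockerham(haplotypes: pd.DataFrame) -> FstResult:
    """Weir & Cockerham (1984) theta on haplotype allele counts.

    ``haplotypes`` has one row per haplotype with columns region, locus,
    allele. Per locus and allele, the among/within variance components are
    estimated from the one-way ANOVA moments

        MSP = sum_i n_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i n_i p_i (1 - p_i) / sum_i (n_i - 1)
        n_c = (N - sum_i n_i^2 / N) / (r - 1)

    giving theta = sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG), with the sums
    over alleles (per-locus theta) and additionally over loci (overall,
    ratio-of-sums). Monomorphic data leave theta undefined (None).
    """
    required = {"region", "locus", "allele"}
    if required - set(haplotypes.columns):
        raise ValueError(f"need columns {sorted(required)}")
    regions = sorted(haplotypes["region"].unique())
    r = len(regions)
    if r < 2:
        raise ValueError("need at least two regions")
    sizes = haplotypes.groupby(["locus", "region"]).size()
    per_locus: dict = {}
    num_total = den_total = 0.0
    for locus in sorted(haplotypes["locus"].unique()):
        sub = haplotypes[haplotypes["locus"] == locus]
        counts = np.array([sizes.get((locus, reg), 0) for reg in regions], float)
        use = counts >= 2  # regions with too few haplotypes at this locus drop out
        if use.sum() < 2:
            warnings.warn(f"locus {locus}: fewer than two regions with >=2 "
                          "haplotypes; skipped")
            per_locus[locus] = None
            continue
        locus_regions = [reg for reg, u in zip(regions, use) if u]
        n_i = counts[use]
        rl = len(locus_regions)
        N = n_i.sum()
        n_c = (N - (n_i ** 2).sum() / N) / (rl - 1)
        num = den = 0.0
        for allele in sub["allele"].unique():
            p_i = np.array([
                ((sub["region"] == reg) & (sub["allele"] == allele)).sum()
                for reg in locus_regions], float) / n_i
            p_bar = (n_i * p_i).sum() / N
            msp = (n_i * (p_i - p_bar) ** 2).sum() / (rl - 1)
            msg = (n_i * p_i * (1 - p_i)).sum() / (n_i - 1).sum()
            num += msp - msg
            den += msp + (n_c - 1) * msg
        per_locus[locus] = num / den if den > 0 else None
        num_total += num
        den_total += den
    overall = num_total / den_total if den_total > 0 else None
    return FstResult(overall=overall, per_locus=per_locus, regions=tuple(regions))


def compare_allele_count_distributions(counts_a, counts_b,
                                       method: str = "asymp"):
    """Two-sample Kolmogorov-Smirnov test on per-segment allele counts.

    Returns (statistic, p-value); the asymptotic p-value is the default, with
    ``method="exact"`` available for small samples.
    """
    if len(counts_a) == 0 or len(counts_b) == 0:
        raise ValueError("empty allele-count list")
    res = sstats.ks_2samp(counts_a, counts_b, method=method)
    return float(res.statistic), float(res.pvalue)


def diversity_summary(allele_table: pd.DataFrame, allele_seqs: dict,
                      snp_table: pd.DataFrame,
                      segment_groups: list[str]) -> DiversitySummary:
    """Headline per-locus summary over the two-copy segment set."""
    novel, total, _ = novel_fraction(allele_table)
    return DiversitySummary(
        avg_pairwise_bp_diff_pct=avg_pairwise_bp_difference(allele_seqs),
        avg_snps_per_segment=snps_per_segment(snp_table, segment_groups),
        novel_count=novel, total_count=total)
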