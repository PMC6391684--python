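"""Read-depth to copy-number conversion.

Per-segment depth from short-read assemblies is reported as k-mer coverage of
the assembled contig. Two corrections turn it into an unbiased per-base depth:
(1) a read of length r contains r - k + 1 k-mers, so k-mer depth understates
base depth by that ratio; (2) read depth over a short contig has a trapezoidal
profile (ramps of length r - 1 at the ends, plateau inside), so the mean depth
understates the plateau by (L - r + 1) / L. Normalizing the corrected depth by
the individual's genome-wide depth (diploid baseline, factor 2) gives a
continuous diploid copy-number estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoverageRecord:
    individual_id: str
    group_id: str
    kmer_coverage: float
    contig_length: int
    read_length: int
    kmer_size: int
    genome_coverage: float


@dataclass
class CopyNumberEstimate:
    individual_id: str
    group_id: str
    cn_estimate: float
    from_kmer: bool = True  # provenance: k-mer conversion applied or base depth given


def kmer_to_base_coverage(kmer_cov: float, read_length: int, kmer_size: int) -> float:
    """Convert mean k-mer depth to mean per-base depth.

    A read of length r yields r - k + 1 k-mers, each covering k bases; the
    expected base depth is therefore kmer_cov * r / (r - k + 1).
    """
    if kmer_size < 1 or kmer_size > read_length:
        raise ValueError("need 1 <= kmer_size <= read_length")
    if kmer_cov < 0:
        raise ValueError("coverage must be non-negative")
    return kmer_cov * read_length / (read_length - kmer_size + 1)


def trapezoid_correction(base_cov: float, contig_length: int, read_length: int) -> float:
    """Scale mean contig depth up to the plateau of the trapezoidal profile.

    Fully contained reads start at L - r + 1 positions; the mean of the
    trapezoid relative to its plateau is (L - r + 1) / L, so the plateau depth
    is base_cov * L / (L - r + 1).
    """
    if contig_length < read_length:
        raise ValueError("contig shorter than the read length")
    if base_cov < 0:
        raise ValueError("coverage must be non-negative")
    return base_cov * contig_length / (contig_length - read_length + 1)


def estimate_copy_number(record: CoverageRecord, apply_kmer: bool = True) -> CopyNumberEstimate:
    """Point estimate of diploid copy number from one coverage record.

    ``apply_kmer=False`` treats ``kmer_coverage`` as base coverage directly
    (no assembly step); the provenance flag records which path was used.
    """
    if record.genome_coverage <= 0:
        raise ValueError("genome coverage must be positive")
    cov = record.kmer_coverage
    if apply_kmer:
        cov = kmer_to_base_coverage(cov, record.read_length, record.kmer_size)
    cov = trapezoid_correction(cov, record.contig_length, record.read_length)
    return CopyNumberEstimate(individual_id=record.individual_id,
                              group_id=record.group_id,
                              cn_estimate=2.0 * cov / record.genome_coverage,
                              from_kmer=apply_kmer)


def copy_number_table(coverage: pd.DataFrame, apply_kmer: bool = True) -> pd.DataFrame:
    """Vectorized :func:`estimate_copy_number` over a long-format coverage table.

    Expects columns individual_id, group_id, kmer_coverage, contig_length,
    read_length, kmer_size, genome_coverage; returns the same keys plus
    cn_estimate.
    """
    required = {"individual_id", "group_id", "kmer_coverage", "contig_length",
                "read_length", "kmer_size", "genome_coverage"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table missing columns {sorted(missing)}")
    if (coverage["genome_coverage"] <= 0).any():
        raise ValueError("genome coverage must be positive")
    r = coverage["read_length"].to_numpy(float)
    k = coverage["kmer_size"].to_numpy(float)
    L = coverage["contig_length"].to_numpy(float)
    if (k > r).any() or (k < 1).any():
        raise ValueError("need 1 <= kmer_size <= read_length")
    if (L < r).any():
        raise ValueError("contig shorter than the read length")
    cov = coverage["kmer_coverage"].to_numpy(float)
    if apply_kmer:
        cov = cov * r / (r - k + 1)
    cov = cov * L / (L - r + 1)
    out = coverage[["individual_id", "group_id"]].copy()
    out["cn_estimate"] = 2.0 * cov / coverage["genome_coverage"].to_numpy(float)
    return out


def cn_matrix(cn_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long copy-number table to individuals x groups."""
    return cn_table.pivot(index="individual_id", columns="group_id",
                          values="cn_estimate")


def flag_two_copy_groups(cn_table: pd.DataFrame, min_fraction: float = 0.95) -> list[str]:
    """Groups whose rounded CN estimate is 2 in at least ``min_fraction`` of
    individuals — the safe set for SNV/allele analyses."""
    mat = cn_matrix(cn_table) if "cn_estimate" in cn_table.columns else cn_table
    rounded_two = (np.round(mat) == 2).mean(axis=0)
    return sorted(rounded_two.index[rounded_two >= min_fraction])
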