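"""CNV haplotype calling from continuous copy-number estimates.

A *polymorphism* is a set of operational groups whose copy numbers co-vary on
a haplotype, described by its candidate haploid variants (per-group copy
vectors). Diploid genotype classes are all unordered sums of haploid variant
pairs. Individuals are clustered on their copy-number estimate vectors
(agglomerative, Ward linkage, Euclidean) and each cluster is assigned to the
diploid class nearest its centroid, which makes every call auditable against
the schematic variant definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from math import prod

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cluster import AgglomerativeClustering


@dataclass(frozen=True)
class DiploidClass:
    label: str
    vector: tuple  # per-group diploid copy numbers
    haploid_pair: tuple  # (variant label, variant label)


@dataclass
class CnvPolymorphism:
    """One copy-number polymorphism: groups + candidate haploid variants.

    ``call_method`` is "cluster" for the schematic multi-gene insertion/
    deletion polymorphisms, or "round" for high-copy single-group sets whose
    diploid totals are called directly by rounding the continuous estimate
    (their per-haplotype split is not identifiable from depth alone; the
    balanced-decomposition bound applies instead).
    """

    polymorphism_id: str
    group_ids: list[str]
    haploid_variants: list[tuple[str, tuple]]  # (label, per-group haploid copies)
    call_method: str = "cluster"

    def __post_init__(self):
        if not self.haploid_variants:
            raise ValueError("polymorphism needs at least one haploid variant")
        if self.call_method not in ("cluster", "round"):
            raise ValueError("call_method must be 'cluster' or 'round'")
        if self.call_method == "round" and len(self.group_ids) != 1:
            raise ValueError("rounded total calling applies to a single group")
        for label, vec in self.haploid_variants:
            if len(vec) != len(self.group_ids):
                raise ValueError(f"variant {label}: vector length mismatch")
            if any(v < 0 for v in vec):
                raise ValueError(f"variant {label}: negative copy number")

    @property
    def variant_labels(self) -> list[str]:
        return [lab for lab, _ in self.haploid_variants]

    def variant_vector(self, label: str) -> tuple:
        for lab, vec in self.haploid_variants:
            if lab == label:
                return tuple(vec)
        raise KeyError(label)

    @property
    def diploid_classes(self) -> list[DiploidClass]:
        """All unordered haploid-pair sums, ordered by total copies then label."""
        classes = []
        for (l1, v1), (l2, v2) in combinations_with_replacement(self.haploid_variants, 2):
            pair = tuple(sorted((l1, l2)))
            classes.append(DiploidClass(label="/".join(pair),
                                        vector=tuple(a + b for a, b in zip(v1, v2)),
                                        haploid_pair=pair))
        classes.sort(key=lambda c: (sum(c.vector), c.label))
        return classes

    def to_dict(self) -> dict:
        return {"polymorphism_id": self.polymorphism_id,
                "group_ids": list(self.group_ids),
                "haploid_variants": [[lab, list(vec)] for lab, vec in self.haploid_variants],
                "call_method": self.call_method}

    @classmethod
    def from_dict(cls, d: dict) -> "CnvPolymorphism":
        return cls(polymorphism_id=d["polymorphism_id"],
                   group_ids=list(d["group_ids"]),
                   haploid_variants=[(lab, tuple(vec)) for lab, vec in d["haploid_variants"]],
                   call_method=d.get("call_method", "cluster"))


@dataclass
class CnvCallSet:
    """Integer genotype calls for one polymorphism across a cohort."""

    polymorphism: CnvPolymorphism
    calls: pd.DataFrame  # individual_id, cluster, class_label, hap1, hap2, cn_<group>...
    centroids: dict = field(default_factory=dict)  # cluster -> centroid vector
    method: str = "cluster"

    def __len__(self) -> int:
        return len(self.calls)


def _nearest_class(vec: np.ndarray, classes: list[DiploidClass]) -> DiploidClass:
    """Euclidean-nearest diploid class; ties resolved toward lower total copy
    number, then lexicographic label (classes are pre-sorted that way)."""
    dists = [float(np.linalg.norm(vec - np.asarray(c.vector, float))) for c in classes]
    best = min(dists)
    for c, d in zip(classes, dists):
        if np.isclose(d, best):
            return c
    raise AssertionError("unreachable")


def cluster_copy_numbers(estimates: pd.DataFrame,
                         polymorphism: CnvPolymorphism) -> CnvCallSet:
    """Cluster CN-estimate vectors and assign each cluster a diploid class.

    ``estimates`` is an individuals x groups matrix (e.g. from
    :func:`vgenepop.coverage.cn_matrix`) containing the polymorphism's groups.
    The number of clusters is the number of diploid classes with non-trivial
    support (at least one individual nearest to them), capped at the number of
    classes.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two individuals")
    missing = [g for g in polymorphism.group_ids if g not in estimates.columns]
    if missing:
        raise ValueError(f"estimate matrix lacks groups {missing}")
    X = estimates[polymorphism.group_ids].to_numpy(float)
    if polymorphism.call_method == "round":
        return _round_total_calls(estimates, X, polymorphism)
    classes = polymorphism.diploid_classes

    supported = {_nearest_class(x, classes).label for x in X}
    k = max(1, min(len(supported), len(classes), len(X)))

    if k == 1 or np.allclose(X, X[0]):
        if np.allclose(X, X[0]) and len(classes) > 1:
            warnings.warn("all estimates identical; collapsing to one cluster")
        labels = np.zeros(len(X), dtype=int)
        k = 1
    else:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)

    centroids = {c: X[labels == c].mean(axis=0) for c in range(k)}
    assigned = {c: _nearest_class(centroids[c], classes) for c in range(k)}

    rows = []
    for ind, x, lab in zip(estimates.index, X, labels):
        cls = assigned[int(lab)]
        row = {"individual_id": ind, "cluster": int(lab), "class_label": cls.label,
               "hap1": cls.haploid_pair[0], "hap2": cls.haploid_pair[1]}
        for g, cn in zip(polymorphism.group_ids, cls.vector):
            row[f"cn_{g}"] = int(cn)
        rows.append(row)
    calls = pd.DataFrame(rows)
    return CnvCallSet(polymorphism=polymorphism, calls=calls,
                      centroids={c: centroids[c].tolist() for c in centroids})


def _round_total_calls(estimates: pd.DataFrame, X: np.ndarray,
                       polymorphism: CnvPolymorphism) -> CnvCallSet:
    """Diploid totals by rounding to the nearest valid class total.

    Valid totals are the sums of haploid variant pairs, so noisy estimates
    cannot be called outside the configured copy-number range. Haploid
    columns carry the balanced-decomposition bound.
    """
    valid = np.array(sorted({sum(c.vector) for c in polymorphism.diploid_classes}))
    idx = np.abs(X[:, [0]] - valid[None, :]).argmin(axis=1)
    totals = valid[idx]
    group = polymorphism.group_ids[0]
    rows = []
    for ind, total in zip(estimates.index, totals):
        hi = min_max_haploid(int(total))
        rows.append({"individual_id": ind, "cluster": -1,
                     "class_label": str(int(total)),
                     "hap1": str(int(total) - hi), "hap2": str(hi),
                     f"cn_{group}": int(total)})
    return CnvCallSet(polymorphism=polymorphism, calls=pd.DataFrame(rows),
                      method="round")


def variant_relative_abundance(callset: CnvCallSet) -> pd.Series:
    """Relative abundance of variants among the called cohort.

    For clustered polymorphisms each individual contributes its two assigned
    haploid variants (fractions over 2N haplotypes). For rounded high-copy
    sets the per-haplotype split is not identifiable, so the distribution is
    over diploid totals across individuals, matching how such sets are
    reported.
    """
    if len(callset) == 0:
        raise ValueError("empty call set")
    if callset.method == "round":
        counts = callset.calls["class_label"].value_counts()
        ra = counts / counts.sum()
        ra.index = ra.index.astype(int)
        ra = ra.sort_index()
        ra.index = ra.index.astype(str)
    else:
        counts = pd.concat([callset.calls["hap1"],
                            callset.calls["hap2"]]).value_counts()
        ra = (counts / counts.sum()).sort_index()
    ra.name = "relative_abundance"
    return ra


def min_max_haploid(max_diploid: int) -> int:
    """Smallest possible largest haploid copy number given a diploid total.

    The most balanced two-part decomposition of d is (floor(d/2), ceil(d/2));
    the bound is its larger element, ceil(d/2). E.g. 13 -> (6, 7) -> 7.
    """
    if max_diploid < 0:
        raise ValueError("diploid copy number cannot be negative")
    return (max_diploid + 1) // 2


def haplotype_count_estimate(variant_counts: list[int]) -> int:
    """Locus-wide haplotype count under polymorphism independence: the product
    of per-polymorphism haploid variant counts."""
    if not variant_counts:
        raise ValueError("no variant counts given")
    if any(c < 1 for c in variant_counts):
        raise ValueError("each polymorphism has at least one variant")
    return prod(variant_counts)


def pairwise_r_squared(estimates: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation between all pairs of group CN estimates.

    Constant columns have undefined correlation and are reported as NaN
    (excluded from any averaging).
    """
    if len(estimates) < 3:
        raise ValueError("need at least three individuals")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r2 = estimates.corr() ** 2
    const = estimates.std(ddof=0) == 0
    r2.loc[const, :] = np.nan
    r2.loc[:, const] = np.nan
    for g in estimates.columns[~const]:
        r2.loc[g, g] = 1.0
    return r2


def mean_off_diagonal_r2(r2: pd.DataFrame, blocks: list[list[str]] | None = None) -> float:
    """Mean R^2 over group pairs, optionally excluding within-block pairs
    (groups belonging to the same polymorphism)."""
    in_block = set()
    for block in blocks or []:
        for a, b in combinations_with_replacement(block, 2):
            in_block.add((a, b))
            in_block.add((b, a))
    vals = []
    cols = list(r2.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if (a, b) in in_block:
                continue
            v = r2.loc[a, b]
            if np.isfinite(v):
                vals.append(float(v))
    if not vals:
        raise ValueError("no off-block pairs with defined correlation")
    return float(np.mean(vals))


def regional_distribution_test(callset: CnvCallSet, regions: pd.Series,
                               alpha: float = 0.01) -> pd.DataFrame:
    """Per-region chi-squared goodness of fit of genotype-class counts against
    the global class distribution; a region is flagged when p < alpha.

    The asymptotic chi-squared distribution is used even at small expected
    counts (regions can be tiny); a warning notes expected counts below 5.
    """
    counts = callset.calls.set_index("individual_id")["class_label"]
    global_counts = counts.value_counts()
    if len(global_counts) < 2:
        raise ValueError("need at least two genotype classes globally")
    global_props = global_counts / global_counts.sum()
    rows = []
    for region in sorted(regions.unique()):
        inds = regions.index[regions == region]
        obs_series = counts.loc[counts.index.intersection(inds)]
        n = len(obs_series)
        if n == 0:
            warnings.warn(f"region {region} has no called individuals; skipped")
            continue
        obs = obs_series.value_counts().reindex(global_props.index, fill_value=0)
        exp = global_props * n
        if (exp < 5).any():
            warnings.warn(f"region {region}: expected counts below 5; "
                          "asymptotic chi-squared p-value is approximate")
        stat, p = sstats.chisquare(obs.to_numpy(float), exp.to_numpy(float))
        rows.append({"region": region, "n": n, "statistic": float(stat),
                     "p_value": float(p), "flagged": bool(p < alpha)})
    return pd.DataFrame(rows)


def segment_set_difference_probability(presence: dict, stratify_by: pd.Series | None = None):
    """Probability that two random individuals carry different segment sets.

    ``presence`` maps individual -> set of groups present in any copy number;
    two individuals differ when at least one group is present in one set but
    absent from the other. Returns the overall pair fraction, or with
    ``stratify_by`` a (overall, per-stratum DataFrame) tuple where within each
    stratum pairs are drawn from that stratum only.
    """
    def _prob(ids):
        n = len(ids)
        if n < 2:
            raise ValueError("need at least two individuals")
        sets = pd.Series([frozenset(presence[i]) for i in ids]).value_counts()
        same = float((sets * (sets - 1)).sum())
        return 1.0 - same / (n * (n - 1))

    all_ids = list(presence)
    overall = _prob(all_ids)
    if stratify_by is None:
        return overall
    rows = []
    for stratum in sorted(stratify_by.unique()):
        ids = [i for i in all_ids if i in stratify_by.index and stratify_by[i] == stratum]
        if len(ids) < 2:
            warnings.warn(f"stratum {stratum} has fewer than two individuals; omitted")
            continue
        rows.append({"stratum": stratum, "n": len(ids),
                     "p_different": _prob(ids)})
    return overall, pd.DataFrame(rows)
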