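"""Population structure from allele content via multidimensional scaling.

Each individual is encoded as a vector x_i whose m-th entry is their copy
number of allele m (0, 1 or 2 for two-copy segments); metric MDS embeds the
Euclidean distances between these vectors, and a silhouette score over the
embedding quantifies regional separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import smacof
from sklearn.metrics import euclidean_distances, silhouette_score


@dataclass
class Embedding:
    coordinates: pd.DataFrame  # index individuals, columns dim1..dimK
    stress: float

    def __post_init__(self):
        if not np.isfinite(self.coordinates.to_numpy()).all():
            raise ValueError("non-finite embedding coordinates")
        if self.stress < 0:
            raise ValueError("negative stress")


def allele_copy_matrix(calls, allele_universe: list | None = None,
                       only_called: bool = True) -> pd.DataFrame:
    """Individuals x alleles copy matrix from per-haplotype allele calls.

    Homozygotes contribute 2 in their allele's column, heterozygotes 1 in
    each; haplotypes left uncalled contribute 0 everywhere (their row sum for
    the segment is below 2, which doubles as a missingness flag). Columns are
    (group, allele) pairs.
    """
    per_ind_group: dict = {}
    for c in calls:
        key = (c.individual_id, c.group_id)
        per_ind_group.setdefault(key, []).append(c)
    for (ind, group), lst in per_ind_group.items():
        if len(lst) > 2:
            raise ValueError(f"{ind}/{group}: more than two haplotypes")
    cells: dict = {}
    for c in calls:
        if only_called and not c.called:
            continue
        cells[(c.individual_id, (c.group_id, c.allele_name))] = cells.get(
            (c.individual_id, (c.group_id, c.allele_name)), 0) + 1
    individuals = sorted({c.individual_id for c in calls})
    columns = allele_universe or sorted({key for _, key in cells})
    mat = pd.DataFrame(0, index=individuals,
                       columns=pd.MultiIndex.from_tuples(columns,
                                                         names=["group", "allele"]))
    for (ind, key), v in cells.items():
        if key in mat.columns:
            mat.loc[ind, key] = v
    return mat


def _classical_scaling(dist: np.ndarray, dims: int) -> np.ndarray:
    """Principal-coordinates (Torgerson) solution, the deterministic start."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def mds_embed(matrix: pd.DataFrame, dims: int = 2, seed: int = 0,
              n_init: int = 4, max_iter: int = 500) -> Embedding:
    """Metric MDS of the allele copy matrix (Euclidean distances).

    Stress majorization (SMACOF) is started from the classical-scaling
    solution plus ``n_init`` seeded random restarts; the lowest-stress
    solution wins, making the embedding deterministic under a fixed seed.
    """
    X = matrix.to_numpy(float)
    if len(X) < dims + 1:
        raise ValueError("need at least dims + 1 individuals")
    D = euclidean_distances(X)
    init = _classical_scaling(D, dims)
    best, best_stress = None, np.inf
    coords, stress = smacof(D, metric=True, n_components=dims, init=init,
                            n_init=1, max_iter=max_iter, eps=1e-12,
                            random_state=seed, normalized_stress=False)
    best, best_stress = coords, stress
    if n_init > 0:
        coords, stress = smacof(D, metric=True, n_components=dims,
                                n_init=n_init, max_iter=max_iter, eps=1e-12,
                                random_state=seed, normalized_stress=False)
        if stress < best_stress:
            best, best_stress = coords, stress
    frame = pd.DataFrame(best, index=matrix.index,
                         columns=[f"dim{i + 1}" for i in range(dims)])
    return Embedding(coordinates=frame, stress=float(best_stress))


def region_separation_score(embedding: Embedding, regions: pd.Series) -> float:
    """Mean silhouette of region labels over the embedded coordinates.

    Near 1 for well-separated regional clouds, near 0 for arbitrary labels.
    """
    labels = regions.loc[embedding.coordinates.index]
    if labels.nunique() < 2:
        raise ValueError("need at least two regions")
    if (labels.value_counts() == 1).any():
        warnings.warn("some region has a single individual; silhouette "
                      "includes it by convention")
    return float(silhouette_score(embedding.coordinates.to_numpy(),
                                  labels.to_numpy()))
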