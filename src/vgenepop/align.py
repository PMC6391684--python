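"""Affine-gap pairwise alignment and repertoire diversity measures.

Both the local (Smith-Waterman) and global (Needleman-Wunsch) aligners are
implemented here with the three-state Gotoh recursion; they are the basis for
operational segment grouping on nucleotide sequences and for within/between
species amino-acid diversity of V-gene repertoires.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``,
i.e. ``gap_open`` is the score penalty of the first gapped column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

try:  # jitted kernels; plain-Python fallback keeps the module importable anywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

_NEG = -1.0e30


@dataclass(frozen=True)
class Scoring:
    """Substitution matrix plus affine gap penalties over a fixed alphabet."""

    alphabet: str
    matrix: np.ndarray  # square, indexed by alphabet position
    gap_open: float  # positive penalty of the first gap column
    gap_extend: float  # positive penalty of each further gap column
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("substitution matrix does not match alphabet size")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([self._index[c] for c in seq.upper()], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"character {exc} not in scoring alphabet") from exc


def nucleotide_scoring(match: float = 2.0, mismatch: float = -2.0,
                       gap_open: float = 3.0, gap_extend: float = 1.0) -> Scoring:
    """Simple DNA scoring; N scores as a mismatch against everything."""
    alphabet = "ACGTN"
    m = np.full((5, 5), mismatch)
    for i in range(4):
        m[i, i] = match
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return Scoring(alphabet, m, gap_open, gap_extend)


def blosum62_scoring(gap_open: float = 11.0, gap_extend: float = 1.0) -> Scoring:
    """BLOSUM62 protein scoring (default for amino-acid repertoires)."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    return Scoring(alphabet, np.array(mat, dtype=float), gap_open, gap_extend)


@dataclass(frozen=True)
class AlignmentResult:
    """Score plus identity of the optimal alignment."""

    score: float
    identity: float  # matches / aligned columns (gap columns included)
    aligned_length: int
    matches: int = 0

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0, 1]")


@njit(cache=False)
def _nw_fill(a, b, sub, go, ge):  # pragma: no cover - exercised via wrappers
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Iy[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = sub[ai, b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge, Iy[i - 1, j] - go)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge, Ix[i, j - 1] - go)
    return M, Ix, Iy


@njit(cache=False)
def _sw_fill(a, b, sub, go, ge):  # pragma: no cover - exercised via wrappers
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)  # gap in a
    F = np.full((n + 1, m + 1), _NEG)  # gap in b
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            H[i, j] = max(0.0, h, E[i, j], F[i, j])
    return H, E, F


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= 1e-9 * (1.0 + abs(y))


def _nw_traceback(a_seq: str, b_seq: str, M, Ix, Iy, sub, ac, bc,
                  go: float, ge: float) -> tuple[int, int]:
    """Count matches and aligned columns of one optimal global alignment."""
    i, j = len(a_seq), len(b_seq)
    scores = [M[i, j], Ix[i, j], Iy[i, j]]
    state = int(np.argmax(scores))
    matches = 0
    cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == 0:  # diagonal step ending here
            if a_seq[i - 1].upper() == b_seq[j - 1].upper():
                matches += 1
            prev = M[i, j] - sub[ac[i - 1], bc[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if _close(prev, M[i, j]):
                state = 0
            elif _close(prev, Ix[i, j]):
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in b, consumes a[i-1]
            cur = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if _close(cur, M[i, j] - go):
                state = 0
            elif _close(cur, Ix[i, j] - ge):
                state = 1
            else:
                state = 2
        else:  # gap in a, consumes b[j-1]
            cur = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if _close(cur, M[i, j] - go):
                state = 0
            elif _close(cur, Iy[i, j] - ge):
                state = 2
            else:
                state = 1
    return matches, cols


def needleman_wunsch(a: str, b: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal global alignment with end gaps penalized."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or nucleotide_scoring()
    ac, bc = scoring.encode(a), scoring.encode(b)
    M, Ix, Iy = _nw_fill(ac, bc, scoring.matrix, scoring.gap_open, scoring.gap_extend)
    n, m = len(a), len(b)
    score = max(M[n, m], Ix[n, m], Iy[n, m])
    matches, cols = _nw_traceback(a, b, M, Ix, Iy, scoring.matrix, ac, bc,
                                  scoring.gap_open, scoring.gap_extend)
    identity = matches / cols if cols else 0.0
    return AlignmentResult(score=float(score), identity=identity,
                           aligned_length=cols, matches=matches)


def smith_waterman(a: str, b: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal local alignment; score is 0 when no positive-scoring pair exists."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or nucleotide_scoring()
    ac, bc = scoring.encode(a), scoring.encode(b)
    H, E, F = _sw_fill(ac, bc, scoring.matrix, scoring.gap_open, scoring.gap_extend)
    score = float(H.max())
    if score <= 0.0:
        return AlignmentResult(score=0.0, identity=0.0, aligned_length=0, matches=0)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    matches = 0
    cols = 0
    go, ge = scoring.gap_open, scoring.gap_extend
    sub = scoring.matrix
    state = 0  # 0=H, 1=E (gap in a), 2=F (gap in b)
    while i > 0 and j > 0:
        if state == 0:
            if _close(H[i, j], 0.0):
                break
            diag = H[i - 1, j - 1] + sub[ac[i - 1], bc[j - 1]]
            if _close(H[i, j], diag):
                cols += 1
                if a[i - 1].upper() == b[j - 1].upper():
                    matches += 1
                i, j = i - 1, j - 1
            elif _close(H[i, j], E[i, j]):
                state = 1
            else:
                state = 2
        elif state == 1:  # consumes b[j-1]
            cur = E[i, j]
            cols += 1
            j -= 1
            state = 0 if _close(cur, H[i, j] - go) else 1
        else:  # consumes a[i-1]
            cur = F[i, j]
            cols += 1
            i -= 1
            state = 0 if _close(cur, H[i, j] - go) else 2
    identity = matches / cols if cols else 0.0
    return AlignmentResult(score=score, identity=identity,
                           aligned_length=cols, matches=matches)


def global_identity(a: str, b: str, scoring: Scoring | None = None) -> float:
    """Global-alignment identity: matches / alignment length, end gaps counted."""
    if a.upper() == b.upper():
        return 1.0
    return needleman_wunsch(a, b, scoring).identity


# ---------------------------------------------------------------------------
# Repertoire-level diversity


@dataclass
class SpeciesRepertoire:
    """Amino-acid V-segment set of one species for one gene family."""

    species: str
    family: str  # "IGHV" or "TRBV"
    segments: list[tuple[str, str]]  # (name, aa sequence)

    def __post_init__(self):
        if self.family not in ("IGHV", "TRBV"):
            raise ValueError("family must be IGHV or TRBV")
        for name, seq in self.segments:
            if not seq:
                raise ValueError(f"empty sequence for segment {name}")


def within_species_diversity(rep: SpeciesRepertoire,
                             scoring: Scoring | None = None) -> float:
    """Mean pairwise diversity (1 - local alignment identity) over all segment pairs.

    Diversity is 0 for a repertoire of identical segments and approaches 1 when
    no two segments share locally alignable sequence.
    """
    if len(rep.segments) < 2:
        raise ValueError("diversity needs at least two segments")
    scoring = scoring or blosum62_scoring()
    divs = [1.0 - smith_waterman(s1, s2, scoring).identity
            for (_, s1), (_, s2) in combinations(rep.segments, 2)]
    return float(np.mean(divs))


def homology_level(human: SpeciesRepertoire, other: SpeciesRepertoire,
                   scoring: Scoring | None = None) -> float:
    """Fraction of human segments closer (by local identity) to the other species.

    For each human segment, its best identity against the other species'
    segments is compared with its best identity against the remaining human
    segments; it counts only when strictly greater (ties do not count).
    """
    if len(human.segments) < 2:
        raise ValueError("need at least two human segments")
    scoring = scoring or blosum62_scoring()
    n_closer = 0
    for idx, (_, hseq) in enumerate(human.segments):
        best_self = max(smith_waterman(hseq, s, scoring).identity
                        for k, (_, s) in enumerate(human.segments) if k != idx)
        best_other = 0.0
        for _, oseq in other.segments:
            best_other = max(best_other, smith_waterman(hseq, oseq, scoring).identity)
        if best_other > best_self:
            n_closer += 1
    return n_closer / len(human.segments)


def pairwise_identity_matrix(seqs: Sequence[str], scoring: Scoring | None = None,
                             local: bool = False) -> np.ndarray:
    """Symmetric identity matrix over a sequence list (diagonal 1)."""
    n = len(seqs)
    out = np.eye(n)
    fn = smith_waterman if local else needleman_wunsch
    for i, j in combinations(range(n), 2):
        ident = fn(seqs[i], seqs[j], scoring).identity
        out[i, j] = out[j, i] = ident
    return out
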