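"""Global pairwise alignment: property-distance and matrix-similarity modes.

The central operation is :func:`align_property`: a global (end-to-end,
terminal gaps penalized) alignment of two protein sequences that *minimizes*
a total distance

    Score(X, Y) = sum over aligned pairs d(x_i, y_j) + sum over gaps g(r_L)

where ``d`` is the weighted L1 distance between the residues' biochemical
property vectors and ``g(r) = alpha + (r - 1) * beta`` is an affine gap
penalty.  A conventional *maximizing* substitution-matrix aligner
(:func:`align_matrix`) with the same gap model and traceback conventions is
provided as a baseline and for percent-identity estimation.

Both aligners use the three-state (match / gap-in-y / gap-in-x) affine-gap
dynamic-programming recurrence, which is exact for affine penalties and
runs in O(n*m).  Adjacent gaps in opposite sequences are charged as two
separate gap openings.  Traceback ties are broken deterministically:
diagonal first, then the gap consuming x (vertical), then the gap
consuming y (horizontal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .properties import ALPHABET_INDEX, WeightedPropertySet

GAP = "-"

_UNKNOWN_POLICIES = ("error", "mean")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an identifier; residues are upper-cased."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if GAP in self.residues or "." in self.residues:
            raise ValueError(f"sequence {self.id!r} contains gap characters")

    def __len__(self) -> int:
        return len(self.residues)


def _as_residues(seq: "SequenceRecord | str") -> str:
    if isinstance(seq, SequenceRecord):
        return seq.residues
    return str(seq).upper()


@dataclass(frozen=True)
class GapParams:
    """Affine gap penalty parameters, in distance units (both >= 0).

    The penalty of a length-r gap is ``alpha + (r - 1) * beta``.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(f"gap penalties must be nonnegative, got {self}")

    def penalty(self, length: int) -> float:
        return gap_penalty(length, self)


def gap_penalty(length: int, gaps: GapParams) -> float:
    """Affine penalty ``alpha + (length - 1) * beta`` of one maximal gap."""
    if length < 1:
        raise ValueError(f"gap length must be >= 1, got {length}")
    return gaps.alpha + (length - 1) * gaps.beta


# ---------------------------------------------------------------------------
# residue encoding and the weighted property distance
# ---------------------------------------------------------------------------


def _encode(residues: str, on_unknown: str, context: str) -> np.ndarray:
    """Map residues to alphabet indices; unknowns to 20 (the mean pseudo-residue)."""
    if on_unknown not in _UNKNOWN_POLICIES:
        raise ValueError(f"on_unknown must be one of {_UNKNOWN_POLICIES}")
    idx = np.empty(len(residues), dtype=np.int64)
    for pos, aa in enumerate(residues):
        code = ALPHABET_INDEX.get(aa)
        if code is None:
            if on_unknown == "error":
                raise ValueError(
                    f"non-standard residue {aa!r} at position {pos + 1} of "
                    f"{context}; pass on_unknown='mean' to impute property means"
                )
            code = 20
        idx[pos] = code
    return idx


def _distance_table(props: WeightedPropertySet, normalize: bool) -> np.ndarray:
    """21x21 weighted-L1 distance table; row/col 20 is the property-mean imputation."""
    p = props.normalize() if normalize else props
    vals = p.value_matrix()  # (k, 20)
    vals = np.concatenate([vals, vals.mean(axis=1, keepdims=True)], axis=1)  # (k, 21)
    diffs = np.abs(vals[:, :, None] - vals[:, None, :])
    return np.tensordot(np.asarray(p.weights), diffs, axes=1)


def pair_distance(
    x: str,
    y: str,
    props: WeightedPropertySet,
    *,
    normalize: bool = True,
    on_unknown: str = "error",
) -> float:
    """Weighted L1 distance ``sum_b w_b |p_b(x) - p_b(y)|`` between residues.

    Symmetric and zero iff all property values agree.  With
    ``normalize=True`` (default) each scale is min-max normalized to [0, 1]
    first.
    """
    xi = _encode(x.upper(), on_unknown, f"residue {x!r}")
    yi = _encode(y.upper(), on_unknown, f"residue {y!r}")
    if len(xi) != 1 or len(yi) != 1:
        raise ValueError("pair_distance takes single residues")
    return float(_distance_table(props, normalize)[xi[0], yi[0]])


# ---------------------------------------------------------------------------
# the three-state affine-gap DP kernel (minimization)
# ---------------------------------------------------------------------------
# States: M (x_i aligned to y_j), IX (x_i against a gap; vertical),
# IY (y_j against a gap; horizontal).  The matrix aligner reuses the same
# kernel on negated similarities, so both modes share one traceback
# convention.  Candidate predecessors are scanned in the order M, IX, IY
# and replaced only on strict improvement, which yields the documented
# diagonal > vertical > horizontal tie-break.


def _gotoh_min_py(xi, yi, dist, alpha, beta):
    n = xi.shape[0]
    m = yi.shape[0]
    INF = np.inf
    M = np.full((n + 1, m + 1), INF)
    IX = np.full((n + 1, m + 1), INF)
    IY = np.full((n + 1, m + 1), INF)
    PM = np.zeros((n + 1, m + 1), dtype=np.int8)
    PX = np.zeros((n + 1, m + 1), dtype=np.int8)
    PY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        IX[i, 0] = alpha + (i - 1) * beta
        PX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        IY[0, j] = alpha + (j - 1) * beta
        PY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        xc = xi[i - 1]
        for j in range(1, m + 1):
            # M: diagonal step ending in an aligned pair
            best = M[i - 1, j - 1]
            ptr = 0
            if IX[i - 1, j - 1] < best:
                best = IX[i - 1, j - 1]
                ptr = 1
            if IY[i - 1, j - 1] < best:
                best = IY[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + dist[xc, yi[j - 1]]
            PM[i, j] = ptr
            # IX: x_i against a gap; opening from M or IY, extending from IX
            best = M[i - 1, j] + alpha
            ptr = 0
            c = IX[i - 1, j] + beta
            if c < best:
                best = c
                ptr = 1
            c = IY[i - 1, j] + alpha
            if c < best:
                best = c
                ptr = 2
            IX[i, j] = best
            PX[i, j] = ptr
            # IY: y_j against a gap
            best = M[i, j - 1] + alpha
            ptr = 0
            c = IX[i, j - 1] + alpha
            if c < best:
                best = c
                ptr = 1
            c = IY[i, j - 1] + beta
            if c < best:
                best = c
                ptr = 2
            IY[i, j] = best
            PY[i, j] = ptr
    # final state: prefer M, then IX, then IY on exact ties
    state = 0
    score = M[n, m]
    if IX[n, m] < score:
        score = IX[n, m]
        state = 1
    if IY[n, m] < score:
        score = IY[n, m]
        state = 2
    if n == 0 and m == 0:
        score = 0.0
    # traceback; ops recorded end-to-start (0 diag, 1 up/IX, 2 left/IY)
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        ops[k] = state
        k += 1
        if state == 0:
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = PX[i, j]
            i -= 1
        else:
            state = PY[i, j]
            j -= 1
    return score, ops, k


try:  # JIT the kernel when numba is present; results are identical without it
    from numba import njit

    _gotoh_min = njit(cache=True)(_gotoh_min_py)
except ImportError:  # pragma: no cover
    _gotoh_min = _gotoh_min_py


# ---------------------------------------------------------------------------
# alignment results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column; positions are 1-based into the ungapped sequences."""

    x_pos: int | None
    y_pos: int | None
    x_char: str
    y_char: str
    distance: float | None  # column d(x_i, y_j); None in gap columns


@dataclass(frozen=True)
class AlignmentResult:
    """A global pairwise alignment with its objective value.

    ``mode`` records the objective: ``"distance"`` (property aligner;
    smaller is better) or ``"similarity"`` (matrix aligner; larger is
    better).  Stripping gaps from ``aligned_x``/``aligned_y`` recovers the
    input sequences.
    """

    aligned_x: str
    aligned_y: str
    score: float
    mode: str
    x_id: str = "x"
    y_id: str = "y"
    columns: tuple[AlignmentColumn, ...] = ()

    def __post_init__(self) -> None:
        if len(self.aligned_x) != len(self.aligned_y):
            raise ValueError("aligned strings must have equal length")
        for cx, cy in zip(self.aligned_x, self.aligned_y):
            if cx == GAP and cy == GAP:
                raise ValueError("gap-gap columns are not allowed")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_x)

    @property
    def n_aligned_pairs(self) -> int:
        return sum(
            1 for cx, cy in zip(self.aligned_x, self.aligned_y) if cx != GAP and cy != GAP
        )

    @property
    def n_identical(self) -> int:
        return sum(
            1
            for cx, cy in zip(self.aligned_x, self.aligned_y)
            if cx != GAP and cx == cy
        )

    def percent_identity(self, denominator: str = "pairs") -> float:
        """Percent identical residues; denominator 'pairs' (default) or 'columns'."""
        if denominator == "pairs":
            denom = self.n_aligned_pairs
        elif denominator == "columns":
            denom = self.n_columns
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        return 100.0 * self.n_identical / denom if denom else 0.0

    @property
    def x_residues(self) -> str:
        return self.aligned_x.replace(GAP, "")

    @property
    def y_residues(self) -> str:
        return self.aligned_y.replace(GAP, "")


def _ops_to_alignment(xres: str, yres: str, ops_rev: np.ndarray, k: int) -> tuple[str, str]:
    ax = []
    ay = []
    i = j = 0
    for t in range(k - 1, -1, -1):
        op = ops_rev[t]
        if op == 0:
            ax.append(xres[i])
            ay.append(yres[j])
            i += 1
            j += 1
        elif op == 1:
            ax.append(xres[i])
            ay.append(GAP)
            i += 1
        else:
            ax.append(GAP)
            ay.append(yres[j])
            j += 1
    return "".join(ax), "".join(ay)


def _columns(ax: str, ay: str, dist_fn) -> tuple[AlignmentColumn, ...]:
    cols = []
    i = j = 0
    for cx, cy in zip(ax, ay):
        xp = yp = None
        d = None
        if cx != GAP:
            i += 1
            xp = i
        if cy != GAP:
            j += 1
            yp = j
        if cx != GAP and cy != GAP:
            d = dist_fn(cx, cy)
        cols.append(AlignmentColumn(xp, yp, cx, cy, d))
    return tuple(cols)


# ---------------------------------------------------------------------------
# the property-profile aligner
# ---------------------------------------------------------------------------


def align_property(
    x: "SequenceRecord | str",
    y: "SequenceRecord | str",
    props: WeightedPropertySet,
    gaps: GapParams,
    *,
    normalize: bool = True,
    on_unknown: str = "error",
    with_columns: bool = True,
) -> AlignmentResult:
    """Minimal-distance global alignment under the weighted property model.

    Finds the global alignment minimizing the summed per-column property
    distance plus affine gap penalties, with boundary conditions that
    penalize terminal gaps (an empty x against y costs ``g(len(y))``).

    Parameters
    ----------
    x, y:
        Sequences (records or plain strings over the 20-letter alphabet).
    props:
        The weighted property set; ``normalize=True`` (default) min-max
        normalizes every scale to [0, 1] before aligning.
    gaps:
        Affine gap penalties (distance units, >= 0).
    on_unknown:
        ``"error"`` rejects non-standard residues; ``"mean"`` imputes the
        per-property mean value.
    """
    xres = _as_residues(x)
    yres = _as_residues(y)
    xid = x.id if isinstance(x, SequenceRecord) else "x"
    yid = y.id if isinstance(y, SequenceRecord) else "y"
    xi = _encode(xres, on_unknown, f"sequence {xid!r}")
    yi = _encode(yres, on_unknown, f"sequence {yid!r}")
    dist = _distance_table(props, normalize)
    score, ops_rev, k = _gotoh_min(xi, yi, dist, float(gaps.alpha), float(gaps.beta))
    ax, ay = _ops_to_alignment(xres, yres, ops_rev, k)
    cols: tuple[AlignmentColumn, ...] = ()
    if with_columns:
        cols = _columns(ax, ay, lambda a, b: float(dist[xi_of(a), xi_of(b)]))
    return AlignmentResult(ax, ay, float(score), "distance", xid, yid, cols)


def xi_of(aa: str) -> int:
    """Alphabet index of a residue; 20 for non-standard letters."""
    return ALPHABET_INDEX.get(aa, 20)


def _gap_runs(gapped: str) -> Iterable[int]:
    """Lengths of maximal runs of '-' in one gapped sequence."""
    run = 0
    for c in gapped:
        if c == GAP:
            run += 1
        elif run:
            yield run
            run = 0
    if run:
        yield run


def score_alignment(
    aligned_x: str,
    aligned_y: str,
    props: WeightedPropertySet,
    gaps: GapParams,
    *,
    normalize: bool = True,
    on_unknown: str = "error",
) -> float:
    """Total distance of a given alignment under the property model.

    Sum of pair distances over residue-residue columns plus the affine
    penalty of every maximal gap run in either sequence; terminal gaps are
    charged like internal ones.
    """
    if len(aligned_x) != len(aligned_y):
        raise ValueError("aligned strings must have equal length")
    if any(cx == GAP and cy == GAP for cx, cy in zip(aligned_x, aligned_y)):
        raise ValueError("gap-gap columns are not allowed")
    dist = _distance_table(props, normalize)
    xi = _encode(aligned_x.replace(GAP, ""), on_unknown, "aligned_x")
    yi = _encode(aligned_y.replace(GAP, ""), on_unknown, "aligned_y")
    total = 0.0
    i = j = 0
    parts = []
    for cx, cy in zip(aligned_x, aligned_y):
        if cx != GAP and cy != GAP:
            parts.append(float(dist[xi[i], yi[j]]))
        if cx != GAP:
            i += 1
        if cy != GAP:
            j += 1
    for run in _gap_runs(aligned_x):
        parts.append(gap_penalty(run, gaps))
    for run in _gap_runs(aligned_y):
        parts.append(gap_penalty(run, gaps))
    return math.fsum(parts)


# ---------------------------------------------------------------------------
# matrix-based baseline aligner
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-similarity matrix (conventional scoring)."""

    name: str
    alphabet: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape must match its alphabet")
        if not np.allclose(s, s.T):
            raise ValueError(f"substitution matrix {self.name!r} is not symmetric")
        object.__setattr__(self, "scores", s)

    def index(self, aa: str, context: str = "sequence") -> int:
        pos = self.alphabet.find(aa)
        if pos < 0:
            raise KeyError(
                f"residue {aa!r} in {context} is absent from matrix {self.name!r}"
            )
        return pos

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.index(a), self.index(b)])


def read_matrix(path, name: str | None = None) -> SubstitutionMatrix:
    """Read a whitespace-delimited NCBI/BLAST-style matrix file."""
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.read(str(path))
    alphabet = "".join(arr.alphabet)
    return SubstitutionMatrix(name or str(path), alphabet, np.asarray(arr, dtype=float))


def load_builtin_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """A substitution matrix bundled with Biopython (default BLOSUM62)."""
    from Bio.Align import substitution_matrices

    arr = substitution_matrices.load(name)
    return SubstitutionMatrix(name, "".join(arr.alphabet), np.asarray(arr, dtype=float))


def align_matrix(
    x: "SequenceRecord | str",
    y: "SequenceRecord | str",
    matrix: SubstitutionMatrix,
    open_penalty: float,
    extend_penalty: float,
    *,
    with_columns: bool = False,
) -> AlignmentResult:
    """Maximal-similarity global alignment with a substitution matrix.

    Gap penalties follow the conventional signed form: a length-r gap *adds*
    ``open + (r - 1) * extend`` to the score, so e.g. ``open=-16, extend=-1``.
    Shares the DP kernel and tie-break conventions with
    :func:`align_property` (maximization is run as minimization of the
    negated similarities).
    """
    xres = _as_residues(x)
    yres = _as_residues(y)
    xid = x.id if isinstance(x, SequenceRecord) else "x"
    yid = y.id if isinstance(y, SequenceRecord) else "y"
    xi = np.array([matrix.index(aa, f"sequence {xid!r}") for aa in xres], dtype=np.int64)
    yi = np.array([matrix.index(aa, f"sequence {yid!r}") for aa in yres], dtype=np.int64)
    neg, ops_rev, k = _gotoh_min(
        xi, yi, -matrix.scores, float(-open_penalty), float(-extend_penalty)
    )
    ax, ay = _ops_to_alignment(xres, yres, ops_rev, k)
    score = -float(neg) if len(xres) + len(yres) else 0.0
    cols: tuple[AlignmentColumn, ...] = ()
    if with_columns:
        cols = _columns(ax, ay, matrix.score)
    return AlignmentResult(ax, ay, score, "similarity", xid, yid, cols)


def score_alignment_matrix(
    aligned_x: str,
    aligned_y: str,
    matrix: SubstitutionMatrix,
    open_penalty: float,
    extend_penalty: float,
) -> float:
    """Total similarity of a given alignment under the matrix model."""
    if len(aligned_x) != len(aligned_y):
        raise ValueError("aligned strings must have equal length")
    parts = []
    for cx, cy in zip(aligned_x, aligned_y):
        if cx == GAP and cy == GAP:
            raise ValueError("gap-gap columns are not allowed")
        if cx != GAP and cy != GAP:
            parts.append(matrix.score(cx, cy))
    for run in _gap_runs(aligned_x):
        parts.append(open_penalty + (run - 1) * extend_penalty)
    for run in _gap_runs(aligned_y):
        parts.append(open_penalty + (run - 1) * extend_penalty)
    return math.fsum(parts)


#: Gap penalties used for percent-identity estimation (signed, similarity units).
IDENTITY_GAP_OPEN = -15.0
IDENTITY_GAP_EXTEND = -1.0


def estimate_identity(
    x: "SequenceRecord | str",
    y: "SequenceRecord | str",
    matrix: SubstitutionMatrix | None = None,
    open_penalty: float = IDENTITY_GAP_OPEN,
    extend_penalty: float = IDENTITY_GAP_EXTEND,
) -> float:
    """Rough percent identity from a conventional matrix alignment.

    Aligns with :func:`align_matrix` (VTML200 with open -15 / extend -1 is
    the documented choice; BLOSUM62 from Biopython is used when no matrix is
    supplied) and returns ``100 * identical / aligned pairs``.  Used to pick
    an identity-range preset; the estimate may differ from the identity of
    the final property alignment.
    """
    if len(_as_residues(x)) == 0 or len(_as_residues(y)) == 0:
        raise ValueError("identity estimation requires non-empty sequences")
    if matrix is None:
        matrix = load_builtin_matrix()
    result = align_matrix(x, y, matrix, open_penalty, extend_penalty)
    return result.percent_identity("pairs")
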