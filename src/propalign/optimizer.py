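"""Grid search over property weights and gap penalties maximizing Q_AVER.

Replicates the preset-optimization protocol at desk scale: every weight
vector on a simplex grid (nonnegative multiples of the step summing to 1)
is combined with every (alpha, beta) on a gap grid; each combination aligns
every benchmark pair and is scored by the mean accuracy Q_AVER against the
reference alignments.  The search is exhaustive and deterministic; ties are
broken by the first-encountered grid point (weights in lexicographic order,
then alpha, then beta ascending).  A matching integer-grid search is
provided for the substitution-matrix baseline's gap penalties.

Over-represented families can be capped beforehand with
:func:`subsample_families` (uniform without replacement, seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import _distance_table, _encode, _gotoh_min
from .evaluation import ReferencePair, aligned_pair_set
from .properties import WeightedPropertySet


def _default_gap_values() -> tuple[float, ...]:
    return tuple(round(0.1 * i, 10) for i in range(1, 11))


@dataclass(frozen=True)
class GridSpec:
    """Grid-search configuration.

    Defaults are the protocol's published choices where stated: 0.05 weight
    increments (a 20-point simplex grid), 0.1 gap increments over a
    10-point grid, at most 10 pairs kept per family.  The gap-grid range
    (0.1..1.0) is a package choice consistent with all shipped preset
    penalties lying in (0, 1].
    """

    weight_step: float = 0.05
    gap_step: float = 0.1
    gap_min: float = 0.1
    gap_max: float = 1.0
    max_pairs_per_family: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_step <= 0 or self.gap_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.max_pairs_per_family < 1:
            raise ValueError("max_pairs_per_family must be >= 1")
        if self.gap_max < self.gap_min:
            raise ValueError("gap_max must be >= gap_min")

    def gap_values(self) -> tuple[float, ...]:
        n = int(round((self.gap_max - self.gap_min) / self.gap_step)) + 1
        return tuple(round(self.gap_min + i * self.gap_step, 10) for i in range(n))


@dataclass(frozen=True)
class GridSearchResult:
    """The argmax of Q_AVER over the grid, plus the optional landscape."""

    best_weights: tuple[float, ...]
    best_alpha: float
    best_beta: float
    best_q_aver: float
    evaluated: int
    trace: tuple[tuple, ...] | None = None  # (weights, alpha, beta, q_aver)


def weight_grid(k: int, step: float) -> list[tuple[float, ...]]:
    """All k-vectors of nonnegative multiples of ``step`` summing to 1.

    Enumerated in lexicographic order; the count is the number of
    compositions of ``1/step`` into k nonnegative parts,
    C(1/step + k - 1, k - 1).  ``1/step`` must be an integer.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = 1.0 / step
    T = int(round(total))
    if abs(total - T) > 1e-9:
        raise ValueError(f"1/step must be an integer; step={step} gives {total}")

    out: list[tuple[float, ...]] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(tuple((c / T) for c in prefix + [remaining]))
            return
        for c in range(remaining + 1):
            rec(prefix + [c], remaining - c, slots - 1)

    rec([], T, k)
    return out


def subsample_families(
    pairs: Sequence[ReferencePair], max_per_family: int, seed: int
) -> list[ReferencePair]:
    """Cap each family at ``max_per_family`` pairs, uniformly at random.

    Selection is without replacement and reproducible for a fixed seed;
    kept pairs retain their original order.  Families are processed in
    order of first appearance, so the result does not depend on dictionary
    hashing.
    """
    if max_per_family < 1:
        raise ValueError("max_per_family must be >= 1")
    by_family: dict[str, list[int]] = {}
    for idx, pair in enumerate(pairs):
        if not pair.family_id:
            raise ValueError(f"pair {pair.pair_id!r} has no family_id")
        by_family.setdefault(pair.family_id, []).append(idx)
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for family in by_family.values():  # insertion-ordered
        if len(family) <= max_per_family:
            keep.update(family)
        else:
            chosen = rng.choice(len(family), size=max_per_family, replace=False)
            keep.update(family[i] for i in chosen)
    return [pair for idx, pair in enumerate(pairs) if idx in keep]


def _pairs_from_ops(ops_rev: np.ndarray, k: int) -> frozenset[tuple[int, int]]:
    """Aligned residue-index pairs straight from the DP traceback ops."""
    pairs = set()
    i = j = 0
    for t in range(k - 1, -1, -1):
        op = ops_rev[t]
        if op == 0:
            i += 1
            j += 1
            pairs.add((i, j))
        elif op == 1:
            i += 1
        else:
            j += 1
    return frozenset(pairs)


def _prepare_pairs(pairs: Sequence[ReferencePair], encode) -> list[tuple]:
    prepped = []
    for pair in pairs:
        ref_pairs = frozenset(aligned_pair_set(pair.reference))
        if not ref_pairs:
            raise ValueError(
                f"pair {pair.pair_id!r}: reference has no aligned residue pairs"
            )
        prepped.append((encode(pair.x.residues), encode(pair.y.residues), ref_pairs))
    return prepped


def _q_aver_point(prepped, dist, alpha: float, beta: float) -> float:
    scores = []
    for xi, yi, ref_pairs in prepped:
        _, ops_rev, k = _gotoh_min(xi, yi, dist, alpha, beta)
        test_pairs = _pairs_from_ops(ops_rev, k)
        n_i = len(test_pairs & ref_pairs)
        f_d = 100.0 * n_i / len(ref_pairs)
        f_m = 100.0 * n_i / len(test_pairs) if test_pairs else 0.0
        scores.append((f_d + f_m) / 2.0)
    return math.fsum(scores) / len(scores)


def grid_search_property(
    pairs: Sequence[ReferencePair],
    props_template: WeightedPropertySet,
    grid: GridSpec,
    *,
    normalize: bool = True,
    keep_trace: bool = False,
) -> GridSearchResult:
    """Exhaustive search for the weight/gap combination maximizing Q_AVER.

    The template's scales are kept; its weights are replaced by every
    vector of :func:`weight_grid`.  Alpha and beta each range over
    ``grid.gap_values()``.
    """
    if not pairs:
        raise ValueError("grid search needs at least one benchmark pair")
    prepped = _prepare_pairs(
        pairs, lambda res: _encode(res, "error", "benchmark sequence")
    )
    template = props_template.normalize() if normalize else props_template
    weights_list = weight_grid(template.k, grid.weight_step)
    gap_values = grid.gap_values()
    best = None
    trace = [] if keep_trace else None
    evaluated = 0
    for weights in weights_list:
        # built exactly as align_property builds it, so per-point results are
        # bit-identical to aligning through the public API
        dist = _distance_table(template.with_weights(weights), normalize=False)
        for alpha in gap_values:
            for beta in gap_values:
                q = _q_aver_point(prepped, dist, float(alpha), float(beta))
                evaluated += 1
                if trace is not None:
                    trace.append((weights, alpha, beta, q))
                if best is None or q > best[0]:
                    best = (q, weights, alpha, beta)
    q, weights, alpha, beta = best
    return GridSearchResult(
        weights, alpha, beta, q, evaluated, tuple(trace) if trace is not None else None
    )


def grid_search_matrix(
    pairs: Sequence[ReferencePair],
    matrix,
    open_values: Iterable[float],
    extend_values: Iterable[float],
    *,
    keep_trace: bool = False,
) -> GridSearchResult:
    """Gap-penalty grid search for the matrix baseline (signed penalties).

    ``open_values``/``extend_values`` are the conventional negative gap
    penalties (e.g. ``range(-50, 0)`` for the published 50-point integer
    grid).  Returns weights ``()`` since the matrix has no weight simplex.
    """
    if not pairs:
        raise ValueError("grid search needs at least one benchmark pair")
    prepped = _prepare_pairs(
        pairs,
        lambda res: np.array(
            [matrix.index(aa, "benchmark sequence") for aa in res], dtype=np.int64
        ),
    )
    neg = -matrix.scores
    best = None
    trace = [] if keep_trace else None
    evaluated = 0
    for open_penalty in open_values:
        for extend_penalty in extend_values:
            q = _q_aver_point(prepped, neg, float(-open_penalty), float(-extend_penalty))
            evaluated += 1
            if trace is not None:
                trace.append(((), open_penalty, extend_penalty, q))
            if best is None or q > best[0]:
                best = (q, open_penalty, extend_penalty)
    q, open_penalty, extend_penalty = best
    return GridSearchResult(
        (), open_penalty, extend_penalty, q, evaluated,
        tuple(trace) if trace is not None else None,
    )


def complexity_estimate(n_pairs: int, grid_points: int, k: int) -> int:
    """Number of pairwise alignments of a full grid search: n * N**(k+2).

    ``k`` weights plus the two gap penalties each range over an N-point
    grid, and every grid point aligns all n benchmark pairs.
    """
    if n_pairs < 1 or grid_points < 1 or k < 1:
        raise ValueError("all arguments must be positive integers")
    return n_pairs * grid_points ** (k + 2)
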