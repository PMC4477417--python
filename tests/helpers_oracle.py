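"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's dynamic-programming path: global
alignments of tiny sequences are enumerated exhaustively and scored by a
direct reading of the objective (per-column distances or similarities plus
affine penalties over maximal gap runs, with a run in one sequence that
directly follows a run in the other charged as two separate gaps).
"""

from __future__ import annotations

import math
from typing import Callable, Iterator

DIAG, UP, LEFT = 0, 1, 2  # aligned pair / x vs gap / gap vs y


def enumerate_ops(n: int, m: int) -> Iterator[tuple[int, ...]]:
    """All monotone global alignments of sequences of lengths n and m."""
    if n == 0 and m == 0:
        yield ()
        return
    if n > 0 and m > 0:
        for rest in enumerate_ops(n - 1, m - 1):
            yield (DIAG,) + rest
    if n > 0:
        for rest in enumerate_ops(n - 1, m):
            yield (UP,) + rest
    if m > 0:
        for rest in enumerate_ops(n, m - 1):
            yield (LEFT,) + rest


def score_ops(
    ops: tuple[int, ...],
    x: str,
    y: str,
    pair_score: Callable[[str, str], float],
    alpha: float,
    beta: float,
) -> float:
    """Objective of one alignment: pair scores plus alpha + (r-1)*beta per gap run."""
    parts = []
    i = j = 0
    prev = None
    for op in ops:
        if op == DIAG:
            parts.append(pair_score(x[i], y[j]))
            i += 1
            j += 1
        else:
            parts.append(beta if op == prev else alpha)
            if op == UP:
                i += 1
            else:
                j += 1
        prev = op
    return math.fsum(parts)


def best_alignment_score(
    x: str,
    y: str,
    pair_score: Callable[[str, str], float],
    alpha: float,
    beta: float,
    maximize: bool = False,
) -> float:
    """Optimal global score by exhaustive enumeration (tiny sequences only)."""
    pick = max if maximize else min
    return pick(
        score_ops(ops, x, y, pair_score, alpha, beta)
        for ops in enumerate_ops(len(x), len(y))
    )


def ops_to_gapped(ops: tuple[int, ...], x: str, y: str) -> tuple[str, str]:
    ax = []
    ay = []
    i = j = 0
    for op in ops:
        if op == DIAG:
            ax.append(x[i])
            ay.append(y[j])
            i += 1
            j += 1
        elif op == UP:
            ax.append(x[i])
            ay.append("-")
            i += 1
        else:
            ax.append("-")
            ay.append(y[j])
            j += 1
    return "".join(ax), "".join(ay)
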