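"""Alignment-accuracy scoring against reference alignments.

A test alignment is scored against a gold (reference) alignment of the same
sequence pair with the developer/modeler-style accuracy

    Q = (f_D + f_M) / 2,
    f_D = n_I / l_R * 100%,   f_M = n_I / l_T * 100%,

where ``n_I`` is the number of residue pairs aligned identically in both
alignments, and ``l_R`` / ``l_T`` count the reference's / test's aligned
residue pairs ("pairs" mode, the default; f_D is then the developer score —
recall of reference pairs — and f_M the modeler score — precision).  A
"columns" mode counting total alignment columns instead is available for
comparison; under it a gapped reference cannot score 100 against itself,
which is why "pairs" is the default.

:func:`compare_methods` runs the head-to-head protocol: align every
benchmark pair with the property aligner (accuracy Q1) and the matrix
baseline (Q2) and categorize each pair by the sign of D = Q1 - Q2.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .align import (
    GAP,
    AlignmentResult,
    GapParams,
    SequenceRecord,
    SubstitutionMatrix,
    align_matrix,
    align_property,
)
from .properties import WeightedPropertySet

Gapped = "AlignmentResult | tuple[str, str]"


@dataclass(frozen=True)
class ReferencePair:
    """Two raw sequences plus their gold alignment, for accuracy scoring."""

    pair_id: str
    x: SequenceRecord
    y: SequenceRecord
    reference: AlignmentResult
    family_id: str = ""
    identity_bin: str = ""

    def __post_init__(self) -> None:
        if (
            self.reference.x_residues != self.x.residues
            or self.reference.y_residues != self.y.residues
        ):
            raise ValueError(
                f"pair {self.pair_id!r}: reference alignment does not strip "
                "back to the stored sequences"
            )


def _gapped(aln) -> tuple[str, str]:
    if isinstance(aln, AlignmentResult):
        return aln.aligned_x, aln.aligned_y
    ax, ay = aln
    return ax, ay


def aligned_pair_set(aln) -> set[tuple[int, int]]:
    """The set of residue-index pairs (1-based) aligned in residue-residue columns."""
    ax, ay = _gapped(aln)
    pairs = set()
    i = j = 0
    for cx, cy in zip(ax, ay):
        if cx != GAP:
            i += 1
        if cy != GAP:
            j += 1
        if cx != GAP and cy != GAP:
            pairs.add((i, j))
    return pairs


def _check_same_sequences(test, reference) -> None:
    tx, ty = _gapped(test)
    rx, ry = _gapped(reference)
    if tx.replace(GAP, "") != rx.replace(GAP, "") or ty.replace(GAP, "") != ry.replace(GAP, ""):
        raise ValueError("test and reference alignments are over different sequences")


def identically_aligned_pairs(test, reference) -> int:
    """n_I: residue pairs aligned in both the test and the reference."""
    _check_same_sequences(test, reference)
    return len(aligned_pair_set(test) & aligned_pair_set(reference))


def _length(aln, mode: str) -> int:
    ax, ay = _gapped(aln)
    if mode == "pairs":
        return sum(1 for cx, cy in zip(ax, ay) if cx != GAP and cy != GAP)
    if mode == "columns":
        return len(ax)
    raise ValueError(f"unknown length mode {mode!r}")


def q_score(test, reference, *, length_mode: str = "pairs") -> float:
    """Accuracy Q = (f_D + f_M)/2 of a test alignment, in percent.

    Raises if the reference has no aligned residue pairs (f_D undefined).
    A test with no aligned pairs scores 0.
    """
    _check_same_sequences(test, reference)
    l_r = _length(reference, length_mode)
    if l_r == 0:
        raise ValueError("reference alignment has no aligned residue pairs; f_D is undefined")
    n_i = len(aligned_pair_set(test) & aligned_pair_set(reference))
    l_t = _length(test, length_mode)
    f_d = 100.0 * n_i / l_r
    f_m = 100.0 * n_i / l_t if l_t else 0.0
    return (f_d + f_m) / 2.0


def q_aver(scored_pairs: Iterable[tuple], *, length_mode: str = "pairs") -> float:
    """Mean Q over a collection of (test, reference) alignment pairs."""
    scores = [q_score(t, r, length_mode=length_mode) for t, r in scored_pairs]
    if not scores:
        raise ValueError("q_aver of an empty collection is undefined")
    return math.fsum(scores) / len(scores)


# ---------------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRecord:
    """Head-to-head accuracy of the two aligners on one benchmark pair."""

    pair_id: str
    q1: float  # property aligner
    q2: float  # matrix aligner
    identity_bin: str = ""

    @property
    def d(self) -> float:
        return self.q1 - self.q2

    @property
    def category(self) -> str:
        if self.d > 0:
            return "better"
        if self.d < 0:
            return "worse"
        return "equal"


def _summarize(records: Sequence[ComparisonRecord]) -> dict:
    n = len(records)
    counts = {"better": 0, "equal": 0, "worse": 0}
    for rec in records:
        counts[rec.category] += 1
    return {
        "n": n,
        "counts": counts,
        "percentages": {k: 100.0 * v / n for k, v in counts.items()},
        "mean_q1": math.fsum(r.q1 for r in records) / n,
        "mean_q2": math.fsum(r.q2 for r in records) / n,
    }


def compare_methods(
    pairs: Sequence[ReferencePair],
    props: WeightedPropertySet,
    gaps: GapParams,
    matrix: SubstitutionMatrix,
    open_penalty: float,
    extend_penalty: float,
    *,
    normalize: bool = True,
    length_mode: str = "pairs",
) -> tuple[list[ComparisonRecord], dict]:
    """Align every pair with both methods and categorize by D = Q1 - Q2.

    Returns the per-pair records and a summary with counts and percentages
    of {better, equal, worse} (property aligner vs. matrix baseline),
    overall and per identity bin where bins are set.
    """
    records = []
    for pair in pairs:
        try:
            a1 = align_property(
                pair.x, pair.y, props, gaps, normalize=normalize, with_columns=False
            )
            a2 = align_matrix(pair.x, pair.y, matrix, open_penalty, extend_penalty)
            q1 = q_score(a1, pair.reference, length_mode=length_mode)
            q2 = q_score(a2, pair.reference, length_mode=length_mode)
        except Exception as exc:
            raise type(exc)(f"pair {pair.pair_id!r}: {exc}") from exc
        records.append(ComparisonRecord(pair.pair_id, q1, q2, pair.identity_bin))
    if not records:
        raise ValueError("compare_methods needs at least one pair")
    summary = _summarize(records)
    bins = sorted({r.identity_bin for r in records if r.identity_bin})
    if bins:
        summary["by_identity_bin"] = {
            b: _summarize([r for r in records if r.identity_bin == b]) for b in bins
        }
    return records, summary


# ---------------------------------------------------------------------------
# benchmark manifest I/O
# ---------------------------------------------------------------------------
#
# A benchmark lives in a directory: one aligned-FASTA reference per pair
# under refs/, described by a tab-delimited manifest.tsv with columns
# pair_id, x_id, y_id, reference (relative path), family_id, identity_bin.

MANIFEST_COLUMNS = ["pair_id", "x_id", "y_id", "reference", "family_id", "identity_bin"]


def write_benchmark(pairs: Sequence[ReferencePair], out_dir) -> Path:
    """Write references as aligned FASTA plus a manifest; returns the manifest path."""
    from .fasta import write_aligned_pair

    out = Path(out_dir)
    refs = out / "refs"
    refs.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.tsv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for pair in pairs:
            ref_path = refs / f"{pair.pair_id}.afa"
            write_aligned_pair(pair.reference, ref_path)
            writer.writerow(
                [
                    pair.pair_id,
                    pair.x.id,
                    pair.y.id,
                    ref_path.relative_to(out).as_posix(),
                    pair.family_id,
                    pair.identity_bin,
                ]
            )
    return manifest


def read_benchmark(manifest_path) -> list[ReferencePair]:
    """Read a benchmark manifest back into :class:`ReferencePair` objects."""
    from .fasta import read_aligned_pair

    manifest = Path(manifest_path)
    base = manifest.parent
    pairs = []
    with manifest.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"manifest {manifest} lacks columns {sorted(missing)}")
        for row in reader:
            ref = read_aligned_pair(base / row["reference"])
            ref = AlignmentResult(
                ref.aligned_x, ref.aligned_y, ref.score, ref.mode, row["x_id"], row["y_id"]
            )
            pairs.append(
                ReferencePair(
                    pair_id=row["pair_id"],
                    x=SequenceRecord(row["x_id"], ref.x_residues),
                    y=SequenceRecord(row["y_id"], ref.y_residues),
                    reference=ref,
                    family_id=row["family_id"],
                    identity_bin=row["identity_bin"],
                )
            )
    if not pairs:
        raise ValueError(f"manifest {manifest} lists no pairs")
    return pairs
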