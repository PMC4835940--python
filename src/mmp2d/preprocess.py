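"""Segment-domain preprocessing for SEMG images.

Two techniques are provided:

* **PDS** (percentage-difference sorting): greedy reordering of matrix columns.
  The first output column is the minimum-variance segment; each following
  column is the unplaced segment most similar (smallest percentage difference)
  to the last placed one.  The permutation must travel with the coded file.

* **SbS** (segmentation by similarity): adaptive choice of the segment length
  itself.  Candidate lengths N = 16n, n ∈ {2, …, 64}, are scored by the mean
  percentage difference between adjacent segments and the smallest mean wins;
  no side information is needed beyond the chosen length.

The percentage difference between a reference segment x and a candidate m is

    PD(x, m) = Σ (x[n] − m[n])² / Σ x²[n]

a dimensionless energy ratio (no ×100 factor despite the name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .semg_matrix import SemgMatrix, SemgRecord

__all__ = [
    "SegmentOrdering",
    "PreprocessPlan",
    "percentage_difference",
    "pds_sort",
    "pds_restore",
    "sbs_select_length",
    "SBS_CANDIDATE_LENGTHS",
]

#: candidate segment lengths explored by SbS: N = 16n, n = 2..64
SBS_CANDIDATE_LENGTHS = tuple(16 * n for n in range(2, 65))


@dataclass
class SegmentOrdering:
    """Column permutation: output column j came from original column perm[j]."""

    permutation: np.ndarray

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=np.int64)
        p = self.permutation
        if p.ndim != 1 or not np.array_equal(np.sort(p), np.arange(p.size)):
            raise ValueError("not a permutation")

    def __len__(self) -> int:
        return int(self.permutation.size)


@dataclass
class PreprocessPlan:
    """What the encoder did before image coding (travels in the header)."""

    method: str = "none"  # one of {"none", "pds", "sbs"}
    segment_length: int = 0
    ordering: SegmentOrdering | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "pds", "sbs"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        # ordering is only meaningful for PDS; it is filled in when the sort
        # actually runs, so it may still be None on a fresh PDS plan
        if self.ordering is not None and self.method != "pds":
            raise ValueError("ordering only applies to the 'pds' method")


def percentage_difference(x: np.ndarray, m: np.ndarray) -> float:
    """Energy-normalized squared difference PD(x, m); x is the reference."""
    x = np.asarray(x, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    if x.shape != m.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("segments must be equal-length 1-D vectors")
    energy = float(np.dot(x, x))
    if energy == 0.0:
        raise ValueError("zero-energy reference segment")
    d = x - m
    return float(np.dot(d, d)) / energy


def _pd_matrix(cols: np.ndarray) -> np.ndarray:
    """All-pairs PD[i, j] = PD(cols[:, i], cols[:, j]) with zero-energy fallback.

    When a reference column has zero energy the unnormalized numerator is used
    for that row (deterministic fallback; never a crash).
    """
    c = cols.astype(np.float64)
    sq = np.einsum("ij,ij->j", c, c)
    g = c.T @ c
    num = sq[:, None] - 2.0 * g + sq[None, :]
    den = np.where(sq > 0, sq, 1.0)
    return num / den[:, None]


def pds_sort(matrix: SemgMatrix) -> tuple[SemgMatrix, SegmentOrdering]:
    """Greedy percentage-difference sort of matrix columns.

    Seed = the column with the smallest (population) variance, ties broken by
    lowest original index; then repeatedly append the unplaced column with the
    smallest PD relative to the last placed one (ties again by lowest index).
    """
    cols = matrix.values
    l = cols.shape[1]
    variances = cols.astype(np.float64).var(axis=0)
    order = [int(np.argmin(variances))]
    if l > 1:
        pd = _pd_matrix(cols)
        np.fill_diagonal(pd, np.inf)  # self never re-selected via placed mask anyway
        placed = np.zeros(l, dtype=bool)
        placed[order[0]] = True
        for _ in range(l - 1):
            row = pd[order[-1]].copy()
            row[placed] = np.inf
            order.append(int(np.argmin(row)))
            placed[order[-1]] = True
    perm = np.asarray(order, dtype=np.int64)
    sorted_matrix = SemgMatrix(
        values=cols[:, perm].copy(),
        original_sample_count=matrix.original_sample_count,
        pad_value=matrix.pad_value,
        meta=dict(matrix.meta),
    )
    return sorted_matrix, SegmentOrdering(perm)


def pds_restore(matrix: SemgMatrix, ordering: SegmentOrdering) -> SemgMatrix:
    """Undo :func:`pds_sort`: put column j back at original position perm[j]."""
    perm = ordering.permutation
    if perm.size != matrix.n_segments:
        raise ValueError("ordering length does not match column count")
    restored = np.empty_like(matrix.values)
    restored[:, perm] = matrix.values
    return SemgMatrix(
        values=restored,
        original_sample_count=matrix.original_sample_count,
        pad_value=matrix.pad_value,
        meta=dict(matrix.meta),
    )


def _mean_adjacent_pd(x: np.ndarray, n_seg: int, length: int) -> float:
    """Mean PD over adjacent full segments of ``length`` samples."""
    segs = x[: n_seg * length].reshape(n_seg, length).astype(np.float64)
    d = segs[:-1] - segs[1:]
    num = np.einsum("ij,ij->i", d, d)
    den = np.einsum("ij,ij->i", segs[:-1], segs[:-1])
    # zero-energy reference segment: fall back to the unnormalized numerator
    ratios = np.where(den > 0, num / np.where(den > 0, den, 1.0), num)
    return float(ratios.mean())


def sbs_select_length(record: SemgRecord) -> int:
    """Adaptive segment length by similarity of adjacent segments.

    For each candidate N = 16n (n = 2..64) with at least two full segments in
    the record, the trailing partial segment is dropped and the mean adjacent
    PD is computed; the N with the smallest mean wins, ties going to the
    smallest N.
    """
    x = np.asarray(record.samples, dtype=np.float64)
    best_n, best_score = None, np.inf
    for length in SBS_CANDIDATE_LENGTHS:
        n_seg = x.size // length
        if n_seg < 2:
            continue
        score = _mean_adjacent_pd(x, n_seg, length)
        if score < best_score:
            best_n, best_score = length, score
    if best_n is None:
        raise ValueError("signal too short for SbS")
    return best_n
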