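"""Small interval-set arithmetic used by the statistics modules.

Everything operates on 0-based half-open spans grouped by sequence name.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io import GenomicInterval


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) spans on a single sequence."""
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def by_seq(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.seq_id, []).append((iv.start, iv.end))
    return out


def union_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    total = 0
    for spans in by_seq(intervals).values():
        total += sum(e - s for s, e in merge_spans(spans))
    return total


def clip_to(intervals: Iterable[GenomicInterval], space: GenomicInterval
            ) -> list[GenomicInterval]:
    """Intersect intervals with a single spanning region."""
    out = []
    for iv in intervals:
        if iv.seq_id != space.seq_id:
            continue
        s, e = max(iv.start, space.start), min(iv.end, space.end)
        if s < e:
            out.append(GenomicInterval(iv.seq_id, s, e, iv.strand))
    return out


class MergedSet:
    """A merged interval set supporting fast bp-overlap and hit queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._per_seq: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for seq, spans in by_seq(intervals).items():
            merged = merge_spans(spans)
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._per_seq[seq] = (starts, ends, cum)

    def overlap_bp(self, seq_id: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """bp of overlap between each query span and the set (vectorized)."""
        if seq_id not in self._per_seq:
            return np.zeros(len(qs), dtype=np.int64)
        starts, ends, cum = self._per_seq[seq_id]
        lo = np.searchsorted(ends, qs, side="right")
        hi = np.searchsorted(starts, qe, side="left")
        out = np.zeros(len(qs), dtype=np.int64)
        full = cum[np.maximum(hi, lo)] - cum[lo]
        # subtract the uncovered flanks of the first/last partially hit blocks
        has = hi > lo
        idx_lo = np.clip(lo, 0, len(starts) - 1)
        idx_hi = np.clip(hi - 1, 0, len(starts) - 1)
        left_trim = np.where(has, np.maximum(qs - starts[idx_lo], 0), 0)
        right_trim = np.where(has, np.maximum(ends[idx_hi] - qe, 0), 0)
        out = np.where(has, full - left_trim - right_trim, 0)
        return out

    def hits(self, seq_id: str, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Boolean: does each query span overlap the set by >= 1 bp?"""
        if seq_id not in self._per_seq:
            return np.zeros(len(qs), dtype=bool)
        starts, ends, _ = self._per_seq[seq_id]
        lo = np.searchsorted(ends, qs, side="right")
        hi = np.searchsorted(starts, qe, side="left")
        return hi > lo
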