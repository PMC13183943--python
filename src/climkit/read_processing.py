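"""Paired-end read merging and per-read quality filtering.

Reads are merged on their 3' overlap: the reverse mate is
reverse-complemented and slid along the forward mate; the ungapped
overlap with the most matching bases wins (ties prefer the longer
overlap).  At mismatching overlap positions the higher-quality base is
kept, with the higher of the two qualities as consensus quality.

Quality filtering mirrors the three per-read rules of common FASTQ
preprocessors: a read fails if more than ``max_unqualified_pct`` percent
of its bases fall below Phred ``qualified_q``, or if its mean Phred score
is below ``min_avg_q``.  Each mate is filtered first; only pairs where
both mates pass are merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "QualityPolicy",
    "MergedRead",
    "merge_pair",
    "merge_pairs",
    "quality_filter",
    "revcomp",
]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

# uint8 reverse-complement lookup used by the vectorized path
_RC_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_LUT[_a] = _b


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QualityPolicy:
    """Per-read quality rules (Phred-score domain)."""

    qualified_q: int = 20
    max_unqualified_pct: float = 30.0
    min_avg_q: float = 25.0

    def __post_init__(self) -> None:
        if not 0 <= self.qualified_q <= 60:
            raise ValueError("qualified_q must be in [0, 60]")
        if not 0 <= self.max_unqualified_pct <= 100:
            raise ValueError("max_unqualified_pct must be in [0, 100]")


@dataclass
class MergedRead:
    """Consensus of a merged pair: sequence, Phred qualities, pair id."""

    sequence: str
    quality: np.ndarray
    pair_id: str = ""
    overlap: int = 0


class MergeReject(ValueError):
    """Merge failure with a reason code (``no_overlap``, ``mismatch``,
    ``empty``)."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


def quality_filter(
    read: tuple[str, Sequence[int]] | MergedRead,
    policy: QualityPolicy,
) -> tuple[bool, str]:
    """Apply the per-read rules; returns (passed, reason)."""
    if isinstance(read, MergedRead):
        seq, qual = read.sequence, read.quality
    else:
        seq, qual = read
    q = np.asarray(qual, dtype=float)
    if len(seq) != q.size:
        raise ValueError("sequence and quality lengths differ")
    if q.size == 0:
        return False, "empty"
    pct_unqualified = 100.0 * np.mean(q < policy.qualified_q)
    if pct_unqualified > policy.max_unqualified_pct:
        return False, "unqualified_bases"
    if q.mean() < policy.min_avg_q:
        return False, "low_mean_quality"
    return True, "pass"


def _best_overlap(
    s1: np.ndarray, s2rc: np.ndarray, min_overlap: int,
    max_mismatch_frac: float,
) -> tuple[int, int]:
    """Best ungapped 3' overlap of s1 with reverse-complemented mate.

    Candidate overlaps are those meeting the mismatch constraint; among
    them the one with the most matching bases wins, ties preferring the
    longer overlap (candidates are scanned longest first).  Returns
    (overlap length, matches), or (0, -1) if no candidate qualifies.
    """
    n1, n2 = s1.size, s2rc.size
    best_len, best_match = 0, -1
    for olap in range(min(n1, n2), min_overlap - 1, -1):
        matches = int(np.count_nonzero(s1[n1 - olap :] == s2rc[:olap]))
        if (olap - matches) / olap > max_mismatch_frac:
            continue
        if matches > best_match:
            best_len, best_match = olap, matches
    return best_len, best_match


def merge_pair(
    r1: tuple[str, Sequence[int]],
    r2: tuple[str, Sequence[int]],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    pair_id: str = "",
) -> MergedRead:
    """Merge one pair; ``r2`` is given in sequencer orientation.

    Raises :class:`MergeReject` when no acceptable overlap exists.
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if not seq1 or not seq2:
        raise MergeReject("empty", "empty read in pair")
    s1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    s2rc = _RC_LUT[np.frombuffer(seq2.encode(), dtype=np.uint8)][::-1]
    q1 = np.asarray(qual1, dtype=np.int16)
    q2rc = np.asarray(qual2, dtype=np.int16)[::-1]

    olap, matches = _best_overlap(s1, s2rc, min_overlap, max_mismatch_frac)
    if matches < 0:
        if min(s1.size, s2rc.size) < min_overlap:
            raise MergeReject("no_overlap", "reads shorter than min_overlap")
        raise MergeReject(
            "mismatch", "no overlap satisfies the mismatch constraint"
        )

    n1 = s1.size
    left_seq = s1[: n1 - olap]
    left_q = q1[: n1 - olap]
    o1, o2 = s1[n1 - olap :], s2rc[:olap]
    oq1, oq2 = q1[n1 - olap :], q2rc[:olap]
    take2 = oq2 > oq1  # mismatches resolved toward the higher quality
    cons = np.where(take2, o2, o1)
    consq = np.maximum(oq1, oq2)
    seq = np.concatenate([left_seq, cons, s2rc[olap:]])
    qual = np.concatenate([left_q, consq, q2rc[olap:]])
    return MergedRead(
        sequence=seq.tobytes().decode(),
        quality=qual.astype(np.int16),
        pair_id=pair_id,
        overlap=olap,
    )


def merge_pairs(
    s1: np.ndarray,
    q1: np.ndarray,
    s2: np.ndarray,
    q2: np.ndarray,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized merge of equal-length read pairs.

    ``s1``/``s2`` are (n, L) uint8 ASCII arrays in sequencer orientation,
    ``q1``/``q2`` matching Phred integer arrays.  All pairs are scored at
    every candidate overlap simultaneously; pairs whose best overlap is
    too short or too mismatched are marked rejected.  Returns
    (merged sequence (n, 2L - best) is ragged, so instead:)
    (ok mask (n,), merged sequences (n_ok, variable) as an object array,
    merged qualities).  For fixed-length inserts all accepted merges share
    one length, so the outputs are dense (n_ok, merged_len) arrays; pairs
    whose best overlap differs from the modal overlap are merged
    individually.  Semantics match :func:`merge_pair` exactly.
    """
    n, L1 = s1.shape
    L2 = s2.shape[1]
    s2rc = _RC_LUT[s2][:, ::-1]
    q2rc = q2[:, ::-1]

    max_olap = min(L1, L2)
    n_cand = max_olap - min_overlap + 1
    if n_cand <= 0:
        return np.zeros(n, bool), np.empty((0, 0), np.uint8), np.empty((0, 0), np.int16)
    best_olap = np.zeros(n, dtype=np.int32)
    best_match = np.full(n, -1, dtype=np.int32)
    # longest first so that equal match counts keep the longer overlap;
    # only overlaps meeting the mismatch constraint are candidates
    for olap in range(max_olap, min_overlap - 1, -1):
        matches = np.count_nonzero(
            s1[:, L1 - olap :] == s2rc[:, :olap], axis=1
        ).astype(np.int32)
        valid = (olap - matches) <= max_mismatch_frac * olap
        better = valid & (matches > best_match)
        best_olap[better] = olap
        best_match[better] = matches[better]
    ok = best_match >= 0

    # dense path for the modal overlap, per-pair fallback for the rest
    if not ok.any():
        return ok, np.empty((0, 0), np.uint8), np.empty((0, 0), np.int16)
    olaps, counts = np.unique(best_olap[ok], return_counts=True)
    modal = int(olaps[np.argmax(counts)])
    uniform = ok & (best_olap == modal)
    if (ok & ~uniform).any():
        # mixed overlap lengths: merge ragged pairs one by one
        merged_seq = []
        merged_q = []
        idx = np.flatnonzero(ok)
        for i in idx:
            m = merge_pair(
                (s1[i].tobytes().decode(), q1[i]),
                (s2[i].tobytes().decode(), q2[i]),
                min_overlap=min_overlap,
                max_mismatch_frac=max_mismatch_frac,
            )
            merged_seq.append(np.frombuffer(m.sequence.encode(), np.uint8))
            merged_q.append(np.asarray(m.quality, np.int16))
        lens = {a.size for a in merged_seq}
        if len(lens) == 1:
            return ok, np.stack(merged_seq), np.stack(merged_q)
        seq_obj = np.empty(len(merged_seq), dtype=object)
        q_obj = np.empty(len(merged_q), dtype=object)
        seq_obj[:] = merged_seq
        q_obj[:] = merged_q
        return ok, seq_obj, q_obj

    sel = np.flatnonzero(uniform)
    a1, a2 = s1[sel], s2rc[sel]
    b1, b2 = q1[sel].astype(np.int16), q2rc[sel].astype(np.int16)
    o1, o2 = a1[:, L1 - modal :], a2[:, :modal]
    oq1, oq2 = b1[:, L1 - modal :], b2[:, :modal]
    take2 = oq2 > oq1
    cons = np.where(take2, o2, o1)
    consq = np.maximum(oq1, oq2)
    seqs = np.concatenate([a1[:, : L1 - modal], cons, a2[:, modal:]], axis=1)
    quals = np.concatenate([b1[:, : L1 - modal], consq, b2[:, modal:]], axis=1)
    return ok, seqs, quals


def quality_filter_matrix(
    q: np.ndarray, policy: QualityPolicy
) -> np.ndarray:
    """Vectorized :func:`quality_filter` over an (n, L) Phred matrix."""
    pct = 100.0 * np.mean(q < policy.qualified_q, axis=1)
    return (pct <= policy.max_unqualified_pct) & (
        q.mean(axis=1) >= policy.min_avg_q
    )
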