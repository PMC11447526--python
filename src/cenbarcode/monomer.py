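"""Consensus-free period detection and monomer decomposition of satellite
arrays.

The workflow mirrors how tandem-repeat monomers are annotated in
centromere studies: estimate the repeat period from self-match
autocorrelation, derive a consensus monomer by phase-registered majority
vote, then tile the array left to right with anchored semi-global
alignments of the consensus, flagging short hits as partial (truncated)
units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import fmean

import numpy as np

from .align import anchored_prefix_align

#: A hit shorter than this fraction of the consensus is flagged partial.
PARTIAL_FRACTION = 0.9
#: A hit shorter than this fraction of the consensus is discarded.
DISCARD_FRACTION = 0.3


@dataclass
class PeriodEstimate:
    period: int
    score: float  # autocorrelation match fraction in [0, 1]


@dataclass
class MonomerHit:
    """One tiled monomer occurrence (0-based half-open array coordinates)."""

    start: int
    end: int
    identity: float
    partial: bool
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LengthStats:
    min: int
    max: int
    mean: float
    mode: int


def match_fraction(seq: str, period: int) -> float:
    """m(p) = fraction of positions i with seq[i] == seq[i + p]."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if period >= arr.size:
        raise ValueError("period must be shorter than the sequence")
    return float(np.mean(arr[:-period] == arr[period:]))


def detect_period(seq: str, min_period: int, max_period: int, near_tie: float = 0.02) -> PeriodEstimate:
    """Estimate the repeat period by self-match autocorrelation.

    Picks the period maximizing m(p), preferring the smallest p scoring
    within `near_tie` of the maximum -- on clean arrays every multiple of
    the true period scores identically, and the smallest one is the monomer.
    """
    if not 1 <= min_period <= max_period:
        raise ValueError("need 1 <= min_period <= max_period")
    if len(seq) < 3 * max_period:
        raise ValueError(
            f"sequence of {len(seq)} bp too short for max_period {max_period} "
            "(need at least 3x max_period)"
        )
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    periods = np.arange(min_period, max_period + 1)
    scores = np.array([np.mean(arr[:-p] == arr[p:]) for p in periods])
    best = float(scores.max())
    chosen = int(periods[np.nonzero(scores >= best - near_tie)[0][0]])
    return PeriodEstimate(period=chosen, score=float(scores[chosen - min_period]))


def _best_rotation(chunk: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Circular offset of `chunk` maximizing matches against `reference`,
    with the match count at that offset."""
    p = reference.size
    doubled = np.concatenate([chunk, chunk])
    windows = np.lib.stride_tricks.sliding_window_view(doubled, p)[:p]
    matches = (windows == reference).sum(axis=1)
    best = int(np.argmax(matches))
    return best, int(matches[best])


def _medoid_chunk(chunks: np.ndarray, n_sample: int = 10) -> int:
    """Index of the sampled chunk agreeing best with the other samples
    (under best circular rotation). A chunk spanning a truncated copy is a
    phase mosaic and scores poorly, so it never becomes the reference."""
    n = min(n_sample, len(chunks))
    scores = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                scores[i] += _best_rotation(chunks[j], chunks[i])[1]
    return int(np.argmax(scores))


def derive_consensus(seq: str, period: int) -> str:
    """Phase-registered per-column majority consensus of length `period`.

    The array is chunked into period-length windows; each chunk is aligned
    to a reference chunk (the medoid of the first few chunks) by its best
    circular offset before the column-wise majority vote (ties broken
    toward the lexicographically smallest base).
    """
    n_chunks = len(seq) // period
    if n_chunks < 3:
        raise ValueError(f"need at least 3 full {period}-bp chunks, got {n_chunks}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    chunks = arr[: n_chunks * period].reshape(n_chunks, period)
    reference = chunks[_medoid_chunk(chunks)]
    aligned = np.empty_like(chunks)
    for i, chunk in enumerate(chunks):
        off, _ = _best_rotation(chunk, reference)
        aligned[i] = np.roll(chunk, -off)
    consensus = bytearray()
    for col in aligned.T:
        counts = Counter(col.tolist())
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        consensus.append(best[0])
    return bytes(consensus).decode()


def canonical_rotation(monomer: str) -> str:
    """Lexicographically minimal rotation (idempotent)."""
    if not monomer:
        raise ValueError("empty monomer")
    doubled = monomer + monomer
    return min(doubled[i : i + len(monomer)] for i in range(len(monomer)))


def decompose(array: str, consensus: str, min_identity: float = 60.0) -> list[MonomerHit]:
    """Greedy left-to-right tiling of the consensus over the array.

    At each cursor the consensus is aligned against the window
    [cursor, cursor + 2L] with the hit anchored at the cursor and free right
    ends; the hit is accepted when identity >= min_identity. Hits shorter
    than 0.9 L are flagged partial; hits shorter than 0.3 L are discarded.
    An empty array yields an empty list.
    """
    if len(consensus) < 10:
        raise ValueError("consensus must be at least 10 bp")
    L = len(consensus)
    hits: list[MonomerHit] = []
    cursor = 0
    min_len = DISCARD_FRACTION * L
    # slack covers the few points gained by trimming mutated terminal
    # bases without letting a genuine truncation be forced through the
    # full consensus; the band keeps the path near the diagonal so the
    # alignment cannot wander into the neighbouring copy via long gaps
    slack = max(4.0, 0.02 * L)
    band = max(10, round(0.1 * L))
    # cells beyond L + band are unreachable under the band constraint, so
    # a window of L + 2*band is equivalent to the nominal 2L window
    window_len = min(2 * L, L + 2 * band)
    while cursor < len(array):
        window = array[cursor : cursor + window_len]
        if len(window) < min_len:
            break
        summary = anchored_prefix_align(
            window, consensus, prefer_full_slack=slack, band=band
        )
        if summary is None or summary.target_end <= summary.target_start:
            cursor += L
            continue
        start = cursor + summary.target_start
        end = cursor + summary.target_end
        # Junction repair against the previous hit. Overshoot: a truncated
        # copy absorbed a few chance-matching bases of the following copy,
        # which shows up as a leading consensus offset (query_start > 0) on
        # this hit -- give the bases back. Undershoot: the truncated copy's
        # own mutated tail was trimmed, so this alignment skips the orphan
        # bases via a leading window gap (target_start > 0) -- extend the
        # partial up to the junction.
        if hits and summary.query_start > 0 and hits[-1].end == start:
            give_back = summary.query_start
            if give_back < min(hits[-1].length, 0.1 * L):
                prev = hits[-1]
                prev.end -= give_back
                prev.sequence = array[prev.start : prev.end]
                prev.partial = prev.length < PARTIAL_FRACTION * L
                start -= give_back
        elif (
            hits
            and summary.target_start > 0
            and hits[-1].end == cursor
            and hits[-1].partial
            and summary.target_start < 0.1 * L
        ):
            prev = hits[-1]
            prev.end += summary.target_start
            prev.sequence = array[prev.start : prev.end]
            prev.partial = prev.length < PARTIAL_FRACTION * L
        length = end - start
        advance = max(summary.target_end, 1)
        if summary.identity >= min_identity and length >= min_len:
            hits.append(
                MonomerHit(
                    start=start,
                    end=end,
                    identity=summary.identity,
                    partial=length < PARTIAL_FRACTION * L,
                    sequence=array[start:end],
                )
            )
        cursor += advance
    return hits


def length_stats(hits: list[MonomerHit], exclude_partial: bool = True) -> LengthStats:
    """Min/max/mean/mode of hit lengths; the mode breaks ties toward the
    smallest length."""
    lengths = [h.length for h in hits if not (exclude_partial and h.partial)]
    if not lengths:
        raise ValueError("no hits to summarize")
    counts = Counter(lengths)
    mode = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return LengthStats(
        min=min(lengths), max=max(lengths), mean=fmean(lengths), mode=mode
    )
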