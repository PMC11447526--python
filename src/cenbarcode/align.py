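"""Shared pairwise-alignment scoring and helpers.

All alignment-based statistics in the package use one DNA scoring scheme:
match +1, mismatch -1, gap open -2, gap extend -1.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from Bio import Align

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0

#: Per-consensus-base penalty used only to pick the endpoint of an
#: anchored prefix alignment (not part of the alignment score itself);
#: sits between the score drift of unrelated in-band DNA (~+0.1/base)
#: and that of genuine monomer homology (>= +0.8/base at usable identity).
END_DRIFT = 0.45


def _base_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def global_aligner() -> Align.PairwiseAligner:
    """Aligner for end-to-end global alignment (all end gaps penalized)."""
    return _base_aligner()


def anchored_prefix_align(
    window: str,
    consensus: str,
    prefer_full_slack: float | None = None,
    band: int | None = None,
) -> "AlignmentSummary | None":
    """Left-anchored prefix alignment of a consensus onto an array window.

    The alignment starts at the window cursor and consensus position 0
    (leading gaps are possible but penalized) and may end anywhere in
    either sequence with both right ends free: the optimum is the
    max-scoring cell of the match layer of a Gotoh affine-gap DP. Free
    right ends on *both* sequences are what let a truncated (partial)
    monomer copy -- a 5' prefix of the full unit -- align as a short hit
    instead of being forced through the following copy.

    The endpoint row (how much consensus is consumed) maximizes the
    drift-penalized score max_j M[i, j] - END_DRIFT * i. Under this
    scoring, gapped alignment of unrelated in-band DNA still climbs at
    roughly +0.1 per consensus base, so the raw optimum would creep past
    a truncation into the following copy; true homology climbs at +0.9
    or better. The penalty rate sits between the two drifts, making the
    score peak exactly where homology ends.

    When `prefer_full_slack` is given, an endpoint that consumes the whole
    consensus is preferred as long as its penalized score is within that
    slack of the best row: trimming a handful of mutated terminal bases
    gains only a few points, while a genuine truncation loses far more
    than the slack when forced through the full consensus.

    A `band` constrains the path to |window position - consensus position|
    <= band. Gapped alignment of unrelated DNA drifts mildly positive under
    this scoring, so an unconstrained optimum can wander through the
    neighbouring monomer copy via long spurious gaps; a genuine monomer hit
    never strays far off the diagonal (indels are rare), so the band
    removes exactly the pathological paths.

    Returns None when no cell scores positive (no usable hit).
    """
    t = np.frombuffer(window.encode(), dtype=np.uint8)
    q = np.frombuffer(consensus.encode(), dtype=np.uint8)
    nt, nq = t.size, q.size
    if nt == 0 or nq == 0:
        return None
    NEG = np.int32(-(10**6))
    o, e = int(GAP_OPEN), int(GAP_EXTEND)
    M = np.full((nq + 1, nt + 1), NEG, dtype=np.int32)
    Ix = np.full_like(M, NEG)  # gap in consensus (consuming window)
    Iy = np.full_like(M, NEG)  # gap in window (consuming consensus)
    M[0, 0] = 0
    Ix[0, 1:] = o + e * np.arange(nt, dtype=np.int32)
    Iy[1:, 0] = o + e * np.arange(nq, dtype=np.int32)
    j_idx = np.arange(1, nt + 1, dtype=np.int32)
    all_j = np.arange(nt + 1)
    if band is not None:
        Ix[0, 1:][j_idx > band] = NEG
    for i in range(1, nq + 1):
        outside = np.abs(all_j - i) > band if band is not None else None
        s = np.where(t == q[i - 1], np.int32(MATCH), np.int32(MISMATCH))
        best_prev = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = best_prev + s
        Iy[i, 1:] = np.maximum(M[i - 1, 1:] + o, Iy[i - 1, 1:] + e)
        if outside is not None:
            M[i, outside] = NEG
            Iy[i, outside] = NEG
        # Ix[i, j] = max_{k<j} M[i, k] + o + (j-1-k) e, via a running max
        aux = M[i] - e * np.arange(nt + 1, dtype=np.int32)
        run = np.maximum.accumulate(aux)
        Ix[i, 1:] = run[:-1] + o + (j_idx - 1) * e
        if outside is not None:
            Ix[i, outside] = NEG

    row_best = M.max(axis=1).astype(np.float64)
    penalized = row_best - END_DRIFT * np.arange(nq + 1)
    qi = int(np.argmax(penalized[1:])) + 1
    if prefer_full_slack is not None and penalized[nq] >= penalized[qi] - prefer_full_slack:
        qi = nq
    tj = int(np.argmax(M[qi]))
    if M[qi, tj] <= 0 or tj == 0:
        return None

    # traceback from the best match cell to the origin
    i, j = qi, tj
    state = "M"
    matches = columns = 0
    t_start, q_start = 0, 0
    while i > 0 or j > 0:
        if state == "M":
            t_start, q_start = j - 1, i - 1
            columns += 1
            if t[j - 1] == q[i - 1]:
                matches += 1
            prev = M[i, j] - (MATCH if t[j - 1] == q[i - 1] else MISMATCH)
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            if i == 0:  # leading window gap: outside the aligned span
                j -= 1
                continue
            columns += 1
            if Ix[i, j] == M[i, j - 1] + o:
                state = "M"
            j -= 1
        else:  # Iy
            if j == 0:
                i -= 1
                continue
            columns += 1
            if Iy[i, j] == M[i - 1, j] + o:
                state = "M"
            i -= 1
    return AlignmentSummary(
        target_start=t_start,
        target_end=tj,
        query_start=q_start,
        query_end=qi,
        matches=matches,
        columns=columns,
    )


class AlignmentSummary(NamedTuple):
    """Aligned-span statistics of a pairwise alignment.

    Columns are counted from the first to the last aligned pair, so free end
    gaps do not dilute identity; for a fully global alignment end gaps are
    part of the span whenever terminal residues are aligned on either side.
    """

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def summarize_alignment(alignment) -> AlignmentSummary | None:
    """Extract span coordinates, match count and column count.

    Returns None when the alignment contains no aligned pair at all.
    """
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        return None
    target, query = alignment.target, alignment.query
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
    # internal gap columns between consecutive aligned blocks
    for i in range(1, len(t_blocks)):
        columns += t_blocks[i][0] - t_blocks[i - 1][1]
        columns += q_blocks[i][0] - q_blocks[i - 1][1]
    return AlignmentSummary(
        target_start=int(t_blocks[0][0]),
        target_end=int(t_blocks[-1][1]),
        query_start=int(q_blocks[0][0]),
        query_end=int(q_blocks[-1][1]),
        matches=matches,
        columns=columns,
    )


def global_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = matches / alignment columns * 100, where columns include every
    gap column of the global alignment (end gaps count against identity).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = global_aligner()
    aln = aligner.align(a, b)[0]
    summary = summarize_alignment(aln)
    if summary is None:
        return 0.0
    # extend the span to the full global alignment: unaligned terminal
    # residues of either sequence are end-gap columns
    columns = summary.columns
    columns += summary.target_start + (len(a) - summary.target_end)
    columns += summary.query_start + (len(b) - summary.query_end)
    return 100.0 * summary.matches / columns
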