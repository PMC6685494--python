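"""Shared pairwise-alignment helpers and a small center-star MSA.

Scored local alignments (network edges, partner calls, core trimming) use
Biopython's PairwiseAligner with BLASTN-like scoring: match +1,
mismatch -2, gap open -5, gap extend -2.  Identity-over-containment
checks use edlib's infix alignment, which is much faster for near-exact
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

__all__ = [
    "make_local_aligner",
    "make_global_aligner",
    "local_stats",
    "longest_common_substring",
    "contained_identity",
    "center_star_msa",
]

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2


def make_local_aligner(match: float = DEFAULT_MATCH,
                       mismatch: float = DEFAULT_MISMATCH,
                       gap_open: float = DEFAULT_GAP_OPEN,
                       gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def make_global_aligner() -> Align.PairwiseAligner:
    """Global aligner with free end gaps, for same-family sequences."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


@dataclass(frozen=True)
class LocalStats:
    score: float
    identity: float          # matches / aligned columns (gaps counted)
    aligned_columns: int
    target_span: tuple       # (start, end) on the first sequence, end-exclusive
    query_span: tuple        # (start, end) on the second sequence


def local_stats(target: str, query: str,
                aligner: Align.PairwiseAligner | None = None) -> LocalStats | None:
    """Best local alignment of query against target, summarized.

    Returns None when no alignment with positive score exists.
    """
    aligner = aligner or make_local_aligner()
    score = aligner.score(target, query)
    if score <= 0:
        return None
    aln = aligner.align(target, query)[0]
    t_segs, q_segs = aln.aligned
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_segs, q_segs):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)
        for i, j in zip(range(ts, te), range(qs, qe)):
            columns += 1
            if target[i] == query[j]:
                matches += 1
        prev_t_end, prev_q_end = te, qe
    t_span = (int(t_segs[0][0]), int(t_segs[-1][1]))
    q_span = (int(q_segs[0][0]), int(q_segs[-1][1]))
    identity = matches / columns if columns else 0.0
    return LocalStats(score=float(score), identity=identity,
                      aligned_columns=columns, target_span=t_span,
                      query_span=q_span)


_LCS_ALIGNER = Align.PairwiseAligner()
_LCS_ALIGNER.mode = "local"
_LCS_ALIGNER.match_score = 1
_LCS_ALIGNER.mismatch_score = -1e9
_LCS_ALIGNER.open_gap_score = -1e9
_LCS_ALIGNER.extend_gap_score = -1e9


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact common substring of a and b."""
    if not a or not b:
        return 0
    return int(round(_LCS_ALIGNER.score(a, b)))


def contained_identity(query: str, target: str) -> float:
    """Identity of query aligned somewhere inside target (infix alignment).

    Uses edit distance over the whole query with free target overhangs;
    identity = 1 - edits / len(query).
    """
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(query))


# -- center-star multiple alignment ---------------------------------------

def center_star_msa(seqs: list[str]) -> list[str]:
    """Center-star progressive multiple alignment.

    The sequence with the highest total global-alignment score to all
    others is the center; every other sequence is aligned to it and the
    pairwise alignments are merged column-wise (once a gap, always a
    gap).  Adequate for closely related repeat copies; not a general MSA.
    """
    if not seqs:
        return []
    if len(seqs) == 1:
        return list(seqs)
    aligner = make_global_aligner()
    k = len(seqs)
    totals = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            s = aligner.score(seqs[i], seqs[j])
            totals[i] += s
            totals[j] += s
    center_idx = max(range(k), key=lambda i: (totals[i], len(seqs[i])))
    center = seqs[center_idx]
    m = len(center)

    # Per sequence: char matched to each center position ('-' if none) and
    # inserted runs before each center position (index 0..m).
    matched: list[list[str]] = []
    inserts: list[list[str]] = []
    order = [i for i in range(k) if i != center_idx]
    for i in order:
        aln = aligner.align(center, seqs[i])[0]
        t_segs, q_segs = aln.aligned
        mch = ["-"] * m
        ins = [""] * (m + 1)
        prev_t = prev_q = 0
        for (ts, te), (qs, qe) in zip(t_segs, q_segs):
            if qs > prev_q:
                ins[ts] += seqs[i][prev_q:qs]
            for t_pos, q_pos in zip(range(ts, te), range(qs, qe)):
                mch[t_pos] = seqs[i][q_pos]
            prev_t, prev_q = te, qe
        if prev_q < len(seqs[i]):
            ins[m] += seqs[i][prev_q:]
        matched.append(mch)
        inserts.append(ins)

    max_ins = [0] * (m + 1)
    for ins in inserts:
        for p in range(m + 1):
            max_ins[p] = max(max_ins[p], len(ins[p]))

    def build_row(mch: list[str], ins: list[str]) -> str:
        parts: list[str] = []
        for p in range(m):
            parts.append(ins[p].ljust(max_ins[p], "-"))
            parts.append(mch[p])
        parts.append(ins[m].ljust(max_ins[m], "-"))
        return "".join(parts)

    center_row = build_row(list(center), [""] * (m + 1))
    rows_by_input: dict[int, str] = {center_idx: center_row}
    for pos, i in enumerate(order):
        rows_by_input[i] = build_row(matched[pos], inserts[pos])
    return [rows_by_input[i] for i in range(k)]
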