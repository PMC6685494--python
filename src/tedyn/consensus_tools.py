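"""Alignment post-processing shared across modules.

Column-occupancy trimming (trimal-style ``-gt 0.6 -cons 60`` semantics)
and plurality-rule consensus calling (EMBOSS ``cons``-style plurality 3),
plus K2P divergence summaries of subfamily members against a consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._align import center_star_msa, make_global_aligner
from .divergence import k2p_distance

__all__ = [
    "MultipleAlignment",
    "trim_alignment",
    "plurality_consensus",
    "divergence_summary",
    "align_copies",
]

_ALPHABET = set("ACGTN-")


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over {A,C,G,T,N,-} with row ids."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"row {rid!r} has length {len(row)} != {width}")
            bad = set(row.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"row {rid!r}: invalid characters {bad}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


def align_copies(ids: Sequence[str], seqs: Sequence[str]) -> MultipleAlignment:
    """Multiple-align unaligned copies with the center-star utility."""
    rows = center_star_msa([s.upper() for s in seqs])
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows))


def trim_alignment(aln: MultipleAlignment, min_occupancy: float = 0.6,
                   min_columns_kept_fraction: float = 0.6) -> MultipleAlignment:
    """Drop low-occupancy columns, keeping at least a floor fraction.

    Columns whose non-gap fraction falls below ``min_occupancy`` are
    removed; if that would leave fewer than ``min_columns_kept_fraction``
    of the original columns, the highest-occupancy columns are retained
    up to the floor instead.  Column order is never changed.
    """
    n_cols = aln.n_columns
    occ = np.array([
        sum(1 for c in aln.column(j) if c != "-") / aln.n_rows
        for j in range(n_cols)
    ])
    keep = occ >= min_occupancy
    floor = int(np.ceil(min_columns_kept_fraction * n_cols))
    if keep.sum() < floor:
        # retain the most-occupied columns up to the floor; ties broken by
        # column index for determinism
        order = sorted(range(n_cols), key=lambda j: (-occ[j], j))
        chosen = sorted(order[:floor])
        keep = np.zeros(n_cols, dtype=bool)
        keep[chosen] = True
    cols = np.flatnonzero(keep)
    rows = tuple("".join(row[j] for j in cols) for row in aln.rows)
    return MultipleAlignment(ids=aln.ids, rows=rows)


def plurality_consensus(aln: MultipleAlignment, plurality: int = 3) -> str:
    """Per-column plurality consensus.

    A column emits its most frequent residue when that residue's count
    reaches ``plurality`` and it is a strict plurality among non-gap
    characters; ties and under-threshold columns emit N.  All-gap columns
    are dropped.
    """
    out = []
    for j in range(aln.n_columns):
        counts = Counter(c for c in aln.column(j).upper() if c != "-")
        if not counts:
            continue
        ranked = counts.most_common()
        top_char, top_n = ranked[0]
        tie = len(ranked) > 1 and ranked[1][1] == top_n
        if top_n >= plurality and not tie:
            out.append(top_char)
        else:
            out.append("N")
    return "".join(out)


def divergence_summary(members: Sequence[str], consensus: str) -> dict:
    """K2P divergence of members to a consensus, plus pairwise summary.

    Members are pairwise-aligned to the consensus (free end gaps) before
    distance computation.  Saturated or incomparable pairs are excluded
    from the means and counted in ``n_undefined``.
    """
    if not members:
        raise ValueError("empty member list")
    aligner = make_global_aligner()

    def _dist(a: str, b: str) -> float | None:
        aln = aligner.align(a.upper(), b.upper())[0]
        ga, gb = str(aln[0]), str(aln[1])
        try:
            return k2p_distance(ga, gb)
        except ValueError:
            return None

    to_cons = [_dist(m, consensus) for m in members]
    defined = [d for d in to_cons if d is not None]
    n_undefined = len(to_cons) - len(defined)

    pairwise = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            d = _dist(members[i], members[j])
            if d is None:
                n_undefined += 1
            else:
                pairwise.append(d)

    return {
        "mean_to_consensus": float(np.mean(defined)) if defined else float("nan"),
        "mean_pairwise": float(np.mean(pairwise)) if pairwise else float("nan"),
        "range_to_consensus": (
            (min(defined), max(defined)) if defined else (float("nan"),) * 2
        ),
        "n_members": len(members),
        "n_undefined": n_undefined,
    }
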