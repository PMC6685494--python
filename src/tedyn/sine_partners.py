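"""SINE-LINE partnerships and tail nucleotide composition.

Nonautonomous SINEs borrow the retrotransposition machinery of a partner
LINE, which recognizes the SINE's 3' end; partner identification
therefore aligns the 3' ~100 bp of each SINE consensus against the
3' ends of candidate LINE consensuses.  Tail composition contrasts the
base content of poly-A/T tails between young and old insertions by
repeated seeded subsampling of full-length copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._align import local_stats, make_local_aligner
from .divergence import AgeClass, classify_age
from .repeat_io import TEFamily

__all__ = [
    "PartnerCall",
    "TailProfile",
    "find_partner",
    "tail_composition",
]

BASE_PAIRS = (("A", "T"), ("A", "C"), ("A", "G"), ("C", "G"), ("C", "T"), ("G", "T"))


@dataclass(frozen=True)
class PartnerCall:
    """Best LINE partner for one SINE family, or none past the gates."""

    sine_family: str
    line_family: str | None
    identity: float
    aligned_bp: int
    score: float


@dataclass
class TailProfile:
    """Pooled tail base counts for one species/stratum/replicate."""

    species_id: str
    stratum: str
    replicate: int
    counts: dict                    # base -> count over degapped tails
    n_copies: int
    empty: bool = False

    def log2_ratio(self, x: str, y: str) -> float:
        """log2((count_x + 1) / (count_y + 1)), computed as a difference of
        logs so that ratio(x, y) == -ratio(y, x) exactly."""
        return (math.log2(self.counts.get(x, 0) + 1)
                - math.log2(self.counts.get(y, 0) + 1))

    def all_ratios(self) -> dict:
        return {f"{x}:{y}": self.log2_ratio(x, y) for x, y in BASE_PAIRS}


def find_partner(sine: TEFamily, lines: Sequence[TEFamily],
                 tail_window: int = 100, line_window: int = 300,
                 min_identity: float = 0.70, min_aligned: int = 40) -> PartnerCall:
    """Identify the likely LINE mobilization partner of a SINE family.

    The SINE's 3'-terminal ``tail_window`` bp are locally aligned against
    the 3'-terminal ``line_window`` bp of every LINE; the best-scoring
    LINE passing the identity and aligned-length gates is called.  The
    result is independent of LINE library order (ties broken by name).
    """
    if not lines:
        raise ValueError("empty LINE library")
    if len(sine.consensus) < tail_window:
        raise ValueError(
            f"SINE {sine.name} consensus shorter than tail window {tail_window}"
        )
    sine_tail = sine.consensus[-tail_window:].upper()
    aligner = make_local_aligner()
    best: tuple | None = None   # (-score, name) for deterministic ordering
    best_stats = None
    best_line = None
    for line in sorted(lines, key=lambda f: f.name):
        line_tail = line.consensus[-line_window:].upper()
        st = local_stats(line_tail, sine_tail, aligner)
        if st is None:
            continue
        key = (-st.score, line.name)
        if best is None or key < best:
            best = key
            best_stats = st
            best_line = line
    if best_stats is None:
        return PartnerCall(sine.name, None, 0.0, 0, 0.0)
    if best_stats.identity < min_identity or best_stats.aligned_columns < min_aligned:
        return PartnerCall(sine.name, None, best_stats.identity,
                           best_stats.aligned_columns, best_stats.score)
    return PartnerCall(sine.name, best_line.name, best_stats.identity,
                       best_stats.aligned_columns, best_stats.score)


def _tail_of(copy_seq: str, consensus: str, aligner) -> str | None:
    """Sequence 3' of the last consensus-aligned position of the copy."""
    st = local_stats(copy_seq, consensus, aligner)
    if st is None:
        return None
    return copy_seq[st.target_span[1]:]


def tail_composition(copies: Sequence[tuple],
                     consensus: str,
                     n_sample: int = 100,
                     reps: int = 10,
                     age_class: AgeClass | None = None,
                     min_core_coverage: float = 0.90,
                     seed: int = 0) -> list[TailProfile]:
    """Tail base composition per species, stratum, and replicate.

    ``copies`` holds (copy_id, species_id, divergence, sequence) tuples.
    Full-length copies (consensus-aligned span covering at least
    ``min_core_coverage`` of the consensus) are stratified recent/old by
    divergence; per species x stratum, ``reps`` seeded replicates each
    sample min(n_sample, available) copies without replacement, extract
    the tail 3' of the last consensus-aligned column, and pool base
    counts.  Strata with no eligible copies yield a flagged empty
    profile rather than fabricated counts.
    """
    age_class = age_class or AgeClass()
    consensus = consensus.upper()
    aligner = make_local_aligner()

    eligible: dict[tuple, list] = {}
    tail_cache: dict[str, str] = {}
    for copy_id, species_id, div, seq in copies:
        seq = seq.upper()
        st = local_stats(seq, consensus, aligner)
        if st is None:
            continue
        covered = st.query_span[1] - st.query_span[0]
        if covered < min_core_coverage * len(consensus):
            continue
        tail = seq[st.target_span[1]:]
        tail_cache[copy_id] = tail
        stratum = classify_age(min(div, 1.0), age_class)
        eligible.setdefault((species_id, stratum), []).append(copy_id)

    profiles: list[TailProfile] = []
    species = sorted({sp for sp, _ in eligible})
    all_species = sorted({c[1] for c in copies})
    rng = np.random.default_rng(seed)
    for sp in all_species:
        for stratum in ("recent", "old"):
            pool = eligible.get((sp, stratum), [])
            for rep in range(1, reps + 1):
                if not pool:
                    profiles.append(TailProfile(sp, stratum, rep,
                                                {b: 0 for b in "ACGT"},
                                                0, empty=True))
                    continue
                k = min(n_sample, len(pool))
                idx = sorted(rng.choice(len(pool), size=k, replace=False).tolist())
                counts = {b: 0 for b in "ACGT"}
                for i in idx:
                    for b in tail_cache[pool[i]]:
                        if b in counts:
                            counts[b] += 1
                profiles.append(TailProfile(sp, stratum, rep, counts, k))
    return profiles
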