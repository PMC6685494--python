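"""Kimura 2-parameter distances, the neutral molecular clock, and TE landscapes.

Divergence of a TE copy from its family consensus accumulates roughly
neutrally after insertion, so K2P distance doubles as an insertion-age
proxy.  The clock used throughout is 1.9e-9 substitutions/site/generation
at 4 generations/year; with the pairwise-divergence convention
(``lineage_factor = 2``) a divergence of 0.05 corresponds to ~3.3 Myr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .repeat_io import RepeatHit

__all__ = [
    "ClockModel",
    "AgeClass",
    "Landscape",
    "k2p_distance",
    "divergence_to_age",
    "classify_age",
    "build_landscape",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class ClockModel:
    """Neutral clock converting divergence to absolute age.

    ``lineage_factor`` is 2 when the observed divergence is a pairwise
    distance accumulating on both the copy and consensus lineages (the
    default, which reproduces the 0.2 -> 13.2 Myr conversion), or 1 for a
    single-lineage reading.
    """

    mu_per_generation: float = 1.9e-9
    generations_per_year: float = 4.0
    lineage_factor: int = 2

    def __post_init__(self) -> None:
        if self.mu_per_generation <= 0 or self.generations_per_year <= 0:
            raise ValueError("clock parameters must be positive")
        if self.lineage_factor not in (1, 2):
            raise ValueError("lineage_factor must be 1 or 2")

    @property
    def subs_per_site_per_year(self) -> float:
        return self.lineage_factor * self.mu_per_generation * self.generations_per_year


@dataclass(frozen=True)
class AgeClass:
    """Recent/old dichotomy on divergence: recent iff d < cutoff."""

    cutoff: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")


@dataclass
class Landscape:
    """Temporal TE landscape: genome proportion per divergence bin.

    Bins are left-closed right-open intervals of equal width; a divergence
    of exactly 1.0 falls in the last bin.  ``midpoint_age_myr`` converts
    bin midpoints with the clock.
    """

    bin_edges: np.ndarray            # length n_bins + 1
    bp: np.ndarray                   # int bp per bin
    genome_size: int
    clock: ClockModel = field(default_factory=ClockModel)

    @property
    def proportions(self) -> np.ndarray:
        return self.bp / self.genome_size

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def midpoint_age_myr(self) -> np.ndarray:
        return np.array([divergence_to_age(m, self.clock) for m in self.midpoints])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "midpoint_age_myr": self.midpoint_age_myr,
            "proportion": self.proportions,
            "bp": self.bp,
        })


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    Columns containing a gap ("-") or N in either sequence are excluded.
    With transition proportion P and transversion proportion Q over the
    comparable columns, d = -0.5*ln[(1-2P-Q)*sqrt(1-2Q)].

    Raises ValueError for unequal lengths, zero comparable columns, or
    saturation (the log argument nonpositive).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    a = seq_a.upper()
    b = seq_b.upper()
    n = 0
    transitions = 0
    transversions = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no comparable (gap/N-free) columns")
    P = transitions / n
    Q = transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise ValueError(f"K2P distance undefined (saturation): P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def divergence_to_age(d: float, clock: ClockModel | None = None) -> float:
    """Convert a divergence fraction to an absolute age in Myr.

    age_years = d / (lineage_factor * mu * generations_per_year).
    """
    if d < 0:
        raise ValueError(f"negative divergence {d}")
    clock = clock or ClockModel()
    return d / clock.subs_per_site_per_year / 1e6


def classify_age(d: float, age_class: AgeClass | None = None) -> str:
    """Classify a divergence as "recent" (d < cutoff) or "old" (d >= cutoff)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"divergence {d} outside [0, 1]")
    age_class = age_class or AgeClass()
    return "recent" if d < age_class.cutoff else "old"


def build_landscape(hits: Sequence[RepeatHit], genome_size: int,
                    bin_width: float = 0.01,
                    clock: ClockModel | None = None) -> Landscape:
    """Bin hit bp by divergence into a genome-proportion landscape.

    Each hit's length is added to the bin containing its divergence
    (left-closed right-open); proportions are bp / genome_size.  All hits
    must come from one species.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    species = {h.species_id for h in hits}
    if len(species) > 1:
        raise ValueError(f"hits span multiple species: {sorted(species)}")
    n_bins = int(math.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    bp = np.zeros(n_bins, dtype=np.int64)
    for h in hits:
        idx = min(int(h.divergence / bin_width), n_bins - 1)
        bp[idx] += h.length_bp
    return Landscape(bin_edges=edges, bp=bp, genome_size=genome_size,
                     clock=clock or ClockModel())
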