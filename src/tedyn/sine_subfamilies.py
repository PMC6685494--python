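"""SINE subfamily detection via similarity networks and community detection.

Copies are trimmed to the consensus-homologous core (poly-A/T tails and
flanks removed) and length-filtered at 235 nt.  A weighted similarity
network over the retained cores (seeded local alignment, word length 8)
is partitioned with resolution-parameterized community detection on the
Reichardt-Bornholdt configuration-null quality function.  Each community
is summarized by a majority-rule consensus from up to 30 sampled
members; communities with effectively identical consensuses are merged,
and subfamily consensuses are finally grouped into clusters at 95%
identity (or collapsed as a library at 90%/90%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np

from ._align import (
    contained_identity,
    local_stats,
    longest_common_substring,
    make_local_aligner,
)
from .consensus_tools import align_copies

__all__ = [
    "CoreRegion",
    "SimilarityNetwork",
    "SubfamilyPartition",
    "trim_to_core",
    "build_network",
    "detect_communities",
    "community_consensus",
    "merge_identical",
    "cluster_subfamilies",
    "collapse_library",
]

MIN_CORE_LENGTH = 235
MIN_COPY_LENGTH = 240
DEFAULT_GAMMA = 59.0
CONSENSUS_SAMPLE_SIZE = 30
WORD_SIZE = 8
MAX_NEIGHBORS = 50
DEFAULT_MIN_SCORE = 50.0


@dataclass(frozen=True)
class CoreRegion:
    """The consensus-homologous span of one SINE copy, tail-trimmed."""

    copy_id: str
    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_CORE_LENGTH:
            raise ValueError(
                f"{self.copy_id}: core length {len(self.sequence)} < {MIN_CORE_LENGTH}"
            )


@dataclass
class SimilarityNetwork:
    """Weighted undirected copy-similarity graph (no self-loops)."""

    nodes: list            # copy ids, fixed order
    edges: dict            # (i, j) with i < j -> weight > 0

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=len(self.nodes))
        g.vs["name"] = list(self.nodes)
        if self.edges:
            pairs = sorted(self.edges)
            g.add_edges(pairs)
            g.es["weight"] = [self.edges[p] for p in pairs]
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SubfamilyPartition:
    """Copy -> community assignment with per-community consensuses."""

    membership: dict                         # copy_id -> community id
    species_of: dict = field(default_factory=dict)   # copy_id -> species
    consensus: dict = field(default_factory=dict)    # community id -> sequence

    def communities(self) -> dict:
        out: dict[int, list] = {}
        for cid in sorted(set(self.membership.values())):
            out[cid] = []
        for copy_id in sorted(self.membership):
            out[self.membership[copy_id]].append(copy_id)
        return out

    def sizes(self) -> dict:
        return {cid: len(members) for cid, members in self.communities().items()}

    def species_counts(self, cid: int) -> dict:
        counts: dict[str, int] = {}
        for copy_id, c in self.membership.items():
            if c == cid:
                sp = self.species_of.get(copy_id, "?")
                counts[sp] = counts.get(sp, 0) + 1
        return counts

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def _canonical_relabel(membership: Mapping[str, int]) -> dict:
    """Relabel community ids 0..k-1 by decreasing size, then first member."""
    groups: dict[int, list] = {}
    for copy_id in sorted(membership):
        groups.setdefault(membership[copy_id], []).append(copy_id)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), m[0]))
    out: dict[str, int] = {}
    for new_cid, members in enumerate(ordered):
        for copy_id in members:
            out[copy_id] = new_cid
    return out


# -- core trimming ---------------------------------------------------------

def trim_to_core(copies: Sequence[tuple],
                 references: Sequence[tuple],
                 min_core: int = MIN_CORE_LENGTH,
                 min_copy: int = MIN_COPY_LENGTH,
                 min_score: float = DEFAULT_MIN_SCORE) -> tuple[list, dict]:
    """Trim copies to their reference-homologous core.

    ``copies`` holds (copy_id, species_id, sequence) triples; references
    are (name, trimmed consensus) pairs.  Each copy is locally aligned to
    every reference; the core runs from the minimum alignment start to
    the maximum alignment end over references scoring at least
    ``min_score``.  Copies shorter than ``min_copy`` before trimming, with
    no reference hit, or with a core shorter than ``min_core`` are
    discarded; the second return value maps copy_id -> discard reason.
    """
    if not references:
        raise ValueError("empty reference set")
    aligner = make_local_aligner()
    cores: list[CoreRegion] = []
    discarded: dict[str, str] = {}
    for copy_id, species_id, seq in copies:
        seq = seq.upper()
        if len(seq) < min_copy:
            discarded[copy_id] = f"copy-shorter-than-{min_copy}"
            continue
        lo, hi = None, None
        for _, ref in references:
            st = local_stats(seq, ref.upper(), aligner)
            if st is None or st.score < min_score:
                continue
            s, e = st.target_span
            lo = s if lo is None else min(lo, s)
            hi = e if hi is None else max(hi, e)
        if lo is None:
            discarded[copy_id] = "no-reference-hit"
            continue
        core = seq[lo:hi]
        if len(core) < min_core:
            discarded[copy_id] = f"core-shorter-than-{min_core}"
            continue
        cores.append(CoreRegion(copy_id=copy_id, species_id=species_id,
                                sequence=core))
    return cores, discarded


# -- network construction --------------------------------------------------

def build_network(cores: Sequence[CoreRegion],
                  min_score: float = DEFAULT_MIN_SCORE,
                  word_size: int = WORD_SIZE,
                  max_neighbors: int = MAX_NEIGHBORS) -> SimilarityNetwork:
    """Pairwise similarity network over trimmed cores.

    Candidate pairs share at least one exact word of ``word_size`` nt
    (plus strand only); for each query the ``max_neighbors`` candidates
    sharing the most words are scored by local alignment, and pairs
    scoring at least ``min_score`` become undirected edges weighted by
    the alignment score (reciprocal hits collapsed by max).
    """
    if not cores:
        raise ValueError("empty core set")
    n = len(cores)
    seqs = [c.sequence for c in cores]
    index: dict[str, list] = {}
    for i, s in enumerate(seqs):
        for p in range(len(s) - word_size + 1):
            index.setdefault(s[p:p + word_size], []).append(i)

    aligner = make_local_aligner()
    edges: dict[tuple, float] = {}
    for i, s in enumerate(seqs):
        shared: dict[int, int] = {}
        for p in range(len(s) - word_size + 1):
            for j in index.get(s[p:p + word_size], ()):
                if j != i:
                    shared[j] = shared.get(j, 0) + 1
        candidates = sorted(shared, key=lambda j: (-shared[j], j))[:max_neighbors]
        for j in candidates:
            key = (min(i, j), max(i, j))
            if key in edges:
                continue
            score = float(aligner.score(s, seqs[j]))
            if score >= min_score:
                edges[key] = score
    return SimilarityNetwork(nodes=[c.copy_id for c in cores], edges=edges)


def random_score_threshold(length: int, n_pairs: int = 200,
                           quantile: float = 0.99, seed: int = 0) -> float:
    """Null local-alignment score threshold from random sequence pairs.

    Scores ``n_pairs`` pairs of i.i.d. uniform random sequences of the
    given length and returns the requested quantile — a data-independent
    gate below which edges are indistinguishable from noise.
    """
    rng = np.random.default_rng(seed)
    aligner = make_local_aligner()
    bases = np.array(list("ACGT"))
    scores = []
    for _ in range(n_pairs):
        a = "".join(rng.choice(bases, size=length))
        b = "".join(rng.choice(bases, size=length))
        scores.append(float(aligner.score(a, b)))
    return float(np.quantile(scores, quantile))


# -- community detection ---------------------------------------------------

def detect_communities(net: SimilarityNetwork, gamma: float = DEFAULT_GAMMA,
                       seed: int = 0,
                       species_of: Mapping[str, str] | None = None) -> SubfamilyPartition:
    """Partition the network by the Reichardt-Bornholdt quality function.

    Minimizes H = -sum_{i<j} (w_ij - gamma * s_i s_j / 2m) delta(c_i, c_j)
    (the configuration null model) with a seeded Leiden optimizer.
    Disconnected components and singletons are handled naturally; larger
    gamma yields finer partitions.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = net.to_igraph()
    if g.ecount() == 0:
        membership = {name: i for i, name in enumerate(net.nodes)}
    else:
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=gamma, seed=seed,
        )
        membership = {name: part.membership[v.index]
                      for v, name in zip(g.vs, g.vs["name"])}
    membership = _canonical_relabel(membership)
    return SubfamilyPartition(membership=membership,
                              species_of=dict(species_of or {}))


# -- consensus building ----------------------------------------------------

def _majority_consensus(rows: Sequence[str]) -> str:
    """Column-majority consensus; columns where gaps are the majority drop."""
    if not rows:
        return ""
    out = []
    width = len(rows[0])
    for j in range(width):
        col = [r[j] for r in rows]
        gaps = col.count("-")
        if 2 * gaps > len(col):
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def community_consensus(partition: SubfamilyPartition,
                        cores: Sequence[CoreRegion],
                        sample_size: int = CONSENSUS_SAMPLE_SIZE,
                        seed: int = 0) -> SubfamilyPartition:
    """Attach a majority-rule consensus to every community.

    Up to ``sample_size`` members are sampled without replacement
    (seeded; communities processed in canonical order so results are
    reproducible), multiple-aligned, and summarized by column majority.
    A singleton community's consensus is its single member.
    """
    seq_of = {c.copy_id: c.sequence for c in cores}
    rng = np.random.default_rng(seed)
    consensus: dict[int, str] = {}
    for cid, members in partition.communities().items():
        if len(members) == 1:
            consensus[cid] = seq_of[members[0]]
            continue
        if len(members) > sample_size:
            picked = sorted(rng.choice(len(members), size=sample_size,
                                       replace=False).tolist())
            chosen = [members[i] for i in picked]
        else:
            chosen = members
        aln = align_copies(chosen, [seq_of[m] for m in chosen])
        consensus[cid] = _majority_consensus(aln.rows)
    return SubfamilyPartition(membership=dict(partition.membership),
                              species_of=dict(partition.species_of),
                              consensus=consensus)


# -- merging and clustering ------------------------------------------------

class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_identical(partition: SubfamilyPartition,
                    cores: Sequence[CoreRegion],
                    identity: float = 1.0,
                    coverage: float = 0.95,
                    sample_size: int = CONSENSUS_SAMPLE_SIZE,
                    seed: int = 0) -> SubfamilyPartition:
    """Merge communities whose consensuses are identical at 95% coverage.

    Two communities merge when their consensuses share an exact common
    run covering at least ``coverage`` of the shorter consensus (100%
    identity over >= 95% query coverage).  Merging is transitive
    (union-find closure); consensuses are recomputed for merged
    communities.
    """
    cids = sorted(partition.consensus)
    uf = _UnionFind(cids)
    for a_idx in range(len(cids)):
        for b_idx in range(a_idx + 1, len(cids)):
            a, b = cids[a_idx], cids[b_idx]
            ca, cb = partition.consensus[a], partition.consensus[b]
            if not ca or not cb:
                continue
            need = int(np.ceil(coverage * min(len(ca), len(cb))))
            if longest_common_substring(ca, cb) >= need:
                uf.union(a, b)
    membership = {copy_id: uf.find(cid)
                  for copy_id, cid in partition.membership.items()}
    membership = _canonical_relabel(membership)
    merged = SubfamilyPartition(membership=membership,
                                species_of=dict(partition.species_of))
    return community_consensus(merged, cores, sample_size=sample_size, seed=seed)


def cluster_subfamilies(consensuses: Sequence[tuple],
                        identity: float = 0.95) -> dict:
    """Greedy full-length clustering of subfamily consensuses.

    Sequences are processed by decreasing length; each joins the first
    existing cluster whose representative matches at >= ``identity`` over
    the full length of the shorter sequence, else founds a new cluster.
    Returns name -> cluster representative name.
    """
    if not consensuses:
        raise ValueError("empty consensus set")
    ordered = sorted(consensuses, key=lambda kv: (-len(kv[1]), kv[0]))
    reps: list[tuple] = []
    assignment: dict[str, str] = {}
    for name, seq in ordered:
        placed = False
        for rep_name, rep_seq in reps:
            short, long_ = (seq, rep_seq) if len(seq) <= len(rep_seq) else (rep_seq, seq)
            if contained_identity(short, long_) >= identity:
                assignment[name] = rep_name
                placed = True
                break
        if not placed:
            reps.append((name, seq))
            assignment[name] = name
    return assignment


def collapse_library(consensuses: Sequence[tuple],
                     identity: float = 0.90,
                     coverage: float = 0.90) -> dict:
    """Collapse near-duplicate library consensuses (90%/90% rule).

    Same greedy scheme as cluster_subfamilies but requiring ``identity``
    over an aligned span covering at least ``coverage`` of each
    sequence's total length; the longest member of each group is kept as
    representative.  Returns name -> representative name.
    """
    ordered = sorted(consensuses, key=lambda kv: (-len(kv[1]), kv[0]))
    aligner = make_local_aligner(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
    reps: list[tuple] = []
    assignment: dict[str, str] = {}
    for name, seq in ordered:
        placed = False
        for rep_name, rep_seq in reps:
            st = local_stats(rep_seq, seq, aligner)
            if st is None:
                continue
            cov_rep = (st.target_span[1] - st.target_span[0]) / len(rep_seq)
            cov_seq = (st.query_span[1] - st.query_span[0]) / len(seq)
            if st.identity >= identity and min(cov_rep, cov_seq) >= coverage:
                assignment[name] = rep_name
                placed = True
                break
        if not placed:
            reps.append((name, seq))
            assignment[name] = name
    return assignment
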