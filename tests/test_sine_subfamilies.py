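"""SINE subfamily detection: trimming, network, communities, consensus,
merging and clustering, with planted-truth recovery checks."""

import numpy as np
import pytest

from tedyn.sine_subfamilies import (
    CoreRegion,
    build_network,
    cluster_subfamilies,
    collapse_library,
    community_consensus,
    detect_communities,
    merge_identical,
    trim_to_core,
)


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutated(rng, seq, frac):
    chars = list(seq)
    for p in rng.choice(len(chars), size=int(frac * len(chars)), replace=False):
        chars[p] = "ACGT"[("ACGT".index(chars[p]) + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(chars)


@pytest.fixture(scope="module")
def module_rng():
    return np.random.default_rng(777)


class TestTrimToCore:
    def test_poly_a_tail_removed(self, module_rng):
        ref = _rand_seq(module_rng, 280)
        copy = ref + "A" * 50
        cores, disc = trim_to_core([("c1", "sp1", copy)], [("ref", ref)])
        assert not disc
        assert len(cores) == 1
        # the recovered core covers the homologous span, tail excluded
        assert abs(len(cores[0].sequence) - 280) <= 3
        assert not cores[0].sequence.endswith("A" * 20)

    def test_short_fragment_discarded(self, module_rng):
        ref = _rand_seq(module_rng, 280)
        cores, disc = trim_to_core([("c1", "sp1", ref[:200] + "A" * 60)],
                                   [("ref", ref)])
        assert cores == []
        assert "c1" in disc

    def test_unrelated_copy_discarded_with_reason(self, module_rng):
        ref = _rand_seq(module_rng, 280)
        cores, disc = trim_to_core([("c1", "sp1", _rand_seq(module_rng, 300))],
                                   [("ref", ref)])
        assert disc.get("c1") == "no-reference-hit"

    def test_boundary_recovery_on_simulated_copies(self, module_rng):
        rng = module_rng
        ref = _rand_seq(rng, 300)
        copies = []
        for i in range(100):
            body = _mutated(rng, ref, 0.03)
            tail = "A" * int(rng.integers(10, 60))
            head = _rand_seq(rng, int(rng.integers(0, 10)))
            copies.append((f"c{i}", "sp1", head + body + tail))
        cores, disc = trim_to_core(copies, [("ref", ref)])
        assert len(cores) >= 99
        ok = sum(1 for c in cores if abs(len(c.sequence) - 300) <= 6)
        assert ok / len(cores) >= 0.99


def _planted_cores(rng, k=3, n_per=40, length=300, div=0.03):
    masters = [_rand_seq(rng, length) for _ in range(k)]
    cores, truth = [], {}
    for mi, m in enumerate(masters):
        for i in range(n_per):
            cid = f"m{mi}_c{i}"
            cores.append(CoreRegion(cid, "sp1", _mutated(rng, m, div)))
            truth[cid] = mi
    return cores, truth, masters


class TestBuildNetwork:
    def test_identical_cores_get_max_score_edge(self, module_rng):
        seq = _rand_seq(module_rng, 300)
        net = build_network([CoreRegion("a", "s", seq), CoreRegion("b", "s", seq)])
        assert net.n_edges == 1
        assert net.edges[(0, 1)] == pytest.approx(300.0)

    def test_unrelated_cores_unconnected(self, module_rng):
        net = build_network([CoreRegion("a", "s", _rand_seq(module_rng, 300)),
                             CoreRegion("b", "s", _rand_seq(module_rng, 300))])
        assert net.n_edges == 0

    def test_within_subfamily_edges_dominate(self, module_rng):
        cores, truth, _ = _planted_cores(module_rng, k=3, n_per=25)
        net = build_network(cores)
        within, between = [], []
        for (i, j), w in net.edges.items():
            (within if truth[cores[i].copy_id] == truth[cores[j].copy_id]
             else between).append(w)
        assert within
        assert not between or np.mean(within) > np.mean(between)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([])


class TestDetectCommunities:
    def test_two_cliques_resolved(self, module_rng):
        from tedyn.sine_subfamilies import SimilarityNetwork
        nodes = [f"n{i}" for i in range(8)]
        edges = {}
        for a in range(4):
            for b in range(a + 1, 4):
                edges[(a, b)] = 10.0
                edges[(a + 4, b + 4)] = 10.0
        edges[(0, 4)] = 1.0
        net = SimilarityNetwork(nodes=nodes, edges=edges)
        part = detect_communities(net, gamma=1.0, seed=0)
        assert part.n_communities == 2
        assert len({part.membership[f"n{i}"] for i in range(4)}) == 1

    def test_gamma_to_zero_gives_one_community(self, module_rng):
        cores, _, _ = _planted_cores(module_rng, k=2, n_per=15)
        net = build_network(cores)
        part = detect_communities(net, gamma=1e-9, seed=0)
        # one community per connected component; planted blocks share no
        # edges, so at most k communities, and weakly-resolved gamma never
        # splits a block
        assert part.n_communities <= 2

    def test_planted_partition_recovery(self, module_rng):
        from sklearn.metrics import adjusted_rand_score
        cores, truth, _ = _planted_cores(module_rng, k=5, n_per=30)
        net = build_network(cores)
        part = detect_communities(net, gamma=1.0, seed=0)
        ids = [c.copy_id for c in cores]
        ari = adjusted_rand_score([truth[i] for i in ids],
                                  [part.membership[i] for i in ids])
        assert ari >= 0.9

    def test_invalid_gamma(self, module_rng):
        cores, _, _ = _planted_cores(module_rng, k=2, n_per=5)
        net = build_network(cores)
        with pytest.raises(ValueError):
            detect_communities(net, gamma=0)

    def test_determinism(self, module_rng):
        cores, _, _ = _planted_cores(module_rng, k=3, n_per=20)
        net = build_network(cores)
        a = detect_communities(net, gamma=1.0, seed=7)
        b = detect_communities(net, gamma=1.0, seed=7)
        assert a.membership == b.membership


class TestCommunityConsensus:
    def test_identical_members_reproduced(self, module_rng):
        seq = _rand_seq(module_rng, 280)
        cores = [CoreRegion(f"c{i}", "s", seq) for i in range(5)]
        part = detect_communities(build_network(cores), gamma=1e-6, seed=0)
        part = community_consensus(part, cores, seed=0)
        assert list(part.consensus.values()) == [seq]

    def test_majority_recovers_master(self, module_rng):
        rng = module_rng
        master = _rand_seq(rng, 300)
        cores = [CoreRegion(f"c{i}", "s", _mutated(rng, master, 0.02))
                 for i in range(100)]
        part = detect_communities(build_network(cores), gamma=1e-6, seed=0)
        part = community_consensus(part, cores, seed=0)
        cons = list(part.consensus.values())[0]
        matches = sum(1 for a, b in zip(cons, master) if a == b)
        assert matches / len(master) >= 0.99

    def test_singleton_consensus_is_member(self, module_rng):
        seq = _rand_seq(module_rng, 260)
        cores = [CoreRegion("only", "s", seq)]
        from tedyn.sine_subfamilies import SubfamilyPartition
        part = SubfamilyPartition(membership={"only": 0})
        part = community_consensus(part, cores, seed=0)
        assert part.consensus[0] == seq


class TestMergeAndCluster:
    def _partition_with(self, consensuses):
        from tedyn.sine_subfamilies import SubfamilyPartition
        membership = {f"c{i}": i for i in range(len(consensuses))}
        part = SubfamilyPartition(membership=membership)
        part.consensus = dict(enumerate(consensuses))
        return part, [CoreRegion(f"c{i}", "s", s)
                      for i, s in enumerate(consensuses)]

    def test_identical_consensuses_merge(self, module_rng):
        seq = _rand_seq(module_rng, 280)
        part, cores = self._partition_with([seq, seq])
        merged = merge_identical(part, cores)
        assert merged.n_communities == 1

    def test_ninety_percent_coverage_does_not_merge(self, module_rng):
        a = _rand_seq(module_rng, 300)
        b = a[:270] + _rand_seq(module_rng, 30)  # identical over 90% only
        part, cores = self._partition_with([a, b])
        merged = merge_identical(part, cores)
        assert merged.n_communities == 2

    def test_transitive_chain_collapses(self, module_rng):
        a = _rand_seq(module_rng, 300)
        b = a[5:]      # identical over 295/300
        c = a[10:]     # identical to b over 290/295
        part, cores = self._partition_with([a, b, c])
        merged = merge_identical(part, cores)
        assert merged.n_communities == 1

    def test_merge_never_increases_count(self, module_rng):
        seqs = [_rand_seq(module_rng, 280) for _ in range(6)]
        part, cores = self._partition_with(seqs)
        merged = merge_identical(part, cores)
        assert merged.n_communities <= part.n_communities

    def test_cluster_one_mismatch_joins(self, module_rng):
        a = _rand_seq(module_rng, 300)
        b = a[:150] + ("A" if a[150] != "A" else "C") + a[151:]
        clusters = cluster_subfamilies([("x", a), ("y", b)])
        assert clusters["x"] == clusters["y"]

    def test_cluster_distant_sequences_split(self, module_rng):
        clusters = cluster_subfamilies([("x", _rand_seq(module_rng, 300)),
                                        ("y", _rand_seq(module_rng, 300))])
        assert clusters["x"] != clusters["y"]

    def test_cluster_planted_masters(self, module_rng):
        rng = module_rng
        masters = [_rand_seq(rng, 300) for _ in range(4)]
        cons = []
        for mi, m in enumerate(masters):
            for i in range(5):
                cons.append((f"m{mi}_{i}", _mutated(rng, m, 0.02)))
        clusters = cluster_subfamilies(cons)
        assert len(set(clusters.values())) == 4

    def test_collapse_rules(self, module_rng):
        rng = module_rng
        a = _rand_seq(rng, 300)
        dup = a
        near = _mutated(rng, a, 0.08)          # 92% identity, full length
        partial = _mutated(rng, a[:150], 0.08) # 92% over half only
        other = _rand_seq(rng, 300)
        col = collapse_library([("a", a), ("dup", dup), ("near", near),
                                ("partial", partial), ("other", other)])
        assert col["dup"] == col["a"]
        assert col["near"] == col["a"]
        assert col["partial"] != col["a"]
        assert col["other"] != col["a"]
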