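import networkx as nx
import numpy as np
import pytest

import oracles
from trajpc import (
    PatientNetwork,
    SubtypePartition,
    TrajectoryProfile,
    baseline_normalizers,
    compute_subtype_profiles,
    filter_small,
    louvain_partition,
    modularity,
    subtype_profile,
)


def net_from_matrix(p):
    p = np.asarray(p, dtype=float)
    return PatientNetwork([f"p{i}" for i in range(len(p))], p, p.max())


def random_network(rng, n):
    a = np.triu(rng.uniform(0, 1, size=(n, n)) * (rng.random((n, n)) < 0.6), k=1)
    a = a + a.T
    if a.sum() == 0:
        a[0, 1] = a[1, 0] = 1.0
    return net_from_matrix(a)


def two_cliques(k=4):
    a = np.zeros((2 * k, 2 * k))
    for c in range(2):
        for i in range(k):
            for j in range(k):
                if i != j:
                    a[c * k + i, c * k + j] = 1.0
    return net_from_matrix(a)


class TestModularity:
    def test_single_community_is_zero(self, rng):
        net = random_network(rng, 7)
        labels = {p: 0 for p in net.patient_ids}
        assert modularity(net, labels) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_edges_split_by_component(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        net = net_from_matrix(a)
        labels = {"p0": 0, "p1": 0, "p2": 1, "p3": 1}
        assert modularity(net, labels) == pytest.approx(0.5)  # 2 * (1/2 - 1/4)

    def test_all_singletons_negative_on_loop_free_graph(self, rng):
        net = random_network(rng, 6)
        labels = {p: i for i, p in enumerate(net.patient_ids)}
        assert modularity(net, labels) < 0

    def test_matches_definition_and_networkx(self, rng):
        for _ in range(25):
            net = random_network(rng, int(rng.integers(3, 9)))
            labels = {p: int(rng.integers(0, 3)) for p in net.patient_ids}
            q_def = oracles.modularity_formula(
                net.P, [labels[p] for p in net.patient_ids]
            )
            assert modularity(net, labels) == pytest.approx(q_def, abs=1e-12)
            comms = {}
            for p, l in labels.items():
                comms.setdefault(l, set()).add(p)
            q_nx = nx.community.modularity(
                net.to_networkx(), comms.values(), weight="weight"
            )
            assert modularity(net, labels) == pytest.approx(q_nx, abs=1e-9)

    def test_missing_label_raises(self, rng):
        net = random_network(rng, 4)
        with pytest.raises(ValueError, match="label"):
            modularity(net, {"p0": 0})


class TestLouvain:
    def test_recovers_two_cliques(self):
        part = louvain_partition(two_cliques(), seed=0, min_size=1)
        groups = {}
        for p, l in part.labels.items():
            groups.setdefault(l, set()).add(p)
        assert sorted(map(sorted, groups.values())) == [
            ["p0", "p1", "p2", "p3"],
            ["p4", "p5", "p6", "p7"],
        ]
        q_best, _ = oracles.best_partition_exhaustive(two_cliques().P)
        assert part.Q == pytest.approx(q_best, abs=1e-12)

    def test_complete_uniform_graph_stays_whole(self):
        a = np.ones((6, 6)) - np.eye(6)
        net = net_from_matrix(a)
        q_best, _ = oracles.best_partition_exhaustive(a)
        assert q_best <= 1e-12  # no split improves on the trivial partition
        part = louvain_partition(net, seed=0, min_size=1)
        assert len(set(part.labels.values())) == 1
        assert part.Q == pytest.approx(0.0, abs=1e-12)

    def test_attains_exhaustive_maximum_on_random_graphs(self, rng):
        """Louvain (best of 10 seeds) reaches the global modularity optimum
        on small graphs where every partition can be enumerated."""
        for _ in range(20):
            net = random_network(rng, int(rng.integers(4, 9)))
            q_best, _ = oracles.best_partition_exhaustive(net.P)
            q_got = max(
                louvain_partition(net, seed=s, min_size=1).Q for s in range(10)
            )
            assert q_got == pytest.approx(q_best, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        net = random_network(rng, 12)
        p1 = louvain_partition(net, seed=5, min_size=1)
        p2 = louvain_partition(net, seed=5, min_size=1)
        assert p1.labels == p2.labels and p1.Q == p2.Q

    def test_zero_weight_graph_raises(self):
        net = net_from_matrix(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="zero total weight"):
            louvain_partition(net, seed=0)


class TestFilterSmall:
    def _partition(self, sizes):
        labels = {}
        i = 0
        for cid, n in enumerate(sizes, start=1):
            for _ in range(n):
                labels[f"p{i}"] = cid
                i += 1
        return SubtypePartition(labels=labels, Q=0.3, seed=0)

    def test_small_communities_flagged(self):
        part = filter_small(self._partition([80, 60, 3]), min_size=10)
        assert part.retained == {1, 2}
        assert len(part.unassigned_for_reporting()) == 3
        assert set(part.labels.values()) == {1, 2, 3}  # labels preserved

    def test_min_size_one_is_identity(self):
        part = filter_small(self._partition([4, 2]), min_size=1)
        assert part.retained == {1, 2}
        assert not part.unassigned_for_reporting()

    def test_all_below_min_size_warns_empty_retained(self):
        with pytest.warns(UserWarning, match="retained set is empty"):
            part = filter_small(self._partition([3, 2]), min_size=10)
        assert part.retained == set()


class TestSubtypeProfile:
    def _prof(self, pid, matrix):
        m = np.asarray(matrix)
        return TrajectoryProfile(pid, m, [f"c{i}" for i in range(m.shape[0])])

    def test_hand_arithmetic(self):
        members = [self._prof("a", [[1, 0]]), self._prof("b", [[1, 1]])]
        sp = subtype_profile(1, members, np.array([0.5]))
        assert sp.S[0, 0] == pytest.approx(2.0)  # 2 / (2 * 0.5)
        assert sp.affected_fraction[0, 0] == pytest.approx(1.0)

    def test_all_zero_column_gives_zero_S(self):
        members = [self._prof("a", [[0, 0]]), self._prof("b", [[0, 0]])]
        sp = subtype_profile(1, members, np.array([0.25]))
        assert (sp.S[0] == 0).all()

    def test_whole_population_self_normalizes_to_one(self, rng):
        profs = [
            self._prof(f"p{i}", rng.integers(0, 2, size=(5, 3))) for i in range(12)
        ]
        u = baseline_normalizers(profs)
        sp = subtype_profile(1, profs, u)
        defined = ~sp.undefined_columns
        assert np.allclose(sp.S[defined, 0], 1.0)

    def test_zero_normalizer_flagged_undefined(self):
        members = [self._prof("a", [[1, 1], [0, 0]])]
        sp = subtype_profile(1, members, np.array([0.5, 0.0]))
        assert not sp.undefined_columns[0]
        assert sp.undefined_columns[1]
        assert np.isnan(sp.S[1]).all()

    def test_count_identity(self, rng):
        """S * U * N_l recovers the integer count of affected members."""
        profs = [
            self._prof(f"p{i}", rng.integers(0, 2, size=(4, 3))) for i in range(20)
        ]
        u = baseline_normalizers(profs)
        sp = subtype_profile(1, profs[:7], u)
        counts = sp.S * u[:, None] * sp.N_l
        counts = counts[~sp.undefined_columns]
        assert np.all(np.abs(counts - np.round(counts)) < 1e-9)

    def test_compute_profiles_only_for_retained(self, rng):
        profs = [
            self._prof(f"p{i}", rng.integers(0, 2, size=(3, 2))) for i in range(12)
        ]
        labels = {f"p{i}": (1 if i < 10 else 2) for i in range(12)}
        part = filter_small(SubtypePartition(labels, Q=0.1, seed=0), min_size=10)
        out = compute_subtype_profiles(profs, part)
        assert set(out) == {1}
        assert out[1].N_l == 10
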