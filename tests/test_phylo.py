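"""TN93 distances, neighbor joining, conservation ranking."""

import math

import numpy as np
import pytest

from solor.phylo import (
    DistanceMatrix,
    SaturatedPairError,
    build_distance_matrix,
    mean_pairwise_distance,
    neighbor_joining,
    rank_by_conservation,
    tn93_distance,
)
from solor.simulate import random_dna


def k80_distance(P, Q):
    """Kimura two-parameter distance (independent closed form)."""
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def random_additive_tree(rng, n):
    """Random unrooted binary tree; returns (leaf names, edge dict)."""
    leaves = [f"L{i}" for i in range(n)]
    active = leaves[:]
    edges = {}
    cnt = 0
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        new = f"I{cnt}"
        cnt += 1
        edges[frozenset((a, new))] = float(rng.uniform(0.05, 1.0))
        edges[frozenset((b, new))] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [new]
    hub = "HUB"
    for x in active:
        edges[frozenset((x, hub))] = float(rng.uniform(0.05, 1.0))
    return leaves, edges


def tree_distances(leaves, edges):
    adj = {}
    for e, w in edges.items():
        u, v = tuple(e)
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    D = {}
    for s in leaves:
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in leaves:
            D[(s, t)] = dist[t]
    return np.array([[D[(a, b)] for b in leaves] for a in leaves])


class TestTn93:
    def test_identical_sequences_have_zero_distance(self, rng):
        s = random_dna(rng, 200)
        r = tn93_distance(s, s)
        assert (r.distance, r.P1, r.P2, r.Q) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_independent_reference_value(self):
        # 500-bp pair with 30 planted substitutions; expected value computed
        # with ape::dist.dna(model="TN93", pairwise.deletion=TRUE)
        rng = np.random.default_rng(0)
        a = random_dna(rng, 500)
        b = list(a)
        for i in rng.choice(500, 30, replace=False):
            b[i] = str(rng.choice([c for c in "ACGT" if c != b[i]]))
        r = tn93_distance(a, "".join(b))
        assert r.distance == pytest.approx(0.0626456791812924, abs=1e-12)

    def test_closed_form_from_counted_proportions(self):
        # 100 sites, equal base composition, exactly 5 A<->G transitions
        a = ("ACGT" * 25)
        b = list(a)
        ag_cols = [0, 4, 8, 12, 16]  # all hold 'A'
        for i in ag_cols:
            b[i] = "G"
        r = tn93_distance(a, "".join(b))
        assert (r.P1, r.P2, r.Q) == (0.05, 0.0, 0.0)
        # independent evaluation of the closed form at these counts:
        # pair-averaged freqs: A=(25+20)/200, G=(25+30)/200, C=T=50/200
        pA, pG, pC, pT = 45 / 200, 55 / 200, 50 / 200, 50 / 200
        pR = pA + pG
        k1 = 2 * pA * pG / pR
        expected = -k1 * math.log(1 - 0.05 / k1)
        assert r.distance == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_k80_with_equal_frequencies(self, rng):
        # equal base composition and balanced transition classes
        for _ in range(10):
            n = 400
            a = "ACGT" * (n // 4)
            b = list(a)
            k = int(rng.integers(2, 10))
            a_cols = rng.choice(n // 4, 2 * k, replace=False)
            for i in a_cols[:k]:
                b[4 * i] = "G"  # A->G transitions
            for i in a_cols[k:]:
                b[4 * i + 1] = "T"  # C->T transitions
            q_cols = rng.choice(n // 4, k, replace=False)
            for i in q_cols:
                b[4 * i + 2] = "C"  # G->C transversions
            r = tn93_distance(a, "".join(b))
            assert r.distance == pytest.approx(
                k80_distance(r.P1 + r.P2, r.Q), rel=1e-3
            )

    def test_gap_and_n_columns_excluded_pairwise(self):
        a = "AC-TACGTNN" + "ACGT" * 30
        b = "ACGTACGTAC" + "ACGT" * 30
        r = tn93_distance(a, b)
        assert r.sites_used == len(a) - 3

    def test_saturated_pair_rejected(self):
        a = "A" * 100 + "ACGT" * 25
        b = "G" * 100 + "ACGT" * 25
        with pytest.raises(SaturatedPairError):
            tn93_distance(a, b)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("ACGT", "ACG")


class TestDistanceMatrix:
    def test_identical_rows_give_zero_matrix(self, rng):
        s = random_dna(rng, 120)
        dm = build_distance_matrix({f"s{i}": s for i in range(4)})
        assert np.all(dm.values == 0)

    def test_symmetry_holds_exactly(self, rng):
        rows = {}
        base = random_dna(rng, 300)
        for i in range(5):
            b = list(base)
            for j in rng.choice(300, 10, replace=False):
                b[j] = str(rng.choice(list("ACGT")))
            rows[f"s{i}"] = "".join(b)
        dm = build_distance_matrix(rows)
        assert np.array_equal(dm.values, dm.values.T)

    def test_star_divergence_gives_similar_entries(self, rng):
        base = random_dna(rng, 2_000)
        rows = {}
        for i in range(4):
            b = list(base)
            for j in rng.choice(2_000, 40, replace=False):  # equal branch loads
                b[j] = str(rng.choice([c for c in "ACGT" if c != b[j]]))
            rows[f"s{i}"] = "".join(b)
        dm = build_distance_matrix(rows)
        off = dm.values[np.triu_indices(4, k=1)]
        assert off.std() / off.mean() < 0.25

    def test_flagged_pairs_block_downstream(self):
        rows = {
            "a": "A" * 100 + "ACGT" * 25,
            "b": "G" * 100 + "ACGT" * 25,
            "c": "A" * 100 + "ACGT" * 25,
        }
        dm = build_distance_matrix(rows)
        assert dm.flagged
        with pytest.raises(ValueError):
            neighbor_joining(dm)
        with pytest.raises(ValueError):
            mean_pairwise_distance(dm)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]),
        )
        tree = neighbor_joining(dm)
        get = lambda x: next(w for e, w in tree.edges.items() if x in e)
        assert get("a") == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert get("b") == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert get("c") == pytest.approx((0.5 + 0.4 - 0.3) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self, rng):
        leaves, edges = random_additive_tree(rng, 4)
        M = tree_distances(leaves, edges)
        tree = neighbor_joining(DistanceMatrix(leaves, M))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert tree.path_length(a, b) == pytest.approx(M[i, j], abs=1e-9)

    @pytest.mark.parametrize("trial", range(15))
    def test_additive_matrices_recovered(self, rng, trial):
        n = int(rng.integers(4, 11))
        leaves, edges = random_additive_tree(rng, n)
        M = tree_distances(leaves, edges)
        tree = neighbor_joining(DistanceMatrix(leaves, M))
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert tree.path_length(a, b) == pytest.approx(M[i, j], abs=1e-9)

    def test_ultrametric_matrix_matches_upgma_grouping(self):
        # clear two-cluster structure: {a,b} and {c,d}
        M = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.3],
                [1.0, 1.0, 0.3, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c", "d"], M))
        # the a-b path must not pass near c/d: it is shorter than any cross pair
        assert tree.path_length("a", "b") < tree.path_length("a", "c")
        assert tree.path_length("c", "d") < tree.path_length("b", "d")
        from scipy.cluster.hierarchy import average, fcluster
        from scipy.spatial.distance import squareform

        labels = fcluster(average(squareform(M)), 2, criterion="maxclust")
        assert labels[0] == labels[1] and labels[2] == labels[3]

    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        leaves, edges = random_additive_tree(rng, 7)
        M = tree_distances(leaves, edges)
        tree = neighbor_joining(DistanceMatrix(leaves, M))
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set(leaves)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]])))


class TestConservation:
    def test_zero_matrix_scores_zero(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        s = mean_pairwise_distance(dm, "g")
        assert s.mean_pairwise_distance == 0 and s.n_pairs == 3

    def test_known_mean(self):
        vals = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        s = mean_pairwise_distance(DistanceMatrix(["a", "b", "c"], vals))
        assert s.mean_pairwise_distance == pytest.approx(0.2)

    def test_invariant_under_reordering(self, rng):
        ids = ["a", "b", "c", "d"]
        M = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        vals = rng.uniform(0.01, 0.5, len(iu[0]))
        M[iu] = vals
        M += M.T
        perm = [2, 0, 3, 1]
        M2 = M[np.ix_(perm, perm)]
        s1 = mean_pairwise_distance(DistanceMatrix(ids, M))
        s2 = mean_pairwise_distance(DistanceMatrix([ids[p] for p in perm], M2))
        assert s1.mean_pairwise_distance == pytest.approx(s2.mean_pairwise_distance)

    def test_monotone_in_any_entry(self):
        M = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        base = mean_pairwise_distance(DistanceMatrix(["a", "b", "c"], M))
        M2 = M.copy()
        M2[0, 1] = M2[1, 0] = 0.4
        up = mean_pairwise_distance(DistanceMatrix(["a", "b", "c"], M2))
        assert up.mean_pairwise_distance > base.mean_pairwise_distance

    def test_rank_most_varied_first_ties_by_gene(self):
        from solor.phylo import ConservationScore

        scores = [
            ConservationScore("gB", 0.1, 3),
            ConservationScore("gA", 0.1, 3),
            ConservationScore("gC", 0.5, 3),
        ]
        ranked = rank_by_conservation(scores)
        assert [s.gene_id for s in ranked] == ["gC", "gA", "gB"]

    def test_high_rate_gene_ranks_most_varied(self, rng):
        base_rate = 0.01
        scores = []
        for gid, rate in [("fast", 3 * base_rate), ("s1", base_rate), ("s2", base_rate)]:
            ref = random_dna(rng, 600)
            rows = {}
            for i in range(6):
                b = list(ref)
                hits = np.nonzero(rng.random(600) < rate)[0]
                for j in hits:
                    b[j] = str(rng.choice([c for c in "ACGT" if c != b[j]]))
                rows[f"{gid}_{i}"] = "".join(b)
            dm = build_distance_matrix(rows)
            scores.append(mean_pairwise_distance(dm, gid))
        assert rank_by_conservation(scores)[0].gene_id == "fast"

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_by_conservation([])
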