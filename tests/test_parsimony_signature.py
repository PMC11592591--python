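import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from bcfdna.parsimony_signature import (
    BRAIN,
    OTHER,
    CharacterMatrix,
    PhyloTree,
    RatchetConfig,
    SignatureConfig,
    UnrootedTree,
    assign_signatures,
    classify_epihaplotype,
    cohort_fraction,
    contains_split,
    fitch_score,
    fitch_score_tree,
    ratchet_search,
    topology_distance,
)


# ---------------------------------------------------------------------------
# tree construction helpers and oracles


def unrooted_from_nested(nested, n_leaves):
    adj: dict[int, set[int]] = {}
    counter = [n_leaves]

    def build(t):
        if isinstance(t, int):
            adj.setdefault(t, set())
            return t
        kids = [build(k) for k in t]
        node = counter[0]
        counter[0] += 1
        adj.setdefault(node, set())
        for k in kids:
            adj[node].add(k)
            adj[k].add(node)
        return node

    root = build(nested)
    if len(adj[root]) == 2:  # suppress the degree-2 root for an unrooted tree
        a, b = adj.pop(root)
        adj[a].remove(root)
        adj[b].remove(root)
        adj[a].add(b)
        adj[b].add(a)
    return UnrootedTree(n_leaves, adj, counter[0])


def all_topologies(n):
    """Every unrooted binary topology on n labelled leaves."""
    trees = [UnrootedTree.star(n)]
    for leaf in range(3, n):
        nxt = []
        for t in trees:
            for edge in t.edges():
                c = t.copy()
                c.attach_leaf(leaf, edge)
                nxt.append(c)
        trees = nxt
    return trees


def brute_force_min_changes(tree: UnrootedTree, leaf_states: np.ndarray) -> int:
    """Exhaustive minimum over all internal labelled histories (binary states)."""
    internals = sorted(v for v in tree.adj if v >= tree.n_leaves)
    edges = tree.edges()
    total = 0
    for c in range(leaf_states.shape[1]):
        best = np.inf
        for assign in itertools.product((0, 1), repeat=len(internals)):
            st = {i: leaf_states[i, c] for i in range(tree.n_leaves)}
            st.update(dict(zip(internals, assign)))
            best = min(best, sum(st[u] != st[v] for u, v in edges))
        total += int(best)
    return total


def _char_matrix(rows, labels):
    states = pd.DataFrame(
        [[BRAIN if v == 0 else OTHER for v in row] for row in rows],
        index=labels,
        columns=[f"c{j}" for j in range(len(rows[0]))],
    )
    return CharacterMatrix(states=states, classes=pd.Series("brain-low", index=states.columns))


# ---------------------------------------------------------------------------
# cohort fraction and percentile rules


class TestCohortFraction:
    def test_reference_cohort_composition(self):
        meta = pd.DataFrame({"is_brain": [True] * 40 + [False] * 101})
        p = cohort_fraction(meta)
        assert p == pytest.approx(40 / 141)
        assert round(p, 2) == 0.28

    def test_quarter_cohort(self):
        meta = pd.DataFrame({"is_brain": [True] * 25 + [False] * 75})
        assert cohort_fraction(meta) == 0.25

    def test_no_brain_samples_raises(self):
        with pytest.raises(ValueError, match="inapplicable"):
            cohort_fraction(pd.DataFrame({"is_brain": [False] * 10}))

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_fraction(pd.DataFrame({"is_brain": []}))


class TestClassify:
    def _flags(self, labels):
        return pd.Series([l.startswith("B") for l in labels], index=labels)

    def test_brain_zero_vs_others_high_is_brain_low(self):
        labels = [f"B{i}" for i in range(3)] + [f"O{i}" for i in range(7)]
        freqs = pd.Series([0.0] * 3 + [0.5] * 7, index=labels)
        assert classify_epihaplotype(freqs, self._flags(labels)) == "brain-low"

    def test_brain_high_vs_others_low_is_brain_high(self):
        labels = [f"B{i}" for i in range(3)] + [f"O{i}" for i in range(7)]
        freqs = pd.Series([0.9] * 3 + [0.1] * 7, index=labels)
        assert classify_epihaplotype(freqs, self._flags(labels)) == "brain-high"

    def test_constant_column_dropped(self):
        labels = ["B0", "O0", "O1"]
        freqs = pd.Series([0.4, 0.4, 0.4], index=labels)
        assert classify_epihaplotype(freqs, self._flags(labels)) is None

    def test_hand_computed_28th_percentile(self):
        # values 0..9: the 28th percentile with linear interpolation is
        # 0.28 * 9 = 2.52
        labels = [f"B{i}" for i in range(2)] + [f"O{i}" for i in range(8)]
        values = [2.0, 3.0] + [0.0, 1.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0]
        freqs = pd.Series(values, index=labels, dtype=float)
        assert np.percentile(values, 28) == pytest.approx(2.52)
        # brain median 2.5 <= 2.52 -> brain-low
        assert classify_epihaplotype(freqs, self._flags(labels)) == "brain-low"
        # shift brain values above the point -> brain-high
        # sorted values become [0,1,4,4,5,5,6,7,8,9]: the 28th percentile is 4.0
        freqs2 = freqs.copy()
        freqs2[["B0", "B1"]] = [4.0, 5.0]
        point = np.percentile(list(freqs2), 28)
        assert point == pytest.approx(4.0)
        assert np.median([4.0, 5.0]) > point
        assert classify_epihaplotype(freqs2, self._flags(labels)) == "brain-high"


class TestAssignSignatures:
    def test_strict_inequalities_at_percentile_points(self):
        labels = [f"S{i}" for i in range(10)]
        flags = pd.Series([i < 3 for i in range(10)], index=labels)
        values = np.array([0.0, 0.0, 0.1, 0.5, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        freq = pd.DataFrame({"low": values, "high": values[::-1]}, index=labels)
        cfg = SignatureConfig(0.28)
        chars = assign_signatures(freq, flags, cfg)
        low_point = np.percentile(values, 28)
        for lab, v in zip(labels, values):
            expected = BRAIN if v < low_point else OTHER
            assert chars.states.loc[lab, "low"] == expected
        # a sample sitting exactly on the high percentile point stays Other
        vals = np.arange(10, dtype=float)
        freq2 = pd.DataFrame({"h": vals}, index=labels)
        flags2 = pd.Series([i >= 7 for i in range(10)], index=labels)
        chars2 = assign_signatures(freq2, flags2, cfg)
        point = np.percentile(vals, 72)
        on_point = np.isclose(vals, point)
        if on_point.any():
            lab = labels[int(np.flatnonzero(on_point)[0])]
            assert chars2.states.loc[lab, "h"] == OTHER

    def test_toy_matrix_matches_direct_rule_evaluation(self):
        labels = [f"B{i}" for i in range(2)] + [f"O{i}" for i in range(4)]
        flags = pd.Series([True, True, False, False, False, False], index=labels)
        rng = np.random.default_rng(0)
        freq = pd.DataFrame(
            {
                "e1": [0.0, 0.02, 0.5, 0.6, 0.55, 0.45],
                "e2": [0.9, 0.8, 0.1, 0.2, 0.15, 0.12],
                "e3": rng.random(6),
            },
            index=labels,
        )
        cfg = SignatureConfig(0.28)
        chars = assign_signatures(freq, flags, cfg)
        for col in chars.states.columns:
            vals = freq[col].to_numpy()
            med_brain = np.median(vals[:2])
            low = np.percentile(vals, cfg.low_percentile)
            high = np.percentile(vals, cfg.high_percentile)
            if med_brain <= low:
                expected = np.where(vals < low, BRAIN, OTHER)
            else:
                expected = np.where(vals > high, BRAIN, OTHER)
            assert list(chars.states[col]) == list(expected)


# ---------------------------------------------------------------------------
# Fitch scoring


class TestFitch:
    def test_constant_character_costs_nothing(self):
        tree = unrooted_from_nested(((0, 1), (2, 3)), 4)
        chars = _char_matrix([[0], [0], [0], [0]], ["A1", "A2", "B1", "B2"])
        pt = PhyloTree(labels=["A1", "A2", "B1", "B2"], tree=tree, score=0)
        assert fitch_score(pt, chars) == 0

    def test_single_split_character_costs_one(self):
        tree = unrooted_from_nested(((0, 1), (2, 3)), 4)
        chars = _char_matrix([[0], [0], [1], [1]], ["A1", "A2", "B1", "B2"])
        pt = PhyloTree(labels=["A1", "A2", "B1", "B2"], tree=tree, score=0)
        assert fitch_score(pt, chars) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_history_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        states = rng.integers(0, 2, size=(n, 10))
        topos = all_topologies(n)
        tree = topos[int(rng.integers(0, len(topos)))]
        bits = np.where(states == 0, 1, 2).astype(np.uint8)
        assert fitch_score_tree(tree, bits) == brute_force_min_changes(tree, states)

    def test_invariant_under_leaf_relabelling(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 2, size=(6, 8))
        tree = all_topologies(6)[17]
        bits = np.where(states == 0, 1, 2).astype(np.uint8)
        base = fitch_score_tree(tree, bits)
        # rotating which leaf anchors the internal root must not change the score
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(6)
            relabel = {int(old): int(new) for new, old in enumerate(perm)}
            adj = {}
            for u, nbrs in tree.adj.items():
                uu = relabel.get(u, u)
                adj[uu] = {relabel.get(v, v) for v in nbrs}
            permuted = UnrootedTree(6, adj, tree._next_id)
            assert fitch_score_tree(permuted, bits[perm]) == base

    def test_missing_leaf_state_raises(self):
        tree = unrooted_from_nested(((0, 1), (2, 3)), 4)
        states = pd.DataFrame(
            [[BRAIN], [BRAIN], [OTHER], ["?"]], index=["A", "B", "C", "D"], columns=["c0"]
        )
        chars = CharacterMatrix(states=states, classes=pd.Series({"c0": "brain-low"}))
        pt = PhyloTree(labels=["A", "B", "C", "D"], tree=tree, score=0)
        with pytest.raises(ValueError, match="missing state"):
            fitch_score(pt, chars)


class TestRatchet:
    def test_four_taxa_reaches_exhaustive_optimum(self):
        rng = np.random.default_rng(3)
        states = rng.integers(0, 2, size=(4, 12))
        chars = _char_matrix(states, [f"s{i}" for i in range(4)])
        bits = np.where(states == 0, 1, 2).astype(np.uint8)
        best = min(fitch_score_tree(t, bits) for t in all_topologies(4))
        assert len(all_topologies(4)) == 3
        result = ratchet_search(chars, RatchetConfig(seed=5, iterations=10))
        assert result.score == best

    @pytest.mark.parametrize("seed", range(3))
    def test_small_instances_reach_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        states = rng.integers(0, 2, size=(n, 10))
        chars = _char_matrix(states, [f"s{i}" for i in range(n)])
        bits = np.where(states == 0, 1, 2).astype(np.uint8)
        best = min(fitch_score_tree(t, bits) for t in all_topologies(n))
        result = ratchet_search(chars, RatchetConfig(seed=seed, iterations=20))
        assert result.score == best

    def test_perfect_two_group_split_recovered_at_minimum_score(self):
        # every character changes exactly once on the true split
        labels = [f"B{i}" for i in range(4)] + [f"O{i}" for i in range(4)]
        states = np.array([[0] * 6] * 4 + [[1] * 6] * 4)
        chars = _char_matrix(states, labels)
        result = ratchet_search(chars, RatchetConfig(seed=2, iterations=5))
        assert result.score == 6
        assert contains_split(result, set(labels[:4]))

    def test_duplicate_rows_tolerated(self):
        labels = [f"s{i}" for i in range(5)]
        states = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
        chars = _char_matrix(states, labels)
        result = ratchet_search(chars, RatchetConfig(seed=1, iterations=5))
        bits = np.where(states == 0, 1, 2).astype(np.uint8)
        best = min(fitch_score_tree(t, bits) for t in all_topologies(5))
        assert result.score == best

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        states = rng.integers(0, 2, size=(7, 9))
        chars = _char_matrix(states, [f"s{i}" for i in range(7)])
        cfg = RatchetConfig(seed=4, iterations=10)
        a = ratchet_search(chars, cfg)
        b = ratchet_search(chars, cfg)
        assert a.score == b.score and a.splits() == b.splits()


class TestTopologyDistance:
    def test_identical_trees_have_zero_distance(self):
        tree = unrooted_from_nested(((0, 1), (2, (3, 4))), 5)
        labels = list("abcde")
        a = PhyloTree(labels=labels, tree=tree, score=0)
        rf, sym, n1, n2 = topology_distance(a, a)
        assert rf == 0.0 and sym == 0

    def test_maximally_different_five_taxon_trees(self):
        labels = list("abcde")
        # splits {ab},{de} vs {ac},{bd}: symmetric difference 4 = 2(n-3)
        t1 = PhyloTree(labels, unrooted_from_nested(((0, 1), (2, (3, 4))), 5), 0)
        t2 = PhyloTree(labels, unrooted_from_nested(((0, 2), (4, (1, 3))), 5), 0)
        assert t1.splits() != t2.splits()
        rf, sym, n1, n2 = topology_distance(t1, t2)
        assert rf == 1.0 and sym == 4

    def test_distance_is_symmetric(self):
        labels = list("abcdef")
        t1 = PhyloTree(labels, unrooted_from_nested(((0, 1), ((2, 3), (4, 5))), 6), 0)
        t2 = PhyloTree(labels, unrooted_from_nested(((0, 5), ((2, 1), (4, 3))), 6), 0)
        assert topology_distance(t1, t2)[0] == topology_distance(t2, t1)[0]

    def test_mismatched_leaf_sets_raise(self):
        t1 = PhyloTree(list("abcd"), unrooted_from_nested(((0, 1), (2, 3)), 4), 0)
        t2 = PhyloTree(list("abcx"), unrooted_from_nested(((0, 1), (2, 3)), 4), 0)
        with pytest.raises(ValueError, match="leaf sets"):
            topology_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_dendropy_symmetric_difference(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(6)]
        topos = all_topologies(6)
        ta = topos[int(rng.integers(len(topos)))]
        tb = topos[int(rng.integers(len(topos)))]
        p1 = PhyloTree(labels, ta, 0)
        p2 = PhyloTree(labels, tb, 0)
        _, sym, _, _ = topology_distance(p1, p2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=p1.to_newick(), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=p2.to_newick(), schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        ref = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert sym == ref
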