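"""Parsimony analysis of brain/other epihaplotype signatures.

Each epihaplotype of a target is first classified, from its frequency
distribution across the tissue cohort, as *brain-low* (median frequency in
brain at or below the cohort's low percentile) or *brain-high* (median at or
above it). The percentile equals 100 times the brain fraction of the cohort
(e.g. 40 brain samples of 141 gives p = 0.28, hence the 28th and 72nd
percentiles). Samples then receive a binary character per epihaplotype:
``Brain`` when their frequency falls strictly below the low percentile point
(brain-low characters) or strictly above the high percentile point
(brain-high characters), ``Other`` otherwise.

Minimum-change (Fitch parsimony) trees over samples are searched with a
parsimony ratchet — alternating hill-climbing under reweighted and flat
character weights with nearest-neighbour-interchange moves — and their
topology is compared with the complete-linkage dendrogram by the normalised
Robinson-Foulds distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bcfdna.cluster_boot import ClusterTree
from bcfdna.targets import stable_hash

logger = logging.getLogger(__name__)

BRAIN, OTHER = "Brain", "Other"
_BITS = {BRAIN: 1, OTHER: 2}


@dataclass(frozen=True)
class SignatureConfig:
    """Percentile rule parameters; ``brain_cohort_fraction`` must be in (0, 0.5)."""

    brain_cohort_fraction: float = 0.28

    def __post_init__(self) -> None:
        if not 0.0 < self.brain_cohort_fraction < 0.5:
            raise ValueError("brain_cohort_fraction must be in (0, 0.5)")

    @property
    def low_percentile(self) -> float:
        return 100.0 * self.brain_cohort_fraction

    @property
    def high_percentile(self) -> float:
        return 100.0 * (1.0 - self.brain_cohort_fraction)


def cohort_fraction(metadata: pd.DataFrame) -> float:
    """Brain fraction of a cohort from per-sample ``is_brain`` flags.

    Raises when the cohort is empty or contains no brain sample (the
    two-sided percentile rule is then inapplicable).
    """
    if len(metadata) == 0:
        raise ValueError("empty cohort")
    n_brain = int(metadata["is_brain"].sum())
    if n_brain == 0:
        raise ValueError("cohort has no brain samples; percentile rule inapplicable")
    return n_brain / len(metadata)


def classify_epihaplotype(
    freqs: pd.Series, brain_flags: pd.Series, cfg: SignatureConfig = SignatureConfig()
) -> str | None:
    """Classify one epihaplotype as ``brain-low`` or ``brain-high``.

    The low-percentile point is computed over ALL samples with linear
    interpolation; the brain median is compared against it (ties resolve to
    brain-low with a warning). Returns ``None`` for columns constant across
    all samples (uninformative, dropped).
    """
    values = freqs.to_numpy(dtype=float)
    if np.all(values == values[0]):
        return None
    flags = brain_flags.reindex(freqs.index).to_numpy(dtype=bool)
    if not flags.any():
        raise ValueError("no brain samples")
    point = float(np.percentile(values, cfg.low_percentile))
    med_brain = float(np.median(values[flags]))
    if med_brain == point:
        logger.warning("epihaplotype median equals percentile point; classified brain-low")
        return "brain-low"
    return "brain-low" if med_brain < point else "brain-high"


@dataclass
class CharacterMatrix:
    """Binary Brain/Other states per sample (rows) and epihaplotype (columns)."""

    states: pd.DataFrame
    classes: pd.Series  # column -> "brain-low" | "brain-high"

    @property
    def labels(self) -> list[str]:
        return list(self.states.index)

    def leaf_bitsets(self) -> np.ndarray:
        """(n_samples, n_chars) uint8 Fitch state sets."""
        arr = self.states.to_numpy()
        return ((arr == BRAIN) * _BITS[BRAIN] + (arr == OTHER) * _BITS[OTHER]).astype(np.uint8)


def assign_signatures(
    freq: pd.DataFrame,
    brain_flags: pd.Series,
    cfg: SignatureConfig = SignatureConfig(),
) -> CharacterMatrix:
    """Build the Brain/Other character matrix from a frequency matrix.

    For brain-low epihaplotypes a sample is ``Brain`` iff its frequency lies
    strictly below the low percentile point; for brain-high ones iff it lies
    strictly above the high percentile point.
    """
    cols = {}
    classes = {}
    for hap in freq.columns:
        cls = classify_epihaplotype(freq[hap], brain_flags, cfg)
        if cls is None:
            continue
        vals = freq[hap].to_numpy(dtype=float)
        if cls == "brain-low":
            point = np.percentile(vals, cfg.low_percentile)
            brain = vals < point
        else:
            point = np.percentile(vals, cfg.high_percentile)
            brain = vals > point
        cols[hap] = np.where(brain, BRAIN, OTHER)
        classes[hap] = cls
    states = pd.DataFrame(cols, index=freq.index)
    return CharacterMatrix(states=states, classes=pd.Series(classes, dtype=object))


# ---------------------------------------------------------------------------
# unrooted trees


class UnrootedTree:
    """Unrooted binary tree over leaves 0..n-1 as an adjacency map."""

    __slots__ = ("n_leaves", "adj", "_next_id")

    def __init__(self, n_leaves: int, adj: dict[int, set[int]], next_id: int):
        self.n_leaves = n_leaves
        self.adj = adj
        self._next_id = next_id

    @classmethod
    def star(cls, n_total: int = 3) -> "UnrootedTree":
        """The unique topology on leaves {0, 1, 2}; internal node ids are
        allocated from ``n_total`` upward so that up to ``n_total`` leaves can
        be attached later without id collisions."""
        if n_total < 3:
            raise ValueError("need room for at least 3 leaves")
        center = n_total
        adj = {0: {center}, 1: {center}, 2: {center}, center: {0, 1, 2}}
        return cls(3, adj, n_total + 1)

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(
            self.n_leaves, {k: set(v) for k, v in self.adj.items()}, self._next_id
        )

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in self.edges()
            if u >= self.n_leaves and v >= self.n_leaves
        ]

    def attach_leaf(self, leaf: int, edge: tuple[int, int]) -> None:
        """Subdivide ``edge`` with a new internal node and hang ``leaf`` on it."""
        u, v = edge
        w = self._next_id
        self._next_id += 1
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.adj[u].add(w)
        self.adj[v].add(w)
        self.adj[w] = {u, v, leaf}
        self.adj.setdefault(leaf, set()).add(w)
        self.n_leaves = max(self.n_leaves, leaf + 1)

    def nni_neighbors(self, edge: tuple[int, int]):
        """The two NNI rearrangements across an internal edge."""
        u, v = edge
        a, b = sorted(self.adj[u] - {v})
        c, d = sorted(self.adj[v] - {u})
        # swap subtree b (attached to u) with c, then with d (attached to v)
        for y in (c, d):
            t = self.copy()
            t.adj[u].remove(b)
            t.adj[b].remove(u)
            t.adj[v].remove(y)
            t.adj[y].remove(v)
            t.adj[u].add(y)
            t.adj[y].add(u)
            t.adj[v].add(b)
            t.adj[b].add(v)
            yield t

    def splits(self, labels: list[str]) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised as the side not containing
        the first leaf label."""
        ref = labels[0]
        out: set[frozenset[str]] = set()
        for u, v in self.internal_edges():
            side = self._leaves_beyond(u, v)
            names = frozenset(labels[i] for i in side)
            if ref in names:
                names = frozenset(set(labels) - set(names))
            if 2 <= len(names) <= self.n_leaves - 2:
                out.add(names)
        return out

    def _leaves_beyond(self, away_from: int, start: int) -> list[int]:
        """Leaves on the ``start`` side of edge (away_from, start)."""
        seen = {away_from, start}
        stack = [start]
        leaves = []
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                leaves.append(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return leaves

    def postorder(self) -> list[tuple[int, int | None]]:
        """(node, parent) pairs in postorder, rooted on the edge at leaf 0."""
        root_nb = next(iter(self.adj[0]))
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int]] = [(root_nb, 0)]
        visit: list[tuple[int, int]] = []
        while stack:
            node, parent = stack.pop()
            visit.append((node, parent))
            for nb in self.adj[node]:
                if nb != parent:
                    stack.append((nb, node))
        for node, parent in reversed(visit):
            order.append((node, parent))
        return order

    def newick(self, labels: list[str]) -> str:
        root_nb = next(iter(self.adj[0]))

        def rec(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return labels[node]
            kids = [rec(nb, node) for nb in sorted(self.adj[node]) if nb != parent]
            return "(" + ",".join(kids) + ")"

        return f"({labels[0]},{rec(root_nb, 0)});"


def fitch_score_tree(
    tree: UnrootedTree, leaf_bitsets: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Weighted Fitch parsimony score of an unrooted binary tree.

    ``leaf_bitsets`` is (n_leaves, n_chars) with one bit per state. The tree
    is rooted on the edge adjacent to leaf 0; each empty child-intersection
    contributes that character's weight.
    """
    n_chars = leaf_bitsets.shape[1]
    w = np.ones(n_chars) if weights is None else weights
    sets: dict[int, np.ndarray] = {}
    changes = np.zeros(n_chars)
    for node, parent in tree.postorder():
        if node < tree.n_leaves:
            sets[node] = leaf_bitsets[node]
            continue
        kids = [nb for nb in tree.adj[node] if nb != parent]
        a, b = sets[kids[0]], sets[kids[1]]
        inter = a & b
        empty = inter == 0
        changes += empty
        sets[node] = np.where(empty, a | b, inter)
    # close the root edge with leaf 0
    root_nb = next(iter(tree.adj[0]))
    inter = sets[root_nb] & leaf_bitsets[0]
    changes += inter == 0
    return float((changes * w).sum())


@dataclass
class PhyloTree:
    """Search result: an unrooted tree over named samples plus its score."""

    labels: list[str]
    tree: UnrootedTree
    score: float

    def splits(self) -> set[frozenset[str]]:
        return self.tree.splits(self.labels)

    def to_newick(self) -> str:
        return self.tree.newick(self.labels)


def fitch_score(tree: PhyloTree, chars: CharacterMatrix) -> int:
    """Fitch parsimony score of a tree for a Brain/Other character matrix."""
    if set(tree.labels) != set(chars.labels):
        raise ValueError("tree leaves and character matrix samples differ")
    order = [chars.labels.index(lab) for lab in tree.labels]
    bits = chars.leaf_bitsets()[order]
    if (bits == 0).any():
        raise ValueError("leaf with missing state")
    return int(round(fitch_score_tree(tree.tree, bits)))


@dataclass(frozen=True)
class RatchetConfig:
    """Parsimony ratchet settings (seed mandatory)."""

    seed: int
    iterations: int = 50
    upweight_fraction: float = 0.25
    upweight_factor: float = 2.0


def _stepwise_addition(bits: np.ndarray, order: np.ndarray) -> UnrootedTree:
    """Greedy stepwise-addition start tree."""
    n = bits.shape[0]
    first3 = [int(order[0]), int(order[1]), int(order[2])]
    center = n
    adj = {first3[0]: {center}, first3[1]: {center}, first3[2]: {center},
           center: set(first3)}
    tree = UnrootedTree(n, adj, n + 1)
    for k in range(3, n):
        leaf = int(order[k])
        best_edge, best_score = None, np.inf
        for edge in tree.edges():
            trial = tree.copy()
            trial.attach_leaf(leaf, edge)
            s = fitch_score_tree(trial, bits)
            if s < best_score:
                best_score, best_edge = s, edge
        tree.attach_leaf(leaf, best_edge)
    return tree


def _hill_climb(
    tree: UnrootedTree, bits: np.ndarray, weights: np.ndarray | None
) -> tuple[UnrootedTree, float]:
    score = fitch_score_tree(tree, bits, weights)
    improved = True
    while improved:
        improved = False
        for edge in tree.internal_edges():
            for nb in tree.nni_neighbors(edge):
                s = fitch_score_tree(nb, bits, weights)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
            if improved:
                break
    return tree, score


def ratchet_search(chars: CharacterMatrix, cfg: RatchetConfig) -> PhyloTree:
    """Parsimony ratchet tree search over the character matrix samples.

    Alternates hill-climbing under randomly upweighted characters (25%
    doubled by default) with flat-weighted hill-climbing, keeping the best
    flat-weight score seen. Deterministic under a fixed seed. Requires at
    least 4 samples.
    """
    labels = chars.labels
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 samples for a tree search")
    bits = chars.leaf_bitsets()
    if bits.shape[1] == 0:
        raise ValueError("character matrix has no informative characters")
    rng = np.random.default_rng([cfg.seed, stable_hash("parsimony-ratchet")])
    tree = _stepwise_addition(bits, np.arange(n))
    tree, best_score = _hill_climb(tree, bits, None)
    best_tree = tree
    n_chars = bits.shape[1]
    for _ in range(cfg.iterations):
        weights = np.ones(n_chars)
        k = max(1, int(round(cfg.upweight_fraction * n_chars)))
        up = rng.choice(n_chars, size=k, replace=False)
        weights[up] = cfg.upweight_factor
        t, _ = _hill_climb(best_tree.copy(), bits, weights)
        t, s = _hill_climb(t, bits, None)
        if s < best_score:
            best_tree, best_score = t, s
    return PhyloTree(labels=labels, tree=best_tree, score=best_score)


# ---------------------------------------------------------------------------
# topology comparison


def _splits_of(tree: "PhyloTree | ClusterTree") -> tuple[set[frozenset[str]], list[str]]:
    if isinstance(tree, PhyloTree):
        return tree.splits(), tree.labels
    # a rooted dendrogram, stripped of heights: its clades induce unrooted splits
    labels = tree.labels
    ref = labels[0]
    all_set = set(labels)
    out: set[frozenset[str]] = set()
    for fs in tree.clades():
        names = set(fs)
        if ref in names:
            names = all_set - names
        if 2 <= len(names) <= len(labels) - 2:
            out.add(frozenset(names))
    return out, labels


def topology_distance(t1, t2) -> tuple[float, int, int, int]:
    """Normalised Robinson-Foulds distance between two trees.

    Accepts :class:`PhyloTree` or :class:`~bcfdna.cluster_boot.ClusterTree`
    (dendrograms are stripped of heights). Returns ``(rf_normalised,
    n_sym_diff, n_splits_1, n_splits_2)`` with the symmetric difference
    normalised by ``2 (n - 3)``, the maximum for binary trees.
    """
    s1, l1 = _splits_of(t1)
    s2, l2 = _splits_of(t2)
    if set(l1) != set(l2):
        raise ValueError("trees have different leaf sets")
    n = len(l1)
    sym = len(s1 ^ s2)
    denom = 2 * (n - 3)
    rf = sym / denom if denom > 0 else 0.0
    return rf, sym, len(s1), len(s2)


def contains_split(tree, leafset: set[str] | frozenset[str]) -> bool:
    """Whether the tree contains the (unrooted) split defined by ``leafset``."""
    splits, labels = _splits_of(tree)
    names = set(leafset)
    if labels[0] in names:
        names = set(labels) - names
    return frozenset(names) in splits
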