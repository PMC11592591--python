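"""Tissue discrimination by hierarchical clustering with multiscale bootstrap.

Samples are clustered by the complete-linkage algorithm on Euclidean
distances between their epihaplotype frequency vectors. Cluster reliability
is assessed by multiscale bootstrap resampling: features (epihaplotypes) are
resampled with replacement at several dataset-size ratios r, the bootstrap
probability BP_r of each original cluster is recorded at every scale, and
the approximately unbiased (AU) support is obtained by extrapolation.

Writing z_r = Phi^-1(1 - BP_r), the multiscale model predicts
z_r ~ v * sqrt(r) + c / sqrt(r); v and c are fitted by weighted least
squares with binomial weights and AU = 1 - Phi(v - c). An AU value above
0.95 indicates a cluster strongly supported by the data, correcting the
known bias of the plain bootstrap probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import norm

from bcfdna.targets import stable_hash

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


@dataclass(frozen=True)
class BootConfig:
    """Multiscale bootstrap settings (2000 replicates per scale)."""

    n_boot: int = 2000
    scales: tuple[float, ...] = DEFAULT_SCALES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if any(r <= 0 for r in self.scales):
            raise ValueError("all scales must be > 0")


@dataclass
class ClusterTree:
    """Complete-linkage dendrogram with optional per-node AU/BP support.

    ``nodes`` has one row per internal node (in merge order): the leaf set,
    merge height, and — after :func:`multiscale_au` — bootstrap probability
    at scale ~1 and the AU value.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    nodes: pd.DataFrame

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def clades(self) -> list[frozenset[str]]:
        return [fs for fs in self.nodes["leafset"]]

    def has_clade(self, leafset: frozenset[str] | set[str]) -> bool:
        target = frozenset(leafset)
        return any(fs == target for fs in self.nodes["leafset"])

    def au_for(self, leafset: frozenset[str] | set[str]) -> float | None:
        target = frozenset(leafset)
        for _, row in self.nodes.iterrows():
            if row["leafset"] == target:
                return row.get("au", None)
        return None

    def to_newick(self) -> str:
        """Newick string with heights as branch lengths and AU/BP comments."""
        n = self.n_leaves
        Z = self.linkage_matrix
        heights = {i: 0.0 for i in range(n)}
        parts: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k in range(Z.shape[0]):
            a, b_, h = int(Z[k, 0]), int(Z[k, 1]), float(Z[k, 2])
            node = n + k
            la = h - heights[a]
            lb = h - heights[b_]
            comment = ""
            row = self.nodes.iloc[k]
            if "au" in self.nodes.columns and not pd.isna(row.get("au", np.nan)):
                comment = f"[&au={row['au']:.4f},bp={row['bp']:.4f}]"
            parts[node] = f"({parts[a]}:{la:.6g},{parts[b_]}:{lb:.6g}){comment}"
            heights[node] = h
        return parts[n + Z.shape[0] - 1] + ";"

    def node_table(self) -> pd.DataFrame:
        out = self.nodes.copy()
        out["leafset"] = out["leafset"].map(lambda fs: ",".join(sorted(fs)))
        return out


def _clade_masks(Z: np.ndarray, n: int) -> list[int]:
    """Leaf bitmask of every internal node, in merge order."""
    masks: list[int] = [1 << i for i in range(n)]
    out = []
    for k in range(Z.shape[0]):
        m = masks[int(Z[k, 0])] | masks[int(Z[k, 1])]
        masks.append(m)
        out.append(m)
    return out


def complete_linkage(freq: pd.DataFrame) -> ClusterTree:
    """Complete-linkage tree on Euclidean distances between frequency rows."""
    labels = list(freq.index)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate sample ids")
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    X = freq.to_numpy(dtype=float)
    Z = linkage(pdist(X), method="complete")
    masks = _clade_masks(Z, len(labels))
    leafsets = [
        frozenset(labels[i] for i in range(len(labels)) if m >> i & 1) for m in masks
    ]
    nodes = pd.DataFrame({"leafset": leafsets, "height": Z[:, 2]})
    return ClusterTree(labels=labels, linkage_matrix=Z, nodes=nodes)


def multiscale_au(freq: pd.DataFrame, cfg: BootConfig = BootConfig()) -> ClusterTree:
    """Complete-linkage tree with AU and BP support per internal node.

    At each scale r, ``n_boot`` feature-resampled datasets of size
    ``round(r * m)`` (columns drawn with replacement) are clustered and the
    fraction of replicate trees containing each original leaf set is
    recorded. Nodes recovered never (always) at every scale are pinned to
    AU = 0 (1); otherwise AU comes from the weighted probit extrapolation.
    Requires at least 3 samples and 2 features; when fewer than 3 scales
    yield informative BP values the AU falls back to the plain bootstrap
    probability with a warning.
    """
    if freq.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if freq.shape[1] < 2:
        raise ValueError("need at least 2 features")
    tree = complete_linkage(freq)
    X = freq.to_numpy(dtype=float)
    n, m = X.shape
    orig_masks = _clade_masks(tree.linkage_matrix, n)
    mask_index = {mk: i for i, mk in enumerate(orig_masks)}
    rng = np.random.default_rng([cfg.seed, stable_hash("multiscale-bootstrap")])

    scales = np.asarray(cfg.scales, dtype=float)
    counts = np.zeros((len(scales), len(orig_masks)), dtype=np.int64)
    for si, r in enumerate(scales):
        m_r = max(2, int(round(r * m)))
        for _ in range(cfg.n_boot):
            cols = rng.integers(0, m, size=m_r)
            Zb = linkage(pdist(X[:, cols]), method="complete")
            for mk in _clade_masks(Zb, n):
                j = mask_index.get(mk)
                if j is not None:
                    counts[si, j] += 1

    bp = counts / cfg.n_boot
    eps = 1.0 / (cfg.n_boot + 1)
    au = np.empty(len(orig_masks))
    bp_unit = np.empty(len(orig_masks))
    # report BP at the scale closest to r = 1
    unit_scale = int(np.argmin(np.abs(scales - 1.0)))
    sqrt_r = np.sqrt(scales)
    for j in range(len(orig_masks)):
        bpj = bp[:, j]
        bp_unit[j] = bpj[unit_scale]
        if np.all(bpj >= 1.0):
            au[j] = 1.0
            continue
        if np.all(bpj <= 0.0):
            au[j] = 0.0
            continue
        clipped = np.clip(bpj, eps, 1.0 - eps)
        informative = (bpj > 0.0) & (bpj < 1.0)
        if informative.sum() < 3:
            logger.warning(
                "multiscale_au: node %d has %d informative scales; AU falls back to BP",
                j, int(informative.sum()),
            )
            au[j] = bp_unit[j]
            continue
        z = norm.ppf(1.0 - clipped[informative])
        s = sqrt_r[informative]
        A = np.stack([s, 1.0 / s], axis=1)
        w = cfg.n_boot * norm.pdf(z) ** 2 / (clipped[informative] * (1.0 - clipped[informative]))
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * W[:, None], z * W, rcond=None)
        v, c = coef
        au[j] = float(1.0 - norm.cdf(v - c))

    tree.nodes["bp"] = bp_unit
    tree.nodes["au"] = au
    for si, r in enumerate(scales):
        tree.nodes[f"bp_r{r:g}"] = bp[si]
    return tree
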