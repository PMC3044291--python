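"""Pocket similarity (S_APF), distance (D_APF), and UPGMA clustering.

The optimal superposition energy E_APF ranks sites by similarity but is not
distance-like: it is unbounded and its self-pair value depends on site size
and composition.  It is therefore squashed to a normalized dot-product-like
similarity

    S_APF = tanh((E0 - E_APF) / Delta0),        E0 = -250, Delta0 = 100,

which approaches +1 for strongly similar pairs, and converted to a distance

    D_APF(A, B) = S_APF(A,A) + S_APF(B,B) - 2 S_APF(A,B),

which is zero for identical pairs and grows with dissimilarity.  E0 and
Delta0 are empirical, estimated from score distributions of identical and
random pocket pairs over a large site collection.  Distance matrices over a
set of sites feed UPGMA (average-linkage) clustering.

Note on orientation: with E_APF always negative for optimal superpositions
and E0 below typical self energies, the tanh argument must be (E0 - E_APF)
for D_APF to satisfy its contract (non-negative, increasing with
dissimilarity); the transform is antisymmetric, so an ``orientation=-1``
flag recovers the opposite sign convention if desired.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .apf_core import EnergyModel, apf_energy_direct
from ._seeds import stable_pair_seed
from .site_io import Site
from .superpose import MCConfig, Pose, monte_carlo_superpose

logger = logging.getLogger(__name__)

DEFAULT_E0 = -250.0
DEFAULT_DELTA0 = 100.0


@dataclass
class SimilarityParams:
    """Empirical normalization constants for the tanh similarity transform."""

    e0: float = DEFAULT_E0
    delta0: float = DEFAULT_DELTA0
    orientation: int = 1  # +1: similar pairs -> +1; -1: printed-sign variant

    def __post_init__(self) -> None:
        if self.delta0 <= 0:
            raise ValueError("delta0 must be positive")
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")


def s_apf(e_apf: float, params: SimilarityParams | None = None) -> float:
    """Normalized similarity in (-1, 1); decreasing in e_apf by default."""
    params = params or SimilarityParams()
    return math.tanh(params.orientation * (params.e0 - e_apf) / params.delta0)


def d_apf(
    s_aa: float, s_bb: float, s_ab: float, *, floor: bool = True
) -> float:
    """Distance from self- and cross-similarities; zero for identical pairs."""
    value = s_aa + s_bb - 2.0 * s_ab
    if value < 0 and floor:
        if value < -1e-9:
            logger.info("negative distance %.3g floored to 0", value)
        return 0.0
    return value


def self_energy(site: Site, model: EnergyModel | None = None) -> float:
    """Deterministic E_APF of a site against itself at the identity pose."""
    model = model or EnergyModel()
    return apf_energy_direct(site, site, Pose(center=site.centroid), model)


@dataclass
class PairResult:
    distance: float
    e_ab: float  # symmetrized cross energy
    e_aa: float
    e_bb: float
    e_directed: tuple[float, float]  # (A as template, B as template)


def pair_distance(
    site_a: Site,
    site_b: Site,
    config: MCConfig | None = None,
    model: EnergyModel | None = None,
    params: SimilarityParams | None = None,
    *,
    full_result: bool = False,
):
    """D_APF between two sites.

    Self-similarities come from the exact identity-pose energies (no
    sampling noise).  The cross term is the mean of the two directed
    Monte-Carlo optima (each site once as the grid template), making the
    distance exactly symmetric; the per-direction seeds are derived from
    the master seed and the ordered label pair.
    """
    config = config or MCConfig()
    model = model or EnergyModel()
    params = params or SimilarityParams()
    label_a = site_a.source_id or "A"
    label_b = site_b.source_id or "B"
    if label_a > label_b:
        return pair_distance(
            site_b, site_a, config, model, params, full_result=full_result
        )
    directed = []
    for template, probe, tag in (
        (site_a, site_b, f"{label_a}>{label_b}"),
        (site_b, site_a, f"{label_b}>{label_a}"),
    ):
        cfg = MCConfig(**{**config.__dict__,
                          "seed": stable_pair_seed(config.seed, tag)})
        directed.append(monte_carlo_superpose(template, probe, cfg, model).e_apf)
    e_ab = 0.5 * (directed[0] + directed[1])
    e_aa = self_energy(site_a, model)
    e_bb = self_energy(site_b, model)
    distance = d_apf(
        s_apf(e_aa, params), s_apf(e_bb, params), s_apf(e_ab, params)
    )
    if full_result:
        return PairResult(distance, e_ab, e_aa, e_bb, tuple(directed))
    return distance


@dataclass
class DistanceMatrix:
    """Symmetric D_APF matrix over labeled sites."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label=""
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy())

    def to_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.labels)}"]
        for label, row in zip(self.labels, self.values):
            lines.append(
                f"{label:<10s} " + " ".join(f"{v:.6f}" for v in row)
            )
        Path(path).write_text("\n".join(lines) + "\n")


def distance_matrix(
    sites: list[Site],
    config: MCConfig | None = None,
    model: EnergyModel | None = None,
    params: SimilarityParams | None = None,
    cache_dir: str | Path | None = None,
) -> DistanceMatrix:
    """All-vs-all D_APF over labeled sites.

    Per-pair seeds derive deterministically from the master seed and the
    label pair, so the matrix is reproducible and resumable: with
    ``cache_dir`` each finished pair is stored as JSON and reused.
    """
    labels = [s.source_id for s in sites]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate site labels")
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    n = len(sites)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cache_file = None
            if cache_dir is not None:
                key = "__".join(sorted([labels[i], labels[j]]))
                cache_file = cache_dir / f"{key}.json"
                if cache_file.exists():
                    values[i, j] = values[j, i] = json.loads(
                        cache_file.read_text()
                    )["distance"]
                    continue
            d = pair_distance(sites[i], sites[j], config, model, params)
            values[i, j] = values[j, i] = d
            if cache_file is not None:
                cache_file.write_text(json.dumps({"distance": d}))
    return DistanceMatrix(labels=labels, values=values)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class ClusterNode:
    height: float
    label: str | None = None  # leaves only
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class ClusterTree:
    """Rooted ultrametric tree from UPGMA; node heights are merge heights."""

    root: ClusterNode
    labels: list[str]

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    def merge_heights(self) -> list[float]:
        heights: list[float] = []

        def walk(node: ClusterNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return sorted(heights)

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (twice the LCA merge height)."""
        labels = self.leaf_order()
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        values = np.zeros((n, n))

        def walk(node: ClusterNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    values[index[a], index[b]] = 2.0 * node.height
                    values[index[b], index[a]] = 2.0 * node.height
            return left + right

        walk(self.root)
        return DistanceMatrix(labels=labels, values=values)

    def deepest_split(self) -> tuple[list[str], list[str]]:
        """Leaf partition defined by the root (the last, deepest merge)."""
        if self.root.is_leaf:
            raise ValueError("tree has a single leaf")
        return (self.root.children[0].leaves(), self.root.children[1].leaves())

    def to_newick(self) -> str:
        """Newick string with branch lengths (height differences)."""
        from skbio import TreeNode  # deferred: heavy import

        def convert(node: ClusterNode, parent_height: float) -> TreeNode:
            length = parent_height - node.height
            if node.is_leaf:
                return TreeNode(name=node.label, length=length)
            return TreeNode(
                length=length,
                children=[convert(c, node.height) for c in node.children],
            )

        tree = TreeNode(
            children=[convert(c, self.root.height) for c in self.root.children]
        )
        return str(tree).strip()


def upgma(matrix: DistanceMatrix) -> ClusterTree:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Repeatedly merges the closest pair of clusters; the distance from the
    merged cluster to any other is the size-weighted mean of its parts,
    and the merge height is half the merge distance.  Ties break on the
    lexicographically smallest (representative) label pair, making the
    tree fully deterministic.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    # cluster id -> (node, size, representative label)
    clusters: dict[int, tuple[ClusterNode, int, str]] = {
        i: (ClusterNode(height=0.0, label=lab), 1, lab)
        for i, lab in enumerate(matrix.labels)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(matrix.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best_key = min(
            dist,
            key=lambda k: (
                dist[k],
                tuple(sorted(clusters[i][2] for i in k)),
            ),
        )
        i, j = sorted(best_key)
        d_merge = dist[best_key]
        node_i, size_i, rep_i = clusters[i]
        node_j, size_j, rep_j = clusters[j]
        # put the lexicographically smaller representative on the left
        if rep_j < rep_i:
            node_i, node_j = node_j, node_i
            rep_i, rep_j = rep_j, rep_i
        merged = ClusterNode(height=d_merge / 2.0, children=(node_i, node_j))
        for k in list(clusters):
            if k in (i, j):
                continue
            d_new = (
                size_i * dist[frozenset((i, k))]
                + size_j * dist[frozenset((j, k))]
            ) / (size_i + size_j)
            dist[frozenset((next_id, k))] = d_new
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del clusters[i], clusters[j]
        clusters[next_id] = (merged, size_i + size_j, min(rep_i, rep_j))
        next_id += 1
    (root, _, _), = clusters.values()
    return ClusterTree(root=root, labels=list(matrix.labels))


def tree_leaf_order(tree: ClusterTree) -> list[str]:
    """Left-to-right leaf order, for heat-map row/column ordering."""
    return tree.leaf_order()
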