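"""Descriptor matching: Euclidean distance, ratio test, KD-tree with
Best-Bin-First search.

Each descriptor in image A is matched to its two nearest neighbours in image
B; the match is accepted when the distance ratio r = d_min / d_min2 falls
below the threshold eta (0.44 by default).  The neighbour search is either
exact brute force or an in-package KD tree traversed Best-Bin-First: nodes
are expanded in order of their lower-bound distance to the query, and the
search stops after a fixed number of leaf examinations, trading exactness for
speed on the 128-dimensional descriptors.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MatchConfig",
    "MatchPair",
    "euclidean_distance",
    "ratio_test",
    "KDTree",
    "build_kdtree",
    "bbf_nearest2",
    "match_images",
    "reverse_match_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchConfig:
    ratio_threshold: float = 0.44
    bbf_max_checks: int = 200
    search_mode: str = "kdtree_bbf"  # or "brute_force"
    mutual: bool = True              # resolve many-to-one collisions

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_threshold < 1.0:
            raise ValueError("ratio_threshold must lie in (0, 1)")
        if self.bbf_max_checks < 1:
            raise ValueError("bbf_max_checks must be >= 1")
        if self.search_mode not in ("brute_force", "kdtree_bbf"):
            raise ValueError(f"unknown search mode {self.search_mode!r}")


@dataclass(frozen=True)
class MatchPair:
    """Accepted correspondence with its two neighbour distances and ratio."""

    index_a: int
    index_b: int
    d_min: float
    d_min2: float
    r: float


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal dimension")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def ratio_test(d_min: float, d_min2: float, eta: float = 0.44) -> bool:
    """Success iff d_min / d_min2 < eta.

    d_min = d_min2 = 0 is an ambiguous duplicate and counts as failure.
    """
    if d_min2 == 0:
        if d_min == 0:
            logger.debug("ambiguous duplicate: both neighbour distances zero")
        return False
    return d_min / d_min2 < eta


class _Leaf:
    __slots__ = ("indices",)

    def __init__(self, indices: np.ndarray) -> None:
        self.indices = indices


class _Node:
    __slots__ = ("dim", "value", "left", "right")

    def __init__(self, dim: int, value: float, left, right) -> None:
        self.dim = dim
        self.value = value
        self.left = left
        self.right = right


class KDTree:
    """Balanced KD tree: median splits on the highest-variance dimension.

    Leaves hold buckets of up to ``leaf_size`` descriptor ids; one BBF
    "check" examines one bucket.  Bucketed leaves are the standard operating
    point for high-dimensional descriptor search (distance evaluation
    vectorises over the bucket).
    """

    def __init__(self, data: np.ndarray, leaf_size: int = 8) -> None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] == 0:
            raise ValueError("need a nonempty (n, k) descriptor array")
        self.data = data
        self.leaf_size = leaf_size
        self.root = self._build(np.arange(data.shape[0]))

    def _build(self, indices: np.ndarray):
        if len(indices) <= self.leaf_size:
            return _Leaf(indices)
        sub = self.data[indices]
        dim = int(np.argmax(sub.var(axis=0)))
        order = np.argsort(sub[:, dim], kind="stable")
        mid = len(indices) // 2
        value = float(sub[order[mid], dim])
        left = indices[order[:mid]]
        right = indices[order[mid:]]
        if len(left) == 0:  # all values identical along dim
            return _Leaf(indices)
        return _Node(dim, value, self._build(left), self._build(right))

    def depth(self) -> int:
        def _d(node):
            if isinstance(node, _Leaf):
                return 1
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def query2_bbf(self, query: np.ndarray, max_checks: int):
        """Two nearest distinct neighbours by Best-Bin-First traversal.

        Nodes are popped from a priority queue keyed by the lower-bound
        distance of their cell to the query; descent to a leaf follows the
        query side while pushing the far child with its updated bound.  The
        search stops after ``max_checks`` leaf examinations or when the best
        bound exceeds the current second-best distance (at which point the
        result is exact).  Returns (d_min, d_min2, idx_min, idx_min2), with
        d_min2 = inf when only one point exists.
        """
        query = np.asarray(query, dtype=float)
        best = [(np.inf, -1), (np.inf, -1)]  # (distance, index), sorted
        counter = itertools.count()
        # heap entries carry the per-dimension offsets of their cell so the
        # bound stays a tight lower bound even when a dimension splits twice
        heap = [(0.0, next(counter), self.root, {})]
        checks = 0
        while heap and checks < max_checks:
            bound_sq, _, node, offsets = heapq.heappop(heap)
            if np.sqrt(bound_sq) >= best[1][0]:
                break  # exact: no remaining cell can improve the result
            while isinstance(node, _Node):
                diff = query[node.dim] - node.value
                if diff < 0:
                    near, far = node.left, node.right
                else:
                    near, far = node.right, node.left
                old = offsets.get(node.dim, 0.0)
                if abs(diff) > old:
                    far_offsets = dict(offsets)
                    far_offsets[node.dim] = abs(diff)
                    far_bound_sq = bound_sq - old * old + diff * diff
                else:
                    far_offsets = offsets
                    far_bound_sq = bound_sq
                heapq.heappush(heap, (far_bound_sq, next(counter), far, far_offsets))
                node = near
            checks += 1
            pts = self.data[node.indices]
            dists = np.sqrt(((pts - query) ** 2).sum(axis=1))
            for dist, idx in zip(dists, node.indices):
                dist = float(dist)
                if dist < best[0][0]:
                    best = [(dist, int(idx)), best[0]]
                elif dist < best[1][0]:
                    best = [best[0], (dist, int(idx))]
        return best[0][0], best[1][0], best[0][1], best[1][1]


def build_kdtree(descriptors: np.ndarray) -> KDTree:
    """Build the BBF search tree over an (n, k) descriptor set."""
    return KDTree(descriptors)


def bbf_nearest2(tree: KDTree, query: np.ndarray, max_checks: int = 200):
    """Module-level convenience wrapper around :meth:`KDTree.query2_bbf`."""
    return tree.query2_bbf(query, max_checks)


def _two_nearest_brute(desc_a: np.ndarray, desc_b: np.ndarray):
    d = cdist(desc_a, desc_b)
    if desc_b.shape[0] == 1:
        i1 = np.zeros(desc_a.shape[0], dtype=int)
        return d[:, 0], np.full(desc_a.shape[0], np.inf), i1, np.full_like(i1, -1)
    idx = np.argpartition(d, 1, axis=1)[:, :2]
    row = np.arange(desc_a.shape[0])
    pair = d[row[:, None], idx]
    order = np.argsort(pair, axis=1, kind="stable")
    idx = idx[row[:, None], order]
    pair = pair[row[:, None], order]
    return pair[:, 0], pair[:, 1], idx[:, 0], idx[:, 1]


def match_images(
    desc_a: np.ndarray, desc_b: np.ndarray, cfg: MatchConfig | None = None
) -> list[MatchPair]:
    """Ratio-test matching of descriptor set A against B.

    With ``cfg.mutual`` (default) many-to-one collisions on B are resolved in
    favour of the smaller d_min (ties: lower index in A).
    """
    cfg = cfg or MatchConfig()
    desc_a = np.atleast_2d(np.asarray(desc_a, dtype=float))
    desc_b = np.atleast_2d(np.asarray(desc_b, dtype=float))
    if desc_a.shape[0] == 0 or desc_b.shape[0] == 0:
        raise ValueError("both descriptor sets must be nonempty")
    if desc_b.shape[0] < 2:
        logger.warning("fewer than 2 descriptors in B; no ratio test possible")
        return []

    if cfg.search_mode == "brute_force":
        d1, d2, i1, _ = _two_nearest_brute(desc_a, desc_b)
        results = list(zip(range(desc_a.shape[0]), d1, d2, i1))
    else:
        tree = build_kdtree(desc_b)
        results = []
        for ia, q in enumerate(desc_a):
            d_min, d_min2, i_min, _ = tree.query2_bbf(q, cfg.bbf_max_checks)
            results.append((ia, d_min, d_min2, i_min))

    accepted: list[MatchPair] = []
    for ia, d_min, d_min2, ib in results:
        d_min, d_min2 = float(d_min), float(d_min2)
        if ib < 0 or not np.isfinite(d_min2):
            continue
        if ratio_test(d_min, d_min2, cfg.ratio_threshold):
            accepted.append(MatchPair(int(ia), int(ib), d_min, d_min2,
                                      d_min / d_min2))
    if cfg.mutual:
        best: dict[int, MatchPair] = {}
        for pair in accepted:
            cur = best.get(pair.index_b)
            if cur is None or (pair.d_min, pair.index_a) < (cur.d_min, cur.index_a):
                best[pair.index_b] = pair
        accepted = sorted(best.values(), key=lambda p: p.index_a)
    return accepted


def reverse_match_check(
    desc_a: np.ndarray, desc_b: np.ndarray, cfg: MatchConfig | None = None
) -> tuple[int, int]:
    """Match counts in forward (A->B) and reverse (B->A) order.

    A well-behaved matcher is nearly symmetric: the two counts should agree
    to within a few percent on comparable frames.
    """
    forward = len(match_images(desc_a, desc_b, cfg))
    reverse = len(match_images(desc_b, desc_a, cfg))
    return forward, reverse
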