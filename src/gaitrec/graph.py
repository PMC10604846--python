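"""Skeleton joint graph with spatial-configuration partitioning.

The intraskeleton edge set is partitioned, per neighborhood, into K = 3
subsets relative to a root joint (the pelvis): the node itself, neighbors
closer to the root (centripetal) and neighbors further from the root
(centrifugal).  Each subset adjacency is normalized so the rows of the
summed adjacency sum to one, balancing neighbor contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .skeleton import JointSet

__all__ = ["JointGraph", "build_joint_graph"]


@dataclass(frozen=True)
class JointGraph:
    """Stacked ``K x N x N`` normalized adjacency with partition metadata."""

    adjacency: np.ndarray
    strategy: str
    temporal_kernel: int
    max_distance: int
    root: str

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.float64)
        object.__setattr__(self, "adjacency", A)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValidationError("adjacency must be K x N x N")
        if (A < 0).any():
            raise ValidationError("adjacency entries must be nonnegative")

    @property
    def n_subsets(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_joints(self) -> int:
        return self.adjacency.shape[1]


def _hop_distances(n: int, edges: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs hop distances by BFS; ``-1`` marks unreachable pairs."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full((n, n), -1, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0
        queue = [s]
        while queue:
            nxt: list[int] = []
            for u in queue:
                for v in adj[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = dist[s, u] + 1
                        nxt.append(v)
            queue = nxt
    return dist


def build_joint_graph(
    joints: JointSet,
    strategy: str = "spatial",
    temporal_kernel: int = 9,
    max_distance: int = 1,
    root: str = "pelvis",
) -> JointGraph:
    """Build the K-subset partitioned, degree-normalized joint graph.

    ``spatial`` strategy (K = 3): subset 0 holds self-loops, subset 1 holds
    edges toward the root joint (centripetal), subset 2 edges away from it
    (centrifugal).  ``uniform`` strategy (K = 1) lumps self plus neighbors.
    Each subset is divided row-wise by the degree of ``A + I`` so the summed
    normalized adjacency has unit row sums.
    """
    if strategy not in ("spatial", "uniform"):
        raise ValidationError(f"unknown partition strategy {strategy!r}")
    if max_distance < 1:
        raise ValidationError("max_distance must be >= 1")
    n = joints.n_joints
    edges = joints.bone_indices()
    dist = _hop_distances(n, edges)
    if (dist < 0).any():
        components = _components(n, edges)
        raise ValidationError(
            f"bone graph is disconnected; components: {components}"
        )
    root_idx = joints.role_index(root)
    hood = dist <= max_distance  # includes self (distance 0)

    degree = hood.sum(axis=1).astype(np.float64)  # row degree of A + I
    if strategy == "uniform":
        A = np.zeros((1, n, n))
        A[0] = hood / degree[:, None]
    else:
        A = np.zeros((3, n, n))
        d_root = dist[root_idx]
        for i in range(n):
            for j in range(n):
                if not hood[i, j]:
                    continue
                if i == j:
                    k = 0
                elif d_root[j] < d_root[i]:
                    k = 1  # centripetal: neighbor closer to root
                else:
                    k = 2  # centrifugal (includes equidistant neighbors)
                A[k, i, j] = 1.0 / degree[i]
    return JointGraph(
        adjacency=A,
        strategy=strategy,
        temporal_kernel=temporal_kernel,
        max_distance=max_distance,
        root=joints.role_name(root),
    )


def _components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())
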