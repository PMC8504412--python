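"""Vascular path distance along the centerline graph.

Every centerline voxel is assigned the shortest path length, in physical
millimeters, from user-selected seed voxels at the root of the vasculature
(in vivo: the most proximal voxel of each internal carotid artery). Path
length sums the Euclidean distance of each inter-voxel step, so a diagonal
step counts √2 (or √3) voxel spacings. With seeds in both carotids each
site obtains two candidate distances via the Circle of Willis; the shorter
is kept. Voxels with no path to any seed — spurs not connected to the
root — receive no distance and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from cerebropwv.centerline import ENDPOINT, CenterlineTree, _tree_from_voxels


@dataclass
class DistanceMap:
    """Per-centerline-voxel path distance from the root seed(s)."""

    distance_mm: np.ndarray  # NaN where unreachable
    seed_ids: np.ndarray  # index into the seed list; -1 where unreachable
    reachable: np.ndarray  # boolean

    def __post_init__(self) -> None:
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        self.seed_ids = np.asarray(self.seed_ids, dtype=int)
        self.reachable = np.asarray(self.reachable, dtype=bool)


def _seed_nodes(tree: CenterlineTree, seeds) -> list[int]:
    index = tree.voxel_index()
    nodes = []
    for s in seeds:
        key = tuple(int(v) for v in s)
        if key not in index:
            raise ValueError(f"seed {key} does not lie on the centerline")
        nodes.append(index[key])
    return nodes


def assign_distances(tree: CenterlineTree, seeds) -> DistanceMap:
    """Multi-source shortest-path distance over the centerline adjacency.

    Parameters
    ----------
    seeds : sequence of voxel coordinates
        Each seed must be a centerline voxel. Per voxel the minimum over
        seeds is kept, together with the identity of the winning seed.

    Raises
    ------
    ValueError
        If a seed is off the centerline or no voxel is reachable.
    """
    seed_nodes = _seed_nodes(tree, seeds)
    k = tree.n_voxels
    dist = np.full(k, np.nan)
    seed_ids = np.full(k, -1, dtype=int)
    for si, sn in enumerate(seed_nodes):
        lengths = nx.single_source_dijkstra_path_length(tree.graph, sn, weight="length_mm")
        for node, d in lengths.items():
            if np.isnan(dist[node]) or d < dist[node]:
                dist[node] = d
                seed_ids[node] = si
    reachable = ~np.isnan(dist)
    if not reachable.any():
        raise ValueError("no centerline voxel is reachable from the seeds")
    return DistanceMap(distance_mm=dist, seed_ids=seed_ids, reachable=reachable)


def main_routes_only(
    tree: CenterlineTree,
    distances: DistanceMap,
    seeds,
    endpoint_percentile: float = 75.0,
) -> CenterlineTree:
    """Keep only the main vascular routes from root to the deepest ends.

    Endpoints whose distance reaches at least the given percentile of all
    reachable endpoint distances are retained, and for each the unique
    shortest centerline path back to its nearest seed is kept; the tree is
    the union of these paths. This reproduces, programmatically, the
    control re-extraction that removes all smaller distal branches (and
    with them most false junctions from kissing vessels). Percentile 0
    keeps the route to every endpoint.
    """
    seed_nodes = _seed_nodes(tree, seeds)
    endpoints = [
        i
        for i in range(tree.n_voxels)
        if tree.node_kind[i] == ENDPOINT and distances.reachable[i]
    ]
    if not endpoints:
        raise ValueError("tree has no reachable endpoints")
    ep_dist = distances.distance_mm[endpoints]
    cutoff = np.percentile(ep_dist, endpoint_percentile)
    chosen = [e for e, d in zip(endpoints, ep_dist) if d >= cutoff]

    keep: set[int] = set(seed_nodes)
    paths_by_seed = {
        sn: nx.single_source_dijkstra(tree.graph, sn, weight="length_mm") for sn in seed_nodes
    }
    for e in chosen:
        best_seed = min(
            (sn for sn in seed_nodes if e in paths_by_seed[sn][0]),
            key=lambda sn: paths_by_seed[sn][0][e],
        )
        keep.update(paths_by_seed[best_seed][1][e])
    return _tree_from_voxels(tree.voxels[sorted(keep)], tree.voxel_size, shape=tree.shape)


def attach_distances(records, tree: CenterlineTree, distances: DistanceMap):
    """Fill ``distance_mm`` on cross-section records; drop unreachable ones."""
    index = tree.voxel_index()
    kept = []
    for r in records:
        node = index.get(r.center_voxel)
        if node is None or not distances.reachable[node]:
            continue
        r.distance_mm = float(distances.distance_mm[node])
        kept.append(r)
    return kept
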