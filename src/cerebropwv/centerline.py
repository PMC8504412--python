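"""Skeletonization and branch-labeled centerline trees.

The binary vessel mask is thinned to a one-voxel-wide skeleton
(topology-preserving 3D thinning), then organized into a tree: every
skeleton voxel is classified by its number of 26-connected skeleton
neighbors (1 → endpoint, 2 → interior, >= 3 → junction), and maximal
junction-free paths are labeled as branches. Junction voxels belong to no
branch; cross-sections are never placed on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from cerebropwv.angiography import VesselMask

ENDPOINT = 1
INTERIOR = 2
JUNCTION = 3

_KIND_NAMES = {ENDPOINT: "endpoint", INTERIOR: "interior", JUNCTION: "junction"}

# all 26 neighbor offsets
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=int,
)


class EmptyTreeError(ValueError):
    """Raised when an operation would leave the centerline tree empty."""


def skeletonize_mask(mask: VesselMask | np.ndarray) -> np.ndarray:
    """Thin the vessel mask to a one-voxel-wide medial skeleton.

    Uses topology-preserving 3D thinning, so connected components of the
    skeleton correspond one-to-one to components of the mask and thin
    (already one-voxel-wide) structures are returned unchanged.
    """
    arr = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask)
    arr = arr.astype(bool)
    if not arr.any():
        raise EmptyTreeError("cannot skeletonize an empty mask")
    return _sk_skeletonize(arr).astype(bool)


@dataclass
class CenterlineTree:
    """Branch-labeled skeleton with 26-connectivity adjacency.

    Attributes
    ----------
    voxels : ndarray, shape (K, 3) int
        Grid coordinates of the skeleton voxels.
    voxel_size : ndarray, shape (3,)
        Spacing in mm; physical coordinates are ``voxels * voxel_size``.
    graph : networkx.Graph
        Nodes are row indices into ``voxels``; edges join 26-neighbors and
        carry a ``length_mm`` attribute (the physical step length).
    branch_id : ndarray, shape (K,) int
        Branch label per voxel (1..B); 0 for junction voxels, which belong
        to no branch.
    node_kind : ndarray, shape (K,) int
        ENDPOINT (1), INTERIOR (2) or JUNCTION (3), from the 26-neighbor
        count. Isolated voxels are classed as endpoints.
    """

    voxels: np.ndarray
    voxel_size: np.ndarray
    graph: nx.Graph
    branch_id: np.ndarray
    node_kind: np.ndarray
    shape: tuple[int, int, int] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def coords_mm(self) -> np.ndarray:
        return self.voxels * self.voxel_size

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def n_branches(self) -> int:
        return int(self.branch_id.max()) if self.n_voxels else 0

    @property
    def n_junction_clusters(self) -> int:
        """Number of 26-connected clusters of junction voxels.

        Thinning can leave a junction as a small clump of mutually adjacent
        high-degree voxels; anatomically those form one bifurcation.
        """
        nodes = np.flatnonzero(self.node_kind == JUNCTION)
        if nodes.size == 0:
            return 0
        sub = self.graph.subgraph(nodes.tolist())
        return nx.number_connected_components(sub)

    def branch_nodes(self, branch: int) -> np.ndarray:
        return np.flatnonzero(self.branch_id == branch)

    def voxel_index(self) -> dict[tuple[int, int, int], int]:
        return {tuple(v): i for i, v in enumerate(self.voxels)}

    def to_label_volume(self, shape: tuple[int, int, int] | None = None) -> np.ndarray:
        """Render branch labels into a volume (0 = background)."""
        shape = shape or self.shape
        if shape is None:
            raise ValueError("grid shape unknown; pass shape=")
        out = np.zeros(shape, dtype=np.int32)
        out[tuple(self.voxels.T)] = self.branch_id
        return out

    def as_dataframe(self):
        import pandas as pd

        coords = self.coords_mm
        return pd.DataFrame(
            {
                "ix": self.voxels[:, 0],
                "iy": self.voxels[:, 1],
                "iz": self.voxels[:, 2],
                "x_mm": coords[:, 0],
                "y_mm": coords[:, 1],
                "z_mm": coords[:, 2],
                "branch_id": self.branch_id,
                "node_kind": [_KIND_NAMES[k] for k in self.node_kind],
            }
        )


def _adjacency_graph(voxels: np.ndarray, voxel_size: np.ndarray) -> nx.Graph:
    index = {tuple(v): i for i, v in enumerate(voxels)}
    g = nx.Graph()
    g.add_nodes_from(range(len(voxels)))
    step = np.asarray(voxel_size, dtype=float)
    for i, v in enumerate(voxels):
        for off in _OFFSETS:
            j = index.get((v[0] + off[0], v[1] + off[1], v[2] + off[2]))
            if j is not None and j > i:
                g.add_edge(i, j, length_mm=float(np.linalg.norm(off * step)))
    return g


def _classify_and_label(voxels: np.ndarray, graph: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    k = len(voxels)
    node_kind = np.empty(k, dtype=np.int8)
    for i in range(k):
        deg = graph.degree(i)
        node_kind[i] = JUNCTION if deg >= 3 else (INTERIOR if deg == 2 else ENDPOINT)
    branch_id = np.zeros(k, dtype=np.int64)
    non_junction = [i for i in range(k) if node_kind[i] != JUNCTION]
    label = 0
    for comp in nx.connected_components(graph.subgraph(non_junction)):
        label += 1
        for i in comp:
            branch_id[i] = label
    return branch_id, node_kind


def _tree_from_voxels(
    voxels: np.ndarray,
    voxel_size: np.ndarray,
    shape: tuple[int, int, int] | None = None,
) -> CenterlineTree:
    voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
    if len(voxels) == 0:
        raise EmptyTreeError("no centerline voxels")
    # canonical voxel order: independent of the caller's enumeration
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    voxels = voxels[order]
    voxel_size = np.asarray(voxel_size, dtype=float).reshape(3)
    graph = _adjacency_graph(voxels, voxel_size)
    branch_id, node_kind = _classify_and_label(voxels, graph)
    return CenterlineTree(
        voxels=voxels,
        voxel_size=voxel_size,
        graph=graph,
        branch_id=branch_id,
        node_kind=node_kind,
        shape=shape,
    )


def build_tree(
    skeleton: np.ndarray,
    voxel_size: np.ndarray | tuple[float, float, float],
    min_spur_len: int = 3,
) -> CenterlineTree:
    """Organize a skeleton into a branch-labeled centerline tree.

    Branches shorter than ``min_spur_len`` voxels that dangle from a
    junction (i.e. contain an endpoint) are pruned — these are thinning
    artifacts that would otherwise inject noisy cross-sections. Set
    ``min_spur_len=0`` to disable pruning.
    """
    skeleton = np.asarray(skeleton).astype(bool)
    voxels = np.argwhere(skeleton)
    if len(voxels) == 0:
        raise EmptyTreeError("empty skeleton")
    tree = _tree_from_voxels(voxels, voxel_size, shape=skeleton.shape)
    if min_spur_len > 0:
        tree = _prune_spurs(tree, min_spur_len)
    return tree


def _prune_spurs(tree: CenterlineTree, min_len: int) -> CenterlineTree:
    """Iteratively drop dangling branches of < ``min_len`` voxels."""
    while True:
        junction_nodes = set(np.flatnonzero(tree.node_kind == JUNCTION).tolist())
        drop: set[int] = set()
        for b in range(1, tree.n_branches + 1):
            nodes = tree.branch_nodes(b)
            if len(nodes) >= min_len:
                continue
            has_endpoint = any(tree.node_kind[n] == ENDPOINT for n in nodes)
            touches_junction = any(
                nb in junction_nodes for n in nodes for nb in tree.graph.neighbors(n)
            )
            if has_endpoint and touches_junction:
                drop.update(int(n) for n in nodes)
        if not drop:
            return tree
        keep = np.setdiff1d(np.arange(tree.n_voxels), np.fromiter(drop, dtype=int))
        if keep.size == 0:
            raise EmptyTreeError("spur pruning removed every voxel")
        tree = _tree_from_voxels(tree.voxels[keep], tree.voxel_size, shape=tree.shape)


def select_branches(
    tree: CenterlineTree,
    region: np.ndarray | list[int],
    mode: str = "remove",
    rule: str = "any",
) -> CenterlineTree:
    """Keep or remove branches by a spatial region or explicit branch ids.

    This is the programmatic counterpart of manually cutting away vessels
    of no interest (veins, posterior circulation) on projections.

    Parameters
    ----------
    region : 3D boolean array or list of branch ids
        Branches are tested for membership voxel-by-voxel when a mask is
        given.
    mode : {"remove", "keep"}
    rule : {"any", "all", "majority"}
        A branch is selected when any / all / the majority of its voxels
        fall inside the region mask.

    Junction voxels survive while they still connect at least two remaining
    arms; node kinds and branch labels are recomputed, so a former junction
    reduced to two neighbors becomes interior and its arms merge into one
    branch.
    """
    if mode not in ("remove", "keep"):
        raise ValueError("mode must be 'remove' or 'keep'")
    if rule not in ("any", "all", "majority"):
        raise ValueError("rule must be 'any', 'all' or 'majority'")

    n_branches = tree.n_branches
    if isinstance(region, np.ndarray) and region.dtype != object:
        region = np.asarray(region).astype(bool)
        selected = []
        for b in range(1, n_branches + 1):
            nodes = tree.branch_nodes(b)
            inside = region[tuple(tree.voxels[nodes].T)]
            hit = {"any": inside.any(), "all": inside.all(), "majority": inside.mean() > 0.5}[rule]
            if hit:
                selected.append(b)
        selected = set(selected)
    else:
        selected = set(int(b) for b in region)

    if mode == "remove":
        keep_branches = set(range(1, n_branches + 1)) - selected
    else:
        keep_branches = selected & set(range(1, n_branches + 1))

    keep_nodes = [i for i in range(tree.n_voxels) if tree.branch_id[i] in keep_branches]
    junction_nodes = [i for i in range(tree.n_voxels) if tree.node_kind[i] == JUNCTION]
    if not keep_nodes:
        raise EmptyTreeError("selection removed every branch")

    # junction voxels are retained only while they still attach >= 2 ways
    candidate = set(keep_nodes) | set(junction_nodes)
    sub = tree.graph.subgraph(candidate).copy()
    junction_set = set(junction_nodes)
    changed = True
    while changed:
        changed = False
        for n in list(sub.nodes):
            if n in junction_set and sub.degree(n) <= 1:
                sub.remove_node(n)
                changed = True

    if sub.number_of_nodes() == 0:
        raise EmptyTreeError("selection removed every voxel")
    return _tree_from_voxels(tree.voxels[sorted(sub.nodes)], tree.voxel_size, shape=tree.shape)
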