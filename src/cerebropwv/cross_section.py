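"""Cross-sectional lumen segmentation and velocity waveform extraction.

At every interior centerline voxel, the local vessel direction is estimated
from the three consecutive centerline voxels centered on it. A plane
perpendicular to that direction is resampled from the volumes (trilinear,
upsampled by a factor of two relative to the voxel grid), the lumen ROI is
segmented on the CD plane at 50% of the peak value within the vessel, and
the ROI-averaged velocity vector per cardiac frame is projected onto the
vessel direction to yield the raw velocity waveform. Waveforms are demeaned
and scaled by the reciprocal of their standard deviation; the weight of
each cross-section is W = area / scaling².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from cerebropwv.angiography import AngiogramVolume, FlowVolume4D
from cerebropwv.centerline import ENDPOINT, INTERIOR, JUNCTION, CenterlineTree


@dataclass
class CrossSectionRecord:
    """One sampling site on the centerline."""

    index: int
    center_voxel: tuple[int, int, int]
    branch_id: int
    direction: np.ndarray  # unit 3-vector
    roi_area_mm2: float
    raw_waveform: np.ndarray  # cm/s, length M
    waveform: np.ndarray  # normalized: mean 0, SD 1
    scaling: float  # 1 / SD of the demeaned raw waveform
    weight: float  # roi_area / scaling**2
    distance_mm: float = float("nan")  # filled by the distance stage
    meta: dict = field(default_factory=dict)


def local_direction(tree: CenterlineTree, node: int, ordered_branch: np.ndarray | None = None) -> np.ndarray:
    """Unit tangent at a centerline voxel from its two branch neighbors.

    The direction is the normalized physical-coordinate difference between
    the successor and predecessor voxels on the branch. Endpoints and
    junction voxels have no direction and raise ``ValueError``.
    """
    kind = tree.node_kind[node]
    if kind in (ENDPOINT, JUNCTION):
        raise ValueError("direction undefined at endpoints and junctions")
    if ordered_branch is not None:
        pos = int(np.flatnonzero(ordered_branch == node)[0])
        if pos == 0 or pos == len(ordered_branch) - 1:
            raise ValueError("voxel lacks a predecessor or successor on the branch")
        pred, succ = ordered_branch[pos - 1], ordered_branch[pos + 1]
    else:
        nbrs = [n for n in tree.graph.neighbors(node)]
        if len(nbrs) != 2:
            raise ValueError("interior voxel must have exactly two neighbors")
        pred, succ = nbrs
    d = (tree.voxels[succ] - tree.voxels[pred]) * tree.voxel_size
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("degenerate direction")
    return d / norm


def plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane axes completing ``direction``.

    The helper axis is the Cartesian axis least aligned with the
    direction; results downstream must be invariant to this choice.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(d)))] = 1.0
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _plane_sample_coords(
    center_voxel: np.ndarray,
    direction: np.ndarray,
    voxel_size: np.ndarray,
    half_width_mm: float,
    upsample: int,
) -> tuple[np.ndarray, float]:
    """Voxel-space sampling coordinates (3, n, n) for a perpendicular plane."""
    e1, e2 = plane_basis(direction)
    pitch = float(np.min(voxel_size)) / upsample
    n_half = int(round(half_width_mm / pitch))
    offs = (np.arange(-n_half, n_half + 1)) * pitch
    u, w = np.meshgrid(offs, offs, indexing="ij")
    center_mm = center_voxel * voxel_size
    pts_mm = (
        center_mm[None, None, :]
        + u[..., None] * e1[None, None, :]
        + w[..., None] * e2[None, None, :]
    )
    coords = (pts_mm / voxel_size).transpose(2, 0, 1)
    return coords, pitch


def extract_plane(
    volume: np.ndarray,
    center_voxel,
    direction,
    voxel_size,
    half_width_mm: float = 5.0,
    upsample: int = 2,
) -> tuple[np.ndarray, float]:
    """Resample a square plane orthogonal to ``direction``.

    Returns the 2D image and its pixel pitch in mm (voxel size divided by
    the upsampling factor). Trilinear interpolation; samples falling
    outside the volume are zero-filled with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    center_voxel = np.asarray(center_voxel, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float).reshape(3)
    if np.any(center_voxel < 0) or np.any(center_voxel > np.array(volume.shape) - 1):
        raise ValueError("plane center lies outside the volume")
    coords, pitch = _plane_sample_coords(center_voxel, np.asarray(direction, float), voxel_size, half_width_mm, upsample)
    outside = (coords < 0).any(axis=0) | (
        coords > (np.array(volume.shape, dtype=float) - 1)[:, None, None]
    ).any(axis=0)
    if outside.any():
        warnings.warn("cross-section plane clipped at the volume border", stacklevel=2)
    plane = ndimage.map_coordinates(volume, coords, order=1, mode="constant", cval=0.0)
    return plane, pitch


def segment_roi(
    cd_plane: np.ndarray,
    pitch_mm: float,
    threshold: float = 0.5,
    search_radius_mm: float = 3.0,
) -> tuple[np.ndarray, float] | None:
    """Segment the lumen on a CD cross-section plane.

    The peak is the maximum CD inside a search disk around the plane
    center ("the peak value within the vessel"); the ROI is the
    8-connected component at (or nearest to) the center among pixels at or
    above ``threshold`` x peak. Returns ``(mask, area_mm2)`` or ``None``
    when no lumen is found.
    """
    cd_plane = np.asarray(cd_plane, dtype=float)
    n = cd_plane.shape[0]
    c = n // 2
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rad2 = ((yy - c) ** 2 + (xx - c) ** 2) * pitch_mm**2
    disk = rad2 <= search_radius_mm**2
    peak = float(np.nanmax(np.where(disk, cd_plane, -np.inf)))
    if not np.isfinite(peak) or peak <= 0:
        return None
    mask = cd_plane >= threshold * peak
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    lab = labels[c, c]
    if lab == 0:
        # center not in any blob: take the nearest masked pixel inside the disk
        cand = mask & disk
        if not cand.any():
            return None
        idx = np.argwhere(cand)
        nearest = idx[np.argmin(((idx - c) ** 2).sum(axis=1))]
        lab = labels[tuple(nearest)]
    roi = labels == lab
    return roi, float(roi.sum()) * pitch_mm**2


def roi_waveform(
    flow: FlowVolume4D,
    coords: np.ndarray,
    roi: np.ndarray,
    direction: np.ndarray,
) -> np.ndarray:
    """ROI-averaged through-plane velocity per cardiac frame (cm/s).

    For each frame the three velocity components are sampled on the same
    plane geometry, averaged over the ROI pixels, and the resulting mean
    velocity vector is projected onto the vessel direction.
    """
    pts = coords[:, roi]  # (3, P)
    m = flow.n_frames
    out = np.empty(m)
    comps = (flow.vel_x, flow.vel_y, flow.vel_z)
    for j in range(m):
        v = np.array(
            [
                ndimage.map_coordinates(comp[..., j], pts, order=1, mode="constant", cval=0.0).mean()
                for comp in comps
            ]
        )
        out[j] = float(v @ direction)
    return out


def normalize_waveform(raw: np.ndarray) -> tuple[np.ndarray, float]:
    """Demean and scale by the reciprocal of the (population) SD.

    Returns ``(normalized, scaling)`` with ``scaling = 1/SD``. A flat
    waveform (SD = 0) raises ``ValueError`` — such cross-sections are
    discarded upstream.
    """
    raw = np.asarray(raw, dtype=float)
    sd = float(raw.std())  # population SD (divisor M)
    if sd == 0:
        raise ValueError("flat waveform: SD is zero")
    scaling = 1.0 / sd
    return (raw - raw.mean()) * scaling, scaling


def section_weight(roi_area_mm2: float, scaling: float) -> float:
    """W = area / scaling² — reciprocal-variance weight of a cross-section."""
    if roi_area_mm2 <= 0 or scaling <= 0:
        raise ValueError("area and scaling must be positive")
    return roi_area_mm2 / scaling**2


def _ordered_branch_paths(tree: CenterlineTree) -> dict[int, np.ndarray]:
    """Voxel order along each branch (path traversal from one branch end)."""
    paths: dict[int, np.ndarray] = {}
    for b in range(1, tree.n_branches + 1):
        nodes = tree.branch_nodes(b)
        sub = tree.graph.subgraph(nodes.tolist())
        ends = [n for n in sub.nodes if sub.degree(n) <= 1]
        start = min(ends) if ends else min(sub.nodes)  # cycles: arbitrary but fixed
        order = list(nx.dfs_preorder_nodes(sub, source=start))
        paths[b] = np.array(order, dtype=int)
    return paths


def extract_cross_sections(
    flow: FlowVolume4D,
    cd: AngiogramVolume,
    tree: CenterlineTree,
    half_width_mm: float = 5.0,
    upsample: int = 2,
    roi_threshold: float = 0.5,
    search_radius_mm: float = 3.0,
    junction_margin: int = 1,
) -> list[CrossSectionRecord]:
    """Extract a normalized velocity waveform at every eligible site.

    Sites are interior branch voxels; branch endpoints and voxels within
    ``junction_margin`` of a junction are skipped (junction exclusion, with
    a one-voxel guard against mixed-lumen ROIs). Cross-sections with an
    empty ROI or a flat waveform are discarded; the reasons are tallied in
    each run's log.

    The waveform sign is oriented along the net flow: if the temporal mean
    of the raw through-plane velocity is negative, the direction (and the
    waveform) is flipped. In an arterial tree net flow runs from the root
    outward, so this orients every direction away from the root.
    """
    junction_nodes = set(np.flatnonzero(tree.node_kind == JUNCTION).tolist())
    near_junction: set[int] = set(junction_nodes)
    for _ in range(junction_margin):
        grown = set(near_junction)
        for n in near_junction:
            grown.update(tree.graph.neighbors(n))
        near_junction = grown

    records: list[CrossSectionRecord] = []
    counts = {"sites": 0, "empty_roi": 0, "flat_waveform": 0, "kept": 0}
    paths = _ordered_branch_paths(tree)
    idx = 0
    for b, order in paths.items():
        for pos in range(1, len(order) - 1):
            node = int(order[pos])
            if node in near_junction or tree.node_kind[node] != INTERIOR:
                continue
            counts["sites"] += 1
            direction = local_direction(tree, node, ordered_branch=order)
            center = tree.voxels[node].astype(float)
            coords, pitch = _plane_sample_coords(
                center, direction, tree.voxel_size, half_width_mm, upsample
            )
            cd_plane = ndimage.map_coordinates(cd.cd, coords, order=1, mode="constant", cval=0.0)
            seg = segment_roi(cd_plane, pitch, threshold=roi_threshold, search_radius_mm=search_radius_mm)
            if seg is None:
                counts["empty_roi"] += 1
                continue
            roi, area = seg
            raw = roi_waveform(flow, coords, roi, direction)
            if raw.mean() < 0:  # orient along net flow (away from the root)
                direction = -direction
                raw = -raw
            try:
                normalized, scaling = normalize_waveform(raw)
            except ValueError:
                counts["flat_waveform"] += 1
                continue
            records.append(
                CrossSectionRecord(
                    index=idx,
                    center_voxel=tuple(int(v) for v in tree.voxels[node]),
                    branch_id=int(b),
                    direction=direction,
                    roi_area_mm2=area,
                    raw_waveform=raw,
                    waveform=normalized,
                    scaling=scaling,
                    weight=section_weight(area, scaling),
                )
            )
            counts["kept"] += 1
            idx += 1
    if records:
        records[0].meta["extraction_counts"] = counts
    return records


def records_to_frame(records: list[CrossSectionRecord]) -> pd.DataFrame:
    """Tabulate cross-section records (one row per site, M waveform columns)."""
    if not records:
        return pd.DataFrame()
    m = len(records[0].waveform)
    rows = []
    for r in records:
        row = {
            "index": r.index,
            "ix": r.center_voxel[0],
            "iy": r.center_voxel[1],
            "iz": r.center_voxel[2],
            "branch_id": r.branch_id,
            "area_mm2": r.roi_area_mm2,
            "scaling": r.scaling,
            "weight": r.weight,
            "distance_mm": r.distance_mm,
        }
        row.update({f"wf{j:02d}": r.waveform[j] for j in range(m)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_arrays(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a cross-section table into (waveforms, distances_mm, weights)."""
    wf_cols = sorted(c for c in frame.columns if c.startswith("wf"))
    waveforms = frame[wf_cols].to_numpy(dtype=float)
    return waveforms, frame["distance_mm"].to_numpy(dtype=float), frame["weight"].to_numpy(dtype=float)
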