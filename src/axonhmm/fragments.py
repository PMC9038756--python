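"""Fragment generation: micron-scale oriented supervoxels from a mask.

A connected component of the thresholded foreground is split into pieces no
larger than a ball of the configured radius (default 7 μm): centers are
greedily placed at the highest-probability uncovered voxel, a physical ball
is carved out around each, and the whole component is then partitioned by
nearest center.  Each retained piece becomes a Fragment carrying its two
endpoints (the geodesically farthest voxel pair) and outward unit tangents
(local PCA around each endpoint), and is simplified to the Bresenham
rasterisation of the straight segment between its endpoints — the voxel set
over which the appearance likelihood is later evaluated.

All distances are physical (μm), so the "ball" is an ellipsoid in index
space under anisotropic spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial import cKDTree

from .volume_io import ImageVolume, LabelVolume, voxel_to_physical

__all__ = [
    "Fragment",
    "threshold_probability",
    "split_component",
    "generate_fragments",
    "estimate_endpoints",
    "estimate_tangents",
    "bresenham_line",
    "fragments_to_label_volume",
    "fragments_to_table",
]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# offsets of the 26-neighbourhood, lexicographic
_NEIGHBOR_OFFSETS = np.array(
    [(di, dj, dk) for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1) if (di, dj, dk) != (0, 0, 0)]
)


@dataclass
class Fragment:
    """An oriented supervoxel: voxels, endpoints, tangents, simplified line.

    ``x0``/``x1`` are voxel centers in μm; ``tau0``/``tau1`` are unit vectors
    pointing *outward* (away from the fragment body) at each endpoint.
    ``line_voxels`` is the Bresenham chain between the endpoint voxels.
    """

    id: int
    voxels: np.ndarray  # (N, 3) int voxel indices
    x0: np.ndarray
    x1: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    line_voxels: np.ndarray  # (M, 3) int

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


class DegenerateFragmentError(ValueError):
    """Raised when a voxel set is too small to define endpoints."""


def threshold_probability(prob_map: ImageVolume, threshold: float = 0.9) -> LabelVolume:
    """Binarise a foreground-probability map: foreground iff p ≥ threshold.

    The default 0.9 is deliberately conservative — false-positive fragments
    are far more damaging to path search than severed ones, which the
    transition model can bridge.
    """
    data = np.asarray(prob_map.data, dtype=float)
    if data.size and (data.min() < 0 or data.max() > 1):
        raise ValueError("probability map values must lie in [0, 1]")
    mask = (data >= threshold).astype(np.uint8)
    return LabelVolume(data=mask, spacing=prob_map.spacing, origin=prob_map.origin)


def _lex_argmax(values: np.ndarray, coords: np.ndarray) -> int:
    """Index of the max value; ties broken by lexicographically smallest voxel."""
    best = np.flatnonzero(values == values.max())
    if len(best) == 1:
        return int(best[0])
    order = np.lexsort((coords[best, 2], coords[best, 1], coords[best, 0]))
    return int(best[order[0]])


def split_component(component_voxels, probabilities, spacing, radius: float = 7.0):
    """Split one connected component into ball-bounded pieces.

    Pass 1 repeatedly records the highest-probability uncovered voxel as a
    center and removes everything within ``radius`` μm of it; pass 2
    partitions the full component by nearest center.  The result is a
    partition whose pieces each fit in a ball of the given radius (diameter
    ≤ 2·radius).

    Parameters
    ----------
    component_voxels : (N, 3) int array of voxel indices.
    probabilities : length-N array of per-voxel foreground probabilities
        (or any seeding score, e.g. a distance transform for mask-only input).
    spacing : per-axis μm voxel size.
    radius : ball radius in μm (default 7).

    Returns
    -------
    list of (n_i, 3) int arrays forming a partition of ``component_voxels``.
    """
    voxels = np.asarray(component_voxels)
    if len(voxels) == 0:
        raise ValueError("component is empty")
    if radius <= 0:
        raise ValueError("radius must be positive")
    prob = np.asarray(probabilities, dtype=float)
    pos = voxels * np.asarray(spacing, dtype=float)

    centers = []
    uncovered = np.ones(len(voxels), dtype=bool)
    tree = cKDTree(pos)
    while uncovered.any():
        idx_unc = np.flatnonzero(uncovered)
        pick = idx_unc[_lex_argmax(prob[idx_unc], voxels[idx_unc])]
        centers.append(pick)
        within = tree.query_ball_point(pos[pick], r=radius)
        uncovered[within] = False

    center_pos = pos[np.asarray(centers)]
    ctree = cKDTree(center_pos)
    _, assign = ctree.query(pos)  # nearest center; ties -> lowest center index
    return [voxels[assign == c] for c in range(len(centers))]


def bresenham_line(p, q) -> np.ndarray:
    """3D Bresenham-style rasterisation of the segment p→q (voxel indices).

    One sample per unit step along the driving axis (the axis of largest
    range); the other coordinates are rounded to the nearest voxel of the
    continuous segment.  Includes both endpoints; consecutive voxels differ
    by at most 1 per axis.
    """
    p = np.asarray(p, dtype=np.int64)
    q = np.asarray(q, dtype=np.int64)
    delta = q - p
    n = int(np.abs(delta).max())
    if n == 0:
        return p[None, :].copy()
    t = np.arange(n + 1) / n
    cont = p[None, :] + t[:, None] * delta[None, :]
    vox = np.floor(cont + 0.5).astype(np.int64)  # half-up rounding, deterministic
    axis = int(np.abs(delta).argmax())
    vox[:, axis] = p[axis] + np.sign(delta[axis]) * np.arange(n + 1)
    return vox


def _adjacency(voxels: np.ndarray, spacing) -> coo_matrix:
    """Sparse 26-connectivity graph over a voxel set, edges weighted in μm."""
    spacing = np.asarray(spacing, dtype=float)
    index = {tuple(v): i for i, v in enumerate(voxels)}
    rows, cols, w = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        shifted = voxels + off
        dist = float(np.linalg.norm(off * spacing))
        for i, v in enumerate(shifted):
            j = index.get(tuple(v))
            if j is not None:
                rows.append(i)
                cols.append(j)
                w.append(dist)
    return coo_matrix((w, (rows, cols)), shape=(len(voxels), len(voxels)))


def estimate_endpoints(voxel_set, spacing, origin=(0.0, 0.0, 0.0)):
    """Endpoints of a fragment: the geodesically farthest voxel pair.

    Distances are physical-μm shortest paths in the fragment's
    26-connectivity graph.  Ties are broken by larger Euclidean separation,
    then by lexicographically smallest voxel index pair.  Orientation of the
    returned (x0, x1) is arbitrary — both orientations become states.
    """
    voxels = np.asarray(voxel_set)
    if len(voxels) < 2:
        raise DegenerateFragmentError("need at least 2 voxels to define endpoints")
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    voxels = voxels[order]
    graph = _adjacency(voxels, spacing)
    dist = shortest_path(graph, method="D", directed=False)
    finite = np.where(np.isfinite(dist), dist, -np.inf)
    best = np.argwhere(finite == finite.max())
    pos = voxels * np.asarray(spacing, dtype=float)
    # tie-break: max Euclidean, then lexicographic (voxels are lex-sorted)
    eud = np.linalg.norm(pos[best[:, 0]] - pos[best[:, 1]], axis=1)
    best = best[eud == eud.max()]
    i, j = min((tuple(sorted((int(a), int(b)))) for a, b in best))
    x0 = voxel_to_physical(voxels[i], spacing, origin)
    x1 = voxel_to_physical(voxels[j], spacing, origin)
    return x0, x1


def estimate_tangents(voxel_set, x0, x1, spacing, window: float = 3.0, origin=(0.0, 0.0, 0.0)):
    """Outward unit tangents at the two endpoints via local PCA.

    Each tangent is the first principal axis of the physical coordinates of
    the voxels within ``window`` μm of the endpoint, sign-flipped to point
    away from the fragment centroid.  A straight continuation across a gap
    then has zero discrete curvature under the transition energy.  Degenerate
    neighbourhoods fall back to the normalised (endpoint − centroid) vector.
    """
    voxels = np.asarray(voxel_set)
    pos = voxel_to_physical(voxels, spacing, origin)
    centroid = pos.mean(axis=0)

    def _tangent(endpoint):
        endpoint = np.asarray(endpoint, dtype=float)
        local = pos[np.linalg.norm(pos - endpoint, axis=1) <= window]
        fallback = endpoint - centroid
        if len(local) < 2 or np.linalg.norm(fallback) == 0:
            fallback = fallback if np.linalg.norm(fallback) > 0 else np.array([1.0, 0.0, 0.0])
            return fallback / np.linalg.norm(fallback)
        centered = local - local.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        tau = vt[0]
        if np.linalg.norm(tau) == 0:
            tau = fallback
        if np.dot(tau, endpoint - centroid) < 0:
            tau = -tau
        return tau / np.linalg.norm(tau)

    return _tangent(x0), _tangent(x1)


def generate_fragments(
    volume: ImageVolume,
    threshold: float | None = None,
    radius: float = 7.0,
    min_voxels: int = 5,
    tangent_window: float = 3.0,
) -> list[Fragment]:
    """Turn a binary mask or probability map into oriented fragments.

    If ``threshold`` is given the input is treated as a probability map and
    binarised first (and the probabilities seed the ball covering); a binary
    input is used as-is, with the Euclidean distance transform as the seeding
    score so that centers land on the medial axis.  Pieces smaller than
    ``min_voxels`` are discarded (too small for tangent estimation).
    """
    data = np.asarray(volume.data)
    if threshold is not None:
        mask_vol = threshold_probability(volume, threshold)
        mask = mask_vol.data.astype(bool)
        score_map = data.astype(float)
    else:
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("binary mask expected when no threshold is given")
        mask = data.astype(bool)
        score_map = ndimage.distance_transform_edt(mask, sampling=volume.spacing)

    if not mask.any():
        return []

    labels, n_comp = ndimage.label(mask, structure=_STRUCT_26)
    fragments: list[Fragment] = []
    n_discarded = 0
    objects = ndimage.find_objects(labels)
    for comp_id, sl in enumerate(objects, start=1):
        local = labels[sl] == comp_id
        offs = np.array([s.start for s in sl])
        comp_voxels = np.argwhere(local) + offs
        pieces = split_component(
            comp_voxels, score_map[tuple(comp_voxels.T)], volume.spacing, radius=radius
        )
        for piece in pieces:
            if len(piece) < min_voxels:
                n_discarded += 1
                continue
            x0, x1 = estimate_endpoints(piece, volume.spacing, volume.origin)
            tau0, tau1 = estimate_tangents(
                piece, x0, x1, volume.spacing, window=tangent_window, origin=volume.origin
            )
            p_vox = volume.physical_to_voxel(x0)
            q_vox = volume.physical_to_voxel(x1)
            line = bresenham_line(p_vox, q_vox)
            fragments.append(
                Fragment(
                    id=len(fragments),
                    voxels=piece,
                    x0=np.asarray(x0, float),
                    x1=np.asarray(x1, float),
                    tau0=np.asarray(tau0, float),
                    tau1=np.asarray(tau1, float),
                    line_voxels=line,
                )
            )
    logger.info(
        "generated %d fragments from %d components (%d sub-minimum pieces discarded)",
        len(fragments), n_comp, n_discarded,
    )
    return fragments


def fragments_to_label_volume(fragments, shape, spacing, origin=(0.0, 0.0, 0.0)) -> LabelVolume:
    """Render fragments as a label volume with value = fragment id + 1."""
    out = np.zeros(shape, dtype=np.int32)
    for frag in fragments:
        out[tuple(frag.voxels.T)] = frag.id + 1
    return LabelVolume(data=out, spacing=spacing, origin=origin)


def fragments_to_table(fragments) -> list[dict]:
    """Flat per-fragment records (id, endpoints, tangents, voxel count)."""
    rows = []
    for f in fragments:
        rows.append(
            {
                "id": f.id,
                "x0_x": f.x0[0], "x0_y": f.x0[1], "x0_z": f.x0[2],
                "x1_x": f.x1[0], "x1_y": f.x1[1], "x1_z": f.x1[2],
                "tau0_x": f.tau0[0], "tau0_y": f.tau0[1], "tau0_z": f.tau0[2],
                "tau1_x": f.tau1[0], "tau1_y": f.tau1[1], "tau1_z": f.tau1[2],
                "n_voxels": f.n_voxels,
            }
        )
    return rows
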