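"""Fixed start/end most-probable state sequences by shortest path.

With every edge weight non-negative (clipped appearance term plus
−log prior), the globally most probable nonrepeating state sequence from a
fixed start to a fixed terminal state is exactly the minimum-weight path in
the trellis, solved here with Dijkstra's algorithm.  The terminal state's
self-transition convention (a finished path may be padded with repeats of
the terminal state) changes nothing: repeats contribute weight only after
arrival, so the solver simply stops at the terminal.

The MAP estimator over the *full* image posterior involves likelihood
ratios α₁/α₀ that can exceed 1 and therefore negative cycles; the path
probability solved here drops the background factor precisely so the
problem stays well-posed.  ``brute_force_path`` enumerates all simple paths
and exists as the definitional oracle for small graphs.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .hmm_graph import TransitionGraph

__all__ = [
    "ReconstructionPath",
    "most_probable_path",
    "brute_force_path",
    "endpoint_states_from_points",
    "NoPathError",
    "NegativeWeightError",
]

logger = logging.getLogger(__name__)


class NoPathError(RuntimeError):
    """Raised when the terminal state cannot be reached from the start."""


class NegativeWeightError(RuntimeError):
    """A negative edge weight reached the solver: an upstream clip failed."""


class PathExplosionError(RuntimeError):
    """Brute-force enumeration exceeded its path budget."""


@dataclass
class ReconstructionPath:
    """A state sequence with its total weight and physical-space polyline.

    The polyline concatenates each visited state's (x0, x1) in order, so the
    curve runs entry→exit through every fragment on the path.
    """

    state_ids: list[int]
    total_weight: float
    polyline: np.ndarray  # (N, 3) μm

    def __len__(self) -> int:
        return len(self.state_ids)


def _assemble_polyline(graph: TransitionGraph, state_ids) -> np.ndarray:
    pts = []
    by_id = {s.id: s for s in graph.states}
    for sid in state_ids:
        s = by_id[sid]
        pts.append(np.asarray(s.x0, float))
        pts.append(np.asarray(s.x1, float))
    out = [pts[0]]
    for p in pts[1:]:
        if not np.array_equal(p, out[-1]):
            out.append(p)
    return np.asarray(out)


def _adjacency(graph: TransitionGraph):
    adj: dict[int, list[tuple[int, float]]] = {s.id: [] for s in graph.states}
    for (i, j), e in graph.edges.items():
        w = float(e["weight"])
        if w < 0:
            raise NegativeWeightError(
                f"edge {i}->{j} has negative weight {w}; the appearance clip invariant is violated"
            )
        adj[i].append((j, w))
    for lst in adj.values():
        lst.sort()
    return adj


def most_probable_path(graph: TransitionGraph, start: int, terminal: int) -> ReconstructionPath:
    """Minimum-weight (maximum-probability) path from start to terminal.

    Dijkstra with deterministic tie-breaking: ties in total weight are broken
    by fewer states, then by the lexicographically smallest id sequence.
    """
    ids = {s.id for s in graph.states}
    if start not in ids or terminal not in ids:
        raise KeyError(f"start/terminal state not in graph: {start}, {terminal}")
    if start == terminal:
        raise ValueError("start and terminal states must differ")
    adj = _adjacency(graph)

    # heap entries: (dist, n_states, id_sequence); first settle wins under
    # the tie rule because all three key components extend monotonically
    heap = [(0.0, 1, (start,))]
    settled: set[int] = set()
    while heap:
        dist, n, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == terminal:
            return ReconstructionPath(
                state_ids=list(path),
                total_weight=dist,
                polyline=_assemble_polyline(graph, path),
            )
        for succ, w in adj[node]:
            if succ not in settled:
                heapq.heappush(heap, (dist + w, n + 1, path + (succ,)))
    raise NoPathError(
        f"terminal state {terminal} unreachable from start {start} "
        f"(reachable set has {len(settled)} states)"
    )


def brute_force_path(
    graph: TransitionGraph, start: int, terminal: int, max_states: int = 12, max_paths: int = 10**6
) -> ReconstructionPath:
    """Exhaustive enumeration of simple paths — the definitional oracle.

    Enumerates every simple path of at most ``max_states`` states and returns
    the minimum-weight one under the same tie rule as the solver.  Intended
    for graphs of about a dozen states; a budget guard trips beyond
    ``max_paths`` enumerated paths.
    """
    adj = _adjacency(graph)
    best = None
    counter = 0

    def _extend(path, dist):
        nonlocal best, counter
        node = path[-1]
        if node == terminal:
            counter += 1
            if counter > max_paths:
                raise PathExplosionError(f"more than {max_paths} simple paths enumerated")
            key = (dist, len(path), path)
            if best is None or key < best:
                best = key
            return
        if len(path) >= max_states:
            return
        for succ, w in adj[node]:
            if succ not in path:
                _extend(path + (succ,), dist + w)

    _extend((start,), 0.0)
    if best is None:
        raise NoPathError(f"no simple path of <= {max_states} states from {start} to {terminal}")
    dist, _, path = best
    return ReconstructionPath(
        state_ids=list(path), total_weight=dist, polyline=_assemble_polyline(graph, path)
    )


def endpoint_states_from_points(
    graph: TransitionGraph, fragments, start_point, end_point, capture_radius: float = 10.0
):
    """Resolve two clicked physical points to (start id, terminal id).

    The start state is the orientation of the nearest fragment whose entry
    point x0 is closer to the click than its exit x1 (so the path travels
    away from the click); the terminal state analogously has x1 nearer the
    end click.  Equidistant fragments resolve to the lower fragment id.
    """
    start_point = np.asarray(start_point, float)
    end_point = np.asarray(end_point, float)

    def _nearest_fragment(point):
        best = None
        for f in fragments:
            d = min(np.linalg.norm(f.x0 - point), np.linalg.norm(f.x1 - point))
            if best is None or d < best[0] - 1e-12:
                best = (d, f)
        if best is None or best[0] > capture_radius:
            raise NoPathError(
                f"no fragment within {capture_radius} um of point {point.tolist()}"
            )
        return best[1]

    f_start = _nearest_fragment(start_point)
    f_end = _nearest_fragment(end_point)
    # forward state of fragment k has id 2k (x0=f.x0); reversed has id 2k+1
    if np.linalg.norm(f_start.x0 - start_point) <= np.linalg.norm(f_start.x1 - start_point):
        start_id = 2 * f_start.id
    else:
        start_id = 2 * f_start.id + 1
    if np.linalg.norm(f_end.x1 - end_point) <= np.linalg.norm(f_end.x0 - end_point):
        term_id = 2 * f_end.id
    else:
        term_id = 2 * f_end.id + 1
    return start_id, term_id
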