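"""Reconstruction accuracy metrics for non-branching neuron traces.

Two complementary distances between discrete curves P, Q ⊂ R³:

* the **discrete Fréchet distance** δ_dF — the minimum over monotone
  couplings of the maximum pointwise distance (the shortest dog leash that
  lets both walkers traverse their curves without backtracking); a metric on
  curves up to reparameterisation and a bound on the worst local deviation;
* the **spatial distance** SD — the symmetrised mean nearest-vertex
  distance, via the directed divergence DDIV(P, Q) = mean over p ∈ P of
  min_q |p − q|.

Both are vertex-set definitions, so curves are resampled to a uniform
(default 1 μm) arc-length step first; the vertex-vs-segment discrepancy is
then bounded by the step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Polyline",
    "resample_polyline",
    "discrete_frechet",
    "directed_divergence",
    "spatial_distance",
    "evaluate_pair",
]


@dataclass
class Polyline:
    """An ordered curve of 3D physical points (μm)."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("polyline points must be 3D")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("polyline contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _as_points(poly) -> np.ndarray:
    return poly.points if isinstance(poly, Polyline) else np.atleast_2d(np.asarray(poly, float))


def resample_polyline(polyline, step: float = 1.0) -> Polyline:
    """Arc-length-uniform linear resampling; endpoints preserved exactly.

    Consecutive output points are ``step`` μm apart except possibly the final
    segment (the remainder of the total length).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pts = _as_points(polyline)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to resample")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0:
        raise ValueError("cannot resample a zero-length polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, total, step)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    t = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    out = pts[idx] + t[:, None] * (pts[idx + 1] - pts[idx])
    out = np.vstack([out, pts[-1]])  # endpoint bit-exact
    out[0] = pts[0]
    return Polyline(points=out)


def discrete_frechet(P, Q) -> float:
    """Discrete Fréchet distance δ_dF(P, Q) in μm (Euclidean norm).

    Iterative dynamic program over the L_p × L_q grid:
    dp[i, j] = max(|P_i − Q_j|, min(dp[i−1, j], dp[i, j−1], dp[i−1, j−1])).
    """
    p = _as_points(P)
    q = _as_points(Q)
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both polylines must be nonempty")
    # pairwise distances row by row keeps memory at O(Lq)
    prev = None
    for i in range(len(p)):
        d = np.linalg.norm(q - p[i], axis=1)
        cur = np.empty(len(q))
        for j in range(len(q)):
            if i == 0 and j == 0:
                reach = 0.0
            elif i == 0:
                reach = cur[j - 1]
            elif j == 0:
                reach = prev[0]
            else:
                reach = min(prev[j], cur[j - 1], prev[j - 1])
            cur[j] = max(d[j], reach)
        prev = cur
    return float(prev[-1])


def directed_divergence(P, Q) -> float:
    """DDIV(P, Q): mean over vertices of P of the nearest-vertex distance to Q."""
    p = _as_points(P)
    q = _as_points(Q)
    if len(p) == 0 or len(q) == 0:
        raise ValueError("both polylines must be nonempty")
    d, _ = cKDTree(q).query(p)
    return float(np.mean(d))


def spatial_distance(P, Q) -> float:
    """SD(P, Q) = (DDIV(P, Q) + DDIV(Q, P)) / 2; symmetric by construction."""
    return 0.5 * (directed_divergence(P, Q) + directed_divergence(Q, P))


def evaluate_pair(P, Q, step: float = 1.0) -> dict[str, float]:
    """Resample both curves at ``step`` μm and report all metrics."""
    Pr = resample_polyline(P, step)
    Qr = resample_polyline(Q, step)
    return {
        "frechet_um": discrete_frechet(Pr, Qr),
        "ddiv_pq_um": directed_divergence(Pr, Qr),
        "ddiv_qp_um": directed_divergence(Qr, Pr),
        "sd_um": spatial_distance(Pr, Qr),
    }
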