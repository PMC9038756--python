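"""Directed trellis over oriented fragment states with HMM transition weights.

Each fragment yields two states, one per traversal direction (endpoints
swapped, tangents swapped and reversed).  A transition s→s′ carries a
Boltzmann prior

    p(s′|s) = exp(−U(s, s′)) / Z(s),
    U(s, s′) = α_d · |x⁰(s′) − x¹(s)|² + α_κ · κ(s, s′)²,

where the squared discrete curvature averages the two turning angles at the
gap: with τ_c the unit vector from x¹(s) to x⁰(s′), κ₁² = 1 − τ¹(s)·τ_c and
κ₂² = 1 − τ_c·(−τ⁰(s′)).  Transitions with a gap over ``d_max`` (15 μm) or
either turning angle over ``theta_max`` (150°) are pruned, as are
self-transitions (and the reverse of the same fragment, a zero-length
U-turn).  The edge weight combines the prior with the appearance data term:

    e(s, s′) = Σ_{v ∈ line(s′) ∪ gap(s,s′)} −log α₁(I_v) − log p(s′|s),

with α₁ clipped at 1 so every weight is non-negative and shortest-path
search is exact.  The gap voxels are the Bresenham rasterisation of the
segment bridging the two fragments ("imputed" voxels), which lets the path
probability see the image evidence inside dropout regions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .appearance import IntensityModel, eval_foreground
from .fragments import Fragment, bresenham_line
from .volume_io import ImageVolume

__all__ = [
    "State",
    "TransitionParams",
    "TransitionGraph",
    "build_states",
    "curvature_sq",
    "transition_energy",
    "allowed",
    "transition_log_prior",
    "imputed_gap",
    "edge_weight",
    "build_graph",
]

logger = logging.getLogger(__name__)


@dataclass
class State:
    """An oriented fragment: travel enters at ``x0`` and exits at ``x1``.

    ``sibling_id`` names the state for the opposite orientation of the same
    fragment (x0↔x1 swapped and the outward tangents swapped with them:
    tau0' = tau1, tau1' = tau0).  Tangents point *away* from the fragment at
    their endpoint, which is what makes the curvature formulas vanish for a
    straight continuation in either traversal direction.
    """

    id: int
    fragment_id: int
    x0: np.ndarray
    x1: np.ndarray
    tau0: np.ndarray
    tau1: np.ndarray
    sibling_id: int


@dataclass
class TransitionParams:
    """Hyperparameters of the transition prior and pruning rules.

    alpha_d : weight on squared gap distance, units 1/μm² (default 10).
    alpha_kappa : weight on mean squared discrete curvature, unitless
        (default 1000).  Both defaults are working values for sparse axons
        imaged at sub-micron resolution; denser neuropil calls for larger
        alpha_kappa relative to alpha_d.
    d_max : μm gap cutoff beyond which transitions get zero probability (15).
    theta_max : turning-angle cutoff in degrees (150).
    """

    alpha_d: float = 10.0
    alpha_kappa: float = 1000.0
    d_max: float = 15.0
    theta_max: float = 150.0

    def __post_init__(self):
        if self.alpha_d < 0 or self.alpha_kappa < 0:
            raise ValueError("energy weights must be nonnegative")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not (0 < self.theta_max <= 180):
            raise ValueError("theta_max must be in (0, 180]")


def build_states(fragments: list[Fragment]) -> list[State]:
    """Two states per fragment, one per orientation, ids dense from 0."""
    states: list[State] = []
    for f in fragments:
        fwd = State(
            id=2 * f.id, fragment_id=f.id,
            x0=f.x0, x1=f.x1, tau0=f.tau0, tau1=f.tau1,
            sibling_id=2 * f.id + 1,
        )
        rev = State(
            id=2 * f.id + 1, fragment_id=f.id,
            x0=f.x1, x1=f.x0, tau0=f.tau1, tau1=f.tau0,
            sibling_id=2 * f.id,
        )
        states.extend((fwd, rev))
    return states


def _gap_and_tau_c(s_prev: State, s_next: State, eps: float):
    gap_vec = np.asarray(s_next.x0, float) - np.asarray(s_prev.x1, float)
    gap = float(np.linalg.norm(gap_vec))
    if gap < eps:
        # below geometric resolution: the connector direction is undefined,
        # take it as the exit tangent (a seamless continuation)
        tau_c = np.asarray(s_prev.tau1, float)
    else:
        tau_c = gap_vec / gap
    return gap, tau_c


def curvature_sq(s_prev: State, s_next: State, eps: float = 0.0) -> float:
    """Mean squared discrete curvature of the connection s_prev → s_next.

    κ₁² = 1 − τ¹(prev)·τ_c penalises the turn leaving the previous fragment,
    κ₂² = 1 − τ_c·(−τ⁰(next)) the turn entering the next one; the returned
    value is their arithmetic mean.  Zero for a straight continuation.
    """
    _, tau_c = _gap_and_tau_c(s_prev, s_next, eps)
    k1 = 1.0 - float(np.dot(s_prev.tau1, tau_c))
    k2 = 1.0 - float(np.dot(tau_c, -np.asarray(s_next.tau0, float)))
    return 0.5 * (k1 + k2)


def transition_energy(s_prev: State, s_next: State, params: TransitionParams, eps: float = 0.0) -> float:
    """U = α_d·gap² + α_κ·κ² (gap in μm)."""
    gap, _ = _gap_and_tau_c(s_prev, s_next, eps)
    return params.alpha_d * gap * gap + params.alpha_kappa * curvature_sq(s_prev, s_next, eps)


def allowed(s_prev: State, s_next: State, params: TransitionParams, eps: float = 0.0) -> bool:
    """Pruning rule: no self/sibling transition, bounded gap, bounded angles."""
    if s_next.id == s_prev.id or s_next.id == s_prev.sibling_id:
        return False
    gap, tau_c = _gap_and_tau_c(s_prev, s_next, eps)
    if gap > params.d_max:
        return False
    cos_cut = math.cos(math.radians(params.theta_max))
    if float(np.dot(s_prev.tau1, tau_c)) < cos_cut:
        return False
    if float(np.dot(tau_c, -np.asarray(s_next.tau0, float))) < cos_cut:
        return False
    return True


def transition_prior(
    s_prev: State, successors: list[State], params: TransitionParams, eps: float = 0.0
) -> dict[int, float]:
    """Normalised Boltzmann priors p(s′|s_prev) over the allowed successors.

    Computed as a max-shifted softmax of −U, so equal energies give exactly
    equal probabilities.  Empty when the state is a dead end.
    """
    if not successors:
        return {}
    energies = np.array([transition_energy(s_prev, s, params, eps) for s in successors])
    shifted = -energies + energies.min()
    ex = np.exp(shifted)
    p = ex / ex.sum()
    return {s.id: float(pi) for s, pi in zip(successors, p)}


def transition_log_prior(
    s_prev: State, successors: list[State], params: TransitionParams, eps: float = 0.0
) -> dict[int, float]:
    """Log-priors log p(s′|s_prev) = −U − log Z, log-sum-exp stabilised.

    Kept in log space throughout so even astronomically unlikely successors
    get a finite value (the softmax of :func:`transition_prior` would
    underflow to 0 there).
    """
    if not successors:
        return {}
    energies = np.array([transition_energy(s_prev, s, params, eps) for s in successors])
    neg = -energies
    log_z = float(np.logaddexp.reduce(neg))
    return {s.id: float(n - log_z) for s, n in zip(successors, neg)}


def imputed_gap(s_prev: State, s_next: State, volume: ImageVolume) -> np.ndarray:
    """Voxels bridging the gap x¹(prev) → x⁰(next), endpoint voxels excluded.

    The Bresenham chain's interior; empty when the fragments touch.
    """
    p = volume.physical_to_voxel(s_prev.x1)
    q = volume.physical_to_voxel(s_next.x0)
    line = bresenham_line(p, q)
    return line[1:-1] if len(line) > 2 else line[:0]


class DisallowedTransitionError(ValueError):
    """Raised when an edge weight is requested for a pruned transition."""


def _clip_voxels(voxels: np.ndarray, shape) -> np.ndarray:
    if len(voxels) == 0:
        return voxels
    ok = np.all((voxels >= 0) & (voxels < np.asarray(shape)), axis=1)
    return voxels[ok]


def _neg_log_alpha1(volume: ImageVolume, model: IntensityModel, voxels: np.ndarray) -> float:
    voxels = _clip_voxels(voxels, volume.shape)
    if len(voxels) == 0:
        return 0.0
    vals = np.asarray(volume.data)[tuple(voxels.T)]
    a1 = eval_foreground(model, vals)
    return float(-np.log(np.maximum(a1, np.finfo(float).tiny)).sum())


def edge_weight(
    volume: ImageVolume,
    model: IntensityModel,
    s_prev: State,
    s_next: State,
    params: TransitionParams,
    fragments: list[Fragment],
    log_prior: float | None = None,
    eps: float = 0.0,
) -> float:
    """e(s, s′) = −log α₁ over next-fragment line + gap voxels − log p(s′|s).

    With the ≤ 1 clip on α₁ and p ≤ 1 the weight is always ≥ 0.  When
    ``log_prior`` is omitted it is computed as if s′ were the only allowed
    successor (log p = 0), which only arises in isolated unit tests.
    """
    if not allowed(s_prev, s_next, params, eps):
        raise DisallowedTransitionError(
            f"transition {s_prev.id} -> {s_next.id} is pruned; no edge weight exists"
        )
    frag = fragments[s_next.fragment_id]
    data_term = _neg_log_alpha1(volume, model, frag.line_voxels)
    data_term += _neg_log_alpha1(volume, model, imputed_gap(s_prev, s_next, volume))
    lp = 0.0 if log_prior is None else float(log_prior)
    return data_term - lp


@dataclass
class TransitionGraph:
    """The directed trellis: states plus sparse weighted edges.

    ``edges[(i, j)]`` holds the transition energy ``U``, the normalised
    ``log_prior``, the appearance ``log_like`` (−Σ log α₁ over the next
    fragment's line voxels and the imputed gap voxels) and the combined
    nonnegative ``weight``.
    """

    states: list[State]
    edges: dict[tuple[int, int], dict[str, float]]
    params: TransitionParams
    fragments: list[Fragment] = field(default_factory=list, repr=False)

    def successors(self, state_id: int):
        return [(j, e) for (i, j), e in self.edges.items() if i == state_id]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for s in self.states:
            g.add_node(s.id, fragment_id=s.fragment_id)
        for (i, j), e in self.edges.items():
            g.add_edge(i, j, **e)
        return g

    def to_json(self, path=None) -> str:
        payload = {
            "params": {
                "alpha_d": self.params.alpha_d,
                "alpha_kappa": self.params.alpha_kappa,
                "d_max": self.params.d_max,
                "theta_max": self.params.theta_max,
            },
            "states": [
                {
                    "id": s.id,
                    "fragment_id": s.fragment_id,
                    "sibling_id": s.sibling_id,
                    "x0": list(map(float, s.x0)),
                    "x1": list(map(float, s.x1)),
                    "tau0": list(map(float, s.tau0)),
                    "tau1": list(map(float, s.tau1)),
                }
                for s in self.states
            ],
            "edges": [
                {"from": i, "to": j, **{k: float(v) for k, v in e.items()}}
                for (i, j), e in sorted(self.edges.items())
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "TransitionGraph":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        params = TransitionParams(**payload["params"])
        states = [
            State(
                id=s["id"], fragment_id=s["fragment_id"], sibling_id=s["sibling_id"],
                x0=np.array(s["x0"]), x1=np.array(s["x1"]),
                tau0=np.array(s["tau0"]), tau1=np.array(s["tau1"]),
            )
            for s in payload["states"]
        ]
        edges = {
            (e["from"], e["to"]): {k: v for k, v in e.items() if k not in ("from", "to")}
            for e in payload["edges"]
        }
        return cls(states=states, edges=edges, params=params)


def build_graph(
    volume: ImageVolume,
    model: IntensityModel,
    fragments: list[Fragment],
    params: TransitionParams | None = None,
) -> TransitionGraph:
    """Assemble the full trellis: states, pruned successors, priors, weights.

    Candidate successors are found with a KD-tree over state entry points
    (radius ``d_max`` around each exit point), which is exact: any allowed
    transition has gap ≤ d_max by definition.
    """
    if params is None:
        params = TransitionParams()
    eps = 0.5 * min(volume.spacing)
    states = build_states(fragments)
    edges: dict[tuple[int, int], dict[str, float]] = {}
    if states:
        entry_pts = np.array([s.x0 for s in states])
        tree = cKDTree(entry_pts)
        for s_prev in states:
            cand_idx = tree.query_ball_point(np.asarray(s_prev.x1, float), r=params.d_max)
            succ = [states[c] for c in sorted(cand_idx) if allowed(s_prev, states[c], params, eps)]
            log_priors = transition_log_prior(s_prev, succ, params, eps)
            for s_next in succ:
                lp = log_priors[s_next.id]
                frag = fragments[s_next.fragment_id]
                like = _neg_log_alpha1(volume, model, frag.line_voxels)
                like += _neg_log_alpha1(volume, model, imputed_gap(s_prev, s_next, volume))
                edges[(s_prev.id, s_next.id)] = {
                    "U": transition_energy(s_prev, s_next, params, eps),
                    "log_prior": lp,
                    "log_like": like,
                    "weight": like - lp,
                }
    graph = TransitionGraph(states=states, edges=edges, params=params, fragments=fragments)
    logger.info("built transition graph: %d states, %d edges", graph.n_states, graph.n_edges)
    return graph
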