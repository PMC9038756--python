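"""End-to-end reconstruction: image + probability map → most probable path.

Thin orchestration over the library modules, shared by the CLI and the
test/evaluation scripts: threshold → fragments → appearance fit → trellis →
shortest path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import appearance, fragments as frag_mod, hmm_graph, pathing
from .volume_io import ImageVolume

logger = logging.getLogger(__name__)


@dataclass
class ReconstructionResult:
    fragments: list
    graph: hmm_graph.TransitionGraph
    path: pathing.ReconstructionPath
    model: appearance.IntensityModel
    counts: dict


def fit_model_from_mask(
    image: ImageVolume,
    mask,
    n_samples: int = 5000,
    seed: int = 0,
) -> appearance.IntensityModel:
    """Fit the fg/bg intensity model from a labelled mask over the image.

    Foreground samples are drawn (seeded) from mask>0 voxels, background
    from mask==0 voxels, mirroring hand-labelling of a volume.
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(image.data)
    m = np.asarray(getattr(mask, "data", mask)) > 0
    fg_idx = np.argwhere(m)
    bg_idx = np.argwhere(~m)
    n_fg = min(n_samples, len(fg_idx))
    n_bg = min(n_samples, len(bg_idx))
    if n_fg < 2 or n_bg < 2:
        raise ValueError("mask must contain at least 2 voxels of each class")
    fg_sel = fg_idx[rng.choice(len(fg_idx), size=n_fg, replace=False)]
    bg_sel = bg_idx[rng.choice(len(bg_idx), size=n_bg, replace=False)]
    return appearance.fit_intensity_model(
        data[tuple(fg_sel.T)].astype(float), data[tuple(bg_sel.T)].astype(float)
    )


def reconstruct(
    image: ImageVolume,
    prob_map: ImageVolume,
    start_point,
    end_point,
    model: appearance.IntensityModel | None = None,
    threshold: float = 0.9,
    radius: float = 7.0,
    min_voxels: int = 5,
    params: hmm_graph.TransitionParams | None = None,
    appearance_samples: int = 5000,
    seed: int = 0,
    capture_radius: float = 10.0,
) -> ReconstructionResult:
    """Run the full pipeline between two physical-space endpoints.

    When no fitted ``model`` is supplied, one is fitted from the thresholded
    probability map's own labels over the image (seeded sampling).
    """
    frags = frag_mod.generate_fragments(
        prob_map, threshold=threshold, radius=radius, min_voxels=min_voxels
    )
    if not frags:
        raise pathing.NoPathError("no fragments were generated from the probability map")
    if model is None:
        mask = frag_mod.threshold_probability(prob_map, threshold)
        model = fit_model_from_mask(image, mask, n_samples=appearance_samples, seed=seed)
    graph = hmm_graph.build_graph(image, model, frags, params)
    start_id, term_id = pathing.endpoint_states_from_points(
        graph, frags, start_point, end_point, capture_radius=capture_radius
    )
    path = pathing.most_probable_path(graph, start_id, term_id)
    counts = {
        "n_fragments": len(frags),
        "n_states": graph.n_states,
        "n_edges": graph.n_edges,
        "n_path_states": len(path),
        "path_weight": path.total_weight,
    }
    logger.info("reconstruction: %s", counts)
    return ReconstructionResult(fragments=frags, graph=graph, path=path, model=model, counts=counts)
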