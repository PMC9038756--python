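"""Synthetic tube phantoms with the statistical structure the model assumes.

A phantom is a ground-truth space curve (a gently curving "axon"), a tube
mask rasterised around it on an anisotropic voxel grid, an intensity image
whose foreground/background voxels are iid draws from two configurable
distributions blurred by a physical-units Gaussian PSF (the only source of
spatial correlation, and a short-range one), an idealised per-voxel
foreground-probability map (the Bayes posterior of the pre-blur sample under
the two generating densities, optionally corrupted by label flips), and
optional luminance-dropout windows along the curve that sever the tube —
the failure mode gap-bridging reconstruction exists to survive.

Defaults emulate sparse sub-micron fluorescence data: 0.3 × 0.3 × 1 μm
voxels, ~1 μm-diameter tubes, ~1 μm PSF, and well-separated intensity
classes.  Everything is driven by a single seed; identical configs produce
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .metrics import Polyline, resample_polyline
from .volume_io import ImageVolume, LabelVolume

__all__ = [
    "IntensityDistribution",
    "PhantomConfig",
    "Phantom",
    "sample_curve",
    "rasterize_tube",
    "render_image",
    "apply_dropout",
    "make_phantom",
]


@dataclass
class IntensityDistribution:
    """A named 1-D intensity distribution: gaussian, lognormal or mixture.

    ``params`` per kind — gaussian: (mu, sigma); lognormal: (mu, sigma) of
    the underlying normal; mixture: (mu1, sigma1, mu2, sigma2, w1) of two
    Gaussian components.
    """

    kind: str
    params: tuple

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "gaussian":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=n)
        if self.kind == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=n)
        if self.kind == "mixture":
            mu1, s1, mu2, s2, w1 = self.params
            pick = rng.random(n) < w1
            out = np.where(pick, rng.normal(mu1, s1, n), rng.normal(mu2, s2, n))
            return out
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def pdf(self, x) -> np.ndarray:
        from scipy import stats

        x = np.asarray(x, dtype=float)
        if self.kind == "gaussian":
            mu, sigma = self.params
            return stats.norm.pdf(x, mu, sigma)
        if self.kind == "lognormal":
            mu, sigma = self.params
            return stats.lognorm.pdf(x, s=sigma, scale=np.exp(mu))
        if self.kind == "mixture":
            mu1, s1, mu2, s2, w1 = self.params
            return w1 * stats.norm.pdf(x, mu1, s1) + (1 - w1) * stats.norm.pdf(x, mu2, s2)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass
class PhantomConfig:
    """Full provenance record for one phantom.

    Units: μm throughout; ``curvature_scale`` is the maximum discrete
    curvature (turn angle per arc length, rad/μm) of the generated curve;
    ``dropout`` is a list of (arc start, gap length) windows measured along
    the curve.  ``confuser_offset`` adds a parallel copy of the first curve
    at that perpendicular offset — the classic nearby-process failure mode.
    ``classifier_noise`` flips that fraction of probability-map voxels to
    emulate an imperfect upstream segmenter.
    """

    shape: tuple[int, int, int] = (400, 96, 64)
    spacing: tuple[float, float, float] = (0.3, 0.3, 1.0)
    tube_radius: float = 0.5
    n_curves: int = 1
    curve_length: float = 100.0
    curvature_scale: float = 0.05
    fg_dist: IntensityDistribution = field(
        default_factory=lambda: IntensityDistribution("gaussian", (200.0, 30.0))
    )
    bg_dist: IntensityDistribution = field(
        default_factory=lambda: IntensityDistribution("gaussian", (100.0, 15.0))
    )
    psf_sigma: float = 0.5
    dropout: list = field(default_factory=list)
    confuser_offset: float | None = None
    classifier_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if any(g < 0 for _, g in self.dropout):
            raise ValueError("dropout gap lengths must be nonnegative")
        if isinstance(self.fg_dist, (tuple, list)):
            self.fg_dist = IntensityDistribution(*self.fg_dist)
        if isinstance(self.bg_dist, (tuple, list)):
            self.bg_dist = IntensityDistribution(*self.bg_dist)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fg_dist"] = {"kind": self.fg_dist.kind, "params": list(self.fg_dist.params)}
        d["bg_dist"] = {"kind": self.bg_dist.kind, "params": list(self.bg_dist.params)}
        return d


def _physical_extent(config: PhantomConfig) -> np.ndarray:
    return (np.asarray(config.shape) - 1) * np.asarray(config.spacing)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate(vec, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return vec * c + np.cross(axis, vec) * s + axis * np.dot(axis, vec) * (1 - c)


def sample_curve(config: PhantomConfig, rng=None, step: float = 0.5) -> Polyline:
    """A smooth seeded space curve of the configured length.

    A unit tangent is integrated in ``step``-μm increments; at each step it
    is rotated by a random angle drawn uniformly from
    [0, curvature_scale·step] about a random axis, so the discrete curvature
    (turn angle / step) never exceeds ``curvature_scale``.  The curve is
    reflected at the physical volume borders (inset by the tube radius).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.curve_length <= 0:
        raise ValueError("curve length must be positive")
    extent = _physical_extent(config)
    margin = config.tube_radius + max(config.spacing)
    lo = np.full(3, margin)
    hi = extent - margin

    # start mid-cross-section near one end of the long axis, heading along it
    long_axis = int(np.argmax(extent))
    start = lo + (hi - lo) * (0.4 + 0.2 * rng.random(3))
    start[long_axis] = lo[long_axis] + (hi[long_axis] - lo[long_axis]) * (0.05 + 0.05 * rng.random())
    tangent = np.zeros(3)
    tangent[long_axis] = 1.0
    tilt_axis = _random_unit(rng)
    tangent = _rotate(tangent, tilt_axis, 0.05 * rng.random())

    n_steps = int(np.ceil(config.curve_length / step))
    pts = [start.copy()]
    pos = start.copy()
    for _ in range(n_steps):
        if config.curvature_scale > 0:
            angle = rng.uniform(0.0, config.curvature_scale * step)
            axis = _random_unit(rng)
            # component of rotation axis along tangent has no effect; keep as is
            tangent = _rotate(tangent, axis, angle)
            tangent /= np.linalg.norm(tangent)
        pos = pos + tangent * step
        for ax in range(3):  # reflect at borders
            if pos[ax] < lo[ax]:
                pos[ax] = 2 * lo[ax] - pos[ax]
                tangent[ax] = -tangent[ax]
            elif pos[ax] > hi[ax]:
                pos[ax] = 2 * hi[ax] - pos[ax]
                tangent[ax] = -tangent[ax]
        pts.append(pos.copy())
    return Polyline(points=np.asarray(pts))


def rasterize_tube(curve: Polyline, radius: float, shape, spacing) -> LabelVolume:
    """Binary tube mask: voxels whose centers lie within ``radius`` μm of the
    curve (point-to-segment distance), plus the nearest-voxel chain of a
    dense sampling of the curve so the tube is 26-connected along its length
    even when the radius drops below the voxel size.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(s) for s in shape)
    mask = np.zeros(shape, dtype=np.uint8)
    pts = curve.points if isinstance(curve, Polyline) else np.asarray(curve, float)

    # within-radius voxels, per segment over a local bounding box
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.floor((np.minimum(a, b) - radius) / spacing).astype(int)
        hi = np.ceil((np.maximum(a, b) + radius) / spacing).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        centers = np.stack(grids, axis=-1).reshape(-1, 3) * spacing
        ab = b - a
        denom = float(np.dot(ab, ab))
        if denom == 0:
            d = np.linalg.norm(centers - a, axis=1)
        else:
            t = np.clip((centers - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(centers - (a + t[:, None] * ab), axis=1)
        inside = np.stack(grids, axis=-1).reshape(-1, 3)[d <= radius]
        mask[tuple(inside.T)] = 1

    # connectivity chain: nearest voxels of a dense resampling
    dense = resample_polyline(Polyline(pts), step=0.4 * float(spacing.min())).points
    chain = np.floor(dense / spacing + 0.5).astype(int)
    ok = np.all((chain >= 0) & (chain < np.asarray(shape)), axis=1)
    mask[tuple(chain[ok].T)] = 1
    return LabelVolume(data=mask, spacing=tuple(spacing))


def render_image(
    tube_mask: LabelVolume,
    fg_dist: IntensityDistribution,
    bg_dist: IntensityDistribution,
    psf_sigma: float,
    rng=None,
    seed: int | None = None,
):
    """Draw iid fg/bg intensities on the mask and blur with a physical PSF.

    Returns ``(image, raw)``: the blurred :class:`ImageVolume` and the
    pre-blur pure-sample volume (the appearance-model ground truth).
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required")
        rng = np.random.default_rng(seed)
    mask = np.asarray(tube_mask.data).astype(bool)
    raw = bg_dist.sample(rng, mask.size).reshape(mask.shape)
    n_fg = int(mask.sum())
    if n_fg:
        raw[mask] = fg_dist.sample(rng, n_fg)
    if psf_sigma > 0:
        sigma_vox = psf_sigma / np.asarray(tube_mask.spacing, dtype=float)
        blurred = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    else:
        blurred = raw.copy()
    image = ImageVolume(data=blurred, spacing=tube_mask.spacing, origin=tube_mask.origin)
    raw_vol = ImageVolume(data=raw, spacing=tube_mask.spacing, origin=tube_mask.origin)
    return image, raw_vol


def _arc_positions(curve_pts: np.ndarray):
    seg = np.linalg.norm(np.diff(curve_pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _merge_windows(dropout):
    wins = sorted((float(p), float(p) + float(g)) for p, g in dropout if g > 0)
    merged = []
    for lo, hi in wins:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def apply_dropout(volume, curve: Polyline, dropout):
    """Censor foreground within arc-length windows along the curve.

    ``dropout`` is a list of (arc start μm, gap length μm); overlapping
    windows are merged.  Every nonzero voxel whose nearest curve vertex has
    an arc position inside a window is zeroed.  Returns the censored copy
    and the (N, 3) array of censored voxel indices.
    """
    pts = curve.points if isinstance(curve, Polyline) else np.asarray(curve, float)
    # densify so nearest-vertex arc positions are accurate for sparse curves
    if len(pts) >= 2 and Polyline(pts).arc_length > 0.5:
        pts = resample_polyline(Polyline(pts), step=0.5).points
    arcs = _arc_positions(pts)
    windows = _merge_windows(dropout)
    data = np.array(volume.data, copy=True)
    cls = type(volume)
    if not windows:
        return cls(data=data, spacing=volume.spacing, origin=volume.origin), np.empty((0, 3), int)
    if windows and windows[-1][0] > arcs[-1]:
        raise ValueError("dropout window starts beyond the curve length")
    coords = np.argwhere(data != 0)
    if len(coords) == 0:
        return cls(data=data, spacing=volume.spacing, origin=volume.origin), np.empty((0, 3), int)
    pos = coords * np.asarray(volume.spacing, dtype=float)
    _, nearest = cKDTree(pts).query(pos)
    vox_arc = arcs[nearest]
    censored = np.zeros(len(coords), dtype=bool)
    for lo, hi in windows:
        censored |= (vox_arc >= lo) & (vox_arc <= hi)
    cens_coords = coords[censored]
    data[tuple(cens_coords.T)] = 0
    return cls(data=data, spacing=volume.spacing, origin=volume.origin), cens_coords


@dataclass
class Phantom:
    """One generated phantom: image, probability map, truth and provenance."""

    image: ImageVolume
    prob_map: ImageVolume
    gt_curves: list[Polyline]
    clean_mask: LabelVolume
    mask: LabelVolume          # after dropout
    raw: ImageVolume           # pre-blur samples
    config: PhantomConfig


def make_phantom(config: PhantomConfig) -> Phantom:
    """Compose curve sampling, rasterisation, rendering, posterior and dropout.

    The probability map is the exact Bayes posterior
    fg_pdf(raw)/(fg_pdf(raw)+bg_pdf(raw)) of the pre-blur sample under the
    generating densities (an idealised upstream classifier), with an optional
    fraction of voxels flipped (``classifier_noise``).  Dropout windows are
    applied along the *first* curve to mask, probability map and image alike,
    so censored stretches look like background everywhere downstream.
    """
    rng = np.random.default_rng(config.seed)
    curves = [sample_curve(config, rng=rng) for _ in range(config.n_curves)]
    if config.confuser_offset is not None:
        base = curves[0].points.copy()
        extent = _physical_extent(config)
        off_axis = int(np.argmin(extent))  # offset along the thinnest axis
        offset = np.zeros(3)
        offset[off_axis] = config.confuser_offset
        shifted = np.clip(base + offset, 0.0, extent)
        curves.append(Polyline(points=shifted))

    masks = [rasterize_tube(c, config.tube_radius, config.shape, config.spacing) for c in curves]
    clean = np.zeros(config.shape, dtype=np.uint8)
    for m in masks:
        clean |= m.data.astype(np.uint8)
    clean_mask = LabelVolume(data=clean, spacing=config.spacing)

    # dropout censors the first curve's tube only
    censored_mask = clean_mask
    if config.dropout:
        censored_first, _ = apply_dropout(masks[0], curves[0], config.dropout)
        merged = censored_first.data.astype(np.uint8)
        for m in masks[1:]:
            merged |= m.data.astype(np.uint8)
        censored_mask = LabelVolume(data=merged, spacing=config.spacing)

    image, raw = render_image(censored_mask, config.fg_dist, config.bg_dist, config.psf_sigma, rng=rng)

    f1 = config.fg_dist.pdf(raw.data)
    f0 = config.bg_dist.pdf(raw.data)
    with np.errstate(invalid="ignore"):
        post = np.where(f1 + f0 > 0, f1 / (f1 + f0), 0.0)
    if config.classifier_noise > 0:
        flip = rng.random(post.shape) < config.classifier_noise
        post = np.where(flip, 1.0 - post, post)
    prob_map = ImageVolume(data=post, spacing=config.spacing)

    return Phantom(
        image=image,
        prob_map=prob_map,
        gt_curves=curves,
        clean_mask=clean_mask,
        mask=censored_mask,
        raw=raw,
        config=config,
    )
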