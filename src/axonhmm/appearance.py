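"""Nonparametric foreground/background intensity model and image statistics.

The appearance model treats voxel intensities as draws from one of two
marginal densities — α₁(·) for voxels on a neuronal process (foreground) and
α₀(·) for everything else — estimated with Gaussian kernel density estimates
(Scott's-rule bandwidth) from labelled training voxels.  The separation of
the two densities, summarised by KL(α₁‖α₀), is the single best predictor of
how easy a volume is to trace: for Gaussian classes of equal variance it
reduces to half the squared signal-to-noise ratio, (Δμ)²/(2σ²).

Downstream, −log α₁ over a candidate path's voxels is the data term of every
transition weight, so evaluation is clipped at 1 to keep those terms
non-negative (a Dijkstra precondition); the clip fraction is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .volume_io import ImageVolume, LabelVolume

__all__ = [
    "IntensityModel",
    "AutocorrCurve",
    "fit_intensity_model",
    "eval_foreground",
    "eval_background",
    "kl_divergence",
    "intensity_autocorrelation",
]

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised when training samples cannot support a density estimate."""


@dataclass
class IntensityModel:
    """Fitted foreground/background intensity densities α₁(·), α₀(·).

    Attributes
    ----------
    fg_density, bg_density : gaussian_kde
        Gaussian KDEs with Scott's-rule bandwidth.
    fg_samples, bg_samples : ndarray
        The training intensities.
    bandwidths : (float, float)
        KDE bandwidth (standard deviation of the kernel, intensity units)
        for the fg and bg densities.
    clip_count, eval_count : int
        Running totals of clipped-to-1 evaluations vs all evaluations.
    """

    fg_density: gaussian_kde
    bg_density: gaussian_kde
    fg_samples: np.ndarray
    bg_samples: np.ndarray
    bandwidths: tuple[float, float]
    clip_count: int = 0
    eval_count: int = 0

    @property
    def clip_fraction(self) -> float:
        return self.clip_count / self.eval_count if self.eval_count else 0.0

    def support_grid(self, n: int = 2048) -> np.ndarray:
        """Uniform grid spanning both sample ranges ± 4 bandwidths."""
        pad = 4.0 * max(self.bandwidths)
        lo = min(self.fg_samples.min(), self.bg_samples.min()) - pad
        hi = max(self.fg_samples.max(), self.bg_samples.max()) + pad
        return np.linspace(lo, hi, n)


def _fit_kde(samples, label: str) -> gaussian_kde:
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError(f"{label} needs at least 2 samples, got {samples.size}")
    if np.ptp(samples) == 0:
        raise DegenerateDataError(f"{label} samples are constant; cannot fit a KDE")
    return gaussian_kde(samples, bw_method="scott")


def fit_intensity_model(fg_samples, bg_samples) -> IntensityModel:
    """Fit Gaussian KDEs (Scott's rule) to labelled fg/bg intensities."""
    fg_kde = _fit_kde(fg_samples, "foreground")
    bg_kde = _fit_kde(bg_samples, "background")
    # gaussian_kde covariance is (factor * std)^2 for 1-D data
    bw = (float(np.sqrt(fg_kde.covariance[0, 0])), float(np.sqrt(bg_kde.covariance[0, 0])))
    model = IntensityModel(
        fg_density=fg_kde,
        bg_density=bg_kde,
        fg_samples=np.asarray(fg_samples, dtype=float).ravel(),
        bg_samples=np.asarray(bg_samples, dtype=float).ravel(),
        bandwidths=bw,
    )
    logger.info(
        "fitted intensity model: n_fg=%d n_bg=%d bw_fg=%.4g bw_bg=%.4g",
        model.fg_samples.size, model.bg_samples.size, bw[0], bw[1],
    )
    return model


def _eval_clipped(model: IntensityModel, kde: gaussian_kde, intensities) -> np.ndarray:
    x = np.atleast_1d(np.asarray(intensities, dtype=float))
    raw = kde(x)
    clipped = np.minimum(raw, 1.0)
    n_clip = int(np.count_nonzero(raw > 1.0))
    model.clip_count += n_clip
    model.eval_count += x.size
    if n_clip:
        logger.debug("clipped %d/%d density evaluations to 1.0", n_clip, x.size)
    return clipped


def eval_foreground(model: IntensityModel, intensities) -> np.ndarray:
    """Evaluate α₁ at the given intensities, clipped to ≤ 1.

    The clip keeps −log α₁ ≥ 0 so every transition weight is non-negative.
    Clipping events are counted on the model (``clip_fraction``).
    """
    return _eval_clipped(model, model.fg_density, intensities)


def eval_background(model: IntensityModel, intensities) -> np.ndarray:
    """Evaluate α₀ at the given intensities, clipped to ≤ 1."""
    return _eval_clipped(model, model.bg_density, intensities)


def kl_divergence(model: IntensityModel, grid_size: int = 2048) -> float:
    """KL(α₁ ‖ α₀) in nats by trapezoid quadrature on a uniform grid.

    The grid spans both sample ranges ± 4 bandwidths.  Integrand terms where
    the fg density underflows contribute 0 (the p→0 limit of p·log(p/q)).
    """
    if grid_size < 100:
        raise ValueError("grid_size must be at least 100")
    grid = model.support_grid(grid_size)
    p = model.fg_density(grid)
    q = model.bg_density(grid)
    tiny = np.finfo(float).tiny
    integrand = np.where(p > tiny, p * (np.log(np.maximum(p, tiny)) - np.log(np.maximum(q, tiny))), 0.0)
    return float(max(np.trapezoid(integrand, grid), 0.0))


@dataclass
class AutocorrCurve:
    """Distance-binned Pearson autocorrelation of voxel intensities.

    ``correlations[b]`` is the Pearson r over all sampled voxel pairs whose
    physical separation falls in bin b; bins with fewer than 4 pairs are NaN.
    ``fisher_sd`` is the standard deviation of the Fisher z-transform,
    1/sqrt(n_pairs − 3).
    """

    bin_centers: np.ndarray
    correlations: np.ndarray
    fisher_sd: np.ndarray
    n_pairs: np.ndarray


def intensity_autocorrelation(
    volume: ImageVolume,
    class_mask: LabelVolume,
    n_samples: int = 5000,
    bins=None,
    seed: int | None = None,
    rng=None,
) -> AutocorrCurve:
    """Spatial intensity autocorrelation within one voxel class.

    Samples ``n_samples`` voxels (without replacement when possible) from the
    nonzero entries of ``class_mask``, forms all pairs, bins pairs by physical
    distance in μm, and computes the Pearson correlation of the intensity
    pairs in each bin.  The pair moments are accumulated in chunks so the
    all-pairs set is never materialised.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required: sampling is randomised")
        rng = np.random.default_rng(seed)
    coords = np.argwhere(np.asarray(class_mask.data) > 0)
    if len(coords) < 2:
        raise ValueError("class mask selects fewer than 2 voxels")
    take = min(n_samples, len(coords))
    sel = rng.choice(len(coords), size=take, replace=False)
    coords = coords[np.sort(sel)]
    pos = coords * np.asarray(volume.spacing)
    vals = np.asarray(volume.data)[tuple(coords.T)].astype(float)

    if bins is None:
        span = float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))
        bins = np.linspace(0.0, max(span, 1e-9), 11)
    bins = np.asarray(bins, dtype=float)
    nb = len(bins) - 1

    # per-bin accumulators for n, Σx, Σy, Σx², Σy², Σxy over unordered pairs
    acc = np.zeros((6, nb))
    chunk = max(1, int(2e7) // max(take, 1))
    for start in range(0, take - 1, chunk):
        stop = min(start + chunk, take - 1)
        for i in range(start, stop):
            d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
            b = np.searchsorted(bins, d, side="right") - 1
            ok = (b >= 0) & (b < nb)
            b = b[ok]
            y = vals[i + 1:][ok]
            x = np.full(y.shape, vals[i])
            acc[0] += np.bincount(b, minlength=nb)
            acc[1] += np.bincount(b, weights=x, minlength=nb)
            acc[2] += np.bincount(b, weights=y, minlength=nb)
            acc[3] += np.bincount(b, weights=x * x, minlength=nb)
            acc[4] += np.bincount(b, weights=y * y, minlength=nb)
            acc[5] += np.bincount(b, weights=x * y, minlength=nb)

    n, sx, sy, sxx, syy, sxy = acc
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sy / n)
        vx = sxx / n - (sx / n) ** 2
        vy = syy / n - (sy / n) ** 2
        r = cov / np.sqrt(vx * vy)
        r = np.clip(r, -1.0, 1.0)
        sd = np.where(n > 3, 1.0 / np.sqrt(np.maximum(n - 3, 1)), np.nan)
    r = np.where(n >= 4, r, np.nan)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return AutocorrCurve(bin_centers=centers, correlations=r, fisher_sd=sd, n_pairs=n.astype(int))
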