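"""Orientation and coherency scoring of tissue texture.

Structure-tensor orientation fields, gradient-energy-weighted axial
directionality histograms, alignment to the dominant direction, pooled
angle-bin scores, the two-sample Watson U-squared circular statistic
(permutation, exhaustive, or asymptotic p), and the Wilcoxon rank-sum test.

Angle convention: 0 deg along the image x axis (columns), counter-clockwise
positive, axial period 180 deg, range (-90, 90].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import ndimage, stats

from .synthetic import wrap_axial_deg

logger = logging.getLogger(__name__)


@dataclass
class OrientationField:
    """Per-pixel structure orientation, coherency, and tensor energy."""

    theta_deg: np.ndarray  # (-90, 90]
    coherency: np.ndarray  # [0, 1]; 0 where energy vanishes
    energy: np.ndarray  # tensor trace, >= 0


@dataclass
class DirectionalityHistogram:
    bin_centers_deg: np.ndarray
    weights: np.ndarray  # nonnegative, sum to 1
    dominant_direction_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, float)
        self.weights = np.asarray(self.weights, float)
        if self.bin_centers_deg.shape != self.weights.shape:
            raise ValueError("bin centers and weights must match")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0):
            raise ValueError("weights must sum to 1")
        self.dominant_direction_deg = float(
            self.bin_centers_deg[int(np.argmax(self.weights))]
        )


@dataclass(frozen=True)
class WatsonResult:
    u2: float
    p_value: float
    method: str  # "permutation" | "exhaustive" | "asymptotic"
    n_a: int
    n_b: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample
    p_value: float


# ---------------------------------------------------------------------------
# structure tensor
# ---------------------------------------------------------------------------

def structure_tensor_field(
    image: np.ndarray,
    gradient_sigma: float = 1.0,
    window_sigma: float = 2.0,
) -> OrientationField:
    """Per-pixel structure-tensor orientation, coherency, and energy.

    Gradients are Gaussian derivatives at ``gradient_sigma``; tensor
    components are smoothed over ``window_sigma``. Theta is the local
    structure (iso-intensity) direction.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(image.shape) < 4 * window_sigma:
        raise ValueError("image smaller than 4 * window_sigma")
    gy = ndimage.gaussian_filter(image, gradient_sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(image, gradient_sigma, order=(0, 1))
    jxx = ndimage.gaussian_filter(gx * gx, window_sigma)
    jyy = ndimage.gaussian_filter(gy * gy, window_sigma)
    jxy = ndimage.gaussian_filter(gx * gy, window_sigma)
    energy = jxx + jyy
    # gradient orientation + 90 deg = structure direction
    theta = np.rad2deg(0.5 * np.arctan2(2.0 * jxy, jxx - jyy)) + 90.0
    theta = wrap_axial_deg(theta)
    eps = 1e-12 * max(float(energy.max()), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2) / energy
    coherency = np.where(energy > eps, coherency, 0.0)
    return OrientationField(theta_deg=theta, coherency=coherency, energy=energy)


def region_coherency(field: OrientationField, mask: np.ndarray | None = None) -> float:
    """Energy-weighted mean coherency over a mask (whole image by default)."""
    if mask is None:
        mask = np.ones_like(field.energy, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    e = field.energy[mask]
    c = field.coherency[mask]
    total = e.sum()
    if total <= 0:
        logger.warning("zero total tensor energy in mask; coherency = 0")
        return 0.0
    return float((e * c).sum() / total)


# ---------------------------------------------------------------------------
# directionality histograms
# ---------------------------------------------------------------------------

def directionality_histogram(
    image: np.ndarray,
    bin_deg: float = 2.0,
    gradient_sigma: float = 1.0,
    window_sigma: float = 2.0,
    border_px: int = 0,
) -> DirectionalityHistogram:
    """Axial histogram of structure orientations weighted by tensor energy.

    Bin centers sit at multiples of ``bin_deg`` covering (-90, 90].
    """
    n_bins = int(round(180.0 / bin_deg))
    if not np.isclose(n_bins * bin_deg, 180.0):
        raise ValueError("bin_deg must divide 180")
    f = structure_tensor_field(image, gradient_sigma, window_sigma)
    theta, weight = f.theta_deg, f.energy
    if border_px > 0:
        theta = theta[border_px:-border_px, border_px:-border_px]
        weight = weight[border_px:-border_px, border_px:-border_px]
    if weight.sum() <= 0:
        raise ValueError("image has zero gradient energy")
    centers = -90.0 + bin_deg * np.arange(1, n_bins + 1)  # (-90+b, ..., 90]
    # shift so each center owns [c - b/2, c + b/2); wrap the half-open seam
    shifted = (theta.ravel() + 90.0 - bin_deg / 2.0) % 180.0
    idx = np.floor(shifted / bin_deg).astype(int) % n_bins
    weights = np.bincount(idx, weights=weight.ravel(), minlength=n_bins)
    weights = weights / weights.sum()
    return DirectionalityHistogram(bin_centers_deg=centers, weights=weights)


def align_to_dominant(hist: DirectionalityHistogram) -> DirectionalityHistogram:
    """Shift bin centers (axial wrap) so the dominant bin sits at 0 deg."""
    shift = hist.dominant_direction_deg
    centers = wrap_axial_deg(hist.bin_centers_deg - shift)
    order = np.argsort(centers)
    return DirectionalityHistogram(
        bin_centers_deg=centers[order], weights=hist.weights[order]
    )


def pool_angle_scores(
    hist: DirectionalityHistogram,
    center_deg: float,
    halfwidth_deg: float,
) -> float:
    """Sum of weights within ``center +/- halfwidth`` under the axial wrap.

    Pooling around 90 deg therefore collects both the +90 and -90
    neighbourhoods of the axial distribution.
    """
    if len(hist.bin_centers_deg) > 1:
        bin_w = float(np.min(np.diff(np.sort(hist.bin_centers_deg))))
        if halfwidth_deg < bin_w:
            logger.info("halfwidth below bin width; effectively a single bin")
    delta = np.abs(((hist.bin_centers_deg - center_deg) + 90.0) % 180.0 - 90.0)
    return float(hist.weights[delta <= halfwidth_deg + 1e-9].sum())


# ---------------------------------------------------------------------------
# Watson U2 two-sample test
# ---------------------------------------------------------------------------

def _u2_from_sorted(indicator: np.ndarray, ends: np.ndarray, t_j: np.ndarray,
                    n_a: int, n_b: int) -> np.ndarray:
    """U2 for indicator rows (1 = sample A) over pre-sorted pooled values.

    ``ends`` are the last sorted index of each distinct value group, ``t_j``
    the group multiplicities (midrank/tie handling).
    """
    total = n_a + n_b
    cum_a = np.cumsum(indicator, axis=-1)[..., ends]
    cum_all = ends + 1.0
    cum_b = cum_all - cum_a
    d = cum_a / n_a - cum_b / n_b
    td = t_j * d
    return (n_a * n_b) / total**2 * ((t_j * d * d).sum(axis=-1) - td.sum(axis=-1) ** 2 / total)


def watson_u2_two_sample(
    angles_a,
    angles_b,
    method: str = "permutation",
    n_perm: int = 10000,
    seed: int | None = None,
    period: float = 360.0,
) -> WatsonResult:
    """Two-sample Watson U-squared test for circular/axial data.

    Ties are handled by grouping equal values (midrank form). ``method``
    is "permutation" (switches to exhaustive enumeration when the number of
    distinct label assignments is at most ``n_perm``) or "asymptotic".
    ``period`` states the period of the data (360 for circular degrees,
    180 for axial orientations).
    """
    a = np.mod(np.asarray(angles_a, float), period)
    b = np.mod(np.asarray(angles_b, float), period)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each sample needs at least 2 angles")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return WatsonResult(u2=0.0, p_value=1.0, method=method, n_a=n_a, n_b=n_b)

    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    is_a = (order < n_a).astype(float)
    distinct = np.flatnonzero(np.diff(sorted_vals) != 0)
    ends = np.concatenate([distinct, [sorted_vals.size - 1]])
    t_j = np.diff(np.concatenate([[-1], ends])).astype(float)

    u2_obs = float(_u2_from_sorted(is_a, ends, t_j, n_a, n_b))

    if method == "asymptotic":
        p = _watson_asymptotic_p(u2_obs)
        return WatsonResult(u2=u2_obs, p_value=p, method="asymptotic", n_a=n_a, n_b=n_b)
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'asymptotic'")

    total = n_a + n_b
    n_assign = comb(total, n_a)
    if n_assign <= n_perm:
        indicators = np.zeros((n_assign, total))
        for i, pos in enumerate(itertools.combinations(range(total), n_a)):
            indicators[i, list(pos)] = 1.0
        u2_all = _u2_from_sorted(indicators, ends, t_j, n_a, n_b)
        p = float(np.count_nonzero(u2_all >= u2_obs - 1e-12) / n_assign)
        return WatsonResult(u2=u2_obs, p_value=p, method="exhaustive", n_a=n_a, n_b=n_b)

    rng = np.random.default_rng(seed)
    base = np.concatenate([np.ones(n_a), np.zeros(n_b)])
    perms = rng.permuted(np.tile(base, (n_perm, 1)), axis=1)
    u2_perm = _u2_from_sorted(perms, ends, t_j, n_a, n_b)
    p = float((1 + np.count_nonzero(u2_perm >= u2_obs - 1e-12)) / (n_perm + 1))
    return WatsonResult(u2=u2_obs, p_value=p, method="permutation", n_a=n_a, n_b=n_b)


def _watson_asymptotic_p(u2: float, n_terms: int = 100) -> float:
    if u2 <= 0:
        return 1.0
    k = np.arange(1, n_terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b) -> RankSumResult:
    """Two-sided rank-sum test, normal approximation with continuity
    correction and tie-corrected variance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs at least one value")
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_a = float(ranks[: a.size].sum())
    if np.unique(np.concatenate([a, b])).size == 1:
        return RankSumResult(statistic=w_a, p_value=1.0)
    try:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    except ValueError:
        p = 1.0
    return RankSumResult(statistic=w_a, p_value=p)
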