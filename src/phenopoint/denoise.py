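"""Color-based noise removal: K-means clustering in RGB space and
Excess-Green (ExG = 2G - R - B) vegetation segmentation.

Time-of-flight sensors emit "flying pixels" along object silhouettes where a
single pixel mixes foreground and background returns; these points sit inside
the plant's bounding volume but carry neutral gray colors, so they separate
cleanly in color space even though they are not spatial outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud_core import PointCloud

__all__ = [
    "ColorClusterConfig",
    "ExGConfig",
    "exg",
    "exg_auto_threshold",
    "exg_segment",
    "choose_k",
    "kmeans_color_denoise",
]

EXG_MIN, EXG_MAX = -510, 510


@dataclass(frozen=True)
class ColorClusterConfig:
    """K-means settings for RGB-space denoising.

    ``k`` may be an integer or ``"auto"`` (histogram-peak count, clamped to
    [2, 4]).  Plant selection keeps every cluster whose mean ExG clears
    ``vegetation_floor``: achromatic flying pixels sit at ExG ~ 0 by
    construction (gray mixtures), while even brown-green stems clear a few
    tens of ExG units.  If no cluster clears the floor, the greenest
    (max mean ExG) cluster is kept.
    """

    k: int | str = "auto"
    max_iterations: int = 100
    tolerance: float = 1e-4
    seed: int = 0
    vegetation_floor: float = 25.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class ExGConfig:
    """Threshold mode: a fixed value, or the automatic histogram valley."""

    threshold: float | None = None  # None => auto valley
    bin_width: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold is not None and not (EXG_MIN - 1 <= self.threshold <= EXG_MAX + 1):
            # one unit of slack so sentinel thresholds -511/511 select all/none
            raise ValueError("fixed threshold outside achievable ExG range")


def exg(colors: np.ndarray) -> np.ndarray:
    """Excess Green Index per point: 2G - R - B, in [-510, 510]."""
    c = np.asarray(colors, dtype=np.int64).reshape(-1, 3)
    if c.size and (c.min() < 0 or c.max() > 255):
        raise ValueError("color channels must lie in [0, 255]")
    return 2 * c[:, 1] - c[:, 0] - c[:, 2]


def exg_auto_threshold(values: np.ndarray, cfg: ExGConfig | None = None) -> float:
    """Histogram-valley threshold between vegetation and non-vegetation modes.

    Builds a fixed-width histogram, finds the two highest local maxima, and
    returns the center of the lowest-count bin strictly between them.  A
    unimodal histogram falls back to the midpoint of mean and max.
    """
    cfg = cfg or ExGConfig()
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("threshold selection needs at least two distinct values")
    edges = np.arange(EXG_MIN, EXG_MAX + cfg.bin_width, cfg.bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # local maxima (plateau-tolerant at the ends)
    peaks = [i for i in range(len(counts))
             if counts[i] > 0
             and (i == 0 or counts[i] >= counts[i - 1])
             and (i == len(counts) - 1 or counts[i] > counts[i + 1])]
    if len(peaks) >= 2:
        top2 = sorted(sorted(peaks, key=lambda i: counts[i])[-2:])
        lo, hi = top2
        if hi - lo > 1:
            valley = lo + 1 + int(np.argmin(counts[lo + 1:hi]))
            return float(centers[valley])
        return float(edges[hi])  # adjacent modes: boundary between them
    return float(0.5 * (v.mean() + v.max()))


def exg_segment(cloud: PointCloud, cfg: ExGConfig | None = None) -> PointCloud:
    """Keep points whose ExG is >= the (fixed or auto) threshold."""
    cfg = cfg or ExGConfig()
    values = exg(cloud.colors)
    thr = cfg.threshold if cfg.threshold is not None else exg_auto_threshold(values, cfg)
    return cloud.select(values >= thr)


def choose_k(colors: np.ndarray, prominence: float = 0.2) -> int:
    """Count dominant modes in a smoothed luminance histogram, clamped to [2, 4].

    A mode counts when its height exceeds ``prominence`` x the tallest mode
    and it is separated from stronger modes by a real valley.  Ambiguous or
    unimodal inputs return 2 (the background/target binary split).
    """
    c = np.asarray(colors, dtype=np.float64).reshape(-1, 3)
    if len(c) == 0:
        raise ValueError("choose_k needs at least one color")
    lum = c.mean(axis=1)
    counts, edges = np.histogram(lum, bins=32, range=(0, 255))
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    n = len(smooth)
    peaks = [i for i in range(n)
             if smooth[i] > 0
             and (i == 0 or smooth[i] > smooth[i - 1])
             and (i == n - 1 or smooth[i] >= smooth[i + 1])]
    if not peaks:
        return 2
    tallest = max(smooth[i] for i in peaks)
    major = [i for i in peaks if smooth[i] >= prominence * tallest]
    # merge peaks not separated by a valley dropping below half the smaller
    merged = [major[0]] if major else []
    for i in major[1:]:
        j = merged[-1]
        valley = smooth[j + 1:i].min() if i - j > 1 else min(smooth[i], smooth[j])
        if valley < 0.5 * min(smooth[i], smooth[j]):
            merged.append(i)
    k = len(merged)
    return int(np.clip(k, 2, 4))


def _farthest_color_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding in color space (deterministic per seed)."""
    n = len(X)
    first = int(rng.integers(n))
    centers = [X[first]]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(X[nxt])
        d2 = np.minimum(d2, ((X - centers[-1]) ** 2).sum(axis=1))
    return np.asarray(centers, dtype=np.float64)


def kmeans_color_denoise(
    cloud: PointCloud, cfg: ColorClusterConfig | None = None
) -> PointCloud:
    """Cluster points by RGB color and keep the plant-colored cluster(s).

    Runs Lloyd iterations (seeded greedy farthest-color initialization) until
    centroid movement drops below the tolerance, then retains the union of
    clusters whose mean ExG clears the vegetation floor (falling back to the
    single greenest cluster).  Output is a subset of the input with order
    preserved.
    """
    cfg = cfg or ColorClusterConfig()
    X = cloud.colors.astype(np.float64)
    n = len(X)
    k = choose_k(cloud.colors) if cfg.k == "auto" else int(cfg.k)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds point count {n}")
    if k == 1:
        return cloud.copy()

    rng = np.random.default_rng(cfg.seed)
    centers = _farthest_color_init(X, k, rng)
    assign = np.zeros(n, dtype=np.int64)
    for _ in range(cfg.max_iterations):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for j in range(k):
            members = X[assign == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift < cfg.tolerance:
            break

    cluster_exg = np.full(k, -np.inf)
    for j in range(k):
        members = cloud.colors[assign == j]
        if len(members):
            cluster_exg[j] = exg(members).mean()
    keep_clusters = np.where(cluster_exg >= cfg.vegetation_floor)[0]
    if len(keep_clusters) == 0:  # nothing vegetative: keep the greenest
        keep_clusters = np.array([int(np.argmax(cluster_exg))])
    return cloud.select(np.isin(assign, keep_clusters))
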