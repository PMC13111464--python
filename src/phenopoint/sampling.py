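"""Voxel-grid downsampling (VGDS) and farthest point sampling (FPS).

Both samplers report a hardware-independent ``distance_ops`` counter — the
number of point-to-point distance evaluations — alongside wall-clock time.
Greedy FPS performs N candidate updates per iteration, so its counter grows
as m*N; centroid-mode VGDS performs none, which is the complexity gap that
makes voxel sampling the practical choice for multi-million-point clouds.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud_core import PointCloud

__all__ = [
    "VoxelGridConfig",
    "FPSConfig",
    "SamplingResult",
    "voxel_downsample",
    "farthest_point_sample",
    "match_voxel_size_to_count",
    "benchmark_sampling",
]


@dataclass(frozen=True)
class VoxelGridConfig:
    """Voxel edge length in mm and the per-voxel representative rule.

    Cells are half-open ``[lo, lo + s)`` anchored at the cloud's min corner;
    points on the global max corner are clamped into the last cell.
    """

    voxel_size: float
    representative: str = "centroid"  # centroid | voxel_center | nearest_to_centroid

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.representative not in ("centroid", "voxel_center", "nearest_to_centroid"):
            raise ValueError(f"unknown representative mode {self.representative!r}")


@dataclass(frozen=True)
class FPSConfig:
    """Greedy max-min selection of ``target_count`` points.

    Distances are squared Euclidean; ties break to the lowest index; the
    start is index 0 unless ``start="random"`` (then drawn under ``seed``).
    """

    target_count: int
    start: str | int = 0  # point index, or "random"
    seed: int = 0


@dataclass
class SamplingResult:
    """Downsampling outcome with cost accounting.

    ``indices`` indexes into the input cloud when the representatives are
    original points (FPS, nearest_to_centroid); it is ``None`` for synthetic
    representatives (voxel centroids / centers).
    """

    cloud: PointCloud
    indices: np.ndarray | None
    distance_ops: int
    elapsed_s: float

    @property
    def count(self) -> int:
        return len(self.cloud)


# ---------------------------------------------------------------------------
# Voxel grid downsampling
# ---------------------------------------------------------------------------

def _voxel_indices(coords: np.ndarray, s: float) -> np.ndarray:
    lo = coords.min(axis=0)
    return np.floor((coords - lo) / s).astype(np.int64)


def voxel_downsample(cloud: PointCloud, cfg: VoxelGridConfig) -> SamplingResult:
    """One representative per occupied voxel, ordered by lexicographic voxel index.

    ``centroid`` averages coordinates and colors (labels take the majority
    vote); ``voxel_center`` emits cell centers; ``nearest_to_centroid``
    returns the original point closest to the cell centroid and counts one
    distance evaluation per in-cell point.
    """
    if len(cloud) == 0:
        raise ValueError("cannot downsample an empty cloud")
    t0 = time.perf_counter()
    coords = cloud.coords
    s = cfg.voxel_size
    vidx = _voxel_indices(coords, s)
    # lexicographic voxel key -> group id
    keys, inverse = np.unique(vidx, axis=0, return_inverse=True)
    n_vox = len(keys)
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)

    sums = np.zeros((n_vox, 3))
    np.add.at(sums, inverse, coords)
    centroids = sums / counts[:, None]

    csums = np.zeros((n_vox, 3))
    np.add.at(csums, inverse, cloud.colors.astype(np.float64))
    mean_colors = np.rint(csums / counts[:, None])

    labels = None
    if cloud.has_labels:
        labels = np.empty(n_vox, dtype=np.int64)
        order = np.argsort(inverse, kind="stable")
        bounds = np.searchsorted(inverse[order], np.arange(n_vox + 1))
        for v in range(n_vox):
            grp = cloud.labels[order[bounds[v]:bounds[v + 1]]]
            vals, cnts = np.unique(grp, return_counts=True)
            labels[v] = vals[np.argmax(cnts)]

    distance_ops = 0
    indices = None
    if cfg.representative == "centroid":
        out = PointCloud(centroids, mean_colors, labels)
    elif cfg.representative == "voxel_center":
        lo = coords.min(axis=0)
        out = PointCloud(lo + (keys + 0.5) * s, mean_colors, labels)
    else:  # nearest_to_centroid
        d2 = ((coords - centroids[inverse]) ** 2).sum(axis=1)
        distance_ops = len(coords)
        best = np.full(n_vox, -1, dtype=np.int64)
        bestd = np.full(n_vox, np.inf)
        for i in range(len(coords)):  # lowest index wins ties
            v = inverse[i]
            if d2[i] < bestd[v]:
                bestd[v] = d2[i]
                best[v] = i
        indices = best
        out = cloud.select(best)
    return SamplingResult(out, indices, distance_ops, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Farthest point sampling
# ---------------------------------------------------------------------------

def farthest_point_sample(cloud: PointCloud, cfg: FPSConfig) -> SamplingResult:
    """Greedy max-min subset selection.

    Each iteration adds the point maximizing the minimum squared distance to
    the already-selected set, updating one distance per candidate (N ops per
    iteration).  Deterministic under the start rule; ties break to the lowest
    index.
    """
    n = len(cloud)
    m = cfg.target_count
    if not 1 <= m <= n:
        raise ValueError(f"target count {m} must lie in [1, {n}]")
    t0 = time.perf_counter()
    coords = cloud.coords
    if cfg.start == "random":
        start = int(np.random.default_rng(cfg.seed).integers(n))
    else:
        start = int(cfg.start)
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start
    min_d2 = ((coords - coords[start]) ** 2).sum(axis=1)
    distance_ops = n
    for j in range(1, m):
        nxt = int(np.argmax(min_d2))  # argmax takes the lowest index on ties
        selected[j] = nxt
        d2 = ((coords - coords[nxt]) ** 2).sum(axis=1)
        distance_ops += n
        np.minimum(min_d2, d2, out=min_d2)
    return SamplingResult(cloud.select(selected), selected, distance_ops,
                          time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Exact-count voxel sampling
# ---------------------------------------------------------------------------

def match_voxel_size_to_count(
    cloud: PointCloud,
    target: int,
    tolerance: int = 0,
    seed: int = 0,
    representative: str = "centroid",
    max_iter: int = 50,
) -> tuple[VoxelGridConfig, SamplingResult]:
    """Bisect the voxel size until the output count reaches ``target``.

    Voxel occupancy is non-increasing in the edge length, so bisection over
    ``[eps, cloud diameter]`` converges; any residual mismatch is fixed by a
    seeded uniform drop (count > target) or by duplicating seeded random
    representatives (count < target), giving exactly ``target`` points —
    the fixed N' a set-abstraction level requires.
    """
    n = len(cloud)
    if not 1 <= target <= n:
        raise ValueError(f"target {target} must lie in [1, {n}]")
    diam = cloud.diameter()
    if diam == 0:
        if target > 1:
            raise ValueError("degenerate cloud: all points identical")
        cfg = VoxelGridConfig(1.0, representative)
        return cfg, voxel_downsample(cloud, cfg)

    lo, hi = 1e-9 * diam, diam
    best_cfg = VoxelGridConfig(hi, representative)
    best = voxel_downsample(cloud, best_cfg)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cfg = VoxelGridConfig(mid, representative)
        res = voxel_downsample(cloud, cfg)
        if abs(res.count - target) < abs(best.count - target) or (
            abs(res.count - target) == abs(best.count - target)
            and res.count >= target > best.count
        ):
            best, best_cfg = res, cfg
        if abs(res.count - target) <= tolerance and res.count >= target:
            best, best_cfg = res, cfg
            break
        if res.count > target:
            lo = mid
        else:
            hi = mid

    rng = np.random.default_rng(seed)
    res, cfg = best, best_cfg
    if res.count > target:
        keep = np.sort(rng.choice(res.count, size=target, replace=False))
        res = SamplingResult(res.cloud.select(keep),
                             None if res.indices is None else res.indices[keep],
                             res.distance_ops, res.elapsed_s)
    elif res.count < target:
        extra = rng.integers(res.count, size=target - res.count)
        sel = np.concatenate([np.arange(res.count), extra])
        res = SamplingResult(res.cloud.select(sel),
                             None if res.indices is None else res.indices[sel],
                             res.distance_ops, res.elapsed_s)
    return cfg, res


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

def benchmark_sampling(
    clouds: list[PointCloud],
    target: int,
    methods: tuple[str, ...] = ("vgds", "fps"),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cloud x method comparison at matched output counts.

    Returns a tidy DataFrame (method, grid_size_mm, input_points,
    output_points, runtime_s, distance_ops) plus per-method ``mean``/``std``
    summary rows, mirroring a runtime-comparison table layout.
    """
    if not clouds:
        raise ValueError("benchmark needs at least one cloud")
    rows = []
    for ci, cloud in enumerate(clouds):
        for method in methods:
            if method == "vgds":
                cfg, res = match_voxel_size_to_count(cloud, target, seed=seed)
                grid = cfg.voxel_size
            elif method == "fps":
                res = farthest_point_sample(cloud, FPSConfig(target))
                grid = np.nan
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(dict(cloud=ci, method=method, grid_size_mm=grid,
                             input_points=len(cloud), output_points=res.count,
                             runtime_s=res.elapsed_s, distance_ops=res.distance_ops))
    df = pd.DataFrame(rows)
    summary = (df.groupby("method")[["runtime_s", "distance_ops"]]
                 .agg(["mean", "std"]).fillna(0.0))
    df.attrs["summary"] = summary
    return df
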