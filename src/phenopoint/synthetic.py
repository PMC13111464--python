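"""Deterministic generator of labeled tomato-like point clouds.

Emulates single-view depth-camera acquisitions of greenhouse tomato
seedlings at the three-to-seven-true-leaves stage: a vertical stem cylinder
of known diameter, curved leaf bands with known midrib arc length, a dense
growing-point cluster at the apex, organ-specific color palettes, and gray
"flying pixel" noise scattered outward from silhouettes.  Every emitted
cloud carries per-point organ labels and a :class:`GroundTruth` record, so
the trait-extraction loop (segment -> measure) can be validated without the
original field data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .cloud_core import GROWING_POINT, STEM, PointCloud

__all__ = [
    "Palette",
    "LeafSpec",
    "PlantSpec",
    "GroundTruth",
    "generate_plant",
    "generate_stem_cylinder",
    "add_flying_pixels",
    "generate_dataset",
    "midrib_arc_length",
]


@dataclass(frozen=True)
class Palette:
    """Mean RGB and per-channel standard deviation, clipped to [0, 255]."""

    mean: tuple[float, float, float]
    std: float = 10.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        c = rng.normal(self.mean, self.std, size=(n, 3))
        return np.clip(np.rint(c), 0, 255).astype(np.uint8)


# Defaults chosen so ExG = 2G - R - B separates organs from noise:
# leaf green ~ +170, stem green-brown ~ +70, flower yellow ~ +120, gray ~ 0.
LEAF_GREEN = Palette((60, 150, 70), 10.0)
STEM_BROWN = Palette((100, 120, 70), 10.0)
FLOWER_YELLOW = Palette((200, 190, 60), 10.0)
NOISE_GRAY = Palette((128, 128, 128), 8.0)


@dataclass(frozen=True)
class LeafSpec:
    """One leaf: a band of half-width ``half_width_mm`` around a midrib curve.

    The midrib runs from the stem attachment outward along a horizontal
    direction at ``azimuth_deg``; over the normalized parameter s in [0, 1]
    it advances ``extent_mm * s`` outward, offsets sideways by the
    ``lateral_coeffs`` polynomial and vertically by the ``vertical_coeffs``
    polynomial (both evaluated in s, in mm, ascending order, zero constant
    term implied by construction).
    """

    azimuth_deg: float
    attach_height_frac: float
    extent_mm: float = 100.0
    lateral_coeffs: tuple[float, ...] = (0.0, 10.0, -10.0)   # s, s^2, s^3 ...
    vertical_coeffs: tuple[float, ...] = (60.0, -20.0, -30.0)
    half_width_mm: float = 8.0
    noise_sigma_mm: float = 1.0


@dataclass(frozen=True)
class PlantSpec:
    """Geometry, palettes and sampling density of one synthetic plant."""

    stem_diameter_mm: float = 8.0
    stem_height_mm: float = 150.0
    leaves: tuple[LeafSpec, ...] | None = None
    leaf_count: int = 5                      # used when ``leaves`` is None
    growing_point_radius_mm: float = 10.0
    growing_point_points: int = 1500
    point_density_per_mm2: float = 1.0
    stem_noise_sigma_mm: float = 0.1
    stem_arc_deg: float = 360.0              # 180 emulates single-view capture
    leaf_palette: Palette = LEAF_GREEN
    stem_palette: Palette = STEM_BROWN
    flower_palette: Palette = FLOWER_YELLOW
    noise_palette: Palette = NOISE_GRAY
    flying_pixel_count: int = 0
    flying_pixel_offset_mm: tuple[float, float] = (5.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stem_diameter_mm, self.stem_height_mm,
               self.growing_point_radius_mm, self.point_density_per_mm2) <= 0:
            raise ValueError("all plant dimensions and densities must be positive")
        if not 3 <= (len(self.leaves) if self.leaves is not None else self.leaf_count) <= 7:
            raise ValueError("leaf count must be 3-7 (seedling stage)")


@dataclass
class GroundTruth:
    """What the generator knows exactly: per-leaf midrib arc lengths (by fine
    quadrature on the generating curve), the stem diameter, and labels."""

    stem_diameter_mm: float
    leaf_lengths_mm: dict[int, float]        # leaf instance id (>= 2) -> mm
    labels: np.ndarray


def _poly_eval(coeffs: tuple[float, ...], s: np.ndarray) -> np.ndarray:
    """Polynomial with zero constant term: sum_j coeffs[j] * s^(j+1)."""
    out = np.zeros_like(s)
    for j, c in enumerate(coeffs):
        out += c * s ** (j + 1)
    return out


def _poly_deriv(coeffs: tuple[float, ...], s: np.ndarray) -> np.ndarray:
    out = np.zeros_like(s)
    for j, c in enumerate(coeffs):
        out += (j + 1) * c * s ** j
    return out


def midrib_arc_length(leaf: LeafSpec, n_intervals: int = 100_000) -> float:
    """Arc length of the generating midrib by composite-Simpson quadrature."""
    s = np.linspace(0.0, 1.0, n_intervals + 1)
    speed = np.sqrt(leaf.extent_mm ** 2
                    + _poly_deriv(leaf.lateral_coeffs, s) ** 2
                    + _poly_deriv(leaf.vertical_coeffs, s) ** 2)
    return float(simpson(speed, x=s))


def _sample_leaf(leaf: LeafSpec, attach: np.ndarray, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    phi = np.deg2rad(leaf.azimuth_deg)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])   # outward
    v = np.array([-np.sin(phi), np.cos(phi), 0.0])  # sideways
    s = rng.uniform(0.0, 1.0, n)
    w = rng.uniform(-leaf.half_width_mm, leaf.half_width_mm, n)
    pts = (attach[None, :]
           + np.outer(leaf.extent_mm * s + 0.0, u)
           + np.outer(_poly_eval(leaf.lateral_coeffs, s) + w, v))
    pts[:, 2] += _poly_eval(leaf.vertical_coeffs, s)
    pts += rng.normal(0.0, leaf.noise_sigma_mm, pts.shape)
    return pts


def generate_stem_cylinder(diameter_mm: float, height_mm: float,
                           density_per_mm2: float = 2.0,
                           noise_sigma_mm: float = 0.1,
                           arc_deg: float = 360.0,
                           center_xy: tuple[float, float] = (0.0, 0.0),
                           base_z: float = 0.0,
                           seed: int = 0) -> PointCloud:
    """Cylinder-surface samples (stem label 0); ``arc_deg`` < 360 keeps only
    the camera-facing arc, emulating single-view visibility."""
    rng = np.random.default_rng(seed)
    r = diameter_mm / 2.0
    n = max(16, int(density_per_mm2 * np.deg2rad(arc_deg) * r * height_mm))
    half = np.deg2rad(arc_deg) / 2.0
    theta = rng.uniform(-half, half, n)
    z = rng.uniform(base_z, base_z + height_mm, n)
    rr = r + rng.normal(0.0, noise_sigma_mm, n)
    pts = np.column_stack([center_xy[0] + rr * np.cos(theta),
                           center_xy[1] + rr * np.sin(theta), z])
    colors = STEM_BROWN.sample(n, rng)
    return PointCloud(pts, colors, np.full(n, STEM))


def _default_leaves(spec: PlantSpec, rng: np.random.Generator) -> tuple[LeafSpec, ...]:
    count = spec.leaf_count
    azim = rng.permutation(np.linspace(0, 360, count, endpoint=False)
                           + rng.uniform(-15, 15, count))
    leaves = []
    for i in range(count):
        leaves.append(LeafSpec(
            azimuth_deg=float(azim[i]),
            attach_height_frac=float(0.35 + 0.55 * i / max(count - 1, 1)),
            extent_mm=float(rng.uniform(70, 130)),
            lateral_coeffs=(float(rng.uniform(-15, 15)),
                            float(rng.uniform(-15, 15))),
            vertical_coeffs=(float(rng.uniform(30, 70)),
                             float(rng.uniform(-40, -5)),
                             float(rng.uniform(-40, -10))),
        ))
    return tuple(leaves)


def generate_plant(spec: PlantSpec) -> tuple[PointCloud, GroundTruth]:
    """Build one labeled plant: stem (0), growing point (1), leaves (2..n).

    Identical specs (same seed) produce bit-identical clouds.  Leaf ground
    truths are the midrib arc lengths of the generating curves.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = spec.leaves if spec.leaves is not None else _default_leaves(spec, rng)

    stem = generate_stem_cylinder(
        spec.stem_diameter_mm, spec.stem_height_mm,
        density_per_mm2=spec.point_density_per_mm2 * 2.0,  # stems are dense
        noise_sigma_mm=spec.stem_noise_sigma_mm,
        arc_deg=spec.stem_arc_deg,
        seed=int(rng.integers(2 ** 31)),
    )
    # recolor under this plant's palette for determinism of the master rng
    parts_coords = [stem.coords]
    parts_colors = [spec.stem_palette.sample(len(stem), rng)]
    parts_labels = [np.full(len(stem), STEM)]

    gp_n = spec.growing_point_points
    gp = rng.normal(0.0, spec.growing_point_radius_mm / 2.0, (gp_n, 3))
    gp = gp[np.linalg.norm(gp, axis=1) <= spec.growing_point_radius_mm * 1.5]
    gp += np.array([0.0, 0.0, spec.stem_height_mm])
    parts_coords.append(gp)
    parts_colors.append(spec.leaf_palette.sample(len(gp), rng))
    parts_labels.append(np.full(len(gp), GROWING_POINT))

    lengths: dict[int, float] = {}
    for i, leaf in enumerate(leaves):
        label = 2 + i
        attach = np.array([0.0, 0.0, leaf.attach_height_frac * spec.stem_height_mm])
        area = 2 * leaf.half_width_mm * leaf.extent_mm
        n = max(64, int(spec.point_density_per_mm2 * area))
        pts = _sample_leaf(leaf, attach, n, rng)
        parts_coords.append(pts)
        parts_colors.append(spec.leaf_palette.sample(n, rng))
        parts_labels.append(np.full(n, label))
        lengths[label] = midrib_arc_length(leaf)

    cloud = PointCloud(np.vstack(parts_coords), np.vstack(parts_colors),
                       np.concatenate(parts_labels))
    if spec.flying_pixel_count:
        cloud = add_flying_pixels(cloud, spec)
    truth = GroundTruth(spec.stem_diameter_mm, lengths, cloud.labels.copy())
    return cloud, truth


def add_flying_pixels(cloud: PointCloud, spec: PlantSpec) -> PointCloud:
    """Append gray noise points offset 5-30 mm outward from silhouette points.

    Silhouette points are those farthest from the plant's vertical axis in
    their height slab; offsets follow seeded random outward directions.  The
    appended points carry label -1.
    """
    n = spec.flying_pixel_count
    if n == 0:
        return cloud.copy()
    rng = np.random.default_rng(spec.seed + 1)
    axis_xy = cloud.coords[:, :2].mean(axis=0)
    radial = np.linalg.norm(cloud.coords[:, :2] - axis_xy, axis=1)
    # bias the anchor draw toward the silhouette (outer radii)
    p = radial - radial.min() + 1e-9
    anchors = cloud.coords[rng.choice(len(cloud), size=n, p=p / p.sum())]
    dirs = rng.normal(size=(n, 3))
    dirs[:, 2] *= 0.3  # flying pixels spread mostly laterally
    out_xy = anchors[:, :2] - axis_xy
    nrm = np.linalg.norm(out_xy, axis=1, keepdims=True) + 1e-9
    dirs[:, :2] += 1.5 * out_xy / nrm  # push outward, away from the plant
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dist = rng.uniform(*spec.flying_pixel_offset_mm, size=(n, 1))
    noise_pts = anchors + dirs * dist
    noise_colors = spec.noise_palette.sample(n, rng)
    labels = cloud.labels if cloud.has_labels else np.full(len(cloud), -1)
    return PointCloud(np.vstack([cloud.coords, noise_pts]),
                      np.vstack([cloud.colors, noise_colors]),
                      np.concatenate([labels, np.full(n, -1)]))


def generate_dataset(n_plants: int,
                     diameter_range_mm: tuple[float, float] = (4.0, 13.0),
                     leaf_count_range: tuple[int, int] = (3, 7),
                     seed: int = 0,
                     **spec_overrides) -> list[tuple[PointCloud, GroundTruth]]:
    """Corpus of plants with per-plant specs drawn from the given ranges.

    Stem diameters sweep the requested range deterministically (spanning it
    end to end); every other varying trait is drawn under a per-plant seed
    derived from the master seed.
    """
    if n_plants < 1:
        raise ValueError("need at least one plant")
    rng = np.random.default_rng(seed)
    out = []
    diam = np.linspace(*diameter_range_mm, n_plants)
    for i in range(n_plants):
        spec = PlantSpec(
            stem_diameter_mm=float(diam[i]),
            leaf_count=int(rng.integers(leaf_count_range[0], leaf_count_range[1] + 1)),
            seed=int(rng.integers(2 ** 31)),
            **spec_overrides,
        )
        out.append(generate_plant(spec))
    return out
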