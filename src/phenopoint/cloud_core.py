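"""Point-cloud data model, PLY I/O, ROI filtering, label scheme, augmentation.

The pipeline's universal currency is :class:`PointCloud`: coordinates in
millimetres, per-point 8-bit RGB colors, and an optional integer organ label
(-1 = unlabeled, 0 = stem, 1 = growing point, >= 2 = leaf instances).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "PointCloud",
    "LabelScheme",
    "ROIFilterConfig",
    "AugmentationScheme",
    "PLYParseError",
    "read_ply",
    "write_ply",
    "roi_filter",
    "augment",
    "coordinate_inversion",
    "collapse_labels",
    "train_test_split_plants",
]

STEM = 0
GROWING_POINT = 1
LEAF = 2  # semantic id after collapsing instances


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """Colored 3D point cloud in millimetres with optional organ labels.

    Parameters
    ----------
    coords
        ``(N, 3)`` float64 array of x, y, z in mm.
    colors
        ``(N, 3)`` uint8-valued array of R, G, B in [0, 255].
    labels
        Optional ``(N,)`` integer array; ``-1`` marks unlabeled points.
    """

    coords: np.ndarray
    colors: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors).reshape(-1, 3)
        if len(self.colors) != len(self.coords):
            raise ValueError("coords and colors must have equal length")
        if self.colors.size and (self.colors.min() < 0 or self.colors.max() > 255):
            raise ValueError("color channels must lie in [0, 255]")
        self.colors = self.colors.astype(np.uint8)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.coords):
                raise ValueError("labels must match point count")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def select(self, mask_or_indices) -> "PointCloud":
        """Sub-cloud at a boolean mask or index array, order preserved."""
        idx = np.asarray(mask_or_indices)
        return PointCloud(
            coords=self.coords[idx],
            colors=self.colors[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.coords.copy(),
            self.colors.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def diameter(self) -> float:
        """Length of the axis-aligned bounding-box diagonal (upper bound on
        the true diameter, sufficient wherever a scale is needed)."""
        if len(self) == 0:
            return 0.0
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(np.linalg.norm(span))


@dataclass(frozen=True)
class LabelScheme:
    """Organ label convention: stem = 0, growing point = 1, leaves >= 2.

    ``collapse`` maps every leaf-instance id (>= 2) onto the single semantic
    class ``leaf_semantic_id`` so the network trains on three classes.
    """

    stem_id: int = STEM
    growing_point_id: int = GROWING_POINT
    leaf_semantic_id: int = LEAF

    def collapse(self, label: int) -> int:
        if label in (self.stem_id, self.growing_point_id):
            return label
        if label >= 2:
            return self.leaf_semantic_id
        raise ValueError(f"label {label} is not a valid organ label")


@dataclass(frozen=True)
class ROIFilterConfig:
    """Per-axis closed intervals [lo, hi] in mm; ``None`` leaves an axis
    unbounded.  Documented acquisition defaults: depth z in [350, 450],
    height y in [500, 650]."""

    x: tuple[float, float] | None = None
    y: tuple[float, float] | None = None
    z: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, iv in (("x", self.x), ("y", self.y), ("z", self.z)):
            if iv is not None and iv[0] > iv[1]:
                raise ValueError(f"{name} interval has lo > hi")

    @property
    def intervals(self) -> tuple[tuple[float, float] | None, ...]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class AugmentationScheme:
    """Rotation x mirror expansion of each sample.

    The default scheme — 8 rotations at 45 deg steps composed with an
    optional horizontal mirror — emits exactly 16 variants per input, the
    composition that multiplies 68 originals into 1,088 training samples.
    Coordinate inversion is available separately (:func:`coordinate_inversion`).
    """

    rotation_angles_deg: tuple[float, ...] = (0, 45, 90, 135, 180, 225, 270, 315)
    mirror: bool = True
    rotation_axis: int = 2  # z is the vertical axis

    def n_variants(self) -> int:
        return len(self.rotation_angles_deg) * (2 if self.mirror else 1)


# ---------------------------------------------------------------------------
# PLY I/O (ASCII and binary little-endian; float x,y,z / uchar rgb / int label)
# ---------------------------------------------------------------------------

class PLYParseError(ValueError):
    """Raised on malformed PLY headers or truncated bodies."""


_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _parse_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Return (format, vertex count, [(type, name), ...], header byte length)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PLYParseError(f"not a PLY file (bad magic at byte 0: {magic[:16]!r})")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        pos = fh.tell()
        line = fh.readline()
        if not line:
            raise PLYParseError(f"header truncated at byte {pos}")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens:
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise PLYParseError(f"list vertex properties unsupported (byte {pos})")
            props.append((tokens[1], tokens[2]))
        elif tokens[0] == "end_header":
            break
    if fmt is None or n_vertex is None:
        raise PLYParseError("header missing format or vertex element")
    if fmt not in ("ascii", "binary_little_endian"):
        raise PLYParseError(f"unsupported PLY format {fmt!r}")
    names = [p[1] for p in props]
    for needed in ("x", "y", "z", "red", "green", "blue"):
        if needed not in names:
            raise PLYParseError(f"vertex element lacks required property {needed!r}")
    return fmt, n_vertex, props, fh.tell()


def read_ply(path: str | Path) -> PointCloud:
    """Read an ASCII or binary little-endian PLY into a :class:`PointCloud`.

    The vertex element must declare float ``x, y, z`` and uchar
    ``red, green, blue``; a scalar ``label`` property is picked up if present.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, n, props, body_off = _parse_header(fh)
        names = [p[1] for p in props]
        if fmt == "ascii":
            rows = []
            for i in range(n):
                pos = fh.tell()
                line = fh.readline()
                if not line:
                    raise PLYParseError(f"body truncated at vertex {i} (byte {pos})")
                vals = line.split()
                if len(vals) != len(props):
                    raise PLYParseError(
                        f"vertex {i} has {len(vals)} fields, expected {len(props)}"
                        f" (byte {pos})")
                rows.append([float(v) for v in vals])
            data = np.asarray(rows, dtype=np.float64).reshape(n, len(props))
        else:
            dt = np.dtype([(nm, "<" + _PLY_TYPES[tp]) for tp, nm in props])
            raw = fh.read(dt.itemsize * n)
            if len(raw) != dt.itemsize * n:
                raise PLYParseError(
                    f"body truncated: expected {dt.itemsize * n} bytes after "
                    f"byte {body_off}, got {len(raw)}")
            rec = np.frombuffer(raw, dtype=dt)
            data = np.column_stack([rec[nm].astype(np.float64) for _, nm in props])
    col = {nm: data[:, i] for i, nm in enumerate(names)}
    coords = np.column_stack([col["x"], col["y"], col["z"]])
    colors = np.column_stack([col["red"], col["green"], col["blue"]])
    labels = col["label"].astype(np.int64) if "label" in col else None
    return PointCloud(coords, np.rint(colors), labels)


def write_ply(cloud: PointCloud, path: str | Path, format: str = "binary_le") -> None:
    """Write a cloud as PLY; ``format`` is ``"ascii"`` or ``"binary_le"``.

    Binary files round-trip coordinates bit-exactly (float32 storage both
    ways is avoided by writing float64 ``x,y,z``).
    """
    if format not in ("ascii", "binary_le"):
        raise ValueError(f"unknown PLY format {format!r}")
    path = Path(path)
    n = len(cloud)
    header = ["ply"]
    header.append("format ascii 1.0" if format == "ascii"
                  else "format binary_little_endian 1.0")
    header.append(f"element vertex {n}")
    header += [f"property double {ax}" for ax in "xyz"]
    header += [f"property uchar {ch}" for ch in ("red", "green", "blue")]
    if cloud.has_labels:
        header.append("property int label")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if format == "ascii":
            for i in range(n):
                parts = [f"{v:.17g}" for v in cloud.coords[i]]
                parts += [str(int(v)) for v in cloud.colors[i]]
                if cloud.has_labels:
                    parts.append(str(int(cloud.labels[i])))
                fh.write((" ".join(parts) + "\n").encode("ascii"))
        else:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                      ("red", "u1"), ("green", "u1"), ("blue", "u1")]
            if cloud.has_labels:
                fields.append(("label", "<i4"))
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.coords.T
            rec["red"], rec["green"], rec["blue"] = cloud.colors.T
            if cloud.has_labels:
                rec["label"] = cloud.labels
            fh.write(rec.tobytes())


# ---------------------------------------------------------------------------
# ROI filtering
# ---------------------------------------------------------------------------

def roi_filter(cloud: PointCloud, cfg: ROIFilterConfig) -> PointCloud:
    """Keep exactly the points inside every bounded closed interval.

    Order is preserved; colors and labels are carried along.  Idempotent by
    construction.
    """
    mask = np.ones(len(cloud), dtype=bool)
    for axis, iv in enumerate(cfg.intervals):
        if iv is None:
            continue
        c = cloud.coords[:, axis]
        mask &= (c >= iv[0]) & (c <= iv[1])
    return cloud.select(mask)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _rotation_about_axis(angle_deg: float, axis: int) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    i, j = [a for a in range(3) if a != axis]
    R = np.eye(3)
    R[i, i], R[i, j], R[j, i], R[j, j] = c, -s, s, c
    return R


def augment(cloud: PointCloud, scheme: AugmentationScheme | None = None) -> list[PointCloud]:
    """Expand one cloud into its rotation x mirror variants.

    Rotations are taken about the scheme's axis through the cloud centroid;
    the mirror flips the first non-axis coordinate (a reflection through a
    vertical plane, i.e. "horizontal mirroring").  The 0 deg unmirrored
    variant is the input itself.
    """
    scheme = scheme or AugmentationScheme()
    if not scheme.rotation_angles_deg:
        raise ValueError("augmentation scheme needs at least one rotation angle")
    center = cloud.centroid()
    mirror_axis = 0 if scheme.rotation_axis != 0 else 1
    out: list[PointCloud] = []
    for mirrored in ([False, True] if scheme.mirror else [False]):
        base = cloud.coords - center
        if mirrored:
            base = base.copy()
            base[:, mirror_axis] = -base[:, mirror_axis]
        for ang in scheme.rotation_angles_deg:
            R = _rotation_about_axis(ang, scheme.rotation_axis)
            out.append(PointCloud(base @ R.T + center, cloud.colors,
                                  cloud.labels))
    return out


def coordinate_inversion(cloud: PointCloud) -> PointCloud:
    """Point reflection through the origin: (x, y, z) -> (-x, -y, -z)."""
    return PointCloud(-cloud.coords, cloud.colors, cloud.labels)


def collapse_labels(cloud: PointCloud, scheme: LabelScheme | None = None) -> PointCloud:
    """Map leaf-instance ids (>= 2) to the semantic leaf class.

    Result labels lie in {0 = stem, 1 = growing point, 2 = leaf}.
    """
    scheme = scheme or LabelScheme()
    if not cloud.has_labels:
        raise ValueError("collapse_labels requires a labeled cloud")
    lab = cloud.labels
    if np.any(lab < 0):
        bad = lab[lab < 0]
        if np.any(bad != -1):
            raise ValueError("negative labels other than -1 are invalid")
        raise ValueError("cloud contains unlabeled points (-1)")
    out = np.where(lab >= 2, scheme.leaf_semantic_id, lab)
    return PointCloud(cloud.coords, cloud.colors, out)


# ---------------------------------------------------------------------------
# Plant-level split
# ---------------------------------------------------------------------------

def train_test_split_plants(n_plants: int, train_fraction: float = 0.7,
                            seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Split plant indices before augmentation (no leakage across variants).

    The training count is ``round(train_fraction * n)`` with banker-free
    nearest-integer rounding, so 97 plants split 7:3 into 68 / 29.
    """
    n_train = int(np.floor(train_fraction * n_plants + 0.5))
    idx = np.arange(n_plants)
    if seed is not None:
        idx = np.random.default_rng(seed).permutation(n_plants)
    return idx[:n_train], idx[n_train:]


# ---------------------------------------------------------------------------
# Flat key/value config files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Read a flat key/value YAML config into typed config objects.

    Recognized keys (all optional; defaults are the dataclass defaults):
    ``roi_x / roi_y / roi_z`` ([lo, hi] in mm), ``rotation_angles_deg``,
    ``mirror``, ``rotation_axis``.  Unrecognized keys are returned verbatim
    under ``"extra"`` so downstream stages can pick up their own settings
    (voxel size, ExG threshold, k, degree, ...).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config file must be a flat key/value mapping")

    def interval(key):
        v = raw.get(key)
        return tuple(float(x) for x in v) if v is not None else None

    roi = ROIFilterConfig(interval("roi_x"), interval("roi_y"),
                          interval("roi_z"))
    scheme = AugmentationScheme(
        rotation_angles_deg=tuple(raw.get(
            "rotation_angles_deg", AugmentationScheme.rotation_angles_deg)),
        mirror=bool(raw.get("mirror", True)),
        rotation_axis=int(raw.get("rotation_axis", 2)),
    )
    known = {"roi_x", "roi_y", "roi_z", "rotation_angles_deg", "mirror",
             "rotation_axis"}
    extra = {k: v for k, v in raw.items() if k not in known}
    return {"roi": roi, "augmentation": scheme, "extra": extra}
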