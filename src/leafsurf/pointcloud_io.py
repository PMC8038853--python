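"""Point-cloud container, PLY I/O and preprocessing filters.

Clouds are ordered sets of 3D points (coordinates in mm) tagged with the
frame they live in: ``"world"`` (scanner coordinates, z vertical) or
``"leaf"`` (the per-leaf (l, w, h) system from :mod:`leafsurf.axes`).
Filters never modify coordinates; they return subsets and preserve each
point's identity label so provenance survives the whole pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import DegenerateGeometryError, PLYParseError

__all__ = [
    "PointCloud3",
    "PlaneFrame2",
    "PolygonRegion2",
    "read_ply",
    "write_ply",
    "remove_statistical_outliers",
    "filter_z_threshold",
    "segment_by_polygon",
]

WORLD = "world"
LEAF = "leaf"


@dataclass
class PointCloud3:
    """An ordered 3D point cloud with a coordinate-frame tag.

    Parameters
    ----------
    coords : (M, 3) float array, mm.
    frame : ``"world"`` or ``"leaf"``.
    index : (M,) integer identity labels, preserved across filtering.
        Defaults to 0..M-1.
    """

    coords: np.ndarray
    frame: str = WORLD
    index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point cloud contains non-finite coordinates")
        if self.frame not in (WORLD, LEAF):
            raise ValueError(f"unknown frame tag {self.frame!r}")
        if self.index is None:
            self.index = np.arange(len(self.coords))
        else:
            self.index = np.asarray(self.index, dtype=np.intp).reshape(-1)
            if len(self.index) != len(self.coords):
                raise ValueError("index labels must match point count")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        if len(self) == 0:
            raise ValueError("empty cloud has no centroid")
        return self.coords.mean(axis=0)

    def select(self, mask_or_indices: np.ndarray) -> "PointCloud3":
        """Subset the cloud, keeping order and identity labels."""
        return PointCloud3(
            self.coords[mask_or_indices],
            frame=self.frame,
            index=self.index[mask_or_indices],
        )

    def with_coords(self, coords: np.ndarray, frame: str | None = None) -> "PointCloud3":
        """Same identities, new coordinates (rigid transforms etc.)."""
        return PointCloud3(coords, frame=frame or self.frame, index=self.index.copy())


# ---------------------------------------------------------------------------
# PLY I/O
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(raw: bytes, path: str):
    """Parse the header; return (fmt, elements, data_offset).

    ``elements`` is a list of (name, count, [(prop_name, np_type_char)]);
    a list property is recorded with type ``None``.
    """
    end = raw.find(b"end_header")
    if end < 0:
        raise PLYParseError(f"{path}: line 1: missing 'end_header'")
    header = raw[:end].decode("ascii", errors="replace")
    lines = header.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PLYParseError(f"{path}: line 1: expected 'ply' magic, got {lines[0]!r}")

    fmt = None
    elements: list[tuple[str, int, list]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if not tokens or tokens[0] == "comment" or tokens[0] == "obj_info":
            continue
        if tokens[0] == "format":
            if len(tokens) != 3 or tokens[1] not in (
                "ascii", "binary_little_endian", "binary_big_endian"
            ):
                raise PLYParseError(f"{path}: line {lineno}: bad format line {line!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            if len(tokens) != 3 or not tokens[2].isdigit():
                raise PLYParseError(f"{path}: line {lineno}: bad element line {line!r}")
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise PLYParseError(
                    f"{path}: line {lineno}: property before any element"
                )
            if tokens[1] == "list":
                elements[-1][2].append((tokens[-1], None))
            else:
                if len(tokens) != 3 or tokens[1] not in _PLY_TYPES:
                    raise PLYParseError(
                        f"{path}: line {lineno}: unknown property type {line!r}"
                    )
                elements[-1][2].append((tokens[2], _PLY_TYPES[tokens[1]]))
        else:
            raise PLYParseError(f"{path}: line {lineno}: unknown keyword {tokens[0]!r}")
    if fmt is None:
        raise PLYParseError(f"{path}: line 2: missing 'format' line")

    # data begins after "end_header" and its newline
    nl = raw.find(b"\n", end)
    return fmt, elements, nl + 1


def read_ply(path: str | Path) -> PointCloud3:
    """Read a PLY point cloud (ASCII or binary, either endianness).

    Only the ``vertex`` element's x, y, z properties are used; extra
    per-vertex properties (color, NIR reflectance, ...) are skipped.
    A file with zero vertices yields an empty cloud.
    """
    path = Path(path)
    raw = path.read_bytes()
    fmt, elements, offset = _parse_ply_header(raw, str(path))

    names = [e[0] for e in elements]
    if "vertex" not in names:
        raise PLYParseError(f"{path}: header defines no 'vertex' element")
    vi = names.index("vertex")
    vname, vcount, vprops = elements[vi]
    pnames = [p for p, _ in vprops]
    if any(t is None for _, t in vprops):
        raise PLYParseError(f"{path}: list properties on the vertex element are unsupported")
    for c in ("x", "y", "z"):
        if c not in pnames:
            raise PLYParseError(f"{path}: vertex element lacks property '{c}'")
    if vcount == 0:
        return PointCloud3(np.empty((0, 3)), frame=WORLD)

    if fmt == "ascii":
        text = raw[offset:].decode("ascii", errors="replace").split()
        # skip elements preceding vertex (one scalar token per property)
        pos = 0
        for name, count, props in elements[:vi]:
            if any(t is None for _, t in props):
                raise PLYParseError(
                    f"{path}: cannot skip list-property element '{name}' before vertices"
                )
            pos += count * len(props)
        need = vcount * len(vprops)
        block = text[pos:pos + need]
        if len(block) < need:
            raise PLYParseError(f"{path}: truncated vertex data")
        arr = np.array(block, dtype=np.float64).reshape(vcount, len(vprops))
        cols = [pnames.index(c) for c in ("x", "y", "z")]
        coords = arr[:, cols]
    else:
        endian = "<" if fmt == "binary_little_endian" else ">"
        pos = offset
        for name, count, props in elements[:vi]:
            if any(t is None for _, t in props):
                raise PLYParseError(
                    f"{path}: cannot skip list-property element '{name}' before vertices"
                )
            itemsize = sum(np.dtype(endian + t).itemsize for _, t in props)
            pos += count * itemsize
        dtype = np.dtype([(p, endian + t) for p, t in vprops])
        need = vcount * dtype.itemsize
        if len(raw) - pos < need:
            raise PLYParseError(f"{path}: truncated vertex data")
        rec = np.frombuffer(raw, dtype=dtype, count=vcount, offset=pos)
        coords = np.stack(
            [rec["x"].astype(np.float64), rec["y"].astype(np.float64),
             rec["z"].astype(np.float64)], axis=1
        )
    return PointCloud3(coords, frame=WORLD)


def write_ply(cloud: PointCloud3, path: str | Path, encoding: str = "ascii") -> None:
    """Write a cloud as a vertex-only PLY re-readable by :func:`read_ply`.

    ASCII output keeps full double precision (17 significant digits), so
    an ASCII round trip reproduces coordinates bit-for-bit in practice.
    """
    if encoding not in ("ascii", "binary_little_endian", "binary_big_endian"):
        raise ValueError(f"unknown PLY encoding {encoding!r}")
    path = Path(path)
    n = len(cloud)
    header = (
        "ply\n"
        f"format {encoding} 1.0\n"
        f"element vertex {n}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if n == 0:
            return
        if encoding == "ascii":
            np.savetxt(fh, cloud.coords, fmt="%.17g")
        else:
            endian = "<" if encoding == "binary_little_endian" else ">"
            fh.write(np.ascontiguousarray(cloud.coords, dtype=endian + "f8").tobytes())


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def remove_statistical_outliers(
    cloud: PointCloud3, k_neighbors: int = 50, std_mult: float = 1.0
) -> PointCloud3:
    """Statistical outlier removal (mean k-nearest-neighbor distance test).

    For each point the mean Euclidean distance to its ``k_neighbors``
    nearest neighbors (query point excluded) is computed; points whose
    mean distance exceeds ``global mean + std_mult * global std`` are
    discarded. Order and identities of survivors are preserved.
    """
    m = len(cloud)
    if k_neighbors <= 0 or k_neighbors >= m:
        raise ValueError(
            f"k_neighbors must be in (0, {m}); got {k_neighbors}"
        )
    tree = cKDTree(cloud.coords)
    # k+1 because the nearest neighbor of each point is itself
    dists, _ = tree.query(cloud.coords, k=k_neighbors + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    threshold = mean_d.mean() + std_mult * mean_d.std()
    return cloud.select(mean_d <= threshold)


def filter_z_threshold(cloud: PointCloud3, z_min: float | None) -> PointCloud3:
    """Keep world-frame points strictly above ``z_min`` (soil clutter cut).

    ``z_min=None`` is the no-op sentinel.
    """
    if cloud.frame != WORLD:
        raise ValueError("z-threshold filter expects a world-frame cloud")
    if z_min is None:
        return cloud.select(np.ones(len(cloud), dtype=bool))
    return cloud.select(cloud.coords[:, 2] > z_min)


# ---------------------------------------------------------------------------
# Polygon segmentation
# ---------------------------------------------------------------------------

@dataclass
class PlaneFrame2:
    """A 2D projection plane embedded in 3D: origin + two orthonormal axes."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.u = np.asarray(self.u, dtype=np.float64).reshape(3)
        self.v = np.asarray(self.v, dtype=np.float64).reshape(3)
        for vec, name in ((self.u, "u"), (self.v, "v")):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-9:
                raise ValueError(f"plane axis {name} is not unit length")
        if abs(self.u @ self.v) > 1e-9:
            raise ValueError("plane axes are not orthogonal")

    def project(self, coords: np.ndarray) -> np.ndarray:
        rel = coords - self.origin
        return np.stack([rel @ self.u, rel @ self.v], axis=1)


@dataclass
class PolygonRegion2:
    """A simple polygon on a projection plane, used for manual leaf cut-outs."""

    vertices: np.ndarray
    plane: PlaneFrame2
    _poly: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise DegenerateGeometryError("polygon is self-intersecting or invalid")
        if poly.area <= 0.0:
            raise DegenerateGeometryError("polygon has zero area")
        self._poly = poly

    def contains(self, pts2d: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for an (M, 2) array."""
        return shapely.covers(self._poly, shapely.points(pts2d))

    def to_json(self) -> str:
        return json.dumps(
            {
                "plane_origin": self.plane.origin.tolist(),
                "plane_u": self.plane.u.tolist(),
                "plane_v": self.plane.v.tolist(),
                "vertices": self.vertices.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PolygonRegion2":
        d = json.loads(text)
        return cls(
            vertices=np.array(d["vertices"]),
            plane=PlaneFrame2(d["plane_origin"], d["plane_u"], d["plane_v"]),
        )


def segment_by_polygon(cloud: PointCloud3, region: PolygonRegion2) -> PointCloud3:
    """Keep the 3D points whose projection onto the region's plane falls
    inside or on the polygon (the manual leaf-segmentation primitive)."""
    pts2d = region.plane.project(cloud.coords)
    return cloud.select(region.contains(pts2d))
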