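"""Triangle-mesh data types, OBJ/PLY input/output and corresponded-mesh error measures.

All geometry is carried as millimetre coordinates in a right-handed frame with
+z pointing anteriorly (out of the face).  Meshes are strictly triangular: a
quad face in an input file is a contract violation, not something to repair
silently, because every downstream stage relies on vertex-level bookkeeping.

The two error measures — the average Euclidean distance (AED) between two
corresponded meshes and the per-vertex signed error map — assume *dense
correspondence*: both meshes share one triangulation and vertex ``i`` is the
same anatomical location on both.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "LandmarkSet",
    "FlatShape",
    "MeshFormatError",
    "CorrespondenceError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "flatten",
    "unflatten",
    "average_euclidean_distance",
    "signed_error_map",
]

#: axis index used for the sign convention of :func:`signed_error_map`
ANTERIOR_AXIS = 2


class MeshFormatError(ValueError):
    """A mesh or landmark file violates the supported dialect."""


class CorrespondenceError(ValueError):
    """Two meshes that must be in dense correspondence are not."""


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3) triangles, got {self.faces.shape}")
        if len(self.vertices) < 3 or len(self.faces) < 1:
            raise ValueError("mesh needs at least 3 vertices and 1 triangle")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices contain NaN/Inf")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def with_vertices(self, vertices: np.ndarray, id: str | None = None) -> "TriMesh":
        """Same triangulation, new vertex positions."""
        return TriMesh(vertices, self.faces, self.id if id is None else id)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        vn = np.zeros_like(v)
        for c in range(3):
            np.add.at(vn, f[:, c], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TriMesh):
            return NotImplemented
        return (
            self.vertices.shape == other.vertices.shape
            and np.array_equal(self.vertices, other.vertices)
            and np.array_equal(self.faces, other.faces)
        )


@dataclass
class LandmarkSet:
    """Sparse named 3D landmarks belonging to one mesh."""

    mesh_id: str
    points: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"landmark points must be (k, 3), got {self.points.shape}")
        if not self.names:
            self.names = [f"lm{i}" for i in range(len(self.points))]
        if len(self.names) != len(self.points):
            raise ValueError("one name per landmark required")

    def validate_on(self, mesh: TriMesh, tolerance: float = 10.0) -> None:
        """Check every landmark lies within the mesh bounding box ± *tolerance* mm."""
        lo = mesh.vertices.min(axis=0) - tolerance
        hi = mesh.vertices.max(axis=0) + tolerance
        bad = np.any((self.points < lo) | (self.points > hi), axis=1)
        if bad.any():
            names = [self.names[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"landmarks outside mesh bounding box (+{tolerance} mm): {names}")


@dataclass
class FlatShape:
    """One shape as the concatenated coordinate vector X = [x1, y1, z1, x2, ...] of length 3n."""

    x: np.ndarray
    n_vertices: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        if self.x.size % 3 != 0:
            raise ValueError(f"flat shape length {self.x.size} not divisible by 3")
        n = self.x.size // 3
        if self.n_vertices == 0:
            self.n_vertices = n
        elif self.n_vertices != n:
            raise ValueError("n_vertices inconsistent with vector length")

    def as_points(self) -> np.ndarray:
        return self.x.reshape(-1, 3)


def flatten(mesh: TriMesh) -> FlatShape:
    """Concatenate vertex coordinates into a single length-3n vector."""
    return FlatShape(mesh.vertices.reshape(-1).copy(), mesh.n_vertices)


def unflatten(shape: FlatShape | np.ndarray, faces: np.ndarray, id: str = "") -> TriMesh:
    """Rebuild a :class:`TriMesh` from a flat coordinate vector and a triangulation."""
    x = shape.x if isinstance(shape, FlatShape) else np.asarray(shape, dtype=np.float64).ravel()
    if x.size % 3 != 0:
        raise ValueError(f"flat shape length {x.size} not divisible by 3")
    return TriMesh(x.reshape(-1, 3), faces, id)


# ---------------------------------------------------------------------------
# error measures


def _check_corresponded(a: TriMesh, b: TriMesh) -> None:
    if a.n_vertices != b.n_vertices:
        raise CorrespondenceError(
            f"meshes not in correspondence: {a.n_vertices} vs {b.n_vertices} vertices"
        )


def average_euclidean_distance(
    a: TriMesh, b: TriMesh, mask: np.ndarray | None = None
) -> float:
    """Mean per-vertex Euclidean distance (mm) between two corresponded meshes.

    ``AED = (1/n) * sum_i ||a_i - b_i||``.  *mask* optionally restricts the
    average to a boolean vertex subset (e.g. a cropped facial region).
    """
    _check_corresponded(a, b)
    d = np.linalg.norm(a.vertices - b.vertices, axis=1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (a.n_vertices,):
            raise ValueError("mask must be a boolean per-vertex array")
        if not mask.any():
            raise ValueError("mask selects no vertices")
        d = d[mask]
    return float(d.mean())


def signed_error_map(
    reference: TriMesh, other: TriMesh, axis: int = ANTERIOR_AXIS
) -> np.ndarray:
    """Per-vertex signed distance (mm) between corresponded meshes.

    Magnitude is the Euclidean vertex distance; the sign is positive where the
    reference has the larger coordinate on *axis* (default the anterior z axis,
    i.e. positive means "reference more protrusive").  Zero-difference ties take
    the positive sign; their magnitude is 0 so the choice is immaterial.
    """
    _check_corresponded(reference, other)
    d = np.linalg.norm(reference.vertices - other.vertices, axis=1)
    sign = np.where(reference.vertices[:, axis] >= other.vertices[:, axis], 1.0, -1.0)
    return d * sign


# ---------------------------------------------------------------------------
# OBJ I/O (ASCII, v/f records; 1-based indices converted at this boundary)


def _read_obj(path: Path) -> TriMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(parts[1]), float(parts[2]), float(parts[3])])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: bad vertex coordinate: {exc}")
            elif tag == "f":
                idx = parts[1:]
                if len(idx) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: only triangular faces supported, got {len(idx)} indices"
                    )
                try:
                    # v, v/vt, v/vt/vn and v//vn forms all start with the vertex index
                    faces.append([int(tok.split("/")[0]) - 1 for tok in idx])
                except ValueError as exc:
                    raise MeshFormatError(f"{path}:{lineno}: bad face index: {exc}")
            # other records (vn, vt, o, g, s, usemtl, ...) carry no geometry we keep
    if not vertices or not faces:
        raise MeshFormatError(f"{path}: no vertices/faces found")
    return TriMesh(np.array(vertices), np.array(faces), id=path.stem)


def _write_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for v in mesh.vertices:
            fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# PLY I/O (ASCII and binary little-endian; optional per-vertex "quality")

_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _parse_ply_header(fh) -> tuple[str, list[tuple[str, int, list]], int]:
    """Return (format, [(element, count, [props])], header byte length)."""
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise MeshFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list]] = []
    offset = len(magic)
    while True:
        raw = fh.readline()
        if not raw:
            raise MeshFormatError("unexpected end of PLY header")
        offset += len(raw)
        line = raw.decode("ascii", "replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        parts = line.split()
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise MeshFormatError("PLY property before any element")
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1][2].append(("scalar", parts[1], parts[2]))
        elif parts[0] == "end_header":
            break
        else:
            raise MeshFormatError(f"unsupported PLY header record: {line!r}")
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements, offset


def _read_ply(path: Path) -> TriMesh:
    with open(path, "rb") as fh:
        fmt, elements, _ = _parse_ply_header(fh)
        data: dict[str, dict] = {}
        if fmt == "ascii":
            tokens = fh.read().decode("ascii").split()
            pos = 0

            def take(n: int) -> list[str]:
                nonlocal pos
                if pos + n > len(tokens):
                    raise MeshFormatError(f"{path}: truncated PLY body at token {pos}")
                out = tokens[pos:pos + n]
                pos += n
                return out

            for name, count, props in elements:
                cols: dict[str, list] = {p[2] if p[0] == "scalar" else p[3]: [] for p in props}
                for _ in range(count):
                    for p in props:
                        if p[0] == "scalar":
                            cols[p[2]].append(float(take(1)[0]))
                        else:
                            k = int(take(1)[0])
                            cols[p[3]].append([int(float(t)) for t in take(k)])
                data[name] = cols
        else:
            for name, count, props in elements:
                cols = {p[2] if p[0] == "scalar" else p[3]: [] for p in props}
                if all(p[0] == "scalar" for p in props):
                    fmt_str = "<" + "".join(_PLY_TYPES[p[1]] for p in props)
                    size = struct.calcsize(fmt_str)
                    buf = fh.read(size * count)
                    if len(buf) != size * count:
                        raise MeshFormatError(f"{path}: truncated PLY element {name!r}")
                    for row in struct.iter_unpack(fmt_str, buf):
                        for p, val in zip(props, row):
                            cols[p[2]].append(val)
                else:
                    for _ in range(count):
                        for p in props:
                            if p[0] == "scalar":
                                code = _PLY_TYPES[p[1]]
                                sz = struct.calcsize(code)
                                cols[p[2]].append(struct.unpack("<" + code, fh.read(sz))[0])
                            else:
                                ccode, icode = _PLY_TYPES[p[1]], _PLY_TYPES[p[2]]
                                k = struct.unpack("<" + ccode, fh.read(struct.calcsize(ccode)))[0]
                                isz = struct.calcsize(icode)
                                cols[p[3]].append(
                                    list(struct.unpack(f"<{k}{icode}", fh.read(k * isz)))
                                )
                data[name] = cols
    if "vertex" not in data or "face" not in data:
        raise MeshFormatError(f"{path}: PLY missing vertex or face element")
    vd = data["vertex"]
    try:
        vertices = np.column_stack([vd["x"], vd["y"], vd["z"]]).astype(np.float64)
    except KeyError as exc:
        raise MeshFormatError(f"{path}: PLY vertex element lacks {exc} property")
    face_lists = next(iter(data["face"].values()))
    for i, fl in enumerate(face_lists):
        if len(fl) != 3:
            raise MeshFormatError(
                f"{path}: face {i} has {len(fl)} vertices; only triangles supported"
            )
    return TriMesh(vertices, np.array(face_lists, dtype=np.int64), id=path.stem)


def _write_ply(
    mesh: TriMesh, path: Path, binary: bool = False, quality: np.ndarray | None = None
) -> None:
    if quality is not None:
        quality = np.asarray(quality, dtype=np.float64)
        if quality.shape != (mesh.n_vertices,):
            raise ValueError("quality must be one scalar per vertex")
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0"]
    header += [f"element vertex {mesh.n_vertices}"]
    header += ["property double x", "property double y", "property double z"]
    if quality is not None:
        header += ["property double quality"]
    header += [f"element face {len(mesh.faces)}",
               "property list uchar int vertex_indices", "end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            cols = [mesh.vertices]
            if quality is not None:
                cols.append(quality[:, None])
            fh.write(np.ascontiguousarray(np.hstack(cols), dtype="<f8").tobytes())
            for f in mesh.faces:
                fh.write(struct.pack("<Biii", 3, *f))
        else:
            for i, v in enumerate(mesh.vertices):
                row = f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}"
                if quality is not None:
                    row += f" {float(quality[i])!r}"
                fh.write((row + "\n").encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def read_mesh(path: str | Path, format: str | None = None) -> TriMesh:
    """Read a triangle mesh from an ASCII OBJ or an ASCII/binary-LE PLY file."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        return _read_obj(path)
    if fmt == "ply":
        return _read_ply(path)
    raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")


def write_mesh(
    mesh: TriMesh,
    path: str | Path,
    format: str | None = None,
    binary: bool = False,
    quality: np.ndarray | None = None,
) -> None:
    """Write *mesh* as OBJ or PLY; *quality* adds a per-vertex scalar (PLY only)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "obj":
        if quality is not None:
            raise ValueError("per-vertex quality export requires PLY")
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, binary=binary, quality=quality)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# landmark I/O: header line of names, then one "x y z" (or CSV) row per landmark


def read_landmarks(path: str | Path, mesh_id: str | None = None) -> LandmarkSet:
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise MeshFormatError(f"{path}: landmark file needs a header and at least one row")
    sep = "," if "," in lines[0] else None
    names = [t.strip() for t in lines[0].split(sep)]
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = [t.strip() for t in line.split("," if "," in line else None)]
        if len(toks) != 3:
            raise MeshFormatError(f"{path}:{lineno}: expected 3 coordinates, got {len(toks)}")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise MeshFormatError(f"{path}:{lineno}: bad coordinate: {exc}")
    if len(rows) != len(names):
        raise MeshFormatError(
            f"{path}: header names {len(names)} landmarks but {len(rows)} rows follow"
        )
    return LandmarkSet(mesh_id or path.stem, np.array(rows), names)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(landmarks.names) + "\n")
        for p in landmarks.points:
            fh.write(f"{float(p[0])!r},{float(p[1])!r},{float(p[2])!r}\n")
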