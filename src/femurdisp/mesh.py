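"""Domain types and file I/O for femur surface meshes and landmarks.

All coordinates are in millimetres.  Files carry no unit metadata (STL has
none); inputs are assumed to be expressed in a patient-like, right-handed
frame in which the sagittal mirror plane is ``x = 0`` unless the caller
overrides the plane.

Mesh reading and writing is delegated to :mod:`trimesh`.  Meshes are always
loaded with ``process=False`` so the vertex order on disk is preserved —
per-vertex region masks are keyed to that order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError

# Region label convention for the per-vertex mask.
REGION_SHAFT = 0
REGION_NECK = 1
REGION_HEAD = 2
REGION_NAMES = {REGION_SHAFT: "shaft", REGION_NECK: "neck", REGION_HEAD: "head"}
REGION_CODES = {v: k for k, v in REGION_NAMES.items()}

_MESH_FORMATS = ("stl", "stl_ascii", "ply", "obj")


def _as_points(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"{name} must be an (n, 3) array, got shape {a.shape}")
    return a


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) in mm and ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(
                f"faces must be an (m, 3) array, got shape {self.faces.shape}"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> "TriangleMesh":
        """Check structural invariants, raising :class:`ValidationError`."""
        if self.n_vertices < 4:
            raise ValidationError(
                f"mesh must have at least 4 vertices, got {self.n_vertices}"
            )
        if self.n_faces < 1:
            raise ValidationError("mesh has no faces")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("mesh contains non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValidationError(
                "face index out of range: "
                f"indices span [{self.faces.min()}, {self.faces.max()}] "
                f"for {self.n_vertices} vertices"
            )
        degenerate = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degenerate.any():
            raise ValidationError(
                f"{int(degenerate.sum())} degenerate face(s) with repeated vertices"
            )
        return self

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def surface_area(self) -> float:
        return float(self.to_trimesh().area)


@dataclass
class FemurModel:
    """A proximal-femur surface with side label and per-vertex region mask.

    ``region_mask`` holds one integer per vertex: 0 = shaft, 1 = neck,
    2 = head.
    """

    mesh: TriangleMesh
    side: str
    region_mask: np.ndarray

    def __post_init__(self) -> None:
        self.region_mask = np.asarray(self.region_mask, dtype=np.int64)

    def validate(self) -> "FemurModel":
        self.mesh.validate()
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.region_mask.shape != (self.mesh.n_vertices,):
            raise ValidationError(
                f"region mask length {self.region_mask.shape} does not match "
                f"{self.mesh.n_vertices} vertices"
            )
        bad = ~np.isin(self.region_mask, list(REGION_NAMES))
        if bad.any():
            raise ValidationError(
                f"region mask contains labels outside {{0, 1, 2}}: "
                f"{sorted(set(self.region_mask[bad].tolist()))}"
            )
        return self

    def region_vertices(self, regions) -> np.ndarray:
        """Vertices whose label is in ``regions`` (names or integer codes)."""
        return self.mesh.vertices[self.region_indices(regions)]

    def region_indices(self, regions) -> np.ndarray:
        codes = [REGION_CODES.get(r, r) for r in regions]
        return np.flatnonzero(np.isin(self.region_mask, codes))

    def copy(self) -> "FemurModel":
        return FemurModel(self.mesh.copy(), self.side, self.region_mask.copy())


@dataclass
class LandmarkSet:
    """Named anatomical points: femoral head center and deepest fovea point."""

    side: str
    head_center: np.ndarray | None = None
    fovea_deepest: np.ndarray | None = None
    source: str = "fitted"

    def __post_init__(self) -> None:
        for name in ("head_center", "fovea_deepest"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).reshape(3))

    def validate(self) -> "LandmarkSet":
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.source not in ("fitted", "manual"):
            raise ValidationError(f"source must be 'fitted' or 'manual', got {self.source!r}")
        for name in ("head_center", "fovea_deepest"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v).all():
                raise ValidationError(f"landmark {name} has non-finite coordinates")
        if (
            self.head_center is not None
            and self.fovea_deepest is not None
            and np.array_equal(self.head_center, self.fovea_deepest)
        ):
            raise ValidationError("fovea_deepest coincides with head_center")
        return self

    def to_dict(self) -> dict:
        d: dict = {"side": self.side, "source": self.source}
        if self.head_center is not None:
            d["head_center"] = self.head_center.tolist()
        if self.fovea_deepest is not None:
            d["fovea_deepest"] = self.fovea_deepest.tolist()
        return d


@dataclass
class Sphere:
    """A fitted sphere: center (mm) and radius (mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radius = float(self.radius)

    def validate(self) -> "Sphere":
        if not np.isfinite(self.center).all():
            raise ValidationError("sphere center has non-finite coordinates")
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValidationError(f"sphere radius must be positive, got {self.radius}")
        return self


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` with R orthonormal, det(R) = +1."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def validate(self, tol: float = 1e-9) -> "RigidTransform":
        r = self.rotation
        if not np.isfinite(r).all() or not np.isfinite(self.translation).all():
            raise ValidationError("transform contains non-finite entries")
        if np.abs(r @ r.T - np.eye(3)).max() > tol:
            raise ValidationError("rotation matrix is not orthonormal within 1e-9")
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise ValidationError("rotation determinant differs from +1 by more than 1e-9")
        return self

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValidationError("rotation axis has zero length")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


# ---------------------------------------------------------------------------
# File I/O


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read an STL/PLY/OBJ surface into a validated :class:`TriangleMesh`.

    ``fmt`` overrides format sniffing from the file extension.  Vertex order
    is preserved exactly as stored (no merging or re-processing).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises assorted types
        raise IOError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise ValidationError(f"mesh file {path} contains no geometry")
        tm = geoms[0]
    mesh = TriangleMesh.from_trimesh(tm)
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix.startswith("stl"):
        # STL is a triangle soup with no shared vertex list; merge exact
        # duplicates deterministically in first-occurrence order
        mesh = _dedupe_vertices(mesh)
    return mesh.validate()


def _dedupe_vertices(mesh: TriangleMesh) -> TriangleMesh:
    _, first, inverse = np.unique(
        mesh.vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)  # first-occurrence order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = mesh.vertices[first[order]]
    faces = rank[inverse][mesh.faces]
    return TriangleMesh(vertices, faces)


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a validated mesh as STL (binary or ASCII), PLY, or OBJ."""
    mesh.validate()
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "stl"
    if fmt not in _MESH_FORMATS:
        raise ValidationError(f"unsupported mesh format {fmt!r}; use one of {_MESH_FORMATS}")
    tm = mesh.to_trimesh()
    try:
        if fmt == "stl_ascii":
            path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
        else:
            tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise IOError(f"could not write mesh to {path}: {exc}") from exc


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file (keys: side, head_center, fovea_deepest).

    Unknown keys are ignored; missing optional points are permitted (their
    absence only matters when an operation needs them).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except OSError as exc:
        raise IOError(f"could not read landmark file {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed landmark JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"landmark file {path} must hold a JSON object")
    if "side" not in doc:
        raise ValidationError(f"landmark file {path} is missing the 'side' key")
    lm = LandmarkSet(
        side=doc["side"],
        head_center=doc.get("head_center"),
        fovea_deepest=doc.get("fovea_deepest"),
        source=doc.get("source", "manual"),
    )
    return lm.validate()


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.validate().to_dict(), indent=2))


def read_region_mask(path, n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex region mask: newline-delimited ints or a JSON array."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValidationError(f"region mask file {path} is empty")
    if text.lstrip().startswith("["):
        mask = np.asarray(json.loads(text), dtype=np.int64)
    else:
        mask = np.asarray([int(line) for line in text.split()], dtype=np.int64)
    if n_vertices is not None and len(mask) != n_vertices:
        raise ValidationError(
            f"region mask length {len(mask)} does not match {n_vertices} vertices"
        )
    return mask


def write_region_mask(mask: np.ndarray, path) -> None:
    Path(path).write_text("\n".join(str(int(v)) for v in np.asarray(mask)) + "\n")
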