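"""Geometric primitives of the measurement: sphere fitting, mirroring,
rigid (ICP) registration, and distance/angle computations.

The sphere fit follows the standard two-stage scheme: an algebraic linear
least-squares fit provides the initializer, and a geometric (orthogonal
distance) refinement minimizes sum((|p - c| - r)^2).  The robust variant
drops points whose inward radial deficit exceeds a threshold — on a femoral
head these are the fovea-pit vertices, which would otherwise pull the
"close-fit sphere" inward — and refits until the exclusion set stabilizes.

Registration is nearest-vertex ICP anchored, by pipeline default, on the
shaft and neck regions only: the displaced head fragment must not drive the
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, ValidationError
from .mesh import FemurModel, RigidTransform, Sphere


@dataclass
class SphereFitReport:
    sphere: Sphere
    rms_residual: float
    n_points_used: int
    n_excluded: int
    iterations: int


@dataclass
class RegistrationReport:
    transform: RigidTransform
    rms_error: float
    iterations: int
    converged: bool


@dataclass(frozen=True)
class MirrorPlane:
    """A plane given by a point on it and a (normalized) unit normal."""

    point: tuple = (0.0, 0.0, 0.0)
    normal: tuple = (1.0, 0.0, 0.0)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-9:
            raise ValidationError("mirror plane normal has (near-)zero length")
        return p, n / norm


#: Default sagittal mirror plane: x = 0.
SAGITTAL_PLANE = MirrorPlane()


# ---------------------------------------------------------------------------
# Sphere fitting


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere: solve |p|^2 = 2 c.p + (r^2 - |c|^2)."""
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, _, rank, sv = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4 or sv[0] / max(sv[-1], 1e-300) > 1e10:
        raise DegenerateGeometryError(
            "points are coplanar or nearly so; sphere fit is ill-posed "
            f"(condition number {sv[0] / max(sv[-1], 1e-300):.2e})"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced non-positive radius")
    return center, float(np.sqrt(r2))


def _radial_residuals(x: np.ndarray, points: np.ndarray) -> np.ndarray:
    return np.linalg.norm(points - x[:3], axis=1) - x[3]


def _geometric_sphere(points: np.ndarray, c0: np.ndarray, r0: float) -> tuple[np.ndarray, float]:
    res = least_squares(
        _radial_residuals, np.r_[c0, r0], args=(points,), method="lm", xtol=1e-14, ftol=1e-14
    )
    return res.x[:3], float(res.x[3])


def _fit_once(points: np.ndarray) -> tuple[Sphere, float]:
    c0, r0 = _algebraic_sphere(points)
    c, r = _geometric_sphere(points, c0, r0)
    rms_alg = float(np.sqrt(np.mean(_radial_residuals(np.r_[c0, r0], points) ** 2)))
    rms_geo = float(np.sqrt(np.mean(_radial_residuals(np.r_[c, r], points) ** 2)))
    # The refinement must never be worse than its initializer.
    if rms_geo > rms_alg:
        c, r, rms_geo = c0, r0, rms_alg
    return Sphere(c, r).validate(), rms_geo


def fit_sphere(
    points: np.ndarray,
    robust: bool = False,
    inlier_deficit_mm: float = 0.5,
    max_passes: int = 5,
) -> SphereFitReport:
    """Least-squares sphere fit with optional robust fovea exclusion.

    Parameters
    ----------
    points
        (n, 3) array, n >= 4, not (near-)coplanar.
    robust
        When true, points whose *inward* radial deficit ``r - |p - c|``
        exceeds ``inlier_deficit_mm`` are excluded and the fit repeated,
        up to ``max_passes`` passes or until the exclusion set is stable.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValidationError(f"points must be (n, 3), got shape {points.shape}")
    if len(points) < 4:
        raise ValidationError(f"sphere fit needs at least 4 points, got {len(points)}")
    if not np.isfinite(points).all():
        raise ValidationError("points contain non-finite coordinates")

    keep = np.ones(len(points), dtype=bool)
    sphere, rms = _fit_once(points)
    passes = 1
    if robust:
        while passes < max_passes:
            deficit = sphere.radius - np.linalg.norm(points - sphere.center, axis=1)
            new_keep = deficit <= inlier_deficit_mm
            if new_keep.sum() < 4 or np.array_equal(new_keep, keep):
                break
            keep = new_keep
            sphere, rms = _fit_once(points[keep])
            passes += 1
    return SphereFitReport(
        sphere=sphere,
        rms_residual=rms,
        n_points_used=int(keep.sum()),
        n_excluded=int(len(points) - keep.sum()),
        iterations=passes,
    )


# ---------------------------------------------------------------------------
# Mirroring


def reflect_points(points: np.ndarray, plane: MirrorPlane) -> np.ndarray:
    """Reflect points across a plane (Householder reflection)."""
    p0, n = plane.as_arrays()
    points = np.asarray(points, dtype=float)
    d = (points - p0) @ n
    return points - 2.0 * np.outer(d, n)


def mirror_mesh(model: FemurModel, plane: MirrorPlane = SAGITTAL_PLANE) -> FemurModel:
    """Mirror a femur model across a plane.

    Face winding is reversed so outward normals survive the orientation
    flip, and the side label is swapped.  The region mask is untouched
    (vertex order is preserved).
    """
    model.validate()
    vertices = reflect_points(model.mesh.vertices, plane)
    faces = model.mesh.faces[:, ::-1].copy()
    side = "right" if model.side == "left" else "left"
    from .mesh import TriangleMesh

    return FemurModel(TriangleMesh(vertices, faces), side, model.region_mask.copy())


# ---------------------------------------------------------------------------
# Rigid registration (ICP)


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired source onto target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, tc - r @ sc)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    """Right-handed eigenbasis of the point covariance, descending variance."""
    c = np.cov((points - points.mean(axis=0)).T)
    w, v = np.linalg.eigh(c)
    v = v[:, ::-1]  # descending eigenvalue order
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _initial_alignment(source: np.ndarray, target: np.ndarray, tree: cKDTree) -> RigidTransform:
    """Centroid + principal-axes initialization.

    The eigenvector sign ambiguity leaves four proper-rotation candidates;
    the one with the smallest nearest-neighbour RMS after alignment wins,
    ties broken in favour of the rotation closest to the identity.
    """
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    vs, vt_ = _principal_axes(source), _principal_axes(target)
    best: tuple[float, float, RigidTransform] | None = None
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flip = np.diag([s1, s2, s1 * s2])  # keeps det = +1
        r = vt_ @ flip @ vs.T
        t = RigidTransform(r, tc - r @ sc)
        d, _ = tree.query(t.apply(source), k=1)
        rms = float(np.sqrt(np.mean(d**2)))
        identity_gap = float(np.linalg.norm(r - np.eye(3)))
        key = (round(rms, 9), identity_gap)
        if best is None or key < (round(best[0], 9), best[1]):
            best = (rms, identity_gap, t)
    assert best is not None
    return best[2]


def register_rigid(
    source: FemurModel,
    target: FemurModel,
    regions=("shaft", "neck"),
    max_iterations: int = 200,
    tol: float = 1e-6,
    trim_fraction: float = 1.0,
    max_points: int | None = None,
    sanity_rms_mm: float = 10.0,
    subsample_seed: int = 0,
) -> RegistrationReport:
    """Register ``source`` onto ``target`` by nearest-vertex ICP.

    Correspondence is restricted to the requested anatomical regions on
    both models (default shaft + neck: the head fragment is excluded so
    that its displacement does not drive the alignment).  Convergence is
    declared when the RMS correspondence distance changes by less than
    ``tol`` mm between iterations.

    ``trim_fraction`` < 1 keeps only that fraction of closest pairs each
    iteration (guards against fracture-gap outliers); ``max_points`` caps
    the number of source points via a deterministic seeded subsample.
    """
    if not (0.8 <= trim_fraction <= 1.0):
        raise ValidationError("trim_fraction must lie in [0.8, 1.0]")
    src = source.validate().region_vertices(regions)
    tgt = target.validate().region_vertices(regions)
    if len(src) == 0 or len(tgt) == 0:
        raise ValidationError(
            f"empty region selection {tuple(regions)} on source or target model"
        )
    if max_points is not None and len(src) > max_points:
        rng = np.random.default_rng(subsample_seed)
        src = src[np.sort(rng.choice(len(src), size=max_points, replace=False))]

    tree = cKDTree(tgt)
    transform = _initial_alignment(src, tgt, tree)
    n_keep = max(3, int(np.ceil(trim_fraction * len(src))))
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        moved = transform.apply(src)
        dist, idx = tree.query(moved, k=1)
        if n_keep < len(src):
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        step = _kabsch(moved[keep], tgt[idx[keep]])
        transform = step.compose(transform)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms

    if rms > sanity_rms_mm:
        warnings.warn(
            f"registration RMS {rms:.3f} mm exceeds sanity bound {sanity_rms_mm} mm; "
            "alignment may have failed",
            RuntimeWarning,
            stacklevel=2,
        )
        converged = False
    return RegistrationReport(transform=transform, rms_error=rms, iterations=it, converged=converged)


# ---------------------------------------------------------------------------
# Scalar measurements


def point_distance(a, b) -> float:
    """Euclidean distance between two points in mm."""
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("point_distance requires finite coordinates")
    return float(np.linalg.norm(a - b))


def angle_between_lines(u_from, u_to, v_from, v_to) -> float:
    """Angle in degrees between two directed segments, in [0, 180].

    Directions are taken as given (directed lines, not axial lines), so
    anti-parallel segments measure 180 degrees.
    """
    u = np.asarray(u_to, dtype=float) - np.asarray(u_from, dtype=float)
    v = np.asarray(v_to, dtype=float) - np.asarray(v_from, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 1e-9 or nv <= 1e-9:
        raise ValidationError("angle_between_lines requires segments longer than 1e-9 mm")
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
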