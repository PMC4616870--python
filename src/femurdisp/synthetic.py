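"""Parametric femur phantoms and simulated study cohorts.

No imaging data accompanies the measurement procedure, so the package
ships a phantom generator that emulates what the pipeline actually needs
from a CT-derived surface pair: a proximal femur composed of a spherical
head carrying a fovea pit, a neck cylinder and a shaft cylinder at
anatomically plausible angles, with true contralateral mirror symmetry and
a known rigid transform applied to the head fragment of the "fractured"
side.  Ground-truth landmarks and the applied transform are emitted
alongside, which turns every phantom into a measurement oracle.

The fragment transform acts on head-region vertices only, about the head
center, leaving a fracture-plane discontinuity at the subcapital junction;
no bone-overlap resolution is attempted (landmark-level measurement does
not need it).

Cohort simulation draws per-subject fragment translations and rotations
from folded-normal magnitude distributions (displacement magnitudes are
non-negative and group summaries are reported as mean +/- SD), with
translation directions uniform on the sphere and rotation axes uniform
among directions perpendicular to the center-to-fovea line — the component
of rotation the angle measure alpha can actually observe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import ValidationError
from .geometry import MirrorPlane, SAGITTAL_PLANE, angle_between_lines, reflect_points
from .mesh import (
    REGION_HEAD,
    REGION_NECK,
    REGION_SHAFT,
    FemurModel,
    LandmarkSet,
    RigidTransform,
    TriangleMesh,
)
from .pipeline import measure_displacement, summarize_cohort
from .stats import mann_whitney_u


@dataclass
class PhantomSpec:
    """Generative parameters for one paired femur phantom.

    Dimensions (mm) and angles (degrees) default to plausible adult
    anatomy; ``mesh_resolution`` is the target edge length of the surface
    triangulation and ``vertex_noise_sd`` the standard deviation of
    isotropic per-vertex noise applied independently to each side (a crude
    stand-in for segmentation error and true anatomical asymmetry).
    """

    head_radius: float = 22.0
    neck_radius: float = 14.0
    neck_length: float = 35.0
    shaft_radius: float = 15.0
    shaft_length: float = 120.0
    neck_shaft_angle: float = 130.0
    anteversion: float = 12.0
    fovea_radius: float = 5.0
    fovea_depth: float = 3.0
    mesh_resolution: float = 1.5
    vertex_noise_sd: float = 0.05
    fragment_transform: RigidTransform = field(default_factory=RigidTransform.identity)
    healthy_side: str = "left"
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        for name in (
            "head_radius",
            "neck_radius",
            "neck_length",
            "shaft_radius",
            "shaft_length",
            "fovea_radius",
            "mesh_resolution",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.neck_shaft_angle < 180.0):
            raise ValidationError("neck_shaft_angle must lie in (0, 180) degrees")
        if not (0.0 <= self.fovea_depth < self.head_radius):
            raise ValidationError("fovea_depth must be non-negative and below head_radius")
        if self.vertex_noise_sd < 0:
            raise ValidationError("vertex_noise_sd must be non-negative")
        if self.healthy_side not in ("left", "right"):
            raise ValidationError("healthy_side must be 'left' or 'right'")
        self.fragment_transform.validate()
        return self


@dataclass
class PhantomGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    fragment_transform: RigidTransform
    landmarks_healthy: LandmarkSet
    landmarks_fractured: LandmarkSet  # in the fractured model's own frame
    mirror_plane: MirrorPlane

    def translation_magnitude(self) -> float:
        """True head-center displacement: what d1 should measure."""
        return float(np.linalg.norm(self.fragment_transform.translation))

    def line_rotation_deg(self) -> float:
        """True rotation of the center-to-fovea line: what alpha should measure."""
        c = self.landmarks_healthy.head_center
        f = self.landmarks_healthy.fovea_deepest
        # mirror the healthy line into the fractured frame, rotate, compare
        cm = reflect_points(c.reshape(1, 3), self.mirror_plane)[0]
        fm = reflect_points(f.reshape(1, 3), self.mirror_plane)[0]
        d = fm - cm
        rd = self.fragment_transform.rotation @ d
        return angle_between_lines(np.zeros(3), d, np.zeros(3), rd)


# ---------------------------------------------------------------------------
# Mesh primitives


def _tube(radius: float, start: np.ndarray, end: np.ndarray, resolution: float):
    """Capped cylinder from ``start`` to ``end`` with ~``resolution`` mm edges.

    Built as rings of vertices along the axis so the lateral surface is
    densely sampled (registration needs surface points along the shaft,
    not just at the caps).
    """
    axis = end - start
    length = float(np.linalg.norm(axis))
    axis = axis / length
    cols = max(8, int(np.ceil(2.0 * np.pi * radius / resolution)))
    rows = max(2, int(np.ceil(length / resolution)))
    # deterministic orthonormal frame around the axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    theta = 2.0 * np.pi * np.arange(cols) / cols
    ring = radius * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    z = np.linspace(0.0, length, rows + 1)
    verts = (start[None, None, :] + z[:, None, None] * axis[None, None, :] + ring[None, :, :]).reshape(-1, 3)
    verts = np.vstack([verts, start, end])
    i_bot, i_top = len(verts) - 2, len(verts) - 1

    faces = []
    for i in range(rows):
        for j in range(cols):
            a = i * cols + j
            b = i * cols + (j + 1) % cols
            c = (i + 1) * cols + j
            d = (i + 1) * cols + (j + 1) % cols
            faces.append((a, b, c))
            faces.append((b, d, c))
    for j in range(cols):
        faces.append((i_bot, (j + 1) % cols, j))
        faces.append((i_top, rows * cols + j, rows * cols + (j + 1) % cols))
    return verts, np.asarray(faces, dtype=np.int64)


def _head_with_fovea(spec: PhantomSpec, fovea_dir: np.ndarray):
    """Icosphere head with a smooth cosine-profile fovea pit along ``fovea_dir``.

    Returns vertices centered at the origin, faces, and the index of the
    pit-bottom vertex (the ground-truth deepest fovea point).
    """
    r = spec.head_radius
    subdiv = int(np.clip(np.ceil(np.log2(1.0514 * r / spec.mesh_resolution)), 1, 5))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=r)
    verts = np.asarray(ico.vertices, dtype=float)
    faces = np.asarray(ico.faces, dtype=np.int64)
    u = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    # rotate the tessellation so one vertex lies exactly on the pit axis:
    # the pit bottom then reaches the full fovea_depth regardless of resolution
    nearest = u[np.argmax(u @ fovea_dir)]
    axis = np.cross(nearest, fovea_dir)
    s = np.linalg.norm(axis)
    if s > 1e-12:
        angle = np.degrees(np.arctan2(s, nearest @ fovea_dir))
        rot = RigidTransform.from_axis_angle(axis, angle)
        u = u @ rot.rotation.T
    verts = r * u
    theta = np.arccos(np.clip(u @ fovea_dir, -1.0, 1.0))
    theta_f = spec.fovea_radius / r  # angular footprint of the pit
    pit = np.where(
        theta < theta_f,
        spec.fovea_depth * 0.5 * (1.0 + np.cos(np.pi * theta / theta_f)),
        0.0,
    )
    verts = (r - pit)[:, None] * u
    return verts, faces, int(np.argmax(pit))


def _healthy_frame(spec: PhantomSpec):
    """Deterministic layout of the healthy femur (medial toward x = 0)."""
    medial = 1.0 if spec.healthy_side == "left" else -1.0
    s0 = np.array([-60.0 * medial, 0.0, 0.0])
    beta = np.deg2rad(180.0 - spec.neck_shaft_angle)  # neck angle from shaft axis
    gamma = np.deg2rad(spec.anteversion)
    neck_dir = np.array(
        [medial * np.sin(beta) * np.cos(gamma), np.sin(beta) * np.sin(gamma), np.cos(beta)]
    )
    head_center = s0 + spec.neck_length * neck_dir
    return s0, neck_dir, head_center


def generate_phantom_pair(
    spec: PhantomSpec, mirror_plane: MirrorPlane = SAGITTAL_PLANE
) -> tuple[FemurModel, FemurModel, PhantomGroundTruth]:
    """Generate a (fractured, healthy) femur pair with known ground truth.

    The healthy model is assembled from head + neck + shaft primitives; the
    fractured model is its exact mirror image across ``mirror_plane`` (true
    contralateral symmetry) with ``spec.fragment_transform`` applied to the
    head-region vertices about the mirrored head center, then independent
    vertex noise is added to each side.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s0, neck_dir, head_center = _healthy_frame(spec)
    fovea_dir = neck_dir  # pit faces the acetabulum, along the neck axis

    hv, hf, pit_idx = _head_with_fovea(spec, fovea_dir)
    hv = hv + head_center
    nv, nf = _tube(spec.neck_radius, s0, head_center, spec.mesh_resolution)
    sv, sf = _tube(
        spec.shaft_radius, s0 + np.array([0.0, 0.0, -spec.shaft_length]), s0, spec.mesh_resolution
    )

    verts = np.vstack([hv, nv, sv])
    faces = np.vstack([hf, nf + len(hv), sf + len(hv) + len(nv)])
    mask = np.concatenate(
        [
            np.full(len(hv), REGION_HEAD),
            np.full(len(nv), REGION_NECK),
            np.full(len(sv), REGION_SHAFT),
        ]
    )
    fovea_point = hv[pit_idx].copy()

    # fractured side: mirror of the clean healthy geometry
    fract_side = "right" if spec.healthy_side == "left" else "left"
    fverts = reflect_points(verts, mirror_plane)
    ffaces = faces[:, ::-1].copy()
    head_center_m = reflect_points(head_center.reshape(1, 3), mirror_plane)[0]
    fovea_m = reflect_points(fovea_point.reshape(1, 3), mirror_plane)[0]

    # fragment transform about the mirrored head center, head region only
    tr = spec.fragment_transform
    head_sel = mask == REGION_HEAD
    fverts[head_sel] = (fverts[head_sel] - head_center_m) @ tr.rotation.T + head_center_m + tr.translation
    gt_center_f = head_center_m + tr.translation
    gt_fovea_f = tr.rotation @ (fovea_m - head_center_m) + head_center_m + tr.translation

    hverts = verts.copy()
    if spec.vertex_noise_sd > 0:
        hverts = hverts + rng.normal(0.0, spec.vertex_noise_sd, hverts.shape)
        fverts = fverts + rng.normal(0.0, spec.vertex_noise_sd, fverts.shape)

    healthy = FemurModel(TriangleMesh(hverts, faces.copy()), spec.healthy_side, mask.copy()).validate()
    fractured = FemurModel(TriangleMesh(fverts, ffaces), fract_side, mask.copy()).validate()
    ground_truth = PhantomGroundTruth(
        fragment_transform=tr,
        landmarks_healthy=LandmarkSet(
            side=spec.healthy_side, head_center=head_center, fovea_deepest=fovea_point
        ).validate(),
        landmarks_fractured=LandmarkSet(
            side=fract_side, head_center=gt_center_f, fovea_deepest=gt_fovea_f
        ).validate(),
        mirror_plane=mirror_plane,
    )
    return fractured, healthy, ground_truth


def mirrored_fovea_direction(spec: PhantomSpec, mirror_plane: MirrorPlane = SAGITTAL_PLANE) -> np.ndarray:
    """Unit center-to-fovea direction in the fractured (mirrored) frame.

    Rotation axes perpendicular to this direction produce fragment
    rotations that the alpha measure can fully observe.  The direction
    points at the actual pit-bottom mesh vertex (not the nominal pit axis),
    so it is exact for the discretized surface.
    """
    _, neck_dir, head_center = _healthy_frame(spec)
    hv, _, pit_idx = _head_with_fovea(spec, neck_dir)
    fovea = hv[pit_idx] + head_center
    a = reflect_points(head_center.reshape(1, 3), mirror_plane)[0]
    b = reflect_points(fovea.reshape(1, 3), mirror_plane)[0]
    d = b - a
    return d / np.linalg.norm(d)


def perpendicular_axis(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random unit vector perpendicular to ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    while True:
        v = rng.normal(size=3)
        v = v - (v @ d) * d
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class GroupSpec:
    """Folded-normal fragment-displacement distribution for one study group."""

    name: str
    size: int
    translation_mean_mm: float
    translation_sd_mm: float
    rotation_mean_deg: float
    rotation_sd_deg: float

    def validate(self) -> "GroupSpec":
        if self.size < 1:
            raise ValidationError(f"group {self.name!r} has size {self.size}; need >= 1")
        for f in ("translation_mean_mm", "translation_sd_mm", "rotation_mean_deg", "rotation_sd_deg"):
            if getattr(self, f) < 0:
                raise ValidationError(f"group {self.name!r}: {f} must be non-negative")
        return self


def _default_groups() -> tuple[GroupSpec, ...]:
    # Incomplete (Garden Ia) vs complete (Garden II) fracture groups, with
    # the reported displacement moments used as generator parameters.
    return (
        GroupSpec("garden_1a", 15, 3.69, 1.77, 4.91, 2.49),
        GroupSpec("garden_2", 60, 7.16, 4.58, 18.77, 9.10),
    )


def _default_cohort_phantom() -> PhantomSpec:
    # Coarser surface than the single-pair default: cohort simulation runs
    # the full pipeline per subject, and landmark-level accuracy at this
    # resolution is far below the millimetre-scale group effects.
    return PhantomSpec(mesh_resolution=3.5, vertex_noise_sd=0.05)


@dataclass
class CohortSpec:
    """Simulated two-group study: per-group displacement distributions."""

    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    phantom: PhantomSpec = field(default_factory=_default_cohort_phantom)
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if len(self.groups) != 2:
            raise ValidationError(
                f"cohort simulation compares exactly 2 groups, got {len(self.groups)}"
            )
        for g in self.groups:
            g.validate()
        self.phantom.validate()
        return self


@dataclass
class CohortRun:
    """Output of a simulated study: per-subject results through to the tests."""

    spec: CohortSpec
    labels: list
    results: list
    ground_truths: list
    summary: object
    tests: dict
    models: list | None = None


def _draw_fragment_transform(group: GroupSpec, fovea_dir_m: np.ndarray, rng: np.random.Generator) -> RigidTransform:
    magnitude = abs(rng.normal(group.translation_mean_mm, group.translation_sd_mm))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    angle = abs(rng.normal(group.rotation_mean_deg, group.rotation_sd_deg))
    axis = perpendicular_axis(fovea_dir_m, rng)
    return RigidTransform.from_axis_angle(axis, angle, translation=magnitude * direction)


def simulate_cohort(
    spec: CohortSpec,
    keep_models: bool = False,
    measure_kwargs: dict | None = None,
) -> CohortRun:
    """Simulate a two-group study and run the full measurement workflow.

    Per subject: draw a fragment transform from the group's distributions,
    generate the phantom pair, measure (d1, d2, alpha) through the complete
    mirror + register + landmark pipeline, then summarize per group and
    compare the groups with two-sided Mann-Whitney U tests on each
    parameter.  Reproducible under ``spec.seed``.
    """
    spec.validate()
    if measure_kwargs is None:
        measure_kwargs = {"max_points": 1000}
    rng = np.random.default_rng(spec.seed)
    fovea_dir_m = mirrored_fovea_direction(spec.phantom)

    labels, results, gts, models = [], [], [], []
    for group in spec.groups:
        for _ in range(group.size):
            tr = _draw_fragment_transform(group, fovea_dir_m, rng)
            subj_seed = int(rng.integers(0, 2**31 - 1))
            pspec = replace(spec.phantom, fragment_transform=tr, seed=subj_seed)
            fractured, healthy, gt = generate_phantom_pair(pspec)
            res = measure_displacement(fractured, healthy, **measure_kwargs)
            labels.append(group.name)
            results.append(res)
            gts.append(gt)
            if keep_models:
                models.append((fractured, healthy))

    summary = summarize_cohort(results, labels)
    g1, g2 = spec.groups[0].name, spec.groups[1].name
    by_group = {g: [r for r, l in zip(results, labels) if l == g] for g in (g1, g2)}
    tests = {
        param: mann_whitney_u(
            [getattr(r, param) for r in by_group[g1]],
            [getattr(r, param) for r in by_group[g2]],
        )
        for param in ("d1", "d2", "alpha")
    }
    return CohortRun(
        spec=spec,
        labels=labels,
        results=results,
        ground_truths=gts,
        summary=summary,
        tests=tests,
        models=models if keep_models else None,
    )
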