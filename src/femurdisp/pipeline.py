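"""End-to-end displacement measurement of a fractured/healthy femur pair.

The measurement follows the mirrored contralateral superimposition idea:
the fractured-side model is reflected across the sagittal plane, rigidly
registered onto the intact contralateral model using the shaft and neck
(the head fragment is deliberately excluded from the alignment), and the
residual misfit of the head is then quantified by three parameters:

* ``d1`` — distance between the femoral head centers (mm), each center
  obtained from a close-fit sphere on the head region;
* ``d2`` — distance between the deepest points of the fovea capitis (mm);
* ``alpha`` — angle (degrees) between the two center-to-fovea lines, the
  rotational-displacement measure.

On a perfectly symmetric, unfractured pair all three vanish; any fragment
motion shows up directly in them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FoveaNotFoundError, ValidationError
from .geometry import (
    MirrorPlane,
    RegistrationReport,
    SAGITTAL_PLANE,
    SphereFitReport,
    angle_between_lines,
    fit_sphere,
    mirror_mesh,
    point_distance,
    reflect_points,
    register_rigid,
)
from .mesh import FemurModel, LandmarkSet, Sphere


@dataclass
class DisplacementResult:
    """The (d1, d2, alpha) triple plus full provenance of how it was measured."""

    d1: float
    d2: float
    alpha: float
    landmarks_healthy: LandmarkSet
    landmarks_fractured_mirrored: LandmarkSet
    registration: RegistrationReport
    sphere_fits: tuple[SphereFitReport | None, SphereFitReport | None]

    def validate(self) -> "DisplacementResult":
        if self.d1 < 0 or self.d2 < 0:
            raise ValidationError("distances must be non-negative")
        if not (0.0 <= self.alpha <= 180.0):
            raise ValidationError("alpha must lie in [0, 180] degrees")
        return self

    def to_row(self) -> dict:
        sf, sh = self.sphere_fits
        return {
            "d1_mm": self.d1,
            "d2_mm": self.d2,
            "alpha_deg": self.alpha,
            "registration_rms_mm": self.registration.rms_error,
            "sphere_rms_fractured_mm": sf.rms_residual if sf else np.nan,
            "sphere_rms_healthy_mm": sh.rms_residual if sh else np.nan,
            "landmark_source_fractured": self.landmarks_fractured_mirrored.source,
            "landmark_source_healthy": self.landmarks_healthy.source,
        }

    def to_dict(self) -> dict:
        sf, sh = self.sphere_fits
        return {
            "d1_mm": self.d1,
            "d2_mm": self.d2,
            "alpha_deg": self.alpha,
            "landmarks_healthy": self.landmarks_healthy.to_dict(),
            "landmarks_fractured_mirrored": self.landmarks_fractured_mirrored.to_dict(),
            "registration": {
                "transform": self.registration.transform.to_dict(),
                "rms_error_mm": self.registration.rms_error,
                "iterations": self.registration.iterations,
                "converged": self.registration.converged,
            },
            "sphere_fits": [
                None
                if r is None
                else {
                    "center": r.sphere.center.tolist(),
                    "radius_mm": r.sphere.radius,
                    "rms_residual_mm": r.rms_residual,
                    "n_points_used": r.n_points_used,
                    "n_excluded": r.n_excluded,
                    "iterations": r.iterations,
                }
                for r in self.sphere_fits
            ],
        }


def locate_head_center(
    model: FemurModel, robust: bool = True, inlier_deficit_mm: float = 0.5
) -> tuple[Sphere, SphereFitReport]:
    """Fit the close-fit sphere to the head region; its center is the landmark.

    The robust pass excludes fovea-pit vertices (inward deficit beyond
    ``inlier_deficit_mm``) so the pit does not bias the sphere.
    """
    head = model.validate().region_vertices(["head"])
    if len(head) < 4:
        raise ValidationError(
            f"head region has {len(head)} vertices; at least 4 required for a sphere fit"
        )
    report = fit_sphere(head, robust=robust, inlier_deficit_mm=inlier_deficit_mm)
    return report.sphere, report


def locate_fovea(model: FemurModel, sphere: Sphere, threshold_mm: float = 1.0) -> np.ndarray:
    """Deepest point of the fovea: the head vertex of maximal inward deficit.

    A vertex only qualifies when its deficit ``r - |p - c|`` exceeds
    ``threshold_mm``; ties are broken by lexicographically smallest
    coordinates so the choice is deterministic.
    """
    head = model.validate().region_vertices(["head"])
    sphere.validate()
    deficit = sphere.radius - np.linalg.norm(head - sphere.center, axis=1)
    candidates = np.flatnonzero(deficit > threshold_mm)
    if len(candidates) == 0:
        raise FoveaNotFoundError(
            f"no head vertex has inward deficit above {threshold_mm} mm; "
            "supply a manual fovea landmark instead"
        )
    best = deficit[candidates].max()
    top = candidates[np.isclose(deficit[candidates], best, rtol=0.0, atol=1e-12)]
    pts = head[top]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order[0]].copy()


def _resolve_landmarks(
    model: FemurModel,
    manual: LandmarkSet | None,
    side: str,
    fovea_threshold_mm: float,
    map_point=None,
) -> tuple[LandmarkSet, SphereFitReport | None]:
    """Combine fitted and manual landmarks; manual points take precedence.

    ``map_point`` transports manual picks (given in the model's original
    frame) into the measurement frame.
    """
    manual_center = manual.head_center if manual is not None else None
    manual_fovea = manual.fovea_deepest if manual is not None else None
    if map_point is not None:
        manual_center = map_point(manual_center) if manual_center is not None else None
        manual_fovea = map_point(manual_fovea) if manual_fovea is not None else None

    fit_report: SphereFitReport | None = None
    sphere: Sphere | None = None
    if manual_center is None or manual_fovea is None:
        sphere, fit_report = locate_head_center(model)

    center = manual_center if manual_center is not None else sphere.center
    if manual_fovea is not None:
        fovea = manual_fovea
    else:
        assert sphere is not None
        fovea = locate_fovea(model, sphere, threshold_mm=fovea_threshold_mm)
    source = "manual" if (manual_center is not None or manual_fovea is not None) else "fitted"
    lm = LandmarkSet(side=side, head_center=center, fovea_deepest=fovea, source=source)
    return lm.validate(), fit_report


def measure_displacement(
    fractured: FemurModel,
    healthy: FemurModel,
    manual_landmarks: tuple[LandmarkSet | None, LandmarkSet | None] | None = None,
    mirror_plane: MirrorPlane = SAGITTAL_PLANE,
    regions=("shaft", "neck"),
    fovea_threshold_mm: float = 1.0,
    allow_same_side: bool = False,
    **icp_kwargs,
) -> DisplacementResult:
    """Measure (d1, d2, alpha) for a fractured/contralateral femur pair.

    Stages: (1) mirror the fractured model across ``mirror_plane``;
    (2) register the mirrored model onto the healthy model by ICP on the
    ``regions`` selection (default shaft + neck); (3) locate head center
    (close-fit sphere) and deepest fovea point on both models — manual
    landmarks, given in each model's original unmirrored frame, are carried
    through the same mirror + registration map and take precedence over
    fitted ones; (4) compute the three displacement parameters.

    ``manual_landmarks`` is an optional ``(fractured, healthy)`` pair.
    """
    fractured.validate()
    healthy.validate()
    if fractured.side == healthy.side and not allow_same_side:
        raise ValidationError(
            f"fractured and healthy models are both side={fractured.side!r}; "
            "a contralateral pair is expected (pass allow_same_side=True to override)"
        )
    manual_fract, manual_heal = manual_landmarks if manual_landmarks is not None else (None, None)

    mirrored = mirror_mesh(fractured, mirror_plane)
    registration = register_rigid(mirrored, healthy, regions=regions, **icp_kwargs)
    t = registration.transform
    aligned = FemurModel(
        mirrored.mesh.__class__(t.apply(mirrored.mesh.vertices), mirrored.mesh.faces.copy()),
        mirrored.side,
        mirrored.region_mask.copy(),
    )

    def map_fractured_point(p):
        return t.apply(reflect_points(np.asarray(p, dtype=float).reshape(1, 3), mirror_plane))[0]

    lm_fract, fit_fract = _resolve_landmarks(
        aligned, manual_fract, aligned.side, fovea_threshold_mm, map_point=map_fractured_point
    )
    lm_heal, fit_heal = _resolve_landmarks(
        healthy, manual_heal, healthy.side, fovea_threshold_mm
    )

    d1 = point_distance(lm_fract.head_center, lm_heal.head_center)
    d2 = point_distance(lm_fract.fovea_deepest, lm_heal.fovea_deepest)
    alpha = angle_between_lines(
        lm_fract.head_center, lm_fract.fovea_deepest, lm_heal.head_center, lm_heal.fovea_deepest
    )
    return DisplacementResult(
        d1=d1,
        d2=d2,
        alpha=alpha,
        landmarks_healthy=lm_heal,
        landmarks_fractured_mirrored=lm_fract,
        registration=registration,
        sphere_fits=(fit_fract, fit_heal),
    ).validate()


# ---------------------------------------------------------------------------
# Cohort-level summaries

#: Thresholds used in cohort summaries (mm / degrees).
D1_THRESHOLD_MM = 10.0
ALPHA_BAND_DEG = (10.0, 50.0)
ALPHA_THRESHOLD_DEG = 20.0


@dataclass
class CohortSummary:
    """Per-group descriptives and threshold fractions for a measured cohort.

    The threshold fractions mirror how marked displacement is usually
    summarized for nominally "undisplaced" fractures: head-center shift
    exceeding 10 mm (strict), rotation within the 10-50 degree band
    (inclusive bounds), and rotation above 20 degrees (strict).
    """

    table: pd.DataFrame = field(repr=False)

    def validate(self) -> "CohortSummary":
        if (self.table["n"] < 1).any():
            raise ValidationError("every group must contain at least one result")
        frac_cols = [c for c in self.table.columns if c.startswith("frac_")]
        if ((self.table[frac_cols] < 0) | (self.table[frac_cols] > 1)).any().any():
            raise ValidationError("threshold fractions must lie in [0, 1]")
        return self

    def group(self, name) -> pd.Series:
        return self.table.loc[name]

    def to_dict(self) -> dict:
        return {str(g): row.to_dict() for g, row in self.table.iterrows()}


def summarize_cohort(results, group_labels) -> CohortSummary:
    """Aggregate per-case (d1, d2, alpha) into per-group descriptives.

    For a single-member group the standard deviation is reported as 0.
    """
    results = list(results)
    group_labels = list(group_labels)
    if len(results) != len(group_labels):
        raise ValidationError("results and group_labels must have equal length")
    if len(results) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    df = pd.DataFrame(
        {
            "group": group_labels,
            "d1": [r.d1 for r in results],
            "d2": [r.d2 for r in results],
            "alpha": [r.alpha for r in results],
        }
    )
    lo, hi = ALPHA_BAND_DEG
    rows = {}
    for g, sub in df.groupby("group", sort=True):
        rows[g] = {
            "n": len(sub),
            "d1_mean": sub["d1"].mean(),
            "d1_sd": sub["d1"].std(ddof=1) if len(sub) > 1 else 0.0,
            "d2_mean": sub["d2"].mean(),
            "d2_sd": sub["d2"].std(ddof=1) if len(sub) > 1 else 0.0,
            "alpha_mean": sub["alpha"].mean(),
            "alpha_sd": sub["alpha"].std(ddof=1) if len(sub) > 1 else 0.0,
            "frac_d1_gt_10mm": float((sub["d1"] > D1_THRESHOLD_MM).mean()),
            "frac_alpha_10_50deg": float(((sub["alpha"] >= lo) & (sub["alpha"] <= hi)).mean()),
            "frac_alpha_gt_20deg": float((sub["alpha"] > ALPHA_THRESHOLD_DEG).mean()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "group"
    return CohortSummary(table).validate()
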