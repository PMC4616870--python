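"""Inter/intra-rater agreement and nonparametric group comparison.

Fleiss' kappa serves the multi-rater inter-observer design (several trauma
surgeons independently marking the same landmarks); Cohen's weighted kappa
serves the two-occasion intra-observer design.  Both are chance-corrected:
kappa = (Po - Pe) / (1 - Pe), interpreted on the Landis-Koch verbal scale.

The Mann-Whitney U test compares the displacement parameters between two
fracture groups without a normality assumption.  Continuous landmark picks
are turned into categorical ratings by an agree/disagree discretization
against a consensus point within a tolerance radius.

Kappa statistics delegate to ``statsmodels.stats.inter_rater``; the U test
delegates to ``scipy.stats.mannwhitneyu`` (exact null distribution when the
pooled sample is small and tie-free, otherwise the normal approximation
with tie and continuity corrections).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu, rankdata
from statsmodels.stats import inter_rater

from .errors import UndefinedKappaError, ValidationError

#: Pooled-sample size at or below which mode="auto" uses the exact test.
EXACT_N_LIMIT = 12

LANDIS_KOCH_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class RatingTable:
    """Subjects x raters matrix of categorical ratings (no missing cells)."""

    ratings: np.ndarray
    categories: tuple

    @classmethod
    def from_array(cls, ratings) -> "RatingTable":
        arr = np.asarray(ratings)
        if arr.ndim != 2:
            raise ValidationError(f"rating table must be 2-D, got shape {arr.shape}")
        if arr.dtype == object and any(v is None for v in arr.ravel()):
            raise ValidationError("rating table contains missing cells")
        if arr.dtype.kind == "f" and not np.isfinite(arr.astype(float)).all():
            raise ValidationError("rating table contains missing cells")
        cats = tuple(sorted(set(arr.ravel().tolist())))
        return cls(arr, cats).validate()

    def validate(self) -> "RatingTable":
        n_subj, n_raters = self.ratings.shape
        if n_subj < 2:
            raise ValidationError(f"need at least 2 subjects, got {n_subj}")
        if n_raters < 2:
            raise ValidationError(f"need at least 2 raters, got {n_raters}")
        if not set(self.ratings.ravel().tolist()) <= set(self.categories):
            raise ValidationError("ratings contain values outside the category set")
        return self

    def counts(self) -> np.ndarray:
        """Subjects x categories table of rating counts."""
        cat_index = {c: j for j, c in enumerate(self.categories)}
        out = np.zeros((self.ratings.shape[0], len(self.categories)), dtype=int)
        for i, row in enumerate(self.ratings):
            for v in row:
                out[i, cat_index[v]] += 1
        return out


@dataclass
class AgreementResult:
    kappa: float
    method: str  # "fleiss" | "cohen_weighted"
    weight_scheme: str  # "none" | "linear" | "quadratic"
    category: str  # Landis-Koch label

    def validate(self) -> "AgreementResult":
        if not (-1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12):
            raise ValidationError(f"kappa {self.kappa} outside [-1, 1]")
        return self


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"
    n1: int
    n2: int

    def validate(self) -> "GroupComparison":
        if not (0.0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValidationError("U statistic outside [0, n1*n2]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")
        return self


def landis_koch_category(kappa: float) -> str:
    """Verbal agreement band for a kappa value.

    Below 0 is "none"; band boundaries belong to the lower band, so 0.2 is
    "slight", 0.4 "fair", 0.6 "moderate", 0.8 "substantial".
    """
    if not np.isfinite(kappa) or kappa < -1.0 or kappa > 1.0:
        raise ValidationError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.0:
        return "none"
    for upper, label in LANDIS_KOCH_BANDS:
        if kappa <= upper:
            return label
    return LANDIS_KOCH_BANDS[-1][1]


def fleiss_kappa(table: RatingTable | np.ndarray) -> AgreementResult:
    """Fleiss' multi-rater kappa with Landis-Koch interpretation."""
    if not isinstance(table, RatingTable):
        table = RatingTable.from_array(table)
    counts = table.counts()
    n_raters = counts.sum(axis=1)
    if not (n_raters == n_raters[0]).all():
        raise ValidationError("every subject must be rated by the same number of raters")
    if n_raters[0] < 2:
        raise ValidationError("Fleiss' kappa requires at least 2 raters")
    # chance agreement from marginal category proportions
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float(p_j @ p_j)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "all ratings fall in a single category; chance agreement is 1 and kappa is undefined"
        )
    kappa = float(inter_rater.fleiss_kappa(counts, method="fleiss"))
    return AgreementResult(
        kappa=kappa,
        method="fleiss",
        weight_scheme="none",
        category=landis_koch_category(kappa),
    ).validate()


def weighted_kappa(ratings_a, ratings_b, ordered_categories, scheme: str = "linear") -> AgreementResult:
    """Cohen's weighted kappa between two rating vectors on ordered categories."""
    if scheme not in ("linear", "quadratic"):
        raise ValidationError(f"scheme must be 'linear' or 'quadratic', got {scheme!r}")
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValidationError("rating vectors must have equal length")
    if len(a) == 0:
        raise ValidationError("rating vectors are empty")
    cats = list(ordered_categories)
    idx = {c: j for j, c in enumerate(cats)}
    try:
        ai = [idx[v] for v in a]
        bi = [idx[v] for v in b]
    except KeyError as exc:
        raise ValidationError(f"rating {exc.args[0]!r} not in the ordered category set") from exc
    k = len(cats)
    confusion = np.zeros((k, k), dtype=float)
    for i, j in zip(ai, bi):
        confusion[i, j] += 1
    res = inter_rater.cohens_kappa(confusion, wt=scheme, return_results=True)
    kappa = float(res.kappa)
    if not np.isfinite(kappa):
        raise UndefinedKappaError(
            "chance-agreement denominator is zero; weighted kappa is undefined"
        )
    return AgreementResult(
        kappa=kappa,
        method="cohen_weighted",
        weight_scheme=scheme,
        category=landis_koch_category(kappa),
    ).validate()


def mann_whitney_u(x, y, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` forces the exact null distribution (ties must be
    absent); ``mode="auto"`` uses it when n1 + n2 <= 12 and the pooled
    sample is tie-free, falling back to the normal approximation with tie
    and continuity corrections; ``mode="approx"`` always approximates.
    The reported U is the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ValidationError(f"mode must be auto/exact/approx, got {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "exact" or (mode == "auto" and len(pooled) <= EXACT_N_LIMIT and not has_ties):
        if has_ties:
            raise ValidationError("exact mode requires a tie-free pooled sample")
        method = "exact"
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n1=len(x),
        n2=len(y),
    ).validate()


def landmark_agreement_ratings(
    picks: np.ndarray,
    reference: np.ndarray | None = None,
    tolerance_mm: float = 2.0,
) -> RatingTable:
    """Discretize continuous landmark picks into agree/disagree ratings.

    ``picks`` is a (subjects, raters, 3) array of picked coordinates in mm.
    Each pick is rated 1 ("agree") when it lies within ``tolerance_mm`` of
    the per-subject reference point — by default the mean of that subject's
    picks — and 0 otherwise.  The resulting table feeds the kappa
    statistics.
    """
    picks = np.asarray(picks, dtype=float)
    if picks.ndim != 3 or picks.shape[2] != 3:
        raise ValidationError(f"picks must be (subjects, raters, 3), got {picks.shape}")
    if tolerance_mm <= 0:
        raise ValidationError("tolerance_mm must be positive")
    if reference is None:
        reference = picks.mean(axis=1)
    reference = np.asarray(reference, dtype=float).reshape(picks.shape[0], 3)
    dist = np.linalg.norm(picks - reference[:, None, :], axis=2)
    ratings = (dist <= tolerance_mm).astype(int)
    return RatingTable(ratings, (0, 1)).validate()


def rank_biserial(x, y) -> float:
    """Rank-biserial effect size r = 1 - 2U/(n1*n2), companion to the U test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = rankdata(np.concatenate([x, y]))
    u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    return float(1.0 - 2.0 * u / (len(x) * len(y)))
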