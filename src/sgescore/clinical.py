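"""Clinical calibration of functional classes.

Implements the ClinGen-style OddsPath calibration (a Bayesian odds ratio
measuring how strongly membership in an assay class shifts the probability
of pathogenicity), its mapping onto ACMG/AMP PS3/BS3 evidence strengths and
points, points-based classification, ROC/AUC evaluation against truth sets,
and case-control odds-ratio statistics.

OddsPath for the pathogenic direction is

    OddsPath = [P2 * (1 - P1)] / [(1 - P2) * P1]

where P1 is the prior fraction of pathogenic variants in the truth set and
P2 the fraction of pathogenic variants among truth variants the assay calls
functionally abnormal; the benign direction uses the functionally normal
class.  Indeterminate-class variants are excluded from the calibration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PATHOGENIC = "pathogenic_or_LP"
BENIGN = "benign_or_LB"
ABNORMAL = "functionally_abnormal"
NORMAL = "functionally_normal"
INDETERMINATE = "indeterminate"

#: OddsPath thresholds for pathogenic evidence strength (Tavtigian-style
#: points: supporting 1, moderate 2, strong 4, very strong 8); the benign
#: side uses the reciprocal thresholds with negative points.
PATHOGENIC_STRENGTHS = (
    (350.0, "very_strong", 8),
    (18.7, "strong", 4),
    (4.3, "moderate", 2),
    (2.08, "supporting", 1),
)

#: ACMG/AMP v3 points-based classification bands, with the modification
#: that likely benign requires only -2 points.
POINT_BANDS = (
    (10, math.inf, "P"),
    (6, 9, "LP"),
    (-1, 5, "VUS"),
    (-6, -2, "LB"),
    (-math.inf, -7, "B"),
)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 case-control carrier table."""
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class OddsPathResult:
    p1: float
    p2_abnormal: float
    p2_normal: float
    oddspath_pathogenic: float
    oddspath_benign: float
    zero_cell_adjusted: bool
    n_truth: int
    counts: dict = field(default_factory=dict)


def _oddspath(p2: float, p1: float) -> float:
    return (p2 * (1 - p1)) / ((1 - p2) * p1)


def compute_oddspath(truth: pd.DataFrame) -> OddsPathResult:
    """OddsPath calibration from a labeled truth table.

    ``truth`` needs columns ``clinical_label`` (pathogenic_or_LP /
    benign_or_LB) and ``functional_class``.  Variants with an indeterminate
    (or missing) functional class are excluded.  A zero cell (a perfect
    classifier) is continuity-adjusted by adding one counter-example to the
    offending class and flagged.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set")
    labeled = truth[truth["clinical_label"].isin([PATHOGENIC, BENIGN])]
    # the prior P1 is the composition of the whole truth set; only the
    # class-conditional cells P2 exclude indeterminate assays
    n_p = int((labeled["clinical_label"] == PATHOGENIC).sum())
    n_b = int((labeled["clinical_label"] == BENIGN).sum())
    t = labeled[labeled["functional_class"].isin([ABNORMAL, NORMAL])]
    if ((t["clinical_label"] == PATHOGENIC).sum() == 0
            or (t["clinical_label"] == BENIGN).sum() == 0):
        raise ValueError("need at least one pathogenic and one benign truth "
                         "variant with a determinate functional class")
    p1 = n_p / (n_p + n_b)

    def cell(cls, label):
        return int(((t["functional_class"] == cls)
                    & (t["clinical_label"] == label)).sum())

    ab_p, ab_b = cell(ABNORMAL, PATHOGENIC), cell(ABNORMAL, BENIGN)
    no_p, no_b = cell(NORMAL, PATHOGENIC), cell(NORMAL, BENIGN)

    adjusted = False
    if ab_p + ab_b > 0 and ab_b == 0:
        ab_b, adjusted = 1, True
    if no_p + no_b > 0 and no_p == 0:
        no_p, adjusted = 1, True

    p2_ab = ab_p / (ab_p + ab_b) if ab_p + ab_b else float("nan")
    p2_no = no_p / (no_p + no_b) if no_p + no_b else float("nan")
    return OddsPathResult(
        p1=p1, p2_abnormal=p2_ab, p2_normal=p2_no,
        oddspath_pathogenic=_oddspath(p2_ab, p1),
        oddspath_benign=_oddspath(p2_no, p1),
        zero_cell_adjusted=adjusted, n_truth=n_p + n_b,
        counts={"abnormal": (ab_p, ab_b), "normal": (no_p, no_b)},
    )


@dataclass(frozen=True)
class EvidenceStrength:
    ps3_strength: str   # "none" | "supporting" | "moderate" | "strong" | "very_strong"
    ps3_points: int
    bs3_strength: str
    bs3_points: int


def map_evidence_strength(oddspath: OddsPathResult) -> EvidenceStrength:
    """Map OddsPath values to PS3/BS3 evidence strengths and points."""
    ps3, ps3_pts = "none", 0
    for thr, name, pts in PATHOGENIC_STRENGTHS:
        if oddspath.oddspath_pathogenic > thr:
            ps3, ps3_pts = name, pts
            break
    bs3, bs3_pts = "none", 0
    for thr, name, pts in PATHOGENIC_STRENGTHS:
        if oddspath.oddspath_benign < 1.0 / thr:
            bs3, bs3_pts = name, -pts
            break
    return EvidenceStrength(ps3, ps3_pts, bs3, bs3_pts)


def classify_points(total: int) -> str:
    for lo, hi, label in POINT_BANDS:
        if lo <= total <= hi:
            return label
    raise AssertionError("point bands must cover the integers")


def combine_points(criteria) -> tuple[int, str]:
    """Sum per-criterion evidence points and classify.

    ``criteria`` is a mapping criterion -> points or an iterable of
    ``(criterion, points)``; a criterion repeated with conflicting points
    is an error.
    """
    if isinstance(criteria, dict):
        items = list(criteria.items())
    else:
        items = list(criteria)
    seen: dict[str, int] = {}
    for name, pts in items:
        if name in seen and seen[name] != pts:
            raise ValueError(f"conflicting duplicate criterion {name!r}")
        seen[name] = int(pts)
    total = sum(seen.values())
    return total, classify_points(total)


def functional_evidence_points(functional_class: str,
                               strengths: EvidenceStrength) -> int:
    """PS3/BS3 points for one variant; indeterminate classes get none."""
    if functional_class == ABNORMAL:
        return strengths.ps3_points
    if functional_class == NORMAL:
        return strengths.bs3_points
    return 0


def reclassify_variants(evidence: pd.DataFrame,
                        strengths: EvidenceStrength) -> pd.DataFrame:
    """Apply calibrated functional evidence and combine points per variant.

    ``evidence`` is indexed by variant_id with a ``functional_class``
    column plus any number of precomputed criterion point columns (PP3,
    BP4, PM2_supporting, PVS1, ...).  Returns the input plus
    ``functional_points``, ``total_points`` and ``classification``.
    """
    point_cols = [c for c in evidence.columns if c != "functional_class"]
    out = evidence.copy()
    out["functional_points"] = [
        functional_evidence_points(fc, strengths)
        for fc in evidence["functional_class"]]
    out["total_points"] = out[point_cols + ["functional_points"]] \
        .fillna(0).sum(axis=1).astype(int)
    out["classification"] = [classify_points(t) for t in out["total_points"]]
    return out


# ---------------------------------------------------------------------------
# discrimination and case-control statistics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, lower_is_pathogenic: bool = True):
    """Rank-based AUC (ties averaged) and the ROC curve.

    ``labels`` are 1 for pathogenic, 0 for benign; by default a lower
    functional score indicates pathogenicity.
    """
    from sklearn.metrics import roc_curve, auc as sk_auc
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    oriented = -scores if lower_is_pathogenic else scores
    fpr, tpr, thresholds = roc_curve(labels, oriented)
    return sk_auc(fpr, tpr), (fpr, tpr, thresholds)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    continuity_applied: bool


def fisher_or(table: ContingencyTable, alpha: float = 0.05,
              exact_ci: bool = False) -> FisherResult:
    """Sample odds ratio, two-sided Fisher exact p, and 95% CI.

    The CI is the Woolf log-OR normal approximation
    ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))`` with a 0.5
    continuity correction when any cell is zero (flagged);
    ``exact_ci=True`` gives the conditional (hypergeometric) interval
    instead.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("table margins must be positive")
    res = stats.fisher_exact(table.as_array(), alternative="two-sided")
    p = float(res.pvalue)
    continuity = 0 in (a, b, c, d)
    if exact_ci:
        ci = stats.contingency.odds_ratio(table.as_array(),
                                          kind="conditional") \
            .confidence_interval(1 - alpha)
        orr = (a * d) / (b * c) if b * c > 0 else float("inf")
        return FisherResult(orr, p, float(ci.low), float(ci.high), False)
    if continuity:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(orr) - z * se), math.exp(math.log(orr) + z * se)
    return FisherResult(float(orr), p, lo, hi, continuity)


def compare_odds_ratios(or1: float, ci1: tuple[float, float],
                        or2: float, ci2: tuple[float, float]) -> tuple[float, float]:
    """Z-test for equality of two odds ratios given their 95% CIs.

    Standard errors are recovered from the CI widths on the log scale:
    ``SE = (ln upper - ln lower) / (2 * 1.96)``.
    """
    for val in (or1, or2, *ci1, *ci2):
        if val <= 0:
            raise ValueError("odds ratios and CI bounds must be positive")
    z975 = 1.959963984540054
    se1 = (math.log(ci1[1]) - math.log(ci1[0])) / (2 * z975)
    se2 = (math.log(ci2[1]) - math.log(ci2[0])) / (2 * z975)
    z = (math.log(or1) - math.log(or2)) / math.sqrt(se1 ** 2 + se2 ** 2)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
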