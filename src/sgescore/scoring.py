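"""Functional and RNA scoring of SGE variants.

The functional score of a variant is the estimated log2 fold-change in its
relative abundance per day.  Per replicate, the day-5 log2 frequency ratio
(day-5 frequency over plasmid-library frequency) is corrected for the
smooth position effect of the Cas9 cut site by subtracting a one-dimensional
LOESS fit of day-5 ratios against genomic position; the same replicate's
fit is subtracted from its cognate day-13 ratios.  Adjusted ratios are then
regressed on time with an anchor point (0, 0) per replicate; the OLS slope
is the functional score.

RNA scores compare a variant's frequency in day-5 mRNA-derived reads with
its day-5 genomic-DNA frequency renormalized over the RNA amplicon window.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .calling import FrequencyTable
from .targets import TargetSpec, VariantDef

DEFAULT_SPAN = 0.20
DEFAULT_PSEUDOCOUNT = 0.5
#: minimum number of variants required to fit the position smoother
MIN_FIT_POINTS = 10
#: fit-subset rule: day-5 frequency no less than half the starting
#: frequency, i.e. a day-5 log2 ratio of at least -1
FIT_SUBSET_MIN_RATIO = -1.0


def _day_of(sample_type: str) -> int | None:
    m = re.fullmatch(r"day(\d+)_dna", sample_type)
    return int(m.group(1)) if m else None


def pseudocount_frequencies(ft: FrequencyTable,
                            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Frequencies with ``pseudocount`` added to every raw count, keeping
    depleted (zero-count) variants finite in log ratios."""
    return (ft.counts + pseudocount).div(ft.totals["total_valid_reads"], axis=1)


def log2_ratio_table(
    ft: FrequencyTable,
    target: TargetSpec,
    variants: list[VariantDef],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-variant, per-replicate log2 frequency ratios vs the plasmid library.

    Long-form columns: variant_id, genomic_pos, replicate, day, log2_ratio,
    in_fit_subset (day-5 rows only; True when the day-5 frequency is at
    least half the starting frequency).
    """
    freqs = pseudocount_frequencies(ft, pseudocount)
    lib_keys = [k for k in freqs.columns if k[0] == "library"]
    if not lib_keys:
        raise ValueError("no plasmid library column present")
    f0 = freqs[lib_keys].mean(axis=1)
    pos = {v.variant_id: target.genomic_position(v.pos) for v in variants}
    rows = []
    for key in freqs.columns:
        day = _day_of(key[0])
        if day is None:
            continue
        ratio = np.log2(freqs[key] / f0)
        for vid, r in ratio.items():
            rows.append((vid, pos.get(vid, np.nan), key[1], day, float(r)))
    df = pd.DataFrame(rows, columns=["variant_id", "genomic_pos", "replicate",
                                     "day", "log2_ratio"])
    df["in_fit_subset"] = (df["day"] == 5) & \
        (df["log2_ratio"] >= FIT_SUBSET_MIN_RATIO)
    return df


def fit_position_smoother(
    positions: np.ndarray,
    ratios: np.ndarray,
    in_fit: np.ndarray,
    eval_positions: np.ndarray,
    span: float = DEFAULT_SPAN,
    min_fit_points: int = MIN_FIT_POINTS,
) -> np.ndarray:
    """LOESS fit of day-5 log2 ratios against position, evaluated anywhere.

    Local linear with tricube weights and no robustness iterations;
    ``span`` is the fraction of fit-subset points in each local window.
    With fewer than ``min_fit_points`` eligible variants the smoother is
    skipped and zeros are returned.
    """
    positions = np.asarray(positions, float)
    ratios = np.asarray(ratios, float)
    in_fit = np.asarray(in_fit, bool) & np.isfinite(ratios)
    if in_fit.sum() < min_fit_points:
        warnings.warn("fewer than %d variants eligible for the position "
                      "smoother; skipping smoothing" % min_fit_points)
        return np.zeros(len(eval_positions))
    fitted = lowess(ratios[in_fit], positions[in_fit], frac=span, it=0,
                    xvals=np.asarray(eval_positions, float))
    return np.asarray(fitted, float)


def smooth_and_adjust(ratios: pd.DataFrame, span: float = DEFAULT_SPAN,
                      min_fit_points: int = MIN_FIT_POINTS) -> pd.DataFrame:
    """Attach LOESS fits and adjusted ratios to a long ratio table.

    The smoother is fit per replicate on day-5 ratios; the replicate's
    fitted value at each variant's position is subtracted from both its
    day-5 and cognate day-13 ratios.
    """
    out = ratios.copy()
    out["loess_fit"] = 0.0
    for rep, sub in ratios.groupby("replicate"):
        d5 = sub[sub["day"] == 5]
        eval_pos = sub["genomic_pos"].to_numpy(float)
        fitted = fit_position_smoother(
            d5["genomic_pos"].to_numpy(), d5["log2_ratio"].to_numpy(),
            d5["in_fit_subset"].to_numpy(), eval_pos, span=span,
            min_fit_points=min_fit_points)
        out.loc[sub.index, "loess_fit"] = fitted
    out["adjusted"] = out["log2_ratio"] - out["loess_fit"]
    return out


@dataclass(frozen=True)
class ScoreRecord:
    variant_id: str
    functional_score: float
    score_se: float
    n_points: int
    source_targets: int = 1
    rna_score: float = float("nan")


def _slope(points: list[tuple[float, float]]):
    t = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)


def score_variants(adjusted: pd.DataFrame, min_points: int = 4) -> pd.DataFrame:
    """OLS slope of adjusted log2 ratio vs day for every variant.

    Points are ``{(0, 0)} u {(day, adjusted)}`` per replicate (the log2
    frequency at the starting timepoint is set to 0, once per replicate so
    replicate count weights the fit).  An optional ``target`` column in
    ``adjusted`` makes the anchor per replicate per target and records the
    number of source targets, which pools overlapping-target data into a
    single score.  Variants with fewer than ``min_points`` points get a
    missing score.
    """
    has_target = "target" in adjusted.columns
    records = []
    for vid, sub in adjusted.groupby("variant_id", sort=False):
        points = []
        anchor_keys = {(row.replicate, getattr(row, "target", None))
                       for row in sub.itertuples()}
        for _ in anchor_keys:
            points.append((0.0, 0.0))
        for row in sub.itertuples():
            if np.isfinite(row.adjusted):
                points.append((float(row.day), float(row.adjusted)))
        n_targets = sub["target"].nunique() if has_target else 1
        if len(points) < min_points:
            records.append(ScoreRecord(vid, float("nan"), float("nan"),
                                       len(points), n_targets))
            continue
        slope, se = _slope(points)
        records.append(ScoreRecord(vid, slope, se, len(points), n_targets))
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("variant_id")
    return df.drop(columns=["rna_score"])


def score_overlapping(adjusted_a: pd.DataFrame,
                      adjusted_b: pd.DataFrame) -> pd.DataFrame:
    """Jointly score variants covered by two adjacent targets by pooling
    both targets' adjusted ratios into one regression."""
    a = adjusted_a.copy()
    b = adjusted_b.copy()
    a["target"] = a.get("target", "A")
    b["target"] = b.get("target", "B")
    return score_variants(pd.concat([a, b], ignore_index=True))


def rna_scores(
    ft: FrequencyTable,
    target: TargetSpec,
    variants: list[VariantDef],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Median-over-replicates RNA score per variant.

    Per replicate, score = log2(f_RNA / f_DNA) where the day-5 DNA
    frequency is renormalized over the variants inside the RNA amplicon
    window before the ratio.  Variants outside the window get no score.
    """
    lo, hi = target.rna_window
    window_ids = [v.variant_id for v in variants
                  if lo <= v.pos < hi and v.variant_id in ft.counts.index]
    rna_keys = sorted(k for k in ft.counts.columns if k[0] == "day5_rna")
    dna_keys = sorted(k for k in ft.counts.columns if k[0] == "day5_dna")
    if not rna_keys:
        return pd.Series(dtype=float, name="rna_score")
    per_rep = {}
    for rkey in rna_keys:
        rep = rkey[1]
        dkey = next((k for k in dna_keys if k[1] == rep), None)
        if dkey is None:
            continue
        rna_c = ft.counts.loc[window_ids, rkey] + pseudocount
        dna_c = ft.counts.loc[window_ids, dkey] + pseudocount
        f_rna = rna_c / rna_c.sum()
        f_dna = dna_c / dna_c.sum()
        per_rep[rep] = np.log2(f_rna / f_dna)
    mat = pd.DataFrame(per_rep)
    score = mat.median(axis=1)
    score.name = "rna_score"
    return score


def combine_rna_scores(score_a: pd.Series, score_b: pd.Series) -> pd.Series:
    """Final RNA score for variants covered by two targets: the mean of
    both individual scores (single-target variants keep their own)."""
    combined = pd.concat([score_a, score_b], axis=1).mean(axis=1)
    combined.name = "rna_score"
    return combined


def score_target(
    ft: FrequencyTable,
    target: TargetSpec,
    variants: list[VariantDef],
    span: float = DEFAULT_SPAN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    with_rna: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline for one target.

    Returns ``(scores, adjusted_ratios)``; ``scores`` has functional_score,
    score_se, n_points, source_targets and (when RNA libraries are present)
    rna_score.
    """
    ratios = log2_ratio_table(ft, target, variants, pseudocount)
    adjusted = smooth_and_adjust(ratios, span=span)
    scores = score_variants(adjusted)
    if with_rna:
        rna = rna_scores(ft, target, variants, pseudocount)
        scores = scores.join(rna)
    else:
        scores["rna_score"] = np.nan
    return scores, adjusted
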