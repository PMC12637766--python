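"""Functional class assignment from score distributions.

SNV scores are modeled as a two-component univariate Gaussian mixture whose
means are initialized from biological anchors: the percentile-trimmed mean
of presumed-neutral (synonymous + intronic) SNVs and the mean of nonsense
SNVs (excluding exons where nonsense variants escape selection, e.g. via
alternative translation initiation or C-terminal position).  Variants whose
posterior probability of membership in a component exceeds a cutoff (0.95)
take that component's label -- "functionally abnormal" for the lesser-mean
component, "functionally normal" for the greater -- and the rest are
indeterminate.  Reusable score thresholds are the observed scores closest
to the posterior cutoffs; they classify 3-bp deletions without refitting.

RNA classes use a one-sided rule: a variant has "normal" RNA abundance when
its RNA score is at least one standard deviation above the mean nonsense
RNA score (mean and SD over the bottom 97.5% of eligible nonsense scores).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

ABNORMAL = "functionally_abnormal"
NORMAL = "functionally_normal"
INDETERMINATE = "indeterminate"

NEUTRAL_CONSEQUENCES = ("synonymous", "intron")
NONSENSE_EXCLUDE_EXONS = ("1", "4", "11")
RNA_NONSENSE_EXCLUDE_EXONS = ("1", "2", "11")
POSTERIOR_CUTOFF = 0.95


@dataclass(frozen=True)
class MixtureInit:
    mean_normal: float
    mean_abnormal: float
    var_normal: float
    var_abnormal: float


@dataclass
class GmmModel:
    """Fitted two-component mixture; component 0 is the abnormal (lesser
    mean) component, component 1 the normal one."""
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float

    def __post_init__(self):
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")

    def posterior_abnormal(self, scores) -> np.ndarray:
        from scipy.stats import norm
        x = np.asarray(scores, float)
        dens = np.stack([w * norm.pdf(x, m, np.sqrt(v)) for m, v, w
                         in zip(self.means, self.variances, self.weights)])
        with np.errstate(invalid="ignore"):
            return dens[0] / dens.sum(axis=0)

    def to_json(self, path=None) -> str:
        d = {"means": self.means.tolist(), "variances": self.variances.tolist(),
             "weights": self.weights.tolist(), "converged": self.converged,
             "n_iter": self.n_iter, "log_likelihood": self.log_likelihood}
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class ThresholdSet:
    lof_threshold: float
    normal_threshold: float
    rna_threshold: float = float("nan")

    def __post_init__(self):
        if self.lof_threshold > self.normal_threshold:
            raise ValueError("lof_threshold must not exceed normal_threshold")


def init_means(
    scores,
    consequences,
    exon_labels,
    neutral_consequences: tuple[str, ...] = NEUTRAL_CONSEQUENCES,
    nonsense_exclude_exons: tuple[str, ...] = NONSENSE_EXCLUDE_EXONS,
    min_neutral: int = 20,
    min_nonsense: int = 5,
) -> MixtureInit:
    """Anchor means (and variances) for the mixture initialization.

    Neutral anchor: mean of the middle 95% (2.5-97.5 percentile trimmed)
    of synonymous + intronic SNV scores.  Abnormal anchor: mean of all
    nonsense SNV scores outside the excluded exons.
    """
    scores = np.asarray(scores, float)
    consequences = np.asarray(consequences, object)
    exon_labels = np.asarray(exon_labels, object).astype(str)
    ok = np.isfinite(scores)

    neutral = scores[ok & np.isin(consequences, neutral_consequences)]
    nonsense = scores[ok & (consequences == "stop_gained")
                      & ~np.isin(exon_labels, nonsense_exclude_exons)]
    if len(neutral) < min_neutral or len(nonsense) < min_nonsense:
        raise ValueError(
            f"insufficient anchors: {len(neutral)} neutral, "
            f"{len(nonsense)} eligible nonsense scores")
    lo, hi = np.percentile(neutral, [2.5, 97.5])
    trimmed = neutral[(neutral >= lo) & (neutral <= hi)]
    return MixtureInit(
        mean_normal=float(trimmed.mean()),
        mean_abnormal=float(nonsense.mean()),
        var_normal=float(max(trimmed.var(ddof=1), 1e-8)),
        var_abnormal=float(max(nonsense.var(ddof=1), 1e-8)),
    )


def fit_gmm(scores, inits: MixtureInit, tol: float = 1e-6,
            max_iter: int = 500, min_scores: int = 100) -> GmmModel:
    """EM fit of the two-component mixture with anchored initialization.

    Means start at the anchors, weights at 0.5/0.5 and variances at the
    anchor-subset variances; variances and weights are free.  Deterministic
    for fixed inputs.  Non-convergence returns the best model with a
    warning; a degenerate fit (vanishing weight or merged components) is
    also flagged by warning.
    """
    x = np.asarray(scores, float)
    x = x[np.isfinite(x)].reshape(-1, 1)
    if len(x) < min_scores:
        raise ValueError(f"need at least {min_scores} scores, got {len(x)}")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        means_init=np.array([[inits.mean_abnormal], [inits.mean_normal]]),
        weights_init=np.array([0.5, 0.5]),
        precisions_init=np.array([[[1.0 / inits.var_abnormal]],
                                  [[1.0 / inits.var_normal]]]),
    )
    gm.fit(x)
    if not gm.converged_:
        warnings.warn("EM did not converge; returning best model")
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    order = np.argsort(means)  # abnormal = lesser mean first
    model = GmmModel(means=means[order], variances=variances[order],
                     weights=weights[order], converged=bool(gm.converged_),
                     n_iter=int(gm.n_iter_),
                     log_likelihood=float(gm.lower_bound_ * len(x)))
    if weights.min() < 1e-3 or abs(means[0] - means[1]) < 1e-6:
        warnings.warn("degenerate mixture fit (single population?)")
    return model


def assign_classes(scores, model: GmmModel,
                   cutoff: float = POSTERIOR_CUTOFF) -> np.ndarray:
    """Posterior-based three-way labels for SNV scores."""
    p_ab = model.posterior_abnormal(scores)
    labels = np.full(len(p_ab), INDETERMINATE, dtype=object)
    labels[p_ab > cutoff] = ABNORMAL
    labels[(1 - p_ab) > cutoff] = NORMAL
    labels[~np.isfinite(np.asarray(scores, float))] = INDETERMINATE
    return labels


def derive_thresholds(scores, model: GmmModel,
                      cutoff: float = POSTERIOR_CUTOFF) -> ThresholdSet:
    """Score thresholds: the observed variants whose posteriors are closest
    to the 0.95 cutoffs (abnormal side and normal side)."""
    x = np.asarray(scores, float)
    x = x[np.isfinite(x)]
    p_ab = model.posterior_abnormal(x)
    lof = float(x[np.argmin(np.abs(p_ab - cutoff))])
    normal = float(x[np.argmin(np.abs((1 - p_ab) - cutoff))])
    if lof > normal:  # posterior ties in sparse data; keep ordering
        lof = normal = float((lof + normal) / 2)
    return ThresholdSet(lof_threshold=lof, normal_threshold=normal)


def classify_by_threshold(scores, thresholds: ThresholdSet) -> np.ndarray:
    """Three-way labels from score thresholds (used for 3-bp deletions,
    without refitting the mixture)."""
    x = np.asarray(scores, float)
    labels = np.full(len(x), INDETERMINATE, dtype=object)
    labels[x <= thresholds.lof_threshold] = ABNORMAL
    labels[x >= thresholds.normal_threshold] = NORMAL
    labels[~np.isfinite(x)] = INDETERMINATE
    return labels


classify_deletions = classify_by_threshold


def rna_threshold_and_classes(
    rna_scores,
    consequences,
    exon_labels,
    exclude_exons: tuple[str, ...] = RNA_NONSENSE_EXCLUDE_EXONS,
    min_nonsense: int = 10,
) -> tuple[float, np.ndarray]:
    """RNA abundance threshold and low/normal labels.

    The threshold is mu + sigma of the bottom 97.5% of nonsense RNA scores
    (excluded exons dropped); a variant is "normal" iff its RNA score is at
    least the threshold (boundary inclusive on the normal side).
    """
    x = np.asarray(rna_scores, float)
    consequences = np.asarray(consequences, object)
    exon_labels = np.asarray(exon_labels, object).astype(str)
    eligible = x[np.isfinite(x) & (consequences == "stop_gained")
                 & ~np.isin(exon_labels, exclude_exons)]
    if len(eligible) < min_nonsense:
        raise ValueError(f"insufficient nonsense RNA scores ({len(eligible)})")
    cap = np.percentile(eligible, 97.5)
    bottom = eligible[eligible <= cap]
    mu, sigma = float(bottom.mean()), float(bottom.std(ddof=1))
    threshold = mu + sigma
    labels = np.where(x >= threshold, "normal", "low").astype(object)
    labels[~np.isfinite(x)] = "missing"
    return threshold, labels


def classify_scores(
    scores: pd.DataFrame,
    cutoff: float = POSTERIOR_CUTOFF,
    neutral_consequences: tuple[str, ...] = NEUTRAL_CONSEQUENCES,
    nonsense_exclude_exons: tuple[str, ...] = NONSENSE_EXCLUDE_EXONS,
    rna_exclude_exons: tuple[str, ...] = RNA_NONSENSE_EXCLUDE_EXONS,
) -> tuple[pd.DataFrame, GmmModel, ThresholdSet]:
    """End-to-end class assignment for a scored variant table.

    ``scores`` is indexed by variant_id with columns functional_score,
    vtype, consequence, exon_label and optionally rna_score.  SNVs get
    posterior-based labels; deletions are classified by the SNV-derived
    thresholds; RNA classes are added when RNA scores are present.
    """
    snv = scores[scores["vtype"] == "snv"]
    inits = init_means(snv["functional_score"], snv["consequence"],
                       snv["exon_label"], neutral_consequences,
                       nonsense_exclude_exons)
    model = fit_gmm(snv["functional_score"].dropna(), inits)
    thresholds = derive_thresholds(snv["functional_score"], model, cutoff)

    out = scores.copy()
    out["functional_class"] = INDETERMINATE
    snv_mask = out["vtype"] == "snv"
    out.loc[snv_mask, "functional_class"] = assign_classes(
        out.loc[snv_mask, "functional_score"], model, cutoff)
    del_mask = out["vtype"] == "del3"
    out.loc[del_mask, "functional_class"] = classify_by_threshold(
        out.loc[del_mask, "functional_score"], thresholds)

    if "rna_score" in out.columns and out["rna_score"].notna().any():
        try:
            rna_thr, rna_labels = rna_threshold_and_classes(
                out["rna_score"], out["consequence"], out["exon_label"],
                rna_exclude_exons)
            out["rna_class"] = rna_labels
            thresholds = ThresholdSet(thresholds.lof_threshold,
                                      thresholds.normal_threshold, rna_thr)
        except ValueError as exc:
            warnings.warn(str(exc))
    return out, model, thresholds
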