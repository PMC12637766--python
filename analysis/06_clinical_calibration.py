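"""Clinical calibration: OddsPath, ACMG/AMP points, ROC and case-control.

Three analyses: (1) OddsPath on the published BARD1 ClinVar calibration
composition (a stated input), mapped to PS3/BS3 evidence points;
(2) the same machinery on this pipeline's own synthetic truth set, plus
ROC/AUC of scores against ground-truth labels and a points-based
reclassification of mock VUS; (3) case-control odds ratios from cohorts
simulated at known enrichment, with a Z-test comparing two of them.
"""
import json

import numpy as np
import pandas as pd

from sgescore import (compare_odds_ratios, compute_oddspath, fisher_or,
                      map_evidence_strength, reclassify_variants, roc_auc,
                      simulate_cohort)
from sgescore.workflows import classify_gene, reference_calibration_table

from common import SEED, outdirs, scored_gene


def main():
    results, _scratch = outdirs()
    out = {}

    # 1. published calibration composition
    calib = compute_oddspath(reference_calibration_table())
    strengths = map_evidence_strength(calib)
    out["published_composition"] = {
        "oddspath_pathogenic": round(calib.oddspath_pathogenic, 2),
        "oddspath_benign": round(calib.oddspath_benign, 4),
        "ps3": [strengths.ps3_strength, strengths.ps3_points],
        "bs3": [strengths.bs3_strength, strengths.bs3_points],
    }

    # 2. this pipeline's synthetic truth set: ground-truth LoF labels play
    # the role of pathogenic/benign clinical classifications
    labeled, _model, _thr = classify_gene(scored_gene())
    snv = labeled[labeled["vtype"] == "snv"].dropna(subset=["functional_score"])
    truth = pd.DataFrame({
        "variant_id": snv.index,
        "clinical_label": np.where(snv["is_lof"], "pathogenic_or_LP",
                                   "benign_or_LB"),
        "functional_class": snv["functional_class"].values,
    })
    own = compute_oddspath(truth)
    own_strengths = map_evidence_strength(own)
    auc, _curve = roc_auc(snv["functional_score"], snv["is_lof"].astype(int))
    out["synthetic_truth"] = {
        "oddspath_pathogenic": round(own.oddspath_pathogenic, 1),
        "oddspath_benign": round(own.oddspath_benign, 5),
        "zero_cell_adjusted": own.zero_cell_adjusted,
        "auc": round(float(auc), 4),
        "n": len(truth),
    }

    # mock VUS reclassification with the calibrated functional evidence
    rng = np.random.default_rng(SEED)
    vus = snv.sample(300, random_state=SEED)
    evidence = pd.DataFrame({
        "functional_class": vus["functional_class"].values,
        "PP3": np.where(vus["is_lof"], 1, 0) * rng.integers(0, 2, 300),
        "BP4": np.where(vus["is_lof"], 0, -1) * rng.integers(0, 2, 300),
        "PM2_supporting": rng.integers(0, 2, 300),
    }, index=vus.index)
    reclassified = reclassify_variants(evidence, own_strengths)
    out["reclassification"] = {
        "n_vus_in": 300,
        "resolved_pct": round(100 * (reclassified["classification"] != "VUS")
                              .mean(), 1),
        "classes": reclassified["classification"].value_counts().to_dict(),
    }

    # 3. case-control enrichment at known odds ratios
    cohorts = {}
    for i, (name, (n_case, n_ctl, freq, true_or)) in enumerate({
        "lof_missense": (60_000, 55_000, 0.003, 1.73),
        "truncating": (60_000, 55_000, 0.002, 1.80),
        "normal_missense": (60_000, 55_000, 0.01, 1.00),
    }.items()):
        t = simulate_cohort(n_case, n_ctl, freq, true_or, seed=SEED + i)
        res = fisher_or(t)
        cohorts[name] = {"true_or": true_or,
                         "or": round(res.odds_ratio, 2),
                         "ci": [round(res.ci_low, 2), round(res.ci_high, 2)],
                         "p": float(f"{res.p_value:.2e}")}
    z, p = compare_odds_ratios(
        cohorts["lof_missense"]["or"], cohorts["lof_missense"]["ci"],
        cohorts["truncating"]["or"], cohorts["truncating"]["ci"])
    out["case_control"] = cohorts
    out["lof_missense_vs_truncating_z_p"] = [round(z, 3), round(p, 3)]

    (results / "clinical_summary.json").write_text(
        json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
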