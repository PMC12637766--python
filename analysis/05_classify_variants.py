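"""Functional class assignment via the two-component Gaussian mixture.

SNV scores anchor the mixture (trimmed synonymous+intronic mean vs
nonsense mean outside escape-prone exons); posteriors above 0.95 assign
the functionally-abnormal / functionally-normal labels, the nearest
observed scores to the posterior cutoffs become reusable thresholds, and
the thresholds classify the 3-bp deletions without refitting.  RNA classes
follow the nonsense-anchored mu + sigma rule.
"""
import json

import pandas as pd

from sgescore.workflows import classify_gene

from common import outdirs, scored_gene


def main():
    results, scratch = outdirs()
    labeled, model, thresholds = classify_gene(scored_gene())

    (results / "thresholds.json").write_text(json.dumps({
        "lof_threshold": round(thresholds.lof_threshold, 4),
        "normal_threshold": round(thresholds.normal_threshold, 4),
        "rna_threshold": round(thresholds.rna_threshold, 3),
        "gmm_means": [round(m, 4) for m in model.means],
        "gmm_weights": [round(w, 4) for w in model.weights],
    }, indent=2) + "\n")

    snv = labeled[labeled["vtype"] == "snv"]
    frac = (pd.crosstab(snv["consequence"], snv["functional_class"],
                        normalize="index") * 100).round(1)
    frac["n"] = snv["consequence"].value_counts()
    frac.to_csv(results / "classification_summary.tsv", sep="\t")

    dels = labeled[labeled["vtype"] == "del3"]
    agree = (snv["functional_class"]
             == snv["is_lof"].map({True: "functionally_abnormal",
                                   False: "functionally_normal"})).mean()
    print(f"GMM means {model.means.round(3)}, "
          f"thresholds LoF<={thresholds.lof_threshold:.4f} / "
          f"normal>={thresholds.normal_threshold:.4f}, "
          f"RNA threshold {thresholds.rna_threshold:.3f}")
    print(f"SNV label vs truth agreement: {100 * agree:.1f}%  "
          f"({len(dels)} deletions classified by threshold)")
    print(frac.to_string())


if __name__ == "__main__":
    main()
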