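"""Position-effect-corrected functional and RNA scores for every variant.

Per replicate, day-5 log2 frequency ratios are LOESS-smoothed against
genomic position (span 0.20, fit restricted to variants retaining at least
half their starting frequency); the fits are subtracted from day-5 and
cognate day-13 ratios, and the OLS slope of adjusted ratio vs day is the
functional score (log2 fold-change per day).  RNA scores compare day-5
mRNA frequencies with window-renormalized day-5 DNA frequencies.
"""
import numpy as np
import pandas as pd
from scipy import stats

from sgescore.io import write_scores_csv

from common import outdirs, scored_gene


def main():
    results, scratch = outdirs()
    scores = scored_gene()
    write_scores_csv(scores.drop(columns=["is_lof"]), scratch / "scores.csv")

    scored = scores.dropna(subset=["functional_score"])
    rho = stats.spearmanr(scored["functional_score"],
                          scored["true_slope"]).statistic
    summary = (scored.groupby("consequence")["functional_score"]
               .agg(["count", "mean", "std"]).round(4)
               .sort_values("mean"))
    summary.to_csv(results / "score_summary.tsv", sep="\t")
    print(f"scored {len(scored)} of {len(scores)} variants "
          f"(Spearman vs true slopes: {rho:.3f})")
    print(f"RNA scores for {int(scores['rna_score'].notna().sum())} variants")
    print(summary.to_string())


if __name__ == "__main__":
    main()
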