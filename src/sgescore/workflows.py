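"""Canonical end-to-end experiments over synthetic SGE data.

These wrap the per-module pieces into the standard study conditions used by
the analysis drivers and the acceptance script: a multi-target synthetic
gene resembling a full SGE tiling of an essential gene, a slope-recovery
benchmark, and the published BARD1 ClinVar calibration composition.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import compute_frequencies
from .classification import classify_scores
from .clinical import ABNORMAL, BENIGN, NORMAL, PATHOGENIC
from .io import variants_to_frame
from .qc import run_library_qc
from .scoring import score_target
from .simulate import draw_truth, gaussian_bump, simulate_counts
from .targets import enumerate_variants, generate_target


def simulate_gene(seed: int, n_targets: int = 8, length: int = 160,
                  depth_scale: float = 1.0):
    """Simulate an SGE tiling of ``n_targets`` regions of one gene.

    Each target gets its own exon label, coding offset and genomic offset;
    a Gaussian cut-site position effect is always on.  Returns a list of
    per-target dicts with keys target, variants, truth, counts.
    """
    ss = np.random.SeedSequence([seed, 7001])
    out = []
    coding_per_target = None
    c_offset = 1
    for i, sub in enumerate(ss.spawn(n_targets)):
        sub_seed = int(sub.generate_state(1)[0] % (2 ** 31))
        target = generate_target(
            length, length // 2, 2, seed=sub_seed, intron_pad=12,
            exon_label=str(i + 1), c_offset=c_offset,
            aa_offset=1 + (c_offset - 1) // 3,
            genomic_offset=1_000_000 + i * (length + 40),
            target_id=f"T{i + 1:02d}",
            domain=("RING", "disordered", "ARD", "BRCT")[i % 4],
        )
        cs, ce = target.coding_region
        coding_per_target = ce - cs
        variants = enumerate_variants(target)
        truth = draw_truth(variants, seed=sub_seed + 1)
        design = {"replicates": 3, "timepoints": (0, 5, 13),
                  "depth": {k: int(v * depth_scale) for k, v in {
                      "library": 600_000, "day5_dna": 250_000,
                      "day13_dna": 250_000, "day5_rna": 200_000,
                      "negative_control": 100_000}.items()}}
        counts = simulate_counts(
            target, variants, truth, design=design, seed=sub_seed + 2,
            position_effect=gaussian_bump(
                target.genomic_position(target.cut_site)))
        out.append({"target": target, "variants": variants,
                    "truth": truth, "counts": counts})
        c_offset += coding_per_target
    return out


def score_gene(sim: list[dict], span: float = 0.20,
               pseudocount: float = 0.5) -> pd.DataFrame:
    """QC, filter and score every target of a simulated gene; returns the
    pooled annotated score table (indexed by variant_id)."""
    frames = []
    for entry in sim:
        target, variants = entry["target"], entry["variants"]
        report = run_library_qc(entry["counts"])
        if not report.target_pass:
            continue
        ft = compute_frequencies(entry["counts"], target, variants)
        scores, _adj = score_target(ft, target, variants, span=span,
                                    pseudocount=pseudocount)
        ann = variants_to_frame(variants)
        frames.append(scores.join(
            ann[["vtype", "pos", "consequence", "aa_change", "exon_label",
                 "domain"]]).join(entry["truth"]))
    return pd.concat(frames)


def classify_gene(scores: pd.DataFrame):
    """Mixture-model classification of a pooled score table."""
    return classify_scores(scores)


def recovery_experiment(seed: int, n_variants: int = 300,
                        depth: int = 200_000, replicates: int = 3):
    """Slope-recovery benchmark: SNVs with slopes uniform on [-0.3, 0],
    position effect on.  Returns (scores-with-truth frame, spearman,
    mean_bias)."""
    from scipy import stats

    target = generate_target(n_variants // 3 + 20, n_variants // 6 + 10, 2,
                             seed=seed, flank=10)
    variants = [v for v in enumerate_variants(target)
                if v.vtype == "snv"][:n_variants]
    rng = np.random.default_rng(seed + 1)
    truth = pd.DataFrame({
        "true_slope": rng.uniform(-0.3, 0.0, len(variants)),
        "true_rna_effect": 0.0,
        "initial_freq": np.full(len(variants), 0.95 / len(variants)),
    }, index=[v.variant_id for v in variants])
    design = {"replicates": replicates, "timepoints": (0, 5, 13),
              "depth": depth}
    counts = simulate_counts(
        target, variants, truth, design=design, seed=seed + 2,
        position_effect=gaussian_bump(
            target.genomic_position(target.cut_site)), rna=False)
    ft = compute_frequencies(counts, target, variants)
    scores, _adj = score_target(ft, target, variants, with_rna=False)
    merged = scores.join(truth).dropna(subset=["functional_score"])
    rho = stats.spearmanr(merged["functional_score"],
                          merged["true_slope"]).statistic
    bias = float((merged["functional_score"] - merged["true_slope"]).mean())
    return merged, float(rho), bias


def reference_calibration_table() -> pd.DataFrame:
    """The published BARD1 ClinVar calibration composition.

    186 pathogenic/likely-pathogenic and 959 benign/likely-benign truth
    variants; the assay called 184 P and 3 B functionally abnormal, 1 P and
    956 B functionally normal, and left one pathogenic variant
    indeterminate.
    """
    rows = []
    rows += [(PATHOGENIC, ABNORMAL)] * 184 + [(BENIGN, ABNORMAL)] * 3
    rows += [(PATHOGENIC, NORMAL)] * 1 + [(BENIGN, NORMAL)] * 956
    rows += [(PATHOGENIC, "indeterminate")] * 1
    df = pd.DataFrame(rows, columns=["clinical_label", "functional_class"])
    df.insert(0, "variant_id", [f"cal_{i}" for i in range(len(df))])
    return df
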