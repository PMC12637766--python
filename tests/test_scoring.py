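import numpy as np
import pandas as pd
import pytest

from sgescore import (compute_frequencies, draw_truth, enumerate_variants,
                      fit_position_smoother, generate_target, score_target,
                      score_overlapping, score_variants, simulate_counts,
                      smooth_and_adjust)
from sgescore.calling import FrequencyTable
from sgescore.scoring import (combine_rna_scores, log2_ratio_table,
                              rna_scores)

from conftest import make_count_table


def _freq_table(per_library, totals):
    counts = make_count_table(per_library, totals)
    freqs = counts.counts.div(counts.totals["total_valid_reads"], axis=1)
    return FrequencyTable(counts=counts.counts, totals=counts.totals,
                          frequencies=freqs)


def _adjusted_frame(points_by_variant):
    """Build an adjusted-ratio frame from {vid: {(rep, day): adjusted}}."""
    rows = []
    for vid, pts in points_by_variant.items():
        for (rep, day), adj in pts.items():
            rows.append((vid, 0.0, rep, day, adj, adj))
    return pd.DataFrame(rows, columns=["variant_id", "genomic_pos",
                                       "replicate", "day", "log2_ratio",
                                       "adjusted"])


def test_day5_log2_ratio_arithmetic(random_target, random_variants):
    t = random_target
    v = random_variants[:2]
    ids = [x.variant_id for x in v]
    # f5 = 0.0005 vs f0 = 0.001 -> ratio -1; equal frequencies -> 0
    ft = _freq_table(
        {("library", 0): {ids[0]: 1000, ids[1]: 500},
         ("day5_dna", 0): {ids[0]: 500, ids[1]: 500}},
        {("library", 0): (1_000_000, 1_000_000, 0),
         ("day5_dna", 0): (1_000_000, 1_000_000, 0)})
    ratios = log2_ratio_table(ft, t, v, pseudocount=0.0)
    r = ratios.set_index("variant_id")["log2_ratio"]
    assert r[ids[0]] == pytest.approx(-1.0)
    assert r[ids[1]] == pytest.approx(0.0)


def test_pseudocount_keeps_zero_counts_finite(random_target, random_variants):
    v = random_variants[:2]
    ids = [x.variant_id for x in v]
    ft = _freq_table(
        {("library", 0): {ids[0]: 1000, ids[1]: 1000},
         ("day5_dna", 0): {ids[0]: 0, ids[1]: 1000}},
        {("library", 0): (1_000_000, 1_000_000, 0),
         ("day5_dna", 0): (1_000_000, 1_000_000, 0)})
    ratios = log2_ratio_table(ft, random_target, v, pseudocount=0.5)
    r = ratios.set_index("variant_id")["log2_ratio"]
    assert np.isfinite(r[ids[0]]) and r[ids[0]] < -5
    assert not ratios.set_index("variant_id")["in_fit_subset"][ids[0]]


def test_smoother_recovers_constant_and_sinusoid():
    rng = np.random.default_rng(0)
    pos = np.arange(300, dtype=float)
    const = np.full(300, -0.3)
    fit = fit_position_smoother(pos, const, np.ones(300, bool), pos)
    assert np.abs(fit - (-0.3)).max() < 1e-6
    wave = 0.5 * np.sin(2 * np.pi * pos / 300)
    fit2 = fit_position_smoother(pos, wave, np.ones(300, bool), pos)
    rmse = np.sqrt(np.mean((fit2 - wave) ** 2))
    assert rmse < 0.05


def test_smoother_skips_below_minimum_points():
    pos = np.arange(5, dtype=float)
    with pytest.warns(UserWarning):
        fit = fit_position_smoother(pos, pos * 0.1, np.ones(5, bool), pos)
    assert (fit == 0).all()


def test_excluded_variants_still_receive_fit():
    pos = np.arange(100, dtype=float)
    y = 0.01 * pos
    in_fit = np.ones(100, bool)
    in_fit[40] = False  # depleted beyond half the starting frequency
    fit = fit_position_smoother(pos, y, in_fit, pos)
    assert np.isfinite(fit[40])
    assert fit[40] == pytest.approx(0.4, abs=0.05)


def test_adjustment_uses_cognate_day5_fit():
    """Day-13 ratios are adjusted with the day-5-derived fit of their own
    replicate; with a flat fit the adjustment is the identity."""
    rows = []
    for rep, offset in ((0, -0.2), (1, 0.4)):
        for vid in range(30):
            rows.append((f"v{vid}", float(vid), rep, 5, offset))
            rows.append((f"v{vid}", float(vid), rep, 13, -1.0))
    df = pd.DataFrame(rows, columns=["variant_id", "genomic_pos", "replicate",
                                     "day", "log2_ratio"])
    df["in_fit_subset"] = df["day"] == 5
    adj = smooth_and_adjust(df)
    d13 = adj[adj["day"] == 13].set_index(["replicate", "variant_id"])
    # each replicate's constant day-5 level is subtracted from its day 13
    assert d13.loc[(0, "v3"), "adjusted"] == pytest.approx(-1.0 - (-0.2), abs=1e-6)
    assert d13.loc[(1, "v3"), "adjusted"] == pytest.approx(-1.0 - 0.4, abs=1e-6)
    d5 = adj[adj["day"] == 5]
    assert np.abs(d5["adjusted"]).max() < 1e-6


def test_ols_slope_collinear_example():
    """Points (0,0), (5,-1.0), (13,-2.6) are collinear through the origin
    with slope -0.2 exactly."""
    frame = _adjusted_frame({
        "v1": {(0, 5): -1.0, (0, 13): -2.6, (1, 5): -1.0, (1, 13): -2.6}})
    scores = score_variants(frame)
    assert scores.loc["v1", "functional_score"] == pytest.approx(-0.2, abs=1e-12)
    assert scores.loc["v1", "score_se"] == pytest.approx(0.0, abs=1e-9)
    assert scores.loc["v1", "n_points"] == 6


def test_zero_ratios_zero_slope():
    frame = _adjusted_frame({"v1": {(0, 5): 0.0, (0, 13): 0.0,
                                    (1, 5): 0.0, (1, 13): 0.0}})
    assert score_variants(frame).loc["v1", "functional_score"] == pytest.approx(0.0)


def test_too_few_points_gives_missing_score():
    frame = _adjusted_frame({"v1": {(0, 5): -1.0}})
    rec = score_variants(frame).loc["v1"]
    assert np.isnan(rec["functional_score"])
    assert rec["n_points"] == 2


def test_score_overlapping_pooling():
    a = _adjusted_frame({"v1": {(0, 5): -0.5, (0, 13): -1.3,
                                (1, 5): -0.5, (1, 13): -1.3}})
    b = a.copy()
    single = score_variants(a).loc["v1", "functional_score"]
    pooled = score_overlapping(a, b)
    # duplicated data leaves the OLS slope unchanged, sources = 2
    assert pooled.loc["v1", "functional_score"] == pytest.approx(single)
    assert pooled.loc["v1", "source_targets"] == 2
    # pooled slope lies between the two single-target slopes
    steep = _adjusted_frame({"v1": {(0, 5): -1.5, (0, 13): -3.9,
                                    (1, 5): -1.5, (1, 13): -3.9}})
    s1 = score_variants(a).loc["v1", "functional_score"]
    s2 = score_variants(steep).loc["v1", "functional_score"]
    sp = score_overlapping(a, steep).loc["v1", "functional_score"]
    assert min(s1, s2) <= sp <= max(s1, s2)
    # pooling with an empty frame reduces to the single-target score
    empty = a.iloc[0:0]
    assert score_overlapping(a, empty).loc["v1", "functional_score"] == \
        pytest.approx(single)


def test_rna_score_arithmetic(random_target, random_variants):
    t = random_target
    lo, hi = t.rna_window
    window = [v for v in random_variants if lo <= v.pos < hi][:2]
    ids = [v.variant_id for v in window]
    # two-variant window: f_rna over window vs renormalized day-5 DNA
    ft = _freq_table(
        {("day5_dna", 0): {ids[0]: 2000, ids[1]: 8000},
         ("day5_rna", 0): {ids[0]: 500, ids[1]: 9500}},
        {("day5_dna", 0): (100_000, 100_000, 0),
         ("day5_rna", 0): (100_000, 100_000, 0)})
    scores = rna_scores(ft, t, window, pseudocount=0.0)
    assert scores[ids[0]] == pytest.approx(np.log2(0.05 / 0.2))
    assert scores[ids[1]] == pytest.approx(np.log2(0.95 / 0.8))


def test_rna_score_median_and_two_target_mean():
    s_reps = pd.DataFrame({0: [-1.0], 1: [-1.2], 2: [-3.0]}, index=["v1"])
    assert s_reps.median(axis=1)["v1"] == -1.2
    a = pd.Series({"v1": -1.0}, name="rna_score")
    b = pd.Series({"v1": -2.0}, name="rna_score")
    assert combine_rna_scores(a, b)["v1"] == pytest.approx(-1.5)
    c = pd.Series({"v2": -0.5}, name="rna_score")
    combined = combine_rna_scores(a, c)
    assert combined["v1"] == -1.0 and combined["v2"] == -0.5


def _simulated_scores(slopes_zero=False, scale=1, position_effect=None,
                      pseudocount=0.5, span=0.2, seed=21):
    target = generate_target(140, 70, 2, seed=7, intron_pad=12, exon_label="2")
    variants = enumerate_variants(target)
    truth = draw_truth(variants, seed=seed)
    if slopes_zero:
        truth["true_slope"] = 0.0
    design = {"replicates": 3, "timepoints": (0, 5, 13),
              "depth": {"library": 300_000 * scale, "day5_dna": 150_000 * scale,
                        "day13_dna": 150_000 * scale, "day5_rna": 100_000,
                        "negative_control": 1_000}}
    counts = simulate_counts(target, variants, truth, design=design,
                             seed=seed + 1, position_effect=position_effect,
                             rna=False)
    ft = compute_frequencies(counts, target, variants)
    scores, adjusted = score_target(ft, target, variants, span=span,
                                    pseudocount=pseudocount, with_rna=False)
    return scores, adjusted, truth


def test_scale_invariance_of_scores():
    """Multiplying all counts (and totals) by 10 leaves scores unchanged
    (frequencies normalize; checked without a pseudocount, which is exact)."""
    target = generate_target(140, 70, 2, seed=7, intron_pad=12, exon_label="2")
    variants = enumerate_variants(target)
    truth = draw_truth(variants, seed=21)
    design = {"replicates": 3, "timepoints": (0, 5, 13),
              "depth": {"library": 300_000, "day5_dna": 150_000,
                        "day13_dna": 150_000, "negative_control": 1_000}}
    counts = simulate_counts(target, variants, truth, design=design, seed=22,
                             rna=False)
    scaled = counts
    scaled.counts = counts.counts * 10
    scaled.totals = counts.totals * 10
    ft1 = compute_frequencies(counts, target, variants)
    base, _ = score_target(ft1, target, variants, pseudocount=0.0,
                           with_rna=False)
    ft10 = compute_frequencies(scaled, target, variants)
    bigger, _ = score_target(ft10, target, variants, pseudocount=0.0,
                             with_rna=False)
    diff = (base["functional_score"] - bigger["functional_score"]).abs()
    assert diff.max() < 1e-9


def test_smoother_null_does_not_inflate_ratios():
    """With no position effect and all slopes zero, adjustment does not
    increase the mean absolute ratio."""
    _s, adjusted, _t = _simulated_scores(slopes_zero=True)
    raw = adjusted["log2_ratio"].abs().mean()
    adj = adjusted["adjusted"].abs().mean()
    assert adj <= raw + 0.01


def test_null_model_recovers_zero_slopes():
    """All slopes zero: estimates are unbiased within two standard errors
    over hundreds of variants."""
    scores, _a, truth = _simulated_scores(slopes_zero=True)
    merged = scores.join(truth)
    est = merged["functional_score"].dropna()
    bias = est.mean()
    se = est.std(ddof=1) / np.sqrt(len(est))
    assert len(est) >= 200
    assert abs(bias) < 2 * se + 5e-4
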