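"""Synthetic SGE experiments with known ground truth.

Emulates the generative structure of a depletion screen: a plasmid repair
template library with uneven (Dirichlet) variant composition, day-5/day-13
genomic-DNA replicates whose expected log2 variant frequencies decline
linearly in time with slope = fitness + a smooth cut-site position effect,
day-5 RNA replicates with variant-specific transcript depletion, a
negative-control (untransfected) library, sequencing errors including
homopolymer length slippage, and labeled truth sets for clinical
calibration.  Everything is deterministic for a fixed top-level seed; each
library draws from its own derived sub-seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CountTable
from .clinical import ContingencyTable
from .targets import TargetSpec, VariantDef

#: (mean, sd) of the fitness slope (log2 fold-change per day) by class
LOF_SLOPE = (-0.2, 0.03)
NEUTRAL_SLOPE = (0.0, 0.01)
#: (mean, sd) of the RNA depletion (log2) for transcript-destabilizing variants
LOF_RNA = (-2.2, 0.5)

#: probability that a variant of a given consequence is loss-of-function;
#: consequences absent from the map are neutral
LOF_PROB = {
    "stop_gained": 0.99,
    "canonical_splice": 0.94,
    "splice_region": 0.128,
    "missense": 0.127,
    "synonymous": 0.005,
    "intron": 0.005,
}
#: probability that an LoF variant of a given consequence also depletes the
#: transcript (nonsense-mediated decay / splice disruption)
RNA_LOF_PROB = {
    "stop_gained": 0.9,
    "canonical_splice": 0.9,
    "splice_region": 0.8,
    "synonymous": 1.0,
    "intron": 1.0,
    "missense": 0.05,
}

DEFAULT_DESIGN = {
    "replicates": 3,
    "timepoints": (0, 5, 13),
    "depth": {
        "library": 600_000,
        "day5_dna": 250_000,
        "day13_dna": 250_000,
        "day5_rna": 200_000,
        "negative_control": 100_000,
    },
}


@dataclass(frozen=True)
class SimTruth:
    variant_id: str
    true_slope: float
    true_rna_effect: float
    initial_freq: float


def gaussian_bump(cut_site_genomic: float, amplitude: float = -0.08,
                  width: float = 15.0):
    """Smooth cut-site position effect: a Gaussian bump, in slope units
    (log2/day), centered on the cut site."""
    def g(pos):
        return amplitude * np.exp(-0.5 * ((np.asarray(pos, float)
                                           - cut_site_genomic) / width) ** 2)
    return g


def draw_truth(
    variants: list[VariantDef],
    seed: int,
    *,
    dirichlet_concentration: float = 50.0,
    wildtype_fraction: float = 0.05,
    lof_prob: dict | None = None,
    lof_slope: tuple[float, float] = LOF_SLOPE,
    neutral_slope: tuple[float, float] = NEUTRAL_SLOPE,
    lof_rna: tuple[float, float] = LOF_RNA,
) -> pd.DataFrame:
    """Assign ground-truth slopes, RNA effects and library frequencies.

    Class composition follows the consequence-level LoF probabilities so a
    full synthetic target reproduces the qualitative structure of a real
    SGE score distribution (neutral bulk, depleting nonsense/splice tail).
    Initial frequencies are symmetric-Dirichlet to emulate uneven synthesis,
    scaled so they sum to ``1 - wildtype_fraction``.
    """
    rng = np.random.default_rng(seed)
    lof_prob = LOF_PROB if lof_prob is None else lof_prob
    n = len(variants)
    freqs = rng.dirichlet(np.full(n, dirichlet_concentration)) \
        * (1.0 - wildtype_fraction)
    rows = []
    for v, f0 in zip(variants, freqs):
        p_lof = lof_prob.get(v.consequence, 0.0)
        is_lof = rng.random() < p_lof
        if is_lof:
            slope = rng.normal(*lof_slope)
            rna = rng.normal(*lof_rna) \
                if rng.random() < RNA_LOF_PROB.get(v.consequence, 0.0) else 0.0
        else:
            slope = rng.normal(*neutral_slope)
            rna = 0.0
        rows.append((v.variant_id, min(slope, 0.05), rna, f0, is_lof))
    return pd.DataFrame(
        rows, columns=["variant_id", "true_slope", "true_rna_effect",
                       "initial_freq", "is_lof"]).set_index("variant_id")


def _depth_for(design: dict, sample_type: str) -> int:
    depth = design.get("depth", DEFAULT_DESIGN["depth"])
    if isinstance(depth, dict):
        return int(depth[sample_type])
    return int(depth)


def simulate_counts(
    target: TargetSpec,
    variants: list[VariantDef],
    truth: pd.DataFrame,
    design: dict | None = None,
    position_effect=None,
    dispersion: float = 0.0,
    seed: int = 0,
    *,
    invalid_fraction: float = 0.02,
    negative_control_valid_fraction: float = 0.002,
    rna: bool = True,
) -> CountTable:
    """Draw per-library variant counts for one target.

    Expected frequency of variant ``v`` at day ``t`` is proportional to
    ``f0_v * 2**((s_v + g(pos_v)) * t)``, renormalized over the library;
    counts are multinomial (``dispersion=0``) or Dirichlet-multinomial with
    per-category concentration ``p/dispersion``.  Per-library totals equal
    the design depth.
    """
    design = {**DEFAULT_DESIGN, **(design or {})}
    timepoints = tuple(design["timepoints"])
    if 0 not in timepoints:
        raise ValueError("timepoints must include 0 (plasmid library)")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_rep = int(design["replicates"])

    ids = [v.variant_id for v in variants]
    truth = truth.loc[ids]
    f0 = truth["initial_freq"].to_numpy(float)
    slopes = truth["true_slope"].to_numpy(float)
    rna_eff = truth["true_rna_effect"].to_numpy(float)
    gpos = np.array([target.genomic_position(v.pos) for v in variants], float)
    g = np.zeros(len(ids)) if position_effect is None else \
        np.asarray(position_effect(gpos), float)
    wt_frac = max(0.0, 1.0 - f0.sum())

    in_window = np.array([target.rna_window[0] <= v.pos < target.rna_window[1]
                          for v in variants])

    ss = np.random.SeedSequence(seed)

    def draw(rng, depth, probs):
        if depth <= 0:
            raise ValueError("depth must be positive")
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        if dispersion > 0:
            alpha = np.where(probs > 0, probs / dispersion, 1e-12)
            probs = rng.dirichlet(alpha)
        return rng.multinomial(depth, probs)

    def variant_probs(t, rna_library=False):
        w = f0 * np.exp2((slopes + g) * t)
        if rna_library:
            w = np.where(in_window, w * np.exp2(rna_eff), 0.0)
        w = w / w.sum() * (1.0 - wt_frac - invalid_fraction)
        return np.concatenate([w, [wt_frac, invalid_fraction]])

    columns, totals = {}, {}

    def add_library(key, depth, probs, sub):
        rng = np.random.default_rng(sub)
        drawn = draw(rng, depth, probs)
        var_counts, wt, _inv = drawn[:-2], drawn[-2], drawn[-1]
        columns[key] = dict(zip(ids, (int(c) for c in var_counts)))
        totals[key] = (depth, int(var_counts.sum()), int(wt))

    subs = iter(ss.spawn(2 + 3 * n_rep * max(1, len(timepoints))))

    add_library(("library", 0), _depth_for(design, "library"),
                variant_probs(0), next(subs))
    for t in timepoints:
        if t == 0:
            continue
        st = f"day{t}_dna"
        for r in range(n_rep):
            add_library((st, r), _depth_for(design, st),
                        variant_probs(t), next(subs))
    if rna:
        for r in range(n_rep):
            add_library(("day5_rna", r), _depth_for(design, "day5_rna"),
                        variant_probs(5, rna_library=True), next(subs))
    # negative control: untransfected cells, almost no valid reads
    nc_depth = _depth_for(design, "negative_control")
    w = f0 / f0.sum() * negative_control_valid_fraction
    nc_probs = np.concatenate(
        [w, [1.0 - negative_control_valid_fraction - invalid_fraction,
             invalid_fraction]])
    add_library(("negative_control", 0), nc_depth, nc_probs, next(subs))

    table = CountTable.from_columns(columns, totals)
    # preserve variant order
    table.counts = table.counts.loc[ids]
    return table


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _variant_read(target: TargetSpec, v: VariantDef) -> str:
    ref = target.edited_ref_seq
    if v.vtype == "snv":
        return ref[:v.pos] + v.alt_allele + ref[v.pos + 1:]
    return ref[:v.pos] + ref[v.pos + 3:]


def _apply_errors(read: str, rng, error_rate: float) -> str:
    k = rng.binomial(len(read), error_rate)
    if k == 0:
        return read
    positions = rng.choice(len(read), size=k, replace=False)
    seq = list(read)
    for p in positions:
        if seq[p] in "ACGT":
            seq[p] = "ACGT"[(("ACGT".index(seq[p]) + rng.integers(1, 4)) % 4)]
    return "".join(seq)


def _apply_slips(read: str, rng, slip_rate: float) -> str:
    from .targets import homopolymer_runs
    runs = homopolymer_runs(read)
    if not runs:
        return read
    out, shift = read, 0
    for start, length in runs:
        if rng.random() >= slip_rate:
            continue
        delta = int(rng.choice([-2, -1, 1, 2], p=[0.05, 0.45, 0.45, 0.05]))
        delta = max(delta, 1 - length)
        s = start + shift
        base = out[s]
        out = out[:s] + base * (length + delta) + out[s + length:]
        shift += delta
    return out


def emit_reads(
    target: TargetSpec,
    counts: CountTable,
    variants: list[VariantDef],
    error_rate: float = 0.0,
    homopolymer_slip_rate: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, int], list[str]]:
    """Turn a count table back into per-library read sequences.

    Each variant count becomes one read of the variant-modified edited
    reference; wild-type totals become unedited reference reads; the
    remainder (received - valid - wildtype) becomes unambiguously invalid
    reads (containing N).  Sequencing errors are injected i.i.d. per base
    and homopolymer slippage changes a run length by +/-1 or +/-2.
    With both rates at zero the reads round-trip exactly through the
    variant caller.
    """
    if not (0 <= error_rate <= 1 and 0 <= homopolymer_slip_rate <= 1):
        raise ValueError("error rates must lie in [0, 1]")
    templates = {v.variant_id: _variant_read(target, v) for v in variants}
    invalid_read = ("N" * len(target.edited_ref_seq))
    ss = np.random.SeedSequence([seed, 911])
    out: dict[tuple[str, int], list[str]] = {}
    for key, sub in zip(counts.library_keys, ss.spawn(len(counts.library_keys))):
        rng = np.random.default_rng(sub)
        reads: list[str] = []
        col = counts.counts[key]
        for vid, c in col.items():
            if c > 0:
                reads.extend([templates[vid]] * int(c))
        received, valid, wt = counts.totals.loc[
            key, ["total_reads_received", "total_valid_reads", "wildtype_reads"]]
        reads.extend([target.ref_seq] * int(wt))
        reads.extend([invalid_read] * max(0, int(received) - int(valid) - int(wt)))
        if homopolymer_slip_rate > 0:
            reads = [_apply_slips(r, rng, homopolymer_slip_rate) for r in reads]
        if error_rate > 0:
            reads = [_apply_errors(r, rng, error_rate) for r in reads]
        rng.shuffle(reads)
        out[key] = reads
    return out


def write_fastq(reads: list[str], path, prefix: str = "read",
                quality: str = "I") -> None:
    """Write reads as Phred-33 FASTQ with a fixed quality character."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{quality * len(seq)}\n")


# ---------------------------------------------------------------------------
# truth sets and cohorts
# ---------------------------------------------------------------------------

def simulate_truth_labels(
    n_path: int,
    n_benign: int,
    p_abnormal_given_path: float,
    p_abnormal_given_benign: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled clinical truth variants with simulated assay classes.

    Each of ``n_path`` pathogenic and ``n_benign`` benign variants is
    assigned a functionally-abnormal class by an independent Bernoulli draw
    with the class-conditional probability given.
    """
    if n_path <= 0 or n_benign <= 0:
        raise ValueError("truth set sizes must be positive")
    for p in (p_abnormal_given_path, p_abnormal_given_benign):
        if not 0 <= p <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_path):
        abn = rng.random() < p_abnormal_given_path
        rows.append((f"path_{i}", "pathogenic_or_LP",
                     "functionally_abnormal" if abn else "functionally_normal"))
    for i in range(n_benign):
        abn = rng.random() < p_abnormal_given_benign
        rows.append((f"benign_{i}", "benign_or_LB",
                     "functionally_abnormal" if abn else "functionally_normal"))
    return pd.DataFrame(rows, columns=["variant_id", "clinical_label",
                                       "functional_class"])


def simulate_cohort(
    n_case: int,
    n_control: int,
    carrier_freq_control: float,
    odds_ratio: float,
    seed: int = 0,
) -> ContingencyTable:
    """Case-control carrier counts under a given odds ratio.

    The case carrier probability solves
    ``p_case / (1 - p_case) = OR * p_ctl / (1 - p_ctl)``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < carrier_freq_control < 1:
        raise ValueError("carrier frequency must lie in (0, 1)")
    odds = odds_ratio * carrier_freq_control / (1 - carrier_freq_control)
    p_case = odds / (1 + odds)
    rng = np.random.default_rng(seed)
    a = int(rng.binomial(n_case, p_case))
    c = int(rng.binomial(n_control, carrier_freq_control))
    return ContingencyTable(a=a, b=n_case - a, c=c, d=n_control - c)


def expected_case_carrier_freq(carrier_freq_control: float,
                               odds_ratio: float) -> float:
    odds = odds_ratio * carrier_freq_control / (1 - carrier_freq_control)
    return odds / (1 + odds)
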