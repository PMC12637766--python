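# Methods

## Read validity and variant calling

A merged read is compared with the *edited reference* (the target sequence
with all fixed edits applied). The rules, applied in order:

1. reads containing `N` are invalid; a read identical to the unedited
   reference is *unedited wild-type* (an uncut/un-repaired allele);
2. expected length, all fixed edits present, zero additional mismatches in
   the edited region → *HDR wild-type*; exactly one → a valid SNV call
   (the mismatch is the programmed edit); two or more → invalid.
   Mismatches outside the edited region are tolerated but a mismatch at a
   fixed-edit position always invalidates the read;
3. a read three bases short is matched exactly against every programmed
   3-bp-deletion molecule (fixed edits removed by the deletion are waived
   with it). If no exact match exists, the read is globally aligned
   (edlib) and must show a single left-aligned 3-bp gap at a programmed
   position with no edited-region substitutions — a deletion plus a
   region mismatch is discarded; flank mismatches are tolerated;
4. for targets containing homopolymer runs of ≥ 4 nt, a change of up to
   two in a sequenced run length is permitted: run lengths are restored
   to their expected values (alignment-guided) and the read re-enters the
   exact-comparison path. Runs shorter than 4 nt get no allowance.

Deletions starting at different positions inside a repeat produce the same
molecule. Programmed deletions are therefore enumerated as *unique
molecules*, keyed by their leftmost equivalent start (the convention used
for indel left-alignment); molecules whose leftmost start falls outside
the edited region are indistinguishable from non-programmed deletions and
are excluded from the design. This makes read→count round trips exact: for
a repeat-free region of L nt there are exactly L−2 deletions, fewer
otherwise.

Frequencies divide each variant count by the library's total valid reads
(valid SNV + deletion reads). Variants with fewer than 10 raw counts in
the plasmid library **or any DNA replicate/timepoint library** are
excluded, as are variants at known cell-line-variant positions. RNA and
negative-control libraries are not subject to the min-count filter — RNA
depletion is signal, and the negative control is empty by design. The
editing rate is (valid SNV + deletion reads) / total reads received.

## Quality control

Gates, each inclusive on the passing side and configurable in
`QcThresholds`: plasmid library ≥ 500,000 merged reads, ≥ 30% valid,
≤ 10% wild-type; negative control ≤ 1% valid; each day-5/day-13 replicate
≥ 150,000 valid reads; ≥ 2 valid replicates per timepoint; minimum
pairwise Pearson correlation between replicate frequency vectors ≥ 0.5.
Correlation is computed on raw frequencies of shared variants (a
`log10(f + 1e-7)` option exists because raw frequencies are heavy-tailed).
The QC verdict is a pure function of the count table.

## Scoring

Per replicate, day-5 log2 frequency ratios (vs the plasmid library) are
smoothed against genomic position with LOESS — local linear, tricube
weights, span 0.20 (fraction of fit-subset points), no robustness
iterations, via `statsmodels.lowess` with `xvals` evaluation so excluded
variants still receive a fitted value. The fit uses only variants whose
day-5 frequency is at least half their starting frequency (equivalently,
day-5 ratio ≥ −1); with fewer than 10 eligible variants smoothing is
skipped (fits = 0) with a warning. Each replicate's fit is subtracted from
its day-5 ratios and its cognate day-13 ratios.

The functional score is the OLS slope (free intercept,
`scipy.stats.linregress`) of adjusted ratio vs day over
{(0, 0), (5, r̃₅), (13, r̃₁₃)} per replicate; the (0, 0) anchor appears once
per replicate (and per target, when two adjacent targets cover the same
variant and their points are pooled into one regression), so replicate
count weights the fit. Fewer than 4 points → no score. The slope standard
error is reported.

A pseudocount of 0.5 is added to every raw count before any frequency that
enters a log ratio, keeping fully depleted variants finite; raw counts are
used for the min-count filter and QC. Score scale-invariance under count
rescaling is exact without the pseudocount and holds to numerical noise
with it at realistic depths.

RNA scores: per replicate, log2(f_RNA / f_DNA) where day-5 DNA frequencies
are first renormalized over the variants inside the RNA amplicon window;
the final score is the median across replicates, and the mean of the two
per-target scores for variants covered by two targets.

### Score identifiability

Frequencies are compositional: scores measure depletion *relative to the
library bulk*, and the LOESS correction centers each replicate's day-5
ratios on the local mean. When most of the library is neutral — the
regime a real essential-gene screen is in, and the default regime of the
synthetic generator — the bulk is an absolute anchor and slope estimates
are unbiased (the all-neutral null recovers zero slopes within two
standard errors). When *every* variant depletes, the common offset is
unidentifiable: in the uniform-depletion benchmark (slopes U[−0.3, 0])
rank recovery stays excellent (Spearman ≈ 0.97) but estimates share a
constant upward shift of ≈ +0.12 log2/day ≈ the mean depletion plus the
renormalization drift. This is a property of relative-abundance scoring
itself, not of the implementation, and no correction is attempted.

## Functional classification

A two-component univariate Gaussian mixture is EM-fit
(`sklearn.GaussianMixture`, tol 1e-6, ≤ 500 iterations) to SNV scores.
Initialization: means from the anchors — the mean of the 2.5–97.5
percentile-trimmed synonymous + intronic scores, and the mean of nonsense
scores outside exons where nonsense variants escape selection (defaults
1, 4, 11: alternative translation initiation near the 5′ end, in-frame
rescue, C-terminal position) — weights 0.5/0.5, variances from the anchor
subsets (the anchors pin only the means; these starts make EM
deterministic). The lesser-mean component is *functionally abnormal*.
Posterior > 0.95 assigns a component's label, otherwise *indeterminate*.
Score thresholds are the observed scores whose posteriors are closest to
the 0.95 cutoffs; they classify 3-bp deletions without refitting. SNVs
keep posterior-based labels even where unequal variances make far-tail
posteriors disagree with the thresholds; thresholds serve deletions and
reporting.

RNA classes: μ and σ are computed from the bottom 97.5% (top 2.5%
discarded) of nonsense RNA scores outside exons 1, 2 and 11; a variant has
*normal* RNA abundance iff its RNA score ≥ μ + σ (boundary inclusive).

## Clinical calibration

OddsPath = [P2·(1−P1)] / [(1−P2)·P1], with the prior P1 the pathogenic
fraction of the **whole** truth set and P2 the pathogenic fraction within
an assay class; indeterminate-class variants drop out of the class cells
only. (With the published BARD1 composition — 186 P/LP and 959 B/LB,
abnormal cell 184 P / 3 B, normal cell 1 P / 956 B, one pathogenic variant
indeterminate — this gives exactly 316.23 = 184·959/(3·186) for the
pathogenic direction and 0.0054 for the benign one; computing the prior
after dropping the indeterminate variant would give 317.9.) A zero cell is
continuity-adjusted by one counter-example and flagged. Evidence strength
follows the OddsPath bands (> 2.08/4.3/18.7/350 → supporting/moderate/
strong/very strong; reciprocals with negative points on the benign side),
points are summed per variant and classified with the points bands
≥ 10 P, 6…9 LP, −1…5 VUS, −6…−2 LB (the −2 likely-benign floor is the
modified convention), ≤ −7 B. Indeterminate functional classes receive no
PS3/BS3 points. Other criteria (PP3, BP4, PM2_supporting, PVS1, …) are
consumed as precomputed input columns.

ROC/AUC is rank-based with ties averaged (lower score = more pathogenic by
default). Case-control odds ratios use the sample OR ad/bc with the
two-sided Fisher exact p and Woolf log-OR 95% CIs (0.5 continuity
correction on a zero cell, flagged; exact conditional CIs optional). Two
odds ratios are compared with a Z-test whose standard errors are recovered
from the CI widths on the log scale — the form available when only CIs are
published.

## Synthetic data

What the generator emulates: uneven plasmid-library composition
(symmetric Dirichlet, concentration 50); expected variant frequency at day
t ∝ f₀·2^((s+g(pos))·t), renormalized per library, with s the true fitness
slope and g a smooth Gaussian bump at the cut site (default amplitude
−0.08 log2/day, width 15 nt — a mild cut-site-proximity effect);
multinomial (or Dirichlet-multinomial for overdispersion) counts at fixed
per-library depth; wild-type reads at a configurable fraction (default 5%)
and a small invalid-read fraction (2%) so QC gates are exercised; RNA
counts with variant-specific log2 depletion inside the RNA window;
negative-control libraries with ~0.2% valid reads; reads with i.i.d.
substitution errors and per-run homopolymer slippage of ±1–2 nt; labeled
truth sets and case-control cohorts from exact binomial models.

Truth assignment is consequence-driven: nonsense/canonical-splice variants
are LoF with probability 0.99/0.94 (slope ~ N(−0.2, 0.03²)), missense and
splice-region with probability ~0.13, synonymous/intronic 0.005, everything
else neutral (slope ~ N(0, 0.01²)); transcript-destabilizing LoF variants
get RNA effects ~ N(−2.2, 0.5²). These rates mirror the class structure a
real essential-gene SGE screen reports, so a full synthetic gene reproduces
its qualitative score distribution.

What it does **not** emulate — hence what passing tests do not show about
real data: PCR jackpotting and UMI-less duplicate structure, paired-end
read artifacts, guide-dependent editing-efficiency differences (real valid
fractions are 10–40%, not ~90%), position-dependent error profiles,
alternative splice isoforms in RNA, cell-line copy-number or trans
effects, and the curation noise of real clinical truth sets. The annotator
is a deliberately simple codon-translation scheme on a synthetic reading
frame, not VEP.

## Problem sizes and numerics

The analysis drivers and acceptance script use an 8-target synthetic gene
(~160 nt per target: 3,360 SNVs and ~820 unique deletions, triplicate
libraries at 0.25–0.6 M reads), a 300-variant uniform-depletion recovery
benchmark at depth 2×10⁵, and n = 2,000 mixture-recovery draws — sizes at
which every check is sharp while the whole suite runs in well under a
minute. All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning, one stream per library. Degenerate
inputs are handled explicitly: empty reads and non-DNA characters are
rejected, zero-valid-read libraries error at frequency computation,
sub-minimum smoothing subsets skip the LOESS, under-anchored mixture or
RNA calibrations raise, single-population mixtures are flagged degenerate,
and zero contingency cells are continuity-corrected and flagged.

## Known limitations

Double-mutant libraries are scored with the same OLS scorer rather than a
negative-binomial count model; overlapping-target pooling assumes both
targets share the variant's true slope; the LOESS span is fixed per
replicate rather than cross-validated; OddsPath is a point estimate (no
bootstrap interval); and absolute score levels are only interpretable
against a mostly-neutral library (see *Score identifiability*).
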