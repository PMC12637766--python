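"""Read-level variant calling for SGE amplicon data.

Merged, orientation-normalized reads are classified against a target's
edited reference.  A read is a *valid* variant observation when it has the
expected length, carries every fixed edit, and differs from the edited
reference by exactly one additional mismatch inside the edited region (SNV)
or by a single programmed 3-bp deletion with no edited-region mismatches.
Mismatches outside the edited region are tolerated.  For targets containing
homopolymer runs of at least four nucleotides, a change in sequenced
homopolymer length of up to two bases is permitted before the length test.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .targets import TargetSpec, VariantDef

SAMPLE_TYPES = ("library", "day5_dna", "day13_dna", "day5_rna", "negative_control")
CATEGORIES = ("valid_snv", "valid_del3", "hdr_wildtype", "unedited_wildtype", "invalid")

#: default sample types the min-count filter applies to ("the variant library
#: or any of the replicate and timepoint libraries")
MIN_COUNT_SAMPLE_TYPES = ("library", "day5_dna", "day13_dna")


@dataclass(frozen=True)
class ReadCall:
    category: str
    variant_id: str = ""
    n_mismatches_in_region: int = 0

    def __post_init__(self):
        if (self.variant_id != "") != (self.category in ("valid_snv", "valid_del3")):
            raise ValueError("variant_id set iff the call is a valid variant")


@dataclass
class CountTable:
    """Per-variant integer counts across sequencing libraries.

    ``counts``: DataFrame indexed by variant_id with a (sample_type,
    replicate) column MultiIndex.  ``totals``: DataFrame indexed the same
    way with columns total_reads_received, total_valid_reads,
    wildtype_reads.  "Valid" reads are usable variant observations
    (valid_snv + valid_del3); "wildtype" are unedited (reference) reads.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_keys(self) -> list[tuple[str, int]]:
        return list(self.counts.columns)

    def keys_of_type(self, sample_type: str) -> list[tuple[str, int]]:
        return [k for k in self.counts.columns if k[0] == sample_type]

    def total_valid(self, key) -> int:
        return int(self.totals.loc[key, "total_valid_reads"])

    @staticmethod
    def from_columns(columns: dict, totals: dict) -> "CountTable":
        """Build from {library_key: {variant_id: count}} and
        {library_key: (received, valid, wildtype)}."""
        counts = pd.DataFrame(columns).fillna(0).astype(int)
        counts.columns = pd.MultiIndex.from_tuples(counts.columns,
                                                   names=["sample_type", "replicate"])
        tot = pd.DataFrame.from_dict(
            {k: dict(zip(("total_reads_received", "total_valid_reads",
                          "wildtype_reads"), v)) for k, v in totals.items()},
            orient="index")
        tot.index = pd.MultiIndex.from_tuples(tot.index,
                                              names=["sample_type", "replicate"])
        return CountTable(counts=counts, totals=tot)


@dataclass
class FrequencyTable:
    """Filtered per-variant frequencies (count / total valid reads).

    Retains the raw counts and totals so downstream scoring can apply its
    own pseudocount policy.  ``excluded_variants`` records variants dropped
    by the min-count filter or because they fall on a known cell-line
    variant position.
    """

    counts: pd.DataFrame
    totals: pd.DataFrame
    frequencies: pd.DataFrame
    excluded_variants: list[tuple[str, str]] = field(default_factory=list)

    def total_valid(self, key) -> int:
        return int(self.totals.loc[key, "total_valid_reads"])


# ---------------------------------------------------------------------------
# read classification
# ---------------------------------------------------------------------------

def _hamming_call(read: str, target: TargetSpec) -> ReadCall:
    """Classify an expected-length read by direct comparison with the
    edited reference."""
    ref = target.edited_ref_seq
    lo, hi = target.edited_region
    fixed_positions = {p for p, _r, _a in target.fixed_edits}
    region_subs = 0
    snv = None
    for i, (a, b) in enumerate(zip(read, ref)):
        if a == b:
            continue
        if i in fixed_positions:
            return ReadCall("invalid")  # fixed edit absent or altered
        if lo <= i < hi:
            region_subs += 1
            snv = (i, a)
    if region_subs == 0:
        return ReadCall("hdr_wildtype")
    if region_subs == 1:
        return ReadCall("valid_snv", target.snv_id(*snv),
                        n_mismatches_in_region=1)
    return ReadCall("invalid", n_mismatches_in_region=region_subs)


def _deletion_call(read: str, target: TargetSpec) -> ReadCall:
    """Classify a read three bases short of expected length.

    Fast path: exact candidate-template match (all fixed edits present
    except those the deletion removed, no other difference anywhere).
    Otherwise the read is aligned and must show a single left-aligned
    3-bp gap at a programmed position; substitutions inside the edited
    region (or at a surviving fixed-edit position) discard the read,
    substitutions outside it are tolerated.
    """
    templates = target.del3_templates()
    hit = templates.get(read)
    if hit is not None:  # exact molecule, leftmost-canonical by construction
        return ReadCall("valid_del3", hit[1])

    ref = target.edited_ref_seq
    aln = edlib.align(read, ref, task="path", mode="NW")
    subs, dels, ins = [], [], []
    ri = qi = 0
    for n, op in _parse_cigar(aln["cigar"]):
        if op == "=":
            ri += n; qi += n
        elif op == "X":
            subs.extend(range(ri, ri + n))
            ri += n; qi += n
        elif op == "D":
            dels.append((ri, n))
            ri += n
        else:
            ins.append((ri, n))
            qi += n
    if ins or len(dels) != 1 or dels[0][1] != 3:
        return ReadCall("invalid")
    start = target.left_align_deletion(dels[0][0])
    hit = templates.get(ref[:start] + ref[start + 3:])
    if hit is None:
        return ReadCall("invalid")  # gap does not match a programmed deletion
    lo, hi = target.edited_region
    fixed_positions = {p for p, _r, _a in target.fixed_edits}
    deleted = range(start, start + 3)
    region_subs = 0
    for p in subs:
        if p in fixed_positions and p not in deleted:
            return ReadCall("invalid")
        if lo <= p < hi:
            region_subs += 1
    if region_subs:
        # a programmed deletion plus an edited-region mismatch is discarded
        return ReadCall("invalid", n_mismatches_in_region=region_subs)
    return ReadCall("valid_del3", hit[1])


def _parse_cigar(cigar: str):
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _is_homopolymer_slip(target: TargetSpec, kind: str, pos: int, payload,
                         max_delta: int = 2) -> bool:
    """Whether an indel is a length change <= ``max_delta`` of a
    homopolymer run (>= 4 nt) of the edited reference."""
    ref = target.edited_ref_seq
    if kind == "del":
        length = payload
        if length > max_delta:
            return False
        bases = ref[pos:pos + length]
        if len(set(bases)) != 1:
            return False
        base = bases[0]
        return any(s <= pos and pos + length <= s + L and ref[s] == base
                   for s, L in target.homopolymer_runs)
    else:  # insertion of `payload` (bases) before ref position `pos`
        bases = payload
        if len(bases) > max_delta or len(set(bases)) != 1:
            return False
        base = bases[0]
        return any(s <= pos <= s + L and ref[s] == base
                   for s, L in target.homopolymer_runs)


def _undo_slips(read: str, target: TargetSpec, max_delta: int) -> str | None:
    """Restore expected homopolymer run lengths in a read.

    Aligns the read to the edited reference, identifies indels that are
    length changes (<= ``max_delta``) of a homopolymer run, and rebuilds
    the read with those runs at their expected length; all other
    differences (substitutions, structural indels) are preserved.  Returns
    None when no slip is found.
    """
    if not target.homopolymer_runs:
        return None
    ref = target.edited_ref_seq
    aln = edlib.align(read, ref, task="path", mode="NW")
    out = []
    ri = qi = 0
    changed = False
    for n, op in _parse_cigar(aln["cigar"]):
        if op in "=X":
            out.append(read[qi:qi + n])
            ri += n; qi += n
        elif op == "D":  # bases of ref absent from read
            if _is_homopolymer_slip(target, "del", ri, n, max_delta):
                out.append(ref[ri:ri + n])  # reinsert the slipped bases
                changed = True
            ri += n
        elif op == "I":  # extra read bases
            if not _is_homopolymer_slip(target, "ins", ri,
                                        read[qi:qi + n], max_delta):
                out.append(read[qi:qi + n])
            else:
                changed = True
            qi += n
    return "".join(out) if changed else None


def classify_read(read: str, target: TargetSpec,
                  max_homopolymer_delta: int = 2) -> ReadCall:
    """Classify one merged read against the target's validity rules."""
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    if any(ch not in "ACGTN" for ch in read):
        raise ValueError("read must be A/C/G/T/N text")
    if "N" in read:
        return ReadCall("invalid")
    if read == target.ref_seq:
        return ReadCall("unedited_wildtype")
    return _classify_core(read, target, max_homopolymer_delta)


def _classify_core(read: str, target: TargetSpec, max_delta: int) -> ReadCall:
    diff = len(read) - target.expected_length
    if diff == 0:
        return _hamming_call(read, target)
    if diff == -3:
        call = _deletion_call(read, target)
        if call.category == "valid_del3":
            return call
    else:
        call = ReadCall("invalid")
    if max_delta > 0:
        normalized = _undo_slips(read, target, max_delta)
        if normalized is not None and len(normalized) != len(read):
            return _classify_core(normalized, target, 0)
    return call


def match_deletion(read: str, target: TargetSpec) -> str | None:
    """Identify a programmed 3-bp deletion by candidate-template matching.

    Compares the read against the edited reference with each programmed
    deletion applied (fixed edits overlapped by the deletion are removed
    with it, i.e. waived).  Ties arising inside repeats resolve to the
    leftmost deletion start.  Returns the variant_id or None.
    """
    hit = target.del3_templates().get(read)
    return hit[1] if hit is not None else None


# ---------------------------------------------------------------------------
# counting and frequencies
# ---------------------------------------------------------------------------

def _iter_sequences(reads):
    if isinstance(reads, (str, os.PathLike)):
        from Bio import SeqIO
        with open(reads) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
        return
    for r in reads:
        yield r if isinstance(r, str) else str(r.seq)


def count_variants(reads, target: TargetSpec,
                   library_key: tuple[str, int] = ("library", 0),
                   max_homopolymer_delta: int = 2):
    """Count programmed variants in one library's reads.

    Returns ``(CountTable, metrics)`` with a single library column.
    ``metrics`` records per-category read counts and the editing rate
    (usable SNV + deletion reads over total reads received).
    """
    counts: dict[str, int] = {}
    cat = dict.fromkeys(CATEGORIES, 0)
    total = 0
    for seq in _iter_sequences(reads):
        total += 1
        call = classify_read(seq, target, max_homopolymer_delta)
        cat[call.category] += 1
        if call.variant_id:
            counts[call.variant_id] = counts.get(call.variant_id, 0) + 1
    n_valid = cat["valid_snv"] + cat["valid_del3"]
    metrics = {
        "total_reads_received": total,
        "total_valid_reads": n_valid,
        "editing_rate": n_valid / total if total else float("nan"),
        "category_counts": cat,
    }
    if total == 0:
        metrics["error"] = "zero reads"
    table = CountTable.from_columns(
        {library_key: counts},
        {library_key: (total, n_valid, cat["unedited_wildtype"])})
    return table, metrics


def compute_frequencies(
    counts: CountTable,
    target: TargetSpec,
    variants: list[VariantDef] | None = None,
    min_count: int = 10,
    min_count_sample_types: tuple[str, ...] = MIN_COUNT_SAMPLE_TYPES,
) -> FrequencyTable:
    """Convert counts to frequencies and apply the variant filters.

    A variant is excluded when its raw count falls below ``min_count`` in
    the plasmid library or any replicate/timepoint library of the types in
    ``min_count_sample_types``, or when it sits on a known cell-line
    variant position of the target.
    """
    totals = counts.totals
    if (totals["total_valid_reads"] <= 0).any():
        bad = totals.index[totals["total_valid_reads"] <= 0].tolist()
        raise ValueError(f"libraries with zero valid reads: {bad}")

    df = counts.counts
    excluded: list[tuple[str, str]] = []

    pos_by_id = {}
    if variants is not None:
        pos_by_id = {v.variant_id: v.pos for v in variants}

    filter_cols = [k for k in df.columns if k[0] in min_count_sample_types]
    keep = []
    for vid in df.index:
        pos = pos_by_id.get(vid)
        if pos is not None and pos in target.excluded_positions:
            excluded.append((vid, "cell_line_position"))
            continue
        if filter_cols and (df.loc[vid, filter_cols] < min_count).any():
            excluded.append((vid, "min_count"))
            continue
        keep.append(vid)

    kept = df.loc[keep]
    freqs = kept.div(totals["total_valid_reads"], axis=1)
    return FrequencyTable(counts=kept, totals=totals.copy(), frequencies=freqs,
                          excluded_variants=excluded)
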