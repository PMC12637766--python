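"""Read classification, counting and frequency filtering.

The reference oracle enumerates every single-substitution and every unique
single-3-bp-deletion molecule of the edited reference and tests exact
string equality (no homopolymer allowance), fully independent of the
alignment-based caller.
"""
import numpy as np
import pandas as pd
import pytest

from sgescore import (classify_read, compute_frequencies, count_variants,
                      enumerate_variants, match_deletion)
from sgescore.targets import TargetSpec

from conftest import make_count_table


def oracle_classify(read: str, target: TargetSpec):
    """Brute-force enumeration oracle: (category, variant_id)."""
    ed = target.edited_ref_seq
    lo, hi = target.edited_region
    fixed = {p for p, _r, _a in target.fixed_edits}
    if "N" in read:
        return "invalid", ""
    if read == target.ref_seq:
        return "unedited_wildtype", ""
    if read == ed:
        return "hdr_wildtype", ""
    for i in range(len(ed)):
        for b in "ACGT":
            if b == ed[i]:
                continue
            if read == ed[:i] + b + ed[i + 1:]:
                if i in fixed:
                    return "invalid", ""
                if lo <= i < hi:
                    return "valid_snv", target.snv_id(i, b)
                return "hdr_wildtype", ""
    matches = [s for s in range(len(ed) - 2) if read == ed[:s] + ed[s + 3:]]
    if matches:
        s0 = min(matches)  # indels left-align: leftmost equivalent start
        if lo <= s0 and s0 + 3 <= hi:
            return "valid_del3", target.del3_id(s0)
    return "invalid", ""


def _random_read(rng, target):
    """A read drawn from a mixture of valid, wild-type and corrupt shapes."""
    ed = target.edited_ref_seq
    lo, hi = target.edited_region
    kind = rng.integers(0, 10)
    if kind == 0:
        return target.ref_seq
    if kind == 1:
        return ed
    pos = int(rng.integers(lo, hi))
    alt = "ACGT"[int(rng.integers(0, 4))]
    if kind in (2, 3):  # single substitution somewhere
        pos = int(rng.integers(0, len(ed)))
        return ed[:pos] + alt + ed[pos + 1:]
    if kind == 4:  # two region substitutions
        p2 = int(rng.integers(lo, hi))
        r = ed[:pos] + alt + ed[pos + 1:]
        return r[:p2] + "ACGT"[int(rng.integers(0, 4))] + r[p2 + 1:]
    if kind in (5, 6):  # 3-bp deletion at an arbitrary start
        s = int(rng.integers(0, len(ed) - 3))
        return ed[:s] + ed[s + 3:]
    if kind == 7:  # deletion plus an edited-region substitution
        s = int(rng.integers(lo, hi - 3))
        r = ed[:s] + ed[s + 3:]
        q = int(rng.integers(lo, hi - 3))  # region position surviving the del
        if s <= q < s + 3:
            q += 3
        p = q if q < s else q - 3
        return r[:p] + alt + r[p + 1:]
    if kind == 8:  # arbitrary indel of length 1-4
        s = int(rng.integers(0, len(ed)))
        k = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            return ed[:s] + ed[s + k:]
        return ed[:s] + "".join(rng.choice(list("ACGT"), k)) + ed[s:]
    r = list(ed)  # read with an N
    r[int(rng.integers(0, len(ed)))] = "N"
    return "".join(r)


@pytest.mark.parametrize("target_fixture", ["periodic_target", "random_target"])
def test_classifier_agrees_with_enumeration_oracle(target_fixture, request, rng):
    target = request.getfixturevalue(target_fixture)
    for _ in range(600):
        read = _random_read(rng, target)
        got = classify_read(read, target, max_homopolymer_delta=0)
        want = oracle_classify(read, target)
        assert (got.category, got.variant_id) == want, read


def test_valid_snv_and_tolerated_outside_mismatch(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    read = ed[:50] + ("A" if ed[50] != "A" else "C") + ed[51:]
    call = classify_read(read, t)
    assert call.category == "valid_snv"
    assert call.variant_id == t.snv_id(50, read[50])
    # an extra mismatch outside the edited region is tolerated
    outside = 2
    assert outside not in {p for p, _r, _a in t.fixed_edits}
    read2 = read[:outside] + ("T" if read[outside] != "T" else "G") + read[outside + 1:]
    call2 = classify_read(read2, t)
    assert (call2.category, call2.variant_id) == ("valid_snv", call.variant_id)


def test_read_missing_fixed_edit_is_invalid(periodic_target):
    t = periodic_target
    pos, ref, _alt = t.fixed_edits[0]
    read = t.edited_ref_seq[:pos] + ref + t.edited_ref_seq[pos + 1:]
    assert classify_read(read, t).category == "invalid"


def test_two_region_mismatches_invalid(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    read = ed[:50] + ("A" if ed[50] != "A" else "C") + ed[51:]
    read = read[:80] + ("A" if ed[80] != "A" else "C") + read[81:]
    call = classify_read(read, t)
    assert call.category == "invalid"
    assert call.n_mismatches_in_region == 2


def test_monotone_safety_second_mismatch(periodic_target, rng):
    """Adding a second edited-region mismatch to any valid SNV read always
    yields an invalid call."""
    t = periodic_target
    ed = t.edited_ref_seq
    lo, hi = t.edited_region
    for _ in range(100):
        p1, p2 = rng.choice(np.arange(lo, hi), size=2, replace=False)
        p1, p2 = int(p1), int(p2)
        a1 = "ACGT"[(("ACGT".index(ed[p1]) + 1) % 4)]
        read = ed[:p1] + a1 + ed[p1 + 1:]
        assert classify_read(read, t).category == "valid_snv"
        a2 = "ACGT"[(("ACGT".index(ed[p2]) + 1) % 4)]
        read2 = read[:p2] + a2 + read[p2 + 1:]
        assert classify_read(read2, t).category == "invalid"


def test_homopolymer_slip_tolerance(homopolymer_target):
    t = homopolymer_target
    ed = t.edited_ref_seq
    (start, length), = [r for r in t.homopolymer_runs if r[1] >= 5]
    pos = 100  # SNV far from the run
    alt = "A" if ed[pos] != "A" else "C"
    read = ed[:pos] + alt + ed[pos + 1:]
    for delta in (-2, -1, 1, 2):
        if delta < 0:
            slipped = read[:start] + read[start - delta:]
        else:
            slipped = read[:start] + read[start] * delta + read[start:]
        call = classify_read(slipped, t)
        assert call.category == "valid_snv", delta
        assert call.variant_id == t.snv_id(pos, alt)
    # a change of three is past the allowance
    over = read[:start] + read[start] * 3 + read[start:]
    assert classify_read(over, t).category == "invalid"
    # without the allowance the slipped read is invalid
    slipped = read[:start] + read[start + 1:]
    assert classify_read(slipped, t, max_homopolymer_delta=0).category == "invalid"


def test_slip_without_variant_is_hdr_wildtype(homopolymer_target):
    t = homopolymer_target
    (start, _length), = [r for r in t.homopolymer_runs if r[1] >= 5]
    read = t.edited_ref_seq[:start] + t.edited_ref_seq[start + 1:]
    assert classify_read(read, t).category == "hdr_wildtype"


def test_indel_outside_homopolymer_invalid(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    assert classify_read(ed[:60] + ed[61:], t).category == "invalid"
    assert classify_read(ed[:60] + "A" + ed[60:], t).category == "invalid"


def test_match_deletion(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    assert match_deletion(ed[:40] + ed[43:], t) == t.del3_id(40)
    # deletion start outside the edited region is not programmed
    assert match_deletion(ed[:2] + ed[5:], t) is None
    assert match_deletion(ed, t) is None


def test_match_deletion_leftmost_in_repeat(homopolymer_target):
    t = homopolymer_target
    ed = t.edited_ref_seq
    # deleting AAA at 41 equals deleting AAA at 40: leftmost id reported
    assert match_deletion(ed[:41] + ed[44:], t) == match_deletion(
        ed[:40] + ed[43:], t)
    assert match_deletion(ed[:40] + ed[43:], t) == t.del3_id(40)


def test_deletion_with_region_mismatch_discarded(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    read = ed[:40] + ed[43:]
    read = read[:90] + ("A" if read[90] != "A" else "C") + read[91:]
    assert classify_read(read, t).category == "invalid"


def test_deletion_with_outside_mismatch_tolerated(periodic_target):
    t = periodic_target
    ed = t.edited_ref_seq
    read = ed[:40] + ed[43:]
    read = read[:2] + ("A" if read[2] != "A" else "C") + read[3:]
    call = classify_read(read, t)
    assert (call.category, call.variant_id) == ("valid_del3", t.del3_id(40))


def test_empty_and_non_dna_reads(periodic_target):
    with pytest.raises(ValueError):
        classify_read("", periodic_target)
    with pytest.raises(ValueError):
        classify_read("ACGU", periodic_target)
    assert classify_read("N" * 140, periodic_target).category == "invalid"


def test_count_variants_conservation_and_editing_rate(periodic_target, rng):
    t = periodic_target
    variants = enumerate_variants(t)
    ed = t.edited_ref_seq
    reads = []
    for v in rng.choice(variants, size=300):
        if v.vtype == "snv":
            reads.append(ed[:v.pos] + v.alt_allele + ed[v.pos + 1:])
        else:
            reads.append(ed[:v.pos] + ed[v.pos + 3:])
    reads += [t.ref_seq] * 50 + [ed] * 30 + ["N" * 140] * 20
    table, metrics = count_variants(reads, t, ("library", 0))
    cats = metrics["category_counts"]
    assert sum(cats.values()) == metrics["total_reads_received"] == 400
    assert metrics["total_valid_reads"] == 300
    assert metrics["editing_rate"] == pytest.approx(300 / 400)
    assert table.counts[("library", 0)].sum() == 300
    assert table.totals.loc[("library", 0), "wildtype_reads"] == 50


def test_count_variants_zero_reads(periodic_target):
    table, metrics = count_variants([], periodic_target)
    assert metrics["error"] == "zero reads"
    assert table.counts.empty


def test_compute_frequencies_values_and_min_count(periodic_target):
    t = periodic_target
    v = enumerate_variants(t)
    ids = [x.variant_id for x in v[:3]]
    col = {ids[0]: 250, ids[1]: 9, ids[2]: 100}
    counts = make_count_table({("library", 0): col},
                              {("library", 0): (500_000, 500_000, 0)})
    ft = compute_frequencies(counts, t, v, min_count=10)
    assert ft.frequencies.loc[ids[0], ("library", 0)] == pytest.approx(5.0e-4)
    assert (ids[1], "min_count") in ft.excluded_variants
    assert ids[1] not in ft.counts.index
    # filter applies to any replicate/timepoint library too
    counts2 = make_count_table(
        {("library", 0): {ids[0]: 250}, ("day13_dna", 0): {ids[0]: 9}},
        {("library", 0): (500_000, 500_000, 0),
         ("day13_dna", 0): (400_000, 400_000, 0)})
    ft2 = compute_frequencies(counts2, t, v, min_count=10)
    assert (ids[0], "min_count") in ft2.excluded_variants


def test_compute_frequencies_cell_line_exclusion():
    t = TargetSpec("x", "ACGT" * 35, (10, 130), [(4, "A", "G")], cut_site=70,
                   excluded_positions={50})
    variants = enumerate_variants(t)
    at50 = next(v for v in variants if v.pos == 50 and v.vtype == "snv")
    other = next(v for v in variants if v.pos == 60 and v.vtype == "snv")
    counts = make_count_table(
        {("library", 0): {at50.variant_id: 500, other.variant_id: 500}},
        {("library", 0): (10_000, 10_000, 0)})
    ft = compute_frequencies(counts, t, variants)
    assert (at50.variant_id, "cell_line_position") in ft.excluded_variants
    assert other.variant_id in ft.counts.index


def test_compute_frequencies_zero_total_errors(periodic_target):
    counts = make_count_table({("library", 0): {"c.1A>C": 0}},
                              {("library", 0): (100, 0, 0)})
    with pytest.raises(ValueError):
        compute_frequencies(counts, periodic_target)
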