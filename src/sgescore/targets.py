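"""Target regions and programmed variants for saturation genome editing (SGE).

An SGE *target* is a short (~120-160 nt) stretch of genome into which every
possible single-nucleotide variant (SNV) and 3-bp deletion is introduced by
homology-directed repair.  Repair templates carry *fixed edits* -- synonymous
single-base substitutions that block Cas9 re-cutting and mark successfully
edited (HDR-derived) alleles; every valid read must carry them.  The *edited
region* is the interval actually saturated with programmed variants.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: molecular consequence labels (VEP-style, highest-impact only)
CONSEQUENCES = (
    "missense", "synonymous", "stop_gained", "canonical_splice",
    "splice_region", "intron", "start_lost", "stop_lost", "utr",
)


def homopolymer_runs(seq: str, min_len: int = 4) -> list[tuple[int, int]]:
    """Maximal single-base runs of ``seq`` with length >= ``min_len``.

    Returns a list of ``(start, length)`` pairs in 0-based coordinates.
    """
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


@dataclass
class TargetSpec:
    """One SGE target region.

    Coordinates are target-local, 0-based, half-open unless stated otherwise.
    ``ref_seq`` is the unedited genomic reference; ``edited_ref_seq`` (derived)
    is the reference with all fixed edits applied and is the template against
    which reads and programmed variants are defined.
    """

    target_id: str
    ref_seq: str
    edited_region: tuple[int, int]
    fixed_edits: list[tuple[int, str, str]]   # (pos, ref_base, alt_base)
    cut_site: int
    genomic_offset: int = 1                   # 1-based genomic coord of local 0
    exon_label: str = "1"
    excluded_positions: set[int] = field(default_factory=set)
    rna_window: tuple[int, int] | None = None
    coding_region: tuple[int, int] | None = None  # coding sub-interval (codon-aligned)
    c_offset: int = 1                         # HGVS c. position of coding_region[0]
    aa_offset: int = 1                        # protein position of first full codon
    domain: str = "none"

    def __post_init__(self):
        self.ref_seq = self.ref_seq.upper()
        n = len(self.ref_seq)
        start, stop = self.edited_region
        if not (0 <= start < stop <= n):
            raise ValueError(f"edited_region {self.edited_region} outside [0, {n})")
        if not (start <= self.cut_site < stop):
            raise ValueError("cut_site must lie inside the edited region")
        for pos, ref, alt in self.fixed_edits:
            if not (0 <= pos < n):
                raise ValueError(f"fixed edit position {pos} outside ref_seq")
            if self.ref_seq[pos] != ref:
                raise ValueError(f"fixed edit ref base mismatch at {pos}")
            if ref == alt:
                raise ValueError("fixed edit must change the base")
        if self.rna_window is None:
            self.rna_window = (start, stop)
        if self.coding_region is None:
            self.coding_region = (start, stop)
        seq = list(self.ref_seq)
        for pos, _ref, alt in self.fixed_edits:
            seq[pos] = alt
        self.edited_ref_seq = "".join(seq)
        self.homopolymer_runs = homopolymer_runs(self.edited_ref_seq)

    # -- coordinate helpers -------------------------------------------------

    @property
    def expected_length(self) -> int:
        return len(self.edited_ref_seq)

    def genomic_position(self, pos: int) -> int:
        return self.genomic_offset + pos

    def hgvs_c_position(self, pos: int) -> str:
        """HGVS-like c. coordinate string for a target-local position."""
        cs, ce = self.coding_region
        if cs <= pos < ce:
            return str(self.c_offset + (pos - cs))
        if pos < cs:
            return f"{self.c_offset}-{cs - pos}"
        return f"{self.c_offset + (ce - cs) - 1}+{pos - ce + 1}"

    def snv_id(self, pos: int, alt: str) -> str:
        return f"c.{self.hgvs_c_position(pos)}{self.edited_ref_seq[pos]}>{alt}"

    def del3_id(self, pos: int) -> str:
        return f"c.{self.hgvs_c_position(pos)}_{self.hgvs_c_position(pos + 2)}del"

    def left_align_deletion(self, start: int, length: int = 3) -> int:
        """Leftmost equivalent start of a deletion, shifted through repeats."""
        ref = self.edited_ref_seq
        while start > 0 and ref[start - 1] == ref[start + length - 1]:
            start -= 1
        return start

    def del3_templates(self) -> dict[str, tuple[int, str]]:
        """Unique, unambiguously programmed 3-bp deletion molecules.

        Deletions at different starts inside a repeat produce the same
        molecule; each unique template maps to ``(canonical_start,
        variant_id)``, the leftmost equivalent start.  Molecules whose
        leftmost equivalent start falls outside the edited region are
        indistinguishable from non-programmed deletions (indels left-align)
        and are excluded.  Cached.
        """
        cached = getattr(self, "_del3_templates", None)
        if cached is not None:
            return cached
        ref = self.edited_ref_seq
        start, stop = self.edited_region
        templates: dict[str, tuple[int, str]] = {}
        for pos in range(start, stop - 2):
            if self.left_align_deletion(pos) != pos:
                continue  # duplicate molecule, or left-aligns out of region
            tpl = ref[:pos] + ref[pos + 3:]
            templates[tpl] = (pos, self.del3_id(pos))
        self._del3_templates = templates
        return templates

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["excluded_positions"] = sorted(self.excluded_positions)
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TargetSpec":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        d["edited_region"] = tuple(d["edited_region"])
        d["fixed_edits"] = [tuple(e) for e in d["fixed_edits"]]
        d["excluded_positions"] = set(d["excluded_positions"])
        for key in ("rna_window", "coding_region"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class VariantDef:
    """A programmed variant (SNV or 3-bp deletion) within one target."""

    variant_id: str
    vtype: str                    # "snv" | "del3"
    pos: int                      # target-local 0-based (first deleted base for del3)
    ref_allele: str
    alt_allele: str
    consequence: str
    aa_change: str = ""
    domain: str = "none"
    exon_label: str = ""

    def __post_init__(self):
        if self.vtype == "snv":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("snv requires single-base alleles")
        elif self.vtype == "del3":
            if len(self.ref_allele) != 3 or self.alt_allele != "":
                raise ValueError("del3 requires 3-base ref and empty alt")
        else:
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


def _codon_at(target: TargetSpec, codon_idx: int) -> tuple[str, int]:
    """Codon string and its local start for the ``codon_idx``-th coding codon."""
    cs, _ce = target.coding_region
    start = cs + 3 * codon_idx
    return target.edited_ref_seq[start:start + 3], start


def annotate_snv(target: TargetSpec, pos: int, alt: str) -> tuple[str, str]:
    """Molecular consequence and amino-acid change for a programmed SNV.

    A deliberately simple annotator for synthetic targets: coding positions
    are translated codon-by-codon; the first two intronic bases flanking the
    coding interval are canonical splice sites, the next six are splice
    region, and anything further is plain intron.
    """
    cs, ce = target.coding_region
    if pos < cs or pos >= ce:
        dist = cs - pos if pos < cs else pos - ce + 1
        if dist <= 2:
            return "canonical_splice", ""
        if dist <= 8:
            return "splice_region", ""
        return "intron", ""
    codon_idx, offset = divmod(pos - cs, 3)
    codon, _start = _codon_at(target, codon_idx)
    if len(codon) < 3:
        return "splice_region", ""
    ref_aa = str(Seq(codon).translate())
    new_codon = codon[:offset] + alt + codon[offset + 1:]
    alt_aa = str(Seq(new_codon).translate())
    aa_pos = target.aa_offset + codon_idx
    aa_change = f"{ref_aa}{aa_pos}{alt_aa}"
    if ref_aa == alt_aa:
        return "synonymous", aa_change
    if alt_aa == "*":
        return "stop_gained", aa_change
    if ref_aa == "*":
        return "stop_lost", aa_change
    if ref_aa == "M" and codon_idx == 0 and target.aa_offset == 1:
        return "start_lost", aa_change
    return "missense", aa_change


def annotate_del3(target: TargetSpec, pos: int) -> tuple[str, str]:
    """Consequence for a programmed 3-bp deletion starting at ``pos``.

    In-frame coding deletions are reported with the highest-impact protein
    label available in the SNV vocabulary (missense-like amino-acid change);
    deletions touching splice positions take the splice label.
    """
    cs, ce = target.coding_region
    span = range(pos, pos + 3)
    dists = []
    for p in span:
        if p < cs:
            dists.append(cs - p)
        elif p >= ce:
            dists.append(p - ce + 1)
        else:
            dists.append(0)
    if all(d > 0 for d in dists):
        dmin = min(dists)
        if dmin <= 2:
            return "canonical_splice", ""
        if dmin <= 8:
            return "splice_region", ""
        return "intron", ""
    if any(0 < d <= 2 for d in dists):
        return "canonical_splice", ""
    first_codon = (max(pos, cs) - cs) // 3
    aa_pos = target.aa_offset + first_codon
    return "missense", f"del{aa_pos}"


def enumerate_variants(target: TargetSpec) -> list[VariantDef]:
    """All programmed variants of a target: 3 SNVs per edited-region base
    and one 3-bp deletion per *unique* deleted molecule.

    Deletions at different starts inside a repeat produce identical
    molecules and are indistinguishable in sequencing; they collapse to the
    leftmost start.  For a repeat-free edited region of L nt this yields
    exactly L - 2 deletions.
    """
    start, stop = target.edited_region
    variants = []
    for pos in range(start, stop):
        ref = target.edited_ref_seq[pos]
        for alt in BASES:
            if alt == ref:
                continue
            cons, aa = annotate_snv(target, pos, alt)
            variants.append(VariantDef(
                variant_id=target.snv_id(pos, alt), vtype="snv", pos=pos,
                ref_allele=ref, alt_allele=alt, consequence=cons,
                aa_change=aa, domain=target.domain, exon_label=target.exon_label,
            ))
    for pos, vid in sorted(target.del3_templates().values()):
        cons, aa = annotate_del3(target, pos)
        variants.append(VariantDef(
            variant_id=vid, vtype="del3", pos=pos,
            ref_allele=target.edited_ref_seq[pos:pos + 3], alt_allele="",
            consequence=cons, aa_change=aa, domain=target.domain,
            exon_label=target.exon_label,
        ))
    return variants


def generate_target(
    length: int,
    cut_site: int,
    n_fixed_edits: int,
    seed: int,
    *,
    flank: int = 10,
    intron_pad: int = 0,
    target_id: str | None = None,
    genomic_offset: int = 1_000_000,
    exon_label: str = "1",
    c_offset: int = 1,
    aa_offset: int = 1,
    domain: str = "none",
    n_excluded_positions: int = 0,
    rna_window: tuple[int, int] | None = None,
) -> TargetSpec:
    """Generate a random synthetic SGE target.

    The edited region is ``[flank, length - flank)``; within it, an optional
    ``intron_pad`` of intronic bases flanks a codon-aligned coding interval.
    Fixed edits are placed in the flanks, outside the edited region, so the
    identity of programmed variants is unambiguous.  Deterministic for a
    fixed seed.
    """
    if length < 30:
        raise ValueError("length must be >= 30")
    if n_fixed_edits < 1:
        raise ValueError("n_fixed_edits must be >= 1")
    if flank < 2 or length - 2 * flank < 6:
        raise ValueError("flanks leave no edited region")
    region = (flank, length - flank)
    if not (region[0] <= cut_site < region[1]):
        raise ValueError("cut_site must fall inside the edited region")
    rng = np.random.default_rng(seed)

    cs = region[0] + intron_pad
    ce = region[1] - intron_pad
    ce = cs + 3 * ((ce - cs) // 3)  # codon-aligned coding interval
    if ce <= cs:
        raise ValueError("intron_pad leaves no coding sequence")

    non_stop = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in STOP_CODONS]
    seq = list(rng.choice(list(BASES), size=length))
    codons = rng.choice(non_stop, size=(ce - cs) // 3)
    seq[cs:ce] = list("".join(codons))
    ref_seq = "".join(seq)

    flank_positions = [p for p in range(2, region[0]) if p < region[0]] + \
                      [p for p in range(region[1], length - 2)]
    if n_fixed_edits > len(flank_positions):
        raise ValueError("not enough flank positions for fixed edits")
    edit_pos = sorted(rng.choice(flank_positions, size=n_fixed_edits, replace=False))
    fixed_edits = []
    for pos in edit_pos:
        ref = ref_seq[pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        fixed_edits.append((int(pos), ref, alt))

    excluded = set()
    if n_excluded_positions > 0:
        excluded = set(int(p) for p in rng.choice(
            np.arange(region[0], region[1]), size=n_excluded_positions, replace=False))

    return TargetSpec(
        target_id=target_id or f"T{seed}",
        ref_seq=ref_seq,
        edited_region=region,
        fixed_edits=fixed_edits,
        cut_site=cut_site,
        genomic_offset=genomic_offset,
        exon_label=exon_label,
        excluded_positions=excluded,
        rna_window=rna_window,
        coding_region=(cs, ce),
        c_offset=c_offset,
        aa_offset=aa_offset,
        domain=domain,
    )
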