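import numpy as np
import pandas as pd
import pytest

from sgescore import CountTable, TargetSpec, enumerate_variants, generate_target


@pytest.fixture(scope="session")
def periodic_target():
    """Repeat-free 140-nt target ("ACGT" period 4): no homopolymer runs and
    no ambiguous 3-bp deletions, so counting identities are exact."""
    return TargetSpec(
        target_id="periodic",
        ref_seq="ACGT" * 35,
        edited_region=(10, 130),
        fixed_edits=[(4, "A", "G"), (134, "G", "T")],
        cut_site=70,
        coding_region=(22, 118),
        genomic_offset=5_000_000,
        exon_label="2",
    )


@pytest.fixture(scope="session")
def homopolymer_target():
    """Target carrying an AAAAA run inside the edited region."""
    seq = list("ACGT" * 35)
    seq[40:45] = "AAAAA"
    return TargetSpec(
        target_id="homopoly",
        ref_seq="".join(seq),
        edited_region=(10, 130),
        fixed_edits=[(4, "A", "G"), (134, "G", "T")],
        cut_site=70,
        coding_region=(22, 118),
        genomic_offset=6_000_000,
        exon_label="3",
    )


@pytest.fixture(scope="session")
def random_target():
    return generate_target(140, 70, 2, seed=7, intron_pad=12, exon_label="2")


@pytest.fixture(scope="session")
def random_variants(random_target):
    return enumerate_variants(random_target)


def make_count_table(per_library: dict, totals: dict | None = None) -> CountTable:
    """Build a CountTable from {library_key: {variant_id: count}}; totals
    default to (sum, sum, 0) per library."""
    if totals is None:
        totals = {k: (sum(v.values()), sum(v.values()), 0)
                  for k, v in per_library.items()}
    return CountTable.from_columns(per_library, totals)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
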