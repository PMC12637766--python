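"""Shared configuration for the analysis drivers.

Each driver regenerates the same deterministic synthetic experiment from
SEED, so the scripts can run independently and in any order; large
intermediates go to scratch/, small result tables to results/.
"""
from functools import lru_cache
from pathlib import Path

SEED = 11
ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


@lru_cache(maxsize=1)
def simulated_gene():
    from sgescore.workflows import simulate_gene
    return simulate_gene(seed=SEED, n_targets=8)


@lru_cache(maxsize=1)
def scored_gene():
    from sgescore.workflows import score_gene
    return score_gene(simulated_gene())


def outdirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH
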