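"""Library- and replicate-level quality control gates.

All thresholds are inclusive on the passing side ("at least", "no more
than", "no less than"), appear exactly once in :class:`QcThresholds`, and
are overridable.  The verdict is a pure function of the count table.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calling import CountTable


@dataclass(frozen=True)
class QcThresholds:
    min_library_reads: int = 500_000
    min_library_valid_fraction: float = 0.30
    max_library_wildtype_fraction: float = 0.10
    max_negative_control_valid_fraction: float = 0.01
    min_replicate_valid_reads: int = 150_000
    min_valid_replicates: int = 2
    min_pairwise_correlation: float = 0.5


@dataclass
class QcReport:
    libraries: pd.DataFrame          # per-library metrics and pass flags
    timepoints: dict                 # per timepoint: n_valid_replicates, min_pairwise_r, matrix
    target_pass: bool
    failure_reasons: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        d = {
            "target_pass": self.target_pass,
            "failure_reasons": self.failure_reasons,
            "libraries": self.libraries.reset_index()
            .astype(object).to_dict(orient="records"),
            "timepoints": {
                st: {"n_valid_replicates": int(v["n_valid_replicates"]),
                     "min_pairwise_r": (None if v["min_pairwise_r"] is None
                                        else float(v["min_pairwise_r"]))}
                for st, v in self.timepoints.items()},
        }
        text = json.dumps(d, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [f"target_pass: {self.target_pass}"]
        if self.failure_reasons:
            lines.append("failures: " + ", ".join(self.failure_reasons))
        for st, v in self.timepoints.items():
            lines.append(f"{st}: {v['n_valid_replicates']} valid replicates, "
                         f"min pairwise r = {v['min_pairwise_r']}")
        return "\n".join(lines)


def replicate_correlations(counts: CountTable, sample_type: str,
                           replicates: list[int] | None = None,
                           log_transform: bool = False):
    """Pearson correlation between replicate frequency vectors.

    Frequencies are count / total valid reads over the variants shared by
    the table; ``log_transform`` switches to log10(freq + 1e-7), useful
    because raw frequencies are heavy-tailed.  Returns ``(matrix, min_r)``;
    with fewer than two replicates the matrix is empty and ``min_r`` None.
    """
    keys = [k for k in counts.counts.columns if k[0] == sample_type
            and (replicates is None or k[1] in replicates)]
    if len(keys) < 2:
        return pd.DataFrame(), None
    freqs = counts.counts[keys].div(
        counts.totals.loc[keys, "total_valid_reads"], axis=1)
    if log_transform:
        freqs = np.log10(freqs + 1e-7)
    mat = freqs.corr(method="pearson")
    off_diag = mat.values[~np.eye(len(keys), dtype=bool)]
    return mat, float(off_diag.min())


def run_library_qc(counts: CountTable,
                   thresholds: QcThresholds = QcThresholds(),
                   log_transform: bool = False) -> QcReport:
    """Apply every QC gate to a target's count table.

    Gates: plasmid library depth, valid fraction and wild-type fraction;
    negative-control valid fraction; per-replicate valid-read depth at each
    DNA timepoint; at least two valid replicates per timepoint; minimum
    pairwise replicate correlation (computed among the valid replicates).
    """
    th = thresholds
    tot = counts.totals
    if not any(k[0] == "library" for k in tot.index):
        raise ValueError("count table lacks a plasmid library column")

    reasons: list[str] = []
    lib_rows = []
    for key in tot.index:
        st, rep = key
        received = int(tot.loc[key, "total_reads_received"])
        valid = int(tot.loc[key, "total_valid_reads"])
        wt = int(tot.loc[key, "wildtype_reads"])
        vfrac = valid / received if received else 0.0
        wfrac = wt / received if received else 0.0
        passed = True
        if st == "library":
            if received < th.min_library_reads:
                passed = False
                reasons.append("library_depth")
            if vfrac < th.min_library_valid_fraction:
                passed = False
                reasons.append("library_valid_fraction")
            if wfrac > th.max_library_wildtype_fraction:
                passed = False
                reasons.append("library_wildtype_fraction")
        elif st == "negative_control":
            if vfrac > th.max_negative_control_valid_fraction:
                passed = False
                reasons.append("negative_control")
        elif st.endswith("_dna"):
            if valid < th.min_replicate_valid_reads:
                passed = False
                reasons.append(f"replicate_depth:{st}:{rep}")
        lib_rows.append((st, rep, received, vfrac, wfrac, passed))
    libraries = pd.DataFrame(
        lib_rows, columns=["sample_type", "replicate", "merged_read_count",
                           "valid_fraction", "wildtype_fraction", "passed"]
    ).set_index(["sample_type", "replicate"])

    timepoints = {}
    dna_types = sorted({k[0] for k in tot.index if k[0].endswith("_dna")})
    for st in dna_types:
        valid_reps = [k[1] for k in tot.index if k[0] == st
                      and libraries.loc[k, "passed"]]
        entry = {"n_valid_replicates": len(valid_reps),
                 "min_pairwise_r": None, "matrix": pd.DataFrame()}
        if len(valid_reps) < th.min_valid_replicates:
            reasons.append(f"replicates:{st}")
        else:
            mat, min_r = replicate_correlations(counts, st, valid_reps,
                                                log_transform)
            entry["matrix"], entry["min_pairwise_r"] = mat, min_r
            if min_r is not None and min_r < th.min_pairwise_correlation:
                reasons.append(f"correlation:{st}")
        timepoints[st] = entry

    return QcReport(libraries=libraries, timepoints=timepoints,
                    target_pass=not reasons, failure_reasons=reasons)
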