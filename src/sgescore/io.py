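"""Plain-text readers/writers for counts, scores and truth sets."""
from __future__ import annotations

import pandas as pd

from .calling import CountTable
from .targets import VariantDef


def write_counts_tsv(counts: CountTable, path) -> None:
    """Long-form TSV: one row per variant per library, with per-library
    totals repeated so the file round-trips without a sidecar."""
    rows = []
    for key in counts.counts.columns:
        st, rep = key
        received, valid, wt = counts.totals.loc[
            key, ["total_reads_received", "total_valid_reads", "wildtype_reads"]]
        for vid, c in counts.counts[key].items():
            rows.append((vid, vid, st, rep, int(c),
                         int(c) / valid if valid else float("nan"),
                         int(received), int(valid), int(wt)))
    pd.DataFrame(rows, columns=[
        "variant_id", "hgvs_c", "sample_type", "replicate", "count",
        "frequency", "total_reads_received", "total_valid_reads",
        "wildtype_reads"]).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t")
    columns, totals = {}, {}
    for (st, rep), sub in df.groupby(["sample_type", "replicate"]):
        key = (st, int(rep))
        columns[key] = dict(zip(sub["variant_id"], sub["count"]))
        first = sub.iloc[0]
        totals[key] = (int(first["total_reads_received"]),
                       int(first["total_valid_reads"]),
                       int(first["wildtype_reads"]))
    return CountTable.from_columns(columns, totals)


def write_scores_csv(scores: pd.DataFrame, path) -> None:
    """MaveDB-style score CSV (hgvs_nt, hgvs_pro, score, ...), keeping any
    annotation columns the table carries."""
    out = scores.drop(columns=["hgvs_nt", "hgvs_pro"], errors="ignore")
    out.insert(0, "hgvs_nt", out.index)
    if "aa_change" in out.columns:
        out.insert(1, "hgvs_pro", ["p." + a if isinstance(a, str) and a else ""
                                   for a in out["aa_change"]])
    else:
        out.insert(1, "hgvs_pro", "")
    out = out.rename(columns={"functional_score": "score"})
    out.to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"exon_label": str})
    df = df.rename(columns={"score": "functional_score"})
    return df.set_index("hgvs_nt")


def variants_to_frame(variants: list[VariantDef]) -> pd.DataFrame:
    df = pd.DataFrame([v.__dict__ for v in variants])
    return df.set_index("variant_id")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
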