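"""Epihaplotype frequency tables from per-molecule methylation calls.

An epihaplotype is the ordered methylation pattern over the CpG sites of one
amplicon on a single DNA molecule. This module turns raw call strings into
analysis-ready frequency tables:

1. CpGs residing within PCR primers are trimmed (their state reflects the
   primer oligo, not the molecule);
2. reads whose call string contains a mismatch symbol ``2`` are removed;
3. epihaplotype classes observed only once per (sample, target) are removed;
4. frequencies are computed over the remaining reads, and (sample, target)
   pairs whose retained depth falls below 500 reads are flagged excluded.

Mismatch removal precedes singleton counting so that singleton status is
decided on clean strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bcfdna.targets import AmpliconTarget, TargetPanel


@dataclass(frozen=True)
class EpihapConfig:
    """Filtering thresholds for epihaplotype tables."""

    min_depth: int = 500
    min_occurrence: int = 2
    trim_primer_cpgs: bool = True
    expected_depth_validation: int = 2000
    expected_depth_cfdna: int = 20000

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_occurrence < 1:
            raise ValueError("min_occurrence must be >= 1")


@dataclass
class EpihapTable:
    """Filtered epihaplotype counts and frequencies.

    ``table`` is long-format with columns (sample_id, target, epihaplotype,
    count, frequency); ``qc`` carries per-(sample, target) depth accounting
    and exclusion flags.
    """

    table: pd.DataFrame
    qc: pd.DataFrame

    def frequencies(self, sample_id: str, target: str) -> pd.Series:
        sub = self.table[
            (self.table["sample_id"] == sample_id) & (self.table["target"] == target)
        ]
        return sub.set_index("epihaplotype")["frequency"]

    def is_excluded(self, sample_id: str, target: str) -> bool:
        sub = self.qc[
            (self.qc["sample_id"] == sample_id) & (self.qc["target"] == target)
        ]
        if sub.empty:
            return True
        return bool(sub["excluded"].iloc[0])

    def write(self, table_path, qc_path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        self.qc.to_csv(qc_path, sep="\t", index=False)


def trim_primer_cpgs(calls: pd.DataFrame, target: AmpliconTarget) -> pd.DataFrame:
    """Drop primer-resident CpG columns from every call string of a target.

    Rows for other targets pass through unchanged.
    """
    keep = target.interior_cpg_indices
    if not keep:
        raise ValueError(f"{target.name}: every CpG lies within a primer; target unusable")
    if len(keep) == target.n_cpgs:
        return calls
    mask = calls["target"] == target.name
    if not mask.any():
        return calls
    # map distinct strings once; reads vastly outnumber distinct epihaplotypes
    distinct = calls.loc[mask, "call_string"].unique()
    trimmed = {s: "".join(s[i] for i in keep) for s in distinct}
    out = calls.copy()
    out.loc[mask, "call_string"] = out.loc[mask, "call_string"].map(trimmed)
    return out


def trim_panel(calls: pd.DataFrame, targets: TargetPanel) -> pd.DataFrame:
    for t in targets:
        calls = trim_primer_cpgs(calls, t)
    return calls


def filter_and_count(calls: pd.DataFrame, cfg: EpihapConfig = EpihapConfig()) -> EpihapTable:
    """Apply mismatch, singleton and depth filters and compute frequencies."""
    rows = []
    qc_rows = []
    for (sample_id, target), grp in calls.groupby(["sample_id", "target"], sort=True):
        counts = grp["call_string"].value_counts()
        raw = int(counts.sum())
        clean = counts[~counts.index.str.contains("2")]
        n_mismatch = raw - int(clean.sum())
        kept = clean[clean >= cfg.min_occurrence]
        n_singleton = int(clean.sum()) - int(kept.sum())
        retained = int(kept.sum())
        excluded = retained < cfg.min_depth
        reason = ""
        if retained == 0:
            reason = "no reads after filtering"
        elif excluded:
            reason = f"retained depth {retained} < {cfg.min_depth}"
        qc_rows.append(
            {
                "sample_id": sample_id,
                "target": target,
                "raw_reads": raw,
                "mismatch_removed": n_mismatch,
                "singleton_removed": n_singleton,
                "retained": retained,
                "excluded": excluded,
                "reason": reason,
            }
        )
        if retained == 0 or excluded:
            continue
        freqs = kept / retained
        for hap, cnt in kept.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "epihaplotype": hap,
                    "count": int(cnt),
                    "frequency": float(freqs[hap]),
                }
            )
    table = pd.DataFrame(
        rows, columns=["sample_id", "target", "epihaplotype", "count", "frequency"]
    )
    qc = pd.DataFrame(
        qc_rows,
        columns=[
            "sample_id", "target", "raw_reads", "mismatch_removed",
            "singleton_removed", "retained", "excluded", "reason",
        ],
    )
    return EpihapTable(table=table, qc=qc)


def per_cpg_methylation(table: EpihapTable) -> pd.DataFrame:
    """Per-CpG mean methylation per (sample, target) from filtered reads.

    Each CpG column's value is the frequency-weighted fraction of ``1``
    symbols, identical to the fraction of methylated calls among retained
    reads.
    """
    rows = []
    for (sample_id, target), grp in table.table.groupby(["sample_id", "target"], sort=True):
        haps = grp["epihaplotype"].to_numpy()
        freqs = grp["frequency"].to_numpy()
        n_cpg = len(haps[0])
        states = np.array([[int(c) for c in h] for h in haps], dtype=float)
        means = freqs @ states
        for j in range(n_cpg):
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "cpg_index": j,
                    "mean_methylation": means[j],
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "target", "cpg_index", "mean_methylation"])


def freq_matrix(
    table: EpihapTable, target: str, top_k: int | None = None
) -> pd.DataFrame:
    """Samples x epihaplotypes frequency matrix for one target.

    With ``top_k`` set, the matrix is restricted to the ``top_k`` epihaplotypes
    with the highest mean frequency across samples (the convention used for
    heatmap display, where only the 10 most frequent epihaplotypes are shown).
    Absent epihaplotypes are 0; excluded samples are not included.
    """
    sub = table.table[table.table["target"] == target]
    wide = sub.pivot_table(
        index="sample_id", columns="epihaplotype", values="frequency", fill_value=0.0
    )
    if top_k is not None and wide.shape[1] > top_k:
        order = wide.mean(axis=0).sort_values(ascending=False)
        wide = wide[order.index[:top_k]]
    wide.columns.name = None
    return wide
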