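"""Brain-derived cfDNA (bcfDNA) scoring of plasma samples.

For each target of the assay panel the brain-specific epihaplotype is the
fully methylated pattern (hypermethylated-in-brain targets) or the fully
unmethylated pattern (hypomethylated-in-brain targets). A sample's per-target
brain percentage is 100 times the fraction of retained reads carrying that
pattern, and the bcfDNA score is the plain sum of the per-target percentages
(0-500 percentage points for a five-target panel).

A target excluded by depth QC contributes 0 to the sum and is flagged; an
optional mode rescales the sum by the number of evaluable targets instead.
The score is linear in the true brain fraction f of a cfDNA mixture,
E[score] = f * S_brain + (1 - f) * S_other, so a calibrated fraction
estimate is f_hat = (score - S_other) / (S_brain - S_other), with S_tissue
the pure-tissue scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bcfdna.epihaplotype import EpihapTable
from bcfdna.targets import AmpliconTarget, TargetPanel


def brain_epihap_percent(
    table: EpihapTable,
    sample_id: str,
    target: AmpliconTarget,
    hamming_tolerance: int = 0,
) -> float | None:
    """Percentage of retained reads carrying the brain-specific epihaplotype.

    Strict matching of the fully methylated / fully unmethylated trimmed
    pattern by default; ``hamming_tolerance`` > 0 also counts epihaplotypes
    within that many mismatching CpGs of the pattern. Returns ``None`` when
    the (sample, target) pair was excluded by depth QC.
    """
    if table.is_excluded(sample_id, target.name):
        return None
    freqs = table.frequencies(sample_id, target.name)
    if freqs.empty:
        return None
    pattern = target.brain_epihaplotype(trimmed=True)
    if hamming_tolerance == 0:
        frac = float(freqs.get(pattern, 0.0))
    else:
        frac = float(
            sum(
                f
                for hap, f in freqs.items()
                if sum(a != b for a, b in zip(hap, pattern)) <= hamming_tolerance
            )
        )
    return 100.0 * frac


@dataclass
class BcfdnaReport:
    """Per-sample per-target brain percentages and summed scores."""

    per_target: pd.DataFrame  # sample_id, target, brain_percent, retained, excluded
    scores: pd.DataFrame      # sample_id, score, n_evaluable, flags

    def write(self, per_target_path, scores_path) -> None:
        self.per_target.to_csv(per_target_path, sep="\t", index=False)
        self.scores.to_csv(scores_path, sep="\t", index=False)


def bcfdna_score(
    table: EpihapTable,
    targets: TargetPanel,
    sample_ids: list[str] | None = None,
    hamming_tolerance: int = 0,
    rescale_by_evaluable: bool = False,
) -> BcfdnaReport:
    """Summed brain-epihaplotype score per sample over the assay panel.

    Excluded targets contribute 0 with a flag; with
    ``rescale_by_evaluable`` the sum is scaled by
    ``n_targets / n_evaluable`` instead. Samples with no evaluable target get
    a missing score.
    """
    if sample_ids is None:
        sample_ids = sorted(set(table.qc["sample_id"]))
    rows = []
    score_rows = []
    for sid in sample_ids:
        total = 0.0
        n_eval = 0
        flags = []
        for t in targets:
            pct = brain_epihap_percent(table, sid, t, hamming_tolerance)
            qc = table.qc[(table.qc["sample_id"] == sid) & (table.qc["target"] == t.name)]
            retained = int(qc["retained"].iloc[0]) if len(qc) else 0
            excluded = pct is None
            rows.append(
                {
                    "sample_id": sid,
                    "target": t.name,
                    "brain_percent": np.nan if excluded else pct,
                    "retained_depth": retained,
                    "excluded": excluded,
                }
            )
            if excluded:
                flags.append(f"{t.name}:excluded")
            else:
                total += pct
                n_eval += 1
        if n_eval == 0:
            score = np.nan
            flags.append("no evaluable targets")
        elif rescale_by_evaluable:
            score = total * len(targets) / n_eval
        else:
            score = total
        score_rows.append(
            {
                "sample_id": sid,
                "score": score,
                "n_evaluable": n_eval,
                "flags": ";".join(flags),
            }
        )
    return BcfdnaReport(
        per_target=pd.DataFrame(rows),
        scores=pd.DataFrame(score_rows),
    )


@dataclass
class GroupComparison:
    t: float | None
    p_value: float | None
    mean_diff: float
    group_means: pd.Series


def compare_groups(scores: pd.Series, groups: pd.Series) -> GroupComparison:
    """Classical two-sided pooled-variance t-test of scores between 2 groups.

    With a single sample in either group the test refuses and only the
    descriptive group difference is reported.
    """
    groups = groups.reindex(scores.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    a = scores[groups == levels[0]].dropna().to_numpy(dtype=float)
    b = scores[groups == levels[1]].dropna().to_numpy(dtype=float)
    means = pd.Series(
        {levels[0]: float(np.mean(a)), levels[1]: float(np.mean(b))}
    )
    diff = means[levels[0]] - means[levels[1]]
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(t=None, p_value=None, mean_diff=diff, group_means=means)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(t=float(t), p_value=float(p), mean_diff=diff, group_means=means)


def calibrate_fraction(score: float, s_brain: float, s_other: float) -> float:
    """Brain-fraction estimate from a score and pure-tissue reference scores."""
    if s_brain == s_other:
        raise ValueError("pure-tissue scores are equal; calibration undefined")
    return (score - s_other) / (s_brain - s_other)
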