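"""Selection of brain-specific CpG markers from a multi-tissue atlas.

The cascade retains probes that

1. show non-overlapping chromatin states between brain and non-brain
   reference epigenomes (:func:`chromatin_disjoint_filter`);
2. have methylation data available in strictly more than 10% of the atlas
   dataset units (:func:`availability_filter`);
3. are differentially methylated between brain and non-brain samples by a
   moderated two-group t-test at Benjamini-Hochberg adjusted p < 0.01
   (:func:`moderated_dm_test`);
4. rank in the top 20 per direction by absolute mean beta difference
   (:func:`rank_and_trim`);
5. carry at least 2 additional CpG dinucleotides within 140 bp both upstream
   and downstream (:func:`cpg_density_filter`);
6. show low DNase hypersensitivity in brain, so that the region is likely
   protected from nuclease digestion and represented in the cfDNA pool
   (:func:`dnase_filter`).

Every stage returns a subset of its input, so the cascade is monotone.

The moderated t-test shrinks probe-wise residual variances toward a prior
fitted by method of moments on the log variances, adding the prior degrees
of freedom to the residual degrees of freedom, and reduces to the ordinary
pooled-variance t-test when the prior weight is forced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    availability_min_fraction: float = 0.10
    adj_p_max: float = 0.01
    top_k: int = 20
    flank_bp: int = 140
    min_flank_cpgs: int = 2
    #: absolute threshold on mean brain DNase signal; ``None`` uses the
    #: ``dnase_percentile`` of the brain signal across the supplied table
    dnase_brain_max: float | None = None
    dnase_percentile: float = 33.0
    #: optional consistency criterion (minimum per-dataset delta quantile);
    #: disabled by default
    min_consistency_delta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.availability_min_fraction < 1.0:
            raise ValueError("availability_min_fraction must be in (0, 1)")
        if self.adj_p_max <= 0 or self.top_k <= 0 or self.flank_bp <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# stage 1: chromatin-state disjointness


def chromatin_disjoint_filter(
    states: pd.DataFrame, groups: pd.Series
) -> list[str]:
    """Probes whose brain and non-brain chromatin-state sets are disjoint.

    ``states`` is probes x epigenomes (15-state labels); ``groups`` maps each
    epigenome to ``"brain"`` or ``"non-brain"``. Probes with a missing state
    in any epigenome are excluded and logged.
    """
    brain_cols = [e for e in states.columns if groups.get(e) == "brain"]
    other_cols = [e for e in states.columns if groups.get(e) == "non-brain"]
    if not brain_cols or not other_cols:
        raise ValueError("need at least one brain and one non-brain epigenome")
    kept = []
    n_missing = 0
    for probe, row in states.iterrows():
        if row.isna().any():
            n_missing += 1
            continue
        if not set(row[brain_cols]) & set(row[other_cols]):
            kept.append(probe)
    if n_missing:
        logger.info("chromatin filter: %d probes excluded for missing states", n_missing)
    return kept


# ---------------------------------------------------------------------------
# stage 2: availability


def availability_filter(
    beta: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
    dataset_ids: pd.Series | None = None,
) -> list[str]:
    """Probes available in strictly more than the minimum fraction of units.

    When ``dataset_ids`` (sample -> dataset label) is given, availability is
    counted per dataset (a probe is available in a dataset if at least one of
    its samples has a value), matching atlases assembled from heterogeneous
    studies; otherwise it is counted per sample.
    """
    present = beta.notna()
    if dataset_ids is not None:
        avail = present.T.groupby(dataset_ids.reindex(beta.columns)).any().T
    else:
        avail = present
    frac = avail.mean(axis=1)
    return list(frac.index[frac > cfg.availability_min_fraction])


# ---------------------------------------------------------------------------
# stage 3: moderated differential methylation


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s2)`` against the theoretical
    moments implied by the hierarchical model, returning ``(prior_df,
    prior_s2)``; ``prior_df`` is ``inf`` when the observed spread of log
    variances is no larger than expected from sampling alone.
    """
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("too few variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # log-variance spread no larger than sampling noise: variances are
        # exchangeable and the prior collapses to their arithmetic mean
        d0 = np.inf
        s0 = float(np.mean(s2))
    return d0, s0


def moderated_dm_test(
    beta: pd.DataFrame,
    is_brain: pd.Series | np.ndarray,
    prior_df_override: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test of brain vs non-brain methylation per probe.

    Returns one row per probe with group means, delta (brain minus other),
    the moderated t statistic, raw and BH-adjusted p-values and the
    direction (``hyper``/``hypo`` in brain). Probes with fewer than 2
    observations in either group are marked untested and excluded from the
    BH family. ``prior_df_override=0`` yields the classical pooled t-test.
    """
    is_brain = np.asarray(
        is_brain.reindex(beta.columns) if isinstance(is_brain, pd.Series) else is_brain,
        dtype=bool,
    )
    X = beta.to_numpy(dtype=float)
    b, o = X[:, is_brain], X[:, ~is_brain]
    nb = np.sum(~np.isnan(b), axis=1)
    no = np.sum(~np.isnan(o), axis=1)
    with np.errstate(invalid="ignore"):
        mb = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
        mo = np.nanmean(np.where(np.isnan(o), np.nan, o), axis=1)
        vb = np.array([np.nanvar(row, ddof=1) if k >= 2 else np.nan for row, k in zip(b, nb)])
        vo = np.array([np.nanvar(row, ddof=1) if k >= 2 else np.nan for row, k in zip(o, no)])
    tested = (nb >= 2) & (no >= 2)
    df = (nb + no - 2).astype(float)
    s2 = np.where(tested, ((nb - 1) * vb + (no - 1) * vo) / np.maximum(df, 1), np.nan)

    if prior_df_override is not None:
        d0, s0 = float(prior_df_override), 1.0
        if d0 == 0:
            s0 = 0.0
    else:
        try:
            d0, s0 = fit_variance_prior(s2[tested], df[tested])
        except ValueError:
            logger.warning("variance prior fit failed; falling back to ordinary t")
            d0, s0 = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = df + d0
    # the information in the shrunk variances cannot exceed the pooled
    # residual df of the whole family
    df_total = np.minimum(df_total, float(np.sum(df[tested])))

    delta = mb - mo
    se = np.sqrt(s2_post * (1.0 / np.maximum(nb, 1) + 1.0 / np.maximum(no, 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = delta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.where(tested, p, np.nan)
    # degenerate zero-variance probes with zero delta: no evidence either way
    p = np.where(tested & ~np.isfinite(tstat) & (delta == 0), 1.0, p)

    adj = np.full_like(p, np.nan)
    if tested.any():
        adj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "probe_id": beta.index,
            "n_brain": nb,
            "n_other": no,
            "mean_brain": mb,
            "mean_other": mo,
            "delta": delta,
            "t": tstat,
            "df_total": df_total,
            "p_value": p,
            "adj_p": adj,
            "direction": np.where(delta > 0, "hyper", "hypo"),
            "tested": tested,
        }
    ).set_index("probe_id")
    out.attrs["prior_df"] = d0
    out.attrs["prior_s2"] = s0
    return out


# ---------------------------------------------------------------------------
# stage 4: ranking


def rank_and_trim(dm: pd.DataFrame, cfg: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Top-k probes per direction by |delta| among BH-significant probes.

    Ties on |delta| break by smaller adjusted p, then lexical probe id.
    """
    sig = dm[(dm["tested"]) & (dm["adj_p"] < cfg.adj_p_max)].copy()
    sig["abs_delta"] = sig["delta"].abs()
    parts = []
    for direction in ("hyper", "hypo"):
        sub = sig[sig["direction"] == direction]
        sub = sub.sort_values(
            by=["abs_delta", "adj_p", "probe_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        if len(sub) < cfg.top_k:
            logger.info(
                "rank_and_trim: only %d %smethylated probes available (top_k=%d)",
                len(sub), direction, cfg.top_k,
            )
        parts.append(sub.head(cfg.top_k))
    out = pd.concat(parts)
    return out.sort_values(
        by=["abs_delta", "adj_p", "probe_id"], ascending=[False, True, True], kind="mergesort"
    )


# ---------------------------------------------------------------------------
# stage 5: CpG density


def count_flanking_cpgs(sequence: str, cpg_pos: int, flank_bp: int = 140) -> tuple[int, int]:
    """Count CpG dinucleotides with their C within ``flank_bp`` of a probe C.

    The probe's own CpG (C at ``cpg_pos``) is not counted. Returns
    ``(n_upstream, n_downstream)``.
    """
    seq = sequence.upper()
    up = sum(
        1
        for i in range(max(0, cpg_pos - flank_bp), cpg_pos)
        if seq[i : i + 2] == "CG"
    )
    down = sum(
        1
        for i in range(cpg_pos + 2, min(len(seq) - 1, cpg_pos + flank_bp + 1))
        if seq[i : i + 2] == "CG"
    )
    return up, down


def cpg_density_filter(
    candidates: pd.DataFrame | list[str],
    annotation: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Retain candidates with enough flanking CpGs on both sides.

    ``annotation`` (indexed or keyed by ``probe_id``) must either carry
    precomputed ``n_cpg_upstream_140``/``n_cpg_downstream_140`` columns or a
    ``sequence`` column plus ``probe_offset`` (position of the probe C within
    the sequence), from which counts are derived. Probes without annotation
    are dropped and logged.
    """
    probes = list(candidates.index) if isinstance(candidates, pd.DataFrame) else list(candidates)
    ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
    kept = []
    for p in probes:
        if p not in ann.index:
            logger.info("cpg_density_filter: %s dropped (no annotation)", p)
            continue
        row = ann.loc[p]
        if "n_cpg_upstream_140" in ann.columns and not pd.isna(row["n_cpg_upstream_140"]):
            up, down = int(row["n_cpg_upstream_140"]), int(row["n_cpg_downstream_140"])
        elif "sequence" in ann.columns and isinstance(row.get("sequence"), str):
            up, down = count_flanking_cpgs(
                row["sequence"], int(row["probe_offset"]), cfg.flank_bp
            )
        else:
            logger.info("cpg_density_filter: %s dropped (no usable annotation)", p)
            continue
        if up >= cfg.min_flank_cpgs and down >= cfg.min_flank_cpgs:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# stage 6: DNase prioritisation


def dnase_filter(
    candidates: list[str],
    dnase: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
) -> tuple[list[str], float]:
    """Retain candidates with low mean brain DNase signal.

    The default threshold is the 33rd percentile of the brain signal across
    all probes in the supplied table, so "low" is judged against the probe
    universe rather than the handful of surviving candidates. Candidates with
    no DNase value are retained with a warning (prioritisation, not a hard
    filter). Returns ``(kept, threshold)``.
    """
    tab = dnase.set_index("probe_id") if "probe_id" in dnase.columns else dnase
    threshold = (
        cfg.dnase_brain_max
        if cfg.dnase_brain_max is not None
        else float(np.percentile(tab["dnase_brain"].dropna(), cfg.dnase_percentile))
    )
    kept = []
    for p in candidates:
        if p not in tab.index or pd.isna(tab.loc[p, "dnase_brain"]):
            logger.warning("dnase_filter: %s has no DNase value; retained", p)
            kept.append(p)
        elif float(tab.loc[p, "dnase_brain"]) <= threshold:
            kept.append(p)
    return kept, threshold


# ---------------------------------------------------------------------------
# full cascade


@dataclass
class SelectionResult:
    """Marker list plus per-stage bookkeeping."""

    markers: pd.DataFrame          # probe_id (index), direction, delta, adj_p
    dm: pd.DataFrame
    stage_counts: pd.Series
    dnase_threshold: float

    def write(self, path) -> None:
        self.markers.to_csv(path, sep="\t")


def select_markers(
    beta: pd.DataFrame,
    is_brain: pd.Series,
    chromatin: pd.DataFrame,
    epigenome_groups: pd.Series,
    dnase: pd.DataFrame,
    annotation: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
    dataset_ids: pd.Series | None = None,
) -> SelectionResult:
    """Run the full marker-selection cascade on an atlas."""
    stage1 = chromatin_disjoint_filter(chromatin, epigenome_groups)
    stage2 = [p for p in availability_filter(beta.loc[stage1], cfg, dataset_ids)]
    dm = moderated_dm_test(beta.loc[stage2], is_brain)
    ranked = rank_and_trim(dm, cfg)
    stage5 = cpg_density_filter(ranked, annotation, cfg)
    stage6, thr = dnase_filter(stage5, dnase, cfg)
    markers = ranked.loc[stage6, ["direction", "delta", "adj_p"]]
    counts = pd.Series(
        {
            "input": len(beta),
            "chromatin_disjoint": len(stage1),
            "available": len(stage2),
            "significant": int((dm["tested"] & (dm["adj_p"] < cfg.adj_p_max)).sum()),
            "ranked": len(ranked),
            "cpg_density": len(stage5),
            "final": len(stage6),
        }
    )
    return SelectionResult(markers=markers, dm=dm, stage_counts=counts, dnase_threshold=thr)
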