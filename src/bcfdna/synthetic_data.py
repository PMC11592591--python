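"""Synthetic inputs with known ground truth for the bcfDNA pipeline.

Three generators cover every input the pipeline consumes:

* :func:`simulate_reads` — amplicon bisulfite reads for one tissue and one
  target, drawn from a per-tissue epihaplotype distribution with a simple
  noise model (bisulfite conversion failure, inappropriate conversion of
  methylated cytosines, uniform sequencing substitution error);
* :func:`simulate_mixture` — plasma-like cfDNA read sets mixing brain and
  non-brain molecules at a known brain fraction;
* :func:`simulate_atlas` — a probe-level methylation atlas (beta values with
  missingness) with planted brain-specific markers, plus the matching
  chromatin-state, DNase and probe-annotation tables.

All randomness flows from one integer seed; per-(target, sample) substreams
are derived deterministically so that outputs are reproducible and
independent of generation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from bcfdna.targets import (
    ALL_METHYLATED,
    AmpliconTarget,
    TargetPanel,
    stable_hash,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class ReadSimConfig:
    """Noise model and depth for read simulation.

    Rates are typical for bisulfite amplicon sequencing: incomplete
    conversion (an unmethylated C read as C) and inappropriate conversion
    (a methylated C read as T) both around 0.5%, and a 0.2% per-base
    substitution error.
    """

    depth_per_target: int = 2000
    conversion_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.005
    seq_error_rate: float = 0.002
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "conversion_failure_rate",
            "inappropriate_conversion_rate",
            "seq_error_rate",
            "indel_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_target < 0:
            raise ValueError("depth_per_target must be >= 0")


@dataclass(frozen=True)
class TissueEpihapProfile:
    """Per-target epihaplotype distribution of one tissue.

    ``per_target`` maps a target name to a dict ``epihaplotype -> probability``
    where epihaplotype strings run over all CpGs of the target (primer CpGs
    included) and probabilities sum to 1.
    """

    tissue_name: str
    is_brain: bool
    per_target: Mapping[str, Mapping[str, float]]

    def distribution(self, target: AmpliconTarget) -> tuple[list[str], np.ndarray]:
        if target.name not in self.per_target:
            raise KeyError(f"profile {self.tissue_name!r} has no target {target.name!r}")
        dist = self.per_target[target.name]
        haps = list(dist)
        probs = np.asarray([dist[h] for h in haps], dtype=float)
        if np.any(probs < 0):
            raise ValueError(f"negative probability in profile for {target.name}")
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"zero-probability distribution for {target.name}")
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"probabilities for {target.name} sum to {total}, not 1")
        for h in haps:
            if len(h) != target.n_cpgs or set(h) - {"0", "1"}:
                raise ValueError(f"invalid epihaplotype {h!r} for {target.name}")
        return haps, probs


@dataclass(frozen=True)
class MixtureTruth:
    """Known composition of one synthetic plasma sample."""

    sample_id: str
    brain_fraction: float
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"component weights sum to {total}, not 1")
        if not 0.0 <= self.brain_fraction <= 1.0:
            raise ValueError("brain_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AtlasSimSpec:
    """Parameters of the synthetic methylation atlas.

    Defaults plant 5 brain-specific markers (1 hypermethylated, 4
    hypomethylated in brain) with a mean beta difference of 0.6 against a
    probe-level noise s.d. of 0.05, across 50 brain and 50 non-brain samples
    organised into datasets of 5 samples; whole (probe, dataset) cells go
    missing at rate 0.2.
    """

    n_probes: int = 400
    n_brain_samples: int = 50
    n_other_samples: int = 50
    planted_marker_ids: tuple[str, ...] | None = None
    planted_delta_beta: float = 0.6
    missingness_rate: float = 0.2
    beta_noise_sd: float = 0.05
    samples_per_dataset: int = 5
    decoy_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.planted_delta_beta <= 1.0:
            raise ValueError("planted_delta_beta must be in [-1, 1]")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# read container


@dataclass
class ReadBatch:
    """A set of simulated (or loaded) reads for one sample and one target.

    Sequences are held either as a dense byte matrix (uniform read length,
    the indel-free case) or as a list of strings; both views are available.
    """

    target_name: str
    sample_id: str
    matrix: np.ndarray | None = None
    _sequences: list[str] | None = None
    id_prefix: str = "read"

    def __post_init__(self) -> None:
        if self.matrix is None and self._sequences is None:
            raise ValueError("ReadBatch needs a matrix or a sequence list")

    @property
    def n_reads(self) -> int:
        if self.matrix is not None:
            return int(self.matrix.shape[0])
        return len(self._sequences)  # type: ignore[arg-type]

    @property
    def sequences(self) -> list[str]:
        if self._sequences is None:
            self._sequences = [
                bytes(row).decode("ascii") for row in self.matrix  # type: ignore[union-attr]
            ]
        return self._sequences

    def read_ids(self) -> list[str]:
        return [f"{self.id_prefix}:{i}" for i in range(self.n_reads)]

    def to_fastq(self, path: str | Path) -> None:
        """Write 4-line FASTQ records with constant Phred+33 quality 'I'."""
        with open(path, "w") as fh:
            for rid, seq in zip(self.read_ids(), self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(
        cls, path: str | Path, target_name: str = "", sample_id: str = ""
    ) -> "ReadBatch":
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
        return cls(
            target_name=target_name,
            sample_id=sample_id,
            _sequences=seqs,
            id_prefix=Path(path).stem,
        )


# ---------------------------------------------------------------------------
# read simulation


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-(seed, labels...) random generator."""
    return np.random.default_rng([seed] + [stable_hash(lab) for lab in labels])


def simulate_reads(
    target: AmpliconTarget,
    profile: TissueEpihapProfile,
    cfg: ReadSimConfig,
    sample_id: str = "sample",
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReadBatch, pd.DataFrame]:
    """Simulate bisulfite amplicon reads for one (tissue, target) pair.

    Each read is the bisulfite image of the reference: CpG cytosines are kept
    or converted according to the drawn epihaplotype, all other cytosines are
    converted, primer regions carry the primer-dictated (fully converted)
    bases, and conversion/sequencing noise is applied on top. The returned
    truth table records the noise-free epihaplotype of every read.
    """
    if rng is None:
        rng = _substream(cfg.seed, target.name, sample_id, profile.tissue_name)
    n = cfg.depth_per_target if depth is None else depth
    haps, probs = profile.distribution(target)

    hap_idx = rng.choice(len(haps), size=n, p=probs)
    # CpG states as a (n_reads, n_cpgs) 0/1 matrix
    states = np.array([[int(c) for c in h] for h in haps], dtype=np.uint8)[hap_idx]

    template = np.frombuffer(target.converted_reference().encode(), dtype=np.uint8)
    reads = np.tile(template, (n, 1)).copy()

    lo, hi = len(target.fwd_primer), target.length - len(target.rev_primer)
    interior = np.array(target.interior_cpg_indices, dtype=int)
    offsets = np.asarray(target.cpg_offsets, dtype=int)

    C, T = ord("C"), ord("T")
    for j in interior:
        col = offsets[j]
        meth = states[:, j] == 1
        base = np.where(meth, C, T).astype(np.uint8)
        if cfg.inappropriate_conversion_rate > 0:
            flip = meth & (rng.random(n) < cfg.inappropriate_conversion_rate)
            base[flip] = T
        if cfg.conversion_failure_rate > 0:
            flip = ~meth & (rng.random(n) < cfg.conversion_failure_rate)
            base[flip] = C
        reads[:, col] = base

    # conversion failure at interior non-CpG cytosines
    if cfg.conversion_failure_rate > 0:
        ref = np.frombuffer(target.reference_sequence.encode(), dtype=np.uint8)
        noncpg_c = np.flatnonzero(ref == C)
        noncpg_c = noncpg_c[(noncpg_c >= lo) & (noncpg_c < hi)]
        noncpg_c = np.setdiff1d(noncpg_c, offsets)
        if noncpg_c.size:
            fail = rng.random((n, noncpg_c.size)) < cfg.conversion_failure_rate
            sub = reads[:, noncpg_c]
            sub[fail] = C
            reads[:, noncpg_c] = sub

    if cfg.seq_error_rate > 0:
        err = rng.random(reads.shape) < cfg.seq_error_rate
        if err.any():
            idx = _BASE_INDEX[reads[err]].astype(np.int64)
            shift = rng.integers(1, 4, size=idx.size)
            reads[err] = _BASES[(idx + shift) % 4]

    prefix = f"{sample_id}|{target.name}"
    trimmed_keep = list(target.interior_cpg_indices)
    hap_arr = np.asarray(haps, dtype=object)
    full = hap_arr[hap_idx]
    trimmed = np.asarray(["".join(h[i] for i in trimmed_keep) for h in haps], dtype=object)[
        hap_idx
    ]
    truth = pd.DataFrame(
        {
            "read_id": [f"{prefix}:{i}" for i in range(n)],
            "sample_id": sample_id,
            "target": target.name,
            "epihaplotype": full,
            "epihaplotype_trimmed": trimmed,
        }
    )

    batch: ReadBatch
    if cfg.indel_rate > 0:
        seqs = [bytes(row).decode("ascii") for row in reads]
        seqs = [_apply_indels(s, cfg.indel_rate, rng) for s in seqs]
        batch = ReadBatch(target.name, sample_id, _sequences=seqs, id_prefix=prefix)
    else:
        batch = ReadBatch(target.name, sample_id, matrix=reads, id_prefix=prefix)
    return batch, truth


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    n_events = rng.binomial(len(out), rate)
    for _ in range(n_events):
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            del out[pos]
        else:
            out.insert(pos, "ACGT"[int(rng.integers(0, 4))])
    return "".join(out)


def simulate_mixture(
    targets: TargetPanel,
    brain_profile: TissueEpihapProfile,
    other_profile: TissueEpihapProfile,
    truth: MixtureTruth,
    cfg: ReadSimConfig,
) -> tuple[dict[str, ReadBatch], pd.DataFrame]:
    """Simulate a plasma-like cfDNA sample as a brain/non-brain read mixture.

    For each target, every read's source tissue is drawn independently with
    probability equal to the component weight; reads from each source follow
    that tissue's epihaplotype profile. Returns per-target read batches and a
    truth table labelling each read with its source tissue and epihaplotype.
    """
    profiles = {brain_profile.tissue_name: brain_profile, other_profile.tissue_name: other_profile}
    for tissue in truth.components:
        if tissue not in profiles:
            raise KeyError(f"no profile for mixture component {tissue!r}")
    f_brain = sum(
        w for t, w in truth.components.items() if profiles[t].is_brain
    )
    if abs(f_brain - truth.brain_fraction) > 1e-8:
        raise ValueError("brain_fraction inconsistent with component weights")

    batches: dict[str, ReadBatch] = {}
    truth_frames: list[pd.DataFrame] = []
    tissues = list(truth.components)
    weights = np.asarray([truth.components[t] for t in tissues], dtype=float)
    for target in targets:
        rng = _substream(cfg.seed, target.name, truth.sample_id, "mixture")
        counts = rng.multinomial(cfg.depth_per_target, weights)
        parts: list[np.ndarray] = []
        seq_parts: list[list[str]] = []
        frames: list[pd.DataFrame] = []
        for tissue, k in zip(tissues, counts):
            if k == 0:
                continue
            batch, tr = simulate_reads(
                target, profiles[tissue], cfg, sample_id=truth.sample_id, depth=int(k), rng=rng
            )
            tr = tr.assign(source_tissue=tissue)
            frames.append(tr)
            if batch.matrix is not None:
                parts.append(batch.matrix)
            else:
                seq_parts.append(batch.sequences)
        prefix = f"{truth.sample_id}|{target.name}"
        if seq_parts:
            seqs = [s for mat in parts for s in ReadBatch(target.name, truth.sample_id, matrix=mat).sequences]
            for chunk in seq_parts:
                seqs.extend(chunk)
            batches[target.name] = ReadBatch(
                target.name, truth.sample_id, _sequences=seqs, id_prefix=prefix
            )
        else:
            mat = np.vstack(parts) if parts else np.empty((0, target.length), dtype=np.uint8)
            batches[target.name] = ReadBatch(
                target.name, truth.sample_id, matrix=mat, id_prefix=prefix
            )
        tr_all = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        if len(tr_all):
            tr_all["read_id"] = [f"{prefix}:{i}" for i in range(len(tr_all))]
        truth_frames.append(tr_all)
    truth_table = pd.concat(truth_frames, ignore_index=True)
    return batches, truth_table


# ---------------------------------------------------------------------------
# default tissue profiles


def _alt(n: int, phase: int) -> str:
    return "".join("01"[(i + phase) % 2] for i in range(n))


def default_tissue_profiles(
    panel: TargetPanel, brain_specific_freq: float = 0.5, other_leak: float = 0.002
) -> tuple[TissueEpihapProfile, TissueEpihapProfile]:
    """Default brain and non-brain epihaplotype profiles for a panel.

    The brain-specific epihaplotype (fully unmethylated for hypomethylated
    targets, fully methylated for the hypermethylated one) sits at ~50%
    frequency in brain and at a trace frequency in other tissues; the
    remaining mass goes to the opposite homogeneous pattern and to two
    alternating partial-methylation patterns shared by both tissues.
    """
    brain: dict[str, dict[str, float]] = {}
    other: dict[str, dict[str, float]] = {}
    for t in panel:
        n = t.n_cpgs
        hyper = t.brain_epihap_direction == ALL_METHYLATED
        brain_hap = ("1" if hyper else "0") * n
        opposite = ("0" if hyper else "1") * n
        a1, a2 = _alt(n, 0), _alt(n, 1)
        rest = 1.0 - brain_specific_freq
        brain[t.name] = {
            brain_hap: brain_specific_freq,
            opposite: rest * 0.5,
            a1: rest * 0.3,
            a2: rest * 0.2,
        }
        other[t.name] = {
            brain_hap: other_leak,
            opposite: 0.7 - other_leak,
            a1: 0.2,
            a2: 0.1,
        }
    return (
        TissueEpihapProfile("brain", True, brain),
        TissueEpihapProfile("non_brain", False, other),
    )


# ---------------------------------------------------------------------------
# atlas simulation

CORE15_STATES = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

_BRAIN_EPIGENOMES = ("E067", "E068", "E069", "E071", "E072", "E073", "E074")
_OTHER_EPIGENOMES = ("E027", "E029", "E032", "E034", "E062", "E065", "E066", "E096", "E098", "E113")

_BIVALENT = ("10_TssBiv", "11_BivFlnk", "12_EnhBiv")
_REPRESSED = ("9_Het", "13_ReprPC", "15_Quies")


@dataclass
class AtlasSim:
    """Output bundle of :func:`simulate_atlas`."""

    beta: pd.DataFrame                 # probes x samples, NaN = missing
    sample_meta: pd.DataFrame          # sample_id, tissue, is_brain, dataset_id
    chromatin: pd.DataFrame            # probes x epigenomes, 15-state labels
    epigenome_groups: pd.Series        # epigenome -> "brain" | "non-brain"
    dnase: pd.DataFrame                # probe_id, dnase_brain, dnase_other
    annotation: pd.DataFrame           # probe_id, chrom, start, end, flank CpG counts
    planted: pd.DataFrame              # probe_id, direction ("hyper"|"hypo")

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "beta": outdir / "atlas_beta.tsv",
            "sample_meta": outdir / "atlas_samples.tsv",
            "chromatin": outdir / "chromatin_states.tsv",
            "dnase": outdir / "dnase.tsv",
            "annotation": outdir / "probe_annotation.tsv",
            "planted": outdir / "planted_truth.tsv",
        }
        self.beta.to_csv(paths["beta"], sep="\t")
        self.sample_meta.to_csv(paths["sample_meta"], sep="\t", index=False)
        self.chromatin.to_csv(paths["chromatin"], sep="\t")
        self.dnase.to_csv(paths["dnase"], sep="\t", index=False)
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.planted.to_csv(paths["planted"], sep="\t", index=False)
        return paths


def simulate_atlas(spec: AtlasSimSpec) -> AtlasSim:
    """Simulate a multi-tissue methylation atlas with planted brain markers.

    Planted markers get a brain-vs-other mean beta difference of
    ``planted_delta_beta`` (first planted probe hypermethylated in brain, the
    rest hypomethylated, mirroring the assay's 1:4 direction split), disjoint
    chromatin states between brain and non-brain epigenomes, low brain DNase
    signal and at least 2 flanking CpGs on each side. A ``decoy_fraction`` of
    the remaining probes also receive disjoint chromatin states but no
    methylation difference, sparse flanking CpGs and high brain DNase signal,
    so every downstream filter is load-bearing. Missingness removes whole
    (probe, dataset) cells at ``missingness_rate``.
    """
    rng = np.random.default_rng([spec.seed, stable_hash("atlas")])
    probes = [f"cg{i:06d}" for i in range(spec.n_probes)]
    if spec.planted_marker_ids is None:
        step = max(1, spec.n_probes // 6)
        planted_ids = [probes[(i + 1) * step % spec.n_probes] for i in range(5)]
    else:
        planted_ids = list(spec.planted_marker_ids)
        unknown = set(planted_ids) - set(probes)
        if unknown:
            raise ValueError(f"planted markers not in probe set: {sorted(unknown)}")
    planted_set = set(planted_ids)
    directions = ["hyper"] + ["hypo"] * (len(planted_ids) - 1)

    n_b, n_o = spec.n_brain_samples, spec.n_other_samples
    sample_ids = [f"B{i:03d}" for i in range(n_b)] + [f"O{i:03d}" for i in range(n_o)]
    is_brain = np.array([True] * n_b + [False] * n_o)
    spd = spec.samples_per_dataset
    dataset_ids = [
        f"{'GSEb' if b else 'GSEo'}{(i if b else i - n_b) // spd:03d}"
        for i, b in enumerate(is_brain)
    ]
    tissues = [
        rng.choice(["frontal cortex", "cerebellum", "hippocampus", "temporal cortex"])
        if b
        else rng.choice(["blood", "liver", "lung", "colon", "kidney"])
        for b in is_brain
    ]
    sample_meta = pd.DataFrame(
        {"sample_id": sample_ids, "tissue": tissues, "is_brain": is_brain, "dataset_id": dataset_ids}
    )

    # beta values
    base = rng.uniform(0.15, 0.85, size=spec.n_probes)
    beta = base[:, None] + rng.normal(0.0, spec.beta_noise_sd, size=(spec.n_probes, n_b + n_o))
    for pid, direction in zip(planted_ids, directions):
        i = probes.index(pid)
        sign = 1.0 if direction == "hyper" else -1.0
        # anchor the non-brain mean so that the shifted brain mean stays in [0, 1]
        base_i = rng.uniform(0.15, 0.35) if direction == "hyper" else rng.uniform(0.65, 0.85)
        vals = base_i + rng.normal(0.0, spec.beta_noise_sd, size=n_b + n_o)
        vals[is_brain] += sign * spec.planted_delta_beta
        beta[i] = vals
    clipped = (beta < 0) | (beta > 1)
    if clipped.any():
        logger.warning("clipped %d beta values to [0, 1]", int(clipped.sum()))
    beta = np.clip(beta, 0.0, 1.0)

    beta_df = pd.DataFrame(beta, index=probes, columns=sample_ids)
    # missingness at (probe, dataset) granularity
    datasets = sorted(set(dataset_ids))
    ds_cols = {d: [s for s, dd in zip(sample_ids, dataset_ids) if dd == d] for d in datasets}
    miss = rng.random((spec.n_probes, len(datasets))) < spec.missingness_rate
    for j, d in enumerate(datasets):
        rows = np.flatnonzero(miss[:, j])
        if rows.size:
            beta_df.loc[np.asarray(probes)[rows], ds_cols[d]] = np.nan

    # chromatin states
    epigenomes = list(_BRAIN_EPIGENOMES) + list(_OTHER_EPIGENOMES)
    groups = pd.Series(
        ["brain"] * len(_BRAIN_EPIGENOMES) + ["non-brain"] * len(_OTHER_EPIGENOMES),
        index=epigenomes,
        name="group",
    )
    non_planted = [p for p in probes if p not in planted_set]
    n_decoys = int(round(spec.decoy_fraction * len(non_planted)))
    decoys = set(rng.choice(non_planted, size=n_decoys, replace=False).tolist())

    state_rows = []
    for p in probes:
        if p in planted_set or p in decoys:
            row = [rng.choice(_BIVALENT) for _ in _BRAIN_EPIGENOMES] + [
                rng.choice(_REPRESSED) for _ in _OTHER_EPIGENOMES
            ]
        else:
            row = [rng.choice(CORE15_STATES) for _ in epigenomes]
            # force an overlap so the probe fails the disjointness filter
            row[len(_BRAIN_EPIGENOMES)] = row[0]
        state_rows.append(row)
    chromatin = pd.DataFrame(state_rows, index=probes, columns=epigenomes)

    # DNase signal
    dnase_brain = np.empty(spec.n_probes)
    dnase_other = rng.uniform(0.2, 3.0, size=spec.n_probes)
    for i, p in enumerate(probes):
        if p in planted_set:
            dnase_brain[i] = rng.uniform(0.01, 0.15)
        elif p in decoys:
            dnase_brain[i] = rng.uniform(1.5, 3.0)
        else:
            dnase_brain[i] = rng.uniform(0.2, 3.0)
    dnase = pd.DataFrame({"probe_id": probes, "dnase_brain": dnase_brain, "dnase_other": dnase_other})

    # probe annotation (BED-style, 0-based half-open) with flanking CpG counts
    up = rng.integers(0, 6, size=spec.n_probes)
    down = rng.integers(0, 6, size=spec.n_probes)
    for i, p in enumerate(probes):
        if p in planted_set:
            up[i] = rng.integers(2, 6)
            down[i] = rng.integers(2, 6)
        elif p in decoys:
            up[i] = rng.integers(0, 2)
            down[i] = rng.integers(0, 2)
    starts = np.arange(spec.n_probes) * 1000 + 500
    annotation = pd.DataFrame(
        {
            "probe_id": probes,
            "chrom": "chrS",
            "start": starts,
            "end": starts + 2,
            "n_cpg_upstream_140": up,
            "n_cpg_downstream_140": down,
        }
    )

    planted_df = pd.DataFrame({"probe_id": planted_ids, "direction": directions})
    return AtlasSim(
        beta=beta_df,
        sample_meta=sample_meta,
        chromatin=chromatin,
        epigenome_groups=groups,
        dnase=dnase,
        annotation=annotation,
        planted=planted_df,
    )
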