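"""End-to-end orchestration: simulate, select, validate, plasma modes.

Each mode reads plain files, runs the corresponding stages and writes plain
files plus a manifest (input checksums, config echo, seed, outputs), so runs
are reproducible and individual stages can be re-run from their inputs. The
log header echoes the analysis defaults (primer similarity 0.8, length
tolerance 0.2, depth floor 500, expected depths 2000/20000, BH 0.01,
availability 0.10, flank 140 bp with 2 CpGs, percentile rule 28/72,
bootstrap n 2000) so any deviation is visible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from bcfdna import synthetic_data as sd
from bcfdna.amplicon_caller import CallerConfig, call_reads
from bcfdna.cluster_boot import BootConfig, complete_linkage, multiscale_au
from bcfdna.epihaplotype import EpihapConfig, filter_and_count, freq_matrix, trim_panel
from bcfdna.marker_selection import SelectionConfig, select_markers
from bcfdna.parsimony_signature import (
    RatchetConfig,
    SignatureConfig,
    assign_signatures,
    cohort_fraction,
    contains_split,
    ratchet_search,
    topology_distance,
)
from bcfdna.quant import bcfdna_score, compare_groups
from bcfdna.targets import TargetPanel, build_default_panel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str
    outdir: str
    seed: int
    input_dir: str | None = None
    n_brain_samples: int = 10
    n_other_samples: int = 26
    validation_depth: int = 2000
    plasma_depth: int = 20000
    brain_fractions: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.5)
    n_boot: int = 2000
    ratchet_iterations: int = 50
    caller: CallerConfig = field(default_factory=CallerConfig)
    epihap: EpihapConfig = field(default_factory=EpihapConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("mode", "outdir", "seed"):
            if key not in raw:
                raise ValueError(f"config is missing required field {key!r}")
        for sub, klass in (("caller", CallerConfig), ("epihap", EpihapConfig), ("selection", SelectionConfig)):
            if sub in raw:
                raw[sub] = klass(**raw[sub])
        if "brain_fractions" in raw:
            raw["brain_fractions"] = tuple(raw["brain_fractions"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _echo_defaults() -> None:
    logger.info(
        "analysis defaults: primTresh=0.8 threshLen=0.2 min_depth=500 "
        "expected_depth=2000/20000 adj_p<0.01 availability>0.10 flank=140bp "
        "min_flank_cpgs=2 percentiles=28/72 n_boot=2000"
    )


def run_simulate(cfg: RunConfig) -> list[Path]:
    """Write synthetic validation-cohort reads, plasma mixtures and atlas files."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = build_default_panel()
    panel.to_yaml(out / "panel.yaml")
    brain_prof, other_prof = sd.default_tissue_profiles(panel)

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    read_cfg = sd.ReadSimConfig(depth_per_target=cfg.validation_depth, seed=cfg.seed)
    meta_rows = []
    truths = []
    for i in range(cfg.n_brain_samples + cfg.n_other_samples):
        is_brain = i < cfg.n_brain_samples
        sid = f"{'BR' if is_brain else 'OT'}{i:02d}"
        prof = brain_prof if is_brain else other_prof
        meta_rows.append({"sample_id": sid, "is_brain": is_brain, "group": "validation"})
        for t in panel:
            batch, truth = sd.simulate_reads(t, prof, read_cfg, sample_id=sid)
            batch.to_fastq(reads_dir / f"{sid}_{t.name}.fastq")
            truths.append(truth)
    pd.DataFrame(meta_rows).to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
    pd.concat(truths, ignore_index=True).to_csv(out / "read_truth.tsv", sep="\t", index=False)

    plasma_dir = out / "plasma_reads"
    plasma_dir.mkdir(exist_ok=True)
    plasma_cfg = sd.ReadSimConfig(depth_per_target=cfg.plasma_depth, seed=cfg.seed + 1)
    plasma_rows = []
    for j, f in enumerate(cfg.brain_fractions):
        sid = f"PL{j:02d}"
        truth = sd.MixtureTruth(
            sample_id=sid,
            brain_fraction=f,
            components={"brain": f, "non_brain": 1.0 - f},
        )
        batches, _ = sd.simulate_mixture(panel, brain_prof, other_prof, truth, plasma_cfg)
        for t_name, batch in batches.items():
            batch.to_fastq(plasma_dir / f"{sid}_{t_name}.fastq")
        plasma_rows.append({"sample_id": sid, "brain_fraction": f})
    pd.DataFrame(plasma_rows).to_csv(out / "plasma_truth.tsv", sep="\t", index=False)

    atlas = sd.simulate_atlas(sd.AtlasSimSpec(seed=cfg.seed))
    atlas.write(out / "atlas")
    return sorted(p for p in out.rglob("*") if p.is_file())


def run_select(cfg: RunConfig) -> list[Path]:
    """Marker selection from atlas TSVs in ``input_dir``."""
    indir = Path(cfg.input_dir or cfg.outdir) / "atlas"
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    beta = pd.read_csv(indir / "atlas_beta.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "atlas_samples.tsv", sep="\t")
    chromatin = pd.read_csv(indir / "chromatin_states.tsv", sep="\t", index_col=0)
    dnase = pd.read_csv(indir / "dnase.tsv", sep="\t")
    annotation = pd.read_csv(indir / "probe_annotation.tsv", sep="\t")
    # brain epigenome ids follow the Roadmap convention used by the simulator
    from bcfdna.synthetic_data import _BRAIN_EPIGENOMES

    groups = pd.Series(
        ["brain" if e in _BRAIN_EPIGENOMES else "non-brain" for e in chromatin.columns],
        index=chromatin.columns,
    )
    result = select_markers(
        beta=beta,
        is_brain=meta.set_index("sample_id")["is_brain"],
        chromatin=chromatin,
        epigenome_groups=groups,
        dnase=dnase,
        annotation=annotation,
        cfg=cfg.selection,
        dataset_ids=meta.set_index("sample_id")["dataset_id"],
    )
    result.write(out / "markers.tsv")
    result.stage_counts.to_csv(out / "selection_stage_counts.tsv", sep="\t", header=False)
    return [out / "markers.tsv", out / "selection_stage_counts.tsv"]


def _call_cohort(
    reads_dir: Path, panel: TargetPanel, meta: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    calls = []
    for sid in meta["sample_id"]:
        for t in panel:
            fq = reads_dir / f"{sid}_{t.name}.fastq"
            if not fq.exists():
                continue
            batch = sd.ReadBatch.from_fastq(fq, target_name=t.name, sample_id=sid)
            calls.append(call_reads(batch, panel, cfg.caller).calls)
    return pd.concat(calls, ignore_index=True)


def run_validate(cfg: RunConfig) -> list[Path]:
    """Tissue-validation mode: call, count, cluster, parsimony per target."""
    indir = Path(cfg.input_dir or cfg.outdir)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = TargetPanel.from_yaml(indir / "panel.yaml")
    meta = pd.read_csv(indir / "sample_metadata.tsv", sep="\t")
    calls = _call_cohort(indir / "reads", panel, meta, cfg)
    calls = trim_panel(calls, panel)
    calls.to_csv(out / "meth_calls.tsv", sep="\t", index=False)
    table = filter_and_count(calls, cfg.epihap)
    table.write(out / "epihaplotypes.tsv", out / "epihap_qc.tsv")

    brain_flags = meta.set_index("sample_id")["is_brain"]
    p = cohort_fraction(meta)
    sig_cfg = SignatureConfig(brain_cohort_fraction=min(max(p, 1e-6), 0.499))
    outputs = [out / "meth_calls.tsv", out / "epihaplotypes.tsv", out / "epihap_qc.tsv"]
    report_rows = []
    for t in panel:
        wide = freq_matrix(table, t.name)
        if wide.shape[0] < 3 or wide.shape[1] < 2:
            logger.warning("target %s: too few samples/features for clustering", t.name)
            continue
        tree = multiscale_au(wide, BootConfig(n_boot=cfg.n_boot, seed=cfg.seed))
        (out / f"cluster_{t.name}.nwk").write_text(tree.to_newick() + "\n")
        tree.node_table().to_csv(out / f"cluster_{t.name}_nodes.tsv", sep="\t", index=False)
        chars = assign_signatures(wide, brain_flags, sig_cfg)
        rf = None
        brain_set = {s for s in wide.index if brain_flags.get(s, False)}
        brain_in_cluster = tree.has_clade(brain_set)
        parsimony_has_split = None
        if chars.states.shape[1] >= 1 and wide.shape[0] >= 4:
            ptree = ratchet_search(
                chars, RatchetConfig(seed=cfg.seed, iterations=cfg.ratchet_iterations)
            )
            (out / f"parsimony_{t.name}.nwk").write_text(ptree.to_newick() + "\n")
            rf = topology_distance(ptree, tree)[0]
            parsimony_has_split = contains_split(ptree, brain_set)
            outputs.append(out / f"parsimony_{t.name}.nwk")
        report_rows.append(
            {
                "target": t.name,
                "n_samples": wide.shape[0],
                "n_epihaplotypes": wide.shape[1],
                "brain_cluster_recovered": brain_in_cluster,
                "brain_cluster_au": tree.au_for(brain_set),
                "parsimony_contains_brain_split": parsimony_has_split,
                "rf_vs_clustering": rf,
            }
        )
        outputs += [out / f"cluster_{t.name}.nwk", out / f"cluster_{t.name}_nodes.tsv"]
    pd.DataFrame(report_rows).to_csv(out / "discrimination_report.tsv", sep="\t", index=False)
    outputs.append(out / "discrimination_report.tsv")
    return outputs


def run_plasma(cfg: RunConfig) -> list[Path]:
    """Plasma mode: score cfDNA samples for brain-derived molecules."""
    indir = Path(cfg.input_dir or cfg.outdir)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel_path = indir / "panel.yaml"
    if not panel_path.exists():
        raise FileNotFoundError(
            f"plasma mode requires a target panel config at {panel_path}"
        )
    panel = TargetPanel.from_yaml(panel_path)
    truth = pd.read_csv(indir / "plasma_truth.tsv", sep="\t")
    meta = truth.rename(columns={"brain_fraction": "truth_fraction"})
    meta["is_brain"] = False
    calls = _call_cohort(indir / "plasma_reads", panel, meta, cfg)
    calls = trim_panel(calls, panel)
    table = filter_and_count(calls, cfg.epihap)
    report = bcfdna_score(table, panel)
    report.write(out / "bcfdna_per_target.tsv", out / "bcfdna_scores.tsv")
    return [out / "bcfdna_per_target.tsv", out / "bcfdna_scores.tsv"]


_MODES = {
    "simulate": run_simulate,
    "select": run_select,
    "validate": run_validate,
    "plasma": run_plasma,
}


def run(cfg: RunConfig) -> dict:
    """Execute a mode (or ``run-all``) and write a manifest; returns the manifest."""
    _echo_defaults()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.mode == "run-all":
        stages = ["simulate", "select", "validate", "plasma"]
    elif cfg.mode in _MODES:
        stages = [cfg.mode]
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    outputs: list[Path] = []
    for stage in stages:
        logger.info("stage %s", stage)
        try:
            outputs += _MODES[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(outputs)) if p.exists()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d
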