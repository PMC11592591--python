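# bcfdna

Detection and quantification of **brain-derived cell-free DNA (bcfDNA)** in
plasma from amplicon bisulfite sequencing of genomic regions with
brain-specific DNA methylation.

Neuronal loss — in neurodegeneration, brain injury, or neurotoxic adverse
events such as ICANS after CAR-T therapy — releases DNA fragments from dying
brain cells into the bloodstream. Because tissue identity is encoded in
stable DNA-methylation patterns, cfDNA molecules carrying a brain-specific
methylation pattern can be counted to estimate the brain's contribution to
the plasma cfDNA pool. This package implements that entire analysis as a
tested, reusable pipeline, exercised end to end on synthetic data with known
ground truth:

1. **Marker selection** (`bcfdna.marker_selection`) — candidate CpG probes
   from a multi-tissue methylation atlas must have (i) chromatin states
   disjoint between brain and non-brain reference epigenomes (Core 15-state
   vocabulary), (ii) data in more than 10% of atlas dataset units, (iii)
   BH-adjusted p < 0.01 in a moderated (empirical-Bayes) two-group t-test of
   beta values, (iv) rank in the top 20 per direction by |Δβ|, (v) at least
   2 CpGs within ±140 bp on each side, and (vi) low brain DNase
   hypersensitivity, so the region survives in cfDNA.
2. **Per-molecule methylation calling** (`bcfdna.amplicon_caller`) — reads
   are demultiplexed by bisulfite-degenerate forward-primer identity
   (threshold 0.8), length-filtered (relative deviation ≤ 0.2), aligned
   bisulfite-aware to the converted reference, and each CpG is called
   1 (methylated), 0 (unmethylated) or 2 (mismatch).
3. **Epihaplotypes** (`bcfdna.epihaplotype`) — the per-molecule pattern over
   adjacent CpGs. Primer-resident CpGs are trimmed; reads with mismatches
   and epihaplotype classes seen only once are removed; samples under 500
   retained reads per target are excluded.
4. **Tissue discrimination** (`bcfdna.cluster_boot`,
   `bcfdna.parsimony_signature`) — complete-linkage clustering on Euclidean
   distances between epihaplotype frequency vectors, with multiscale
   bootstrap (n = 2000) approximately-unbiased (AU) cluster support; and a
   Fitch-parsimony analysis on binary Brain/Other signatures assigned by a
   cohort percentile rule (brain fraction 0.28 → 28th/72nd percentiles),
   with Robinson–Foulds comparison of the two topologies.
5. **Plasma scoring** (`bcfdna.quant`) — per target, the percentage of
   retained reads carrying the brain-specific epihaplotype (fully methylated
   for APC2, fully unmethylated for PACRG, FAM123, cg02619656, cg09787504);
   the bcfDNA score is the sum over the five targets (0–500 percentage
   points). The score is linear in the true brain fraction f,
   E[score] = f·S_brain + (1−f)·S_other, giving the calibrated estimate
   f̂ = (score − S_other)/(S_brain − S_other).
6. **Synthetic data** (`bcfdna.synthetic_data`) — generates every input with
   known truth: amplicon bisulfite reads from per-tissue epihaplotype
   distributions (with conversion-failure, inappropriate-conversion and
   sequencing-error noise), brain/non-brain cfDNA mixtures at known
   fractions, and a methylation atlas with planted brain-specific markers,
   chromatin-state structure, DNase signal and missingness.

## Worked example

Score a synthetic plasma sample containing 10% brain-derived cfDNA at
20,000× depth per target:

```python
import pandas as pd
from bcfdna.targets import build_default_panel
from bcfdna import synthetic_data as sd
from bcfdna.amplicon_caller import call_reads
from bcfdna.epihaplotype import filter_and_count, trim_panel
from bcfdna.quant import bcfdna_score, calibrate_fraction

panel = build_default_panel()
brain, other = sd.default_tissue_profiles(panel)

def score(f, seed):
    cfg = sd.ReadSimConfig(depth_per_target=20_000, seed=seed)
    truth = sd.MixtureTruth("plasma", f, {"brain": f, "non_brain": 1 - f})
    batches, _ = sd.simulate_mixture(panel, brain, other, truth, cfg)
    calls = pd.concat([call_reads(b, panel).calls for b in batches.values()],
                      ignore_index=True)
    table = filter_and_count(trim_panel(calls, panel))
    return bcfdna_score(table, panel)

report = score(0.10, seed=7)
print(report.per_target[["target", "brain_percent", "retained_depth"]].to_string(index=False))
s = report.scores["score"].iloc[0]
s_brain = score(1.0, seed=8).scores["score"].iloc[0]
s_other = score(0.0, seed=9).scores["score"].iloc[0]
print(f"bcfDNA score: {s:.1f}  (pure brain {s_brain:.1f}, pure non-brain {s_other:.1f})")
print(f"calibrated brain fraction: {calibrate_fraction(s, s_brain, s_other):.3f}")
```

Output:

```
    target  brain_percent  retained_depth
      APC2       4.807498           19844
     PACRG       5.059344           19884
    FAM123       5.161290           19840
cg02619656       5.161128           19860
cg09787504       4.919355           19840
bcfDNA score: 25.1  (pure brain 241.6, pure non-brain 1.0)
calibrated brain fraction: 0.100
```

Each per-target percentage is the fraction of retained molecules carrying
the brain-specific epihaplotype; with the brain pattern at ~50% frequency in
brain tissue, a 10% brain fraction yields ~5% per target and a summed score
of ~25 points, and the calibration against pure-tissue scores recovers the
mixed-in fraction.

A command-line interface mirrors the library
(`bcfdna simulate|select|validate|plasma|run-all --outdir OUT --seed N`);
`run-all` writes reads, atlas, marker report, per-target dendrograms with
AU support, parsimony trees, bcfDNA scores and a manifest with checksums.

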