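# Methods

This note documents the models, parameter choices and numerical details
behind `bcfdna`, in the order the pipeline runs.

## Synthetic data model

The generator produces every input the pipeline consumes, under conditions
chosen to match the assay's intended operating regime.

**Amplicons.** The default panel has five targets (APC2 hypermethylated in
brain; PACRG, FAM123, cg02619656, cg09787504 hypomethylated), 144–166 bp
long (the assay caps amplicons at 170 bp for compatibility with ~167 bp
cfDNA fragments), with 5–7 CpGs each and 20 bp primers. Reference sequences
are synthetic: random A/C/G/T with CpGs planted at fixed offsets and
accidental CG dinucleotides scrubbed, so the declared CpG set is exactly the
CG content of the amplicon. APC2 carries one CpG inside its forward primer
and PACRG one inside its reverse primer, so primer-CpG trimming is exercised
by default. Primer sequences are the fully converted ends of the amplicon;
in simulated reads, primer regions always carry the primer-dictated
(converted) bases — which is precisely why primer CpGs are uninformative and
trimmed.

**Tissue profiles.** Each tissue is a per-target categorical distribution
over epihaplotypes. Defaults: the brain-specific pattern (all-0 for
hypomethylated targets, all-1 for APC2) at frequency **0.50** in brain —
the regime in which the assay's discrimination was established — and
**0.002** in other tissues (a trace rather than exactly zero, as real
non-brain tissues are never perfectly clean); the rest of the mass sits on
the opposite homogeneous pattern (0.25 brain / ~0.70 other) and two
alternating partial-methylation patterns shared by both tissues. These
shared backgrounds make discrimination depend on the brain-specific pattern
rather than on disjoint supports.

**Read noise.** Three independent mechanisms, applied in order: bisulfite
conversion failure (unmethylated C reads as C, default **0.005**),
inappropriate conversion (methylated C reads as T, default **0.005**), and
uniform substitution error (default **0.002**/base). These are conventional
bisulfite-amplicon figures chosen as package defaults (no measured error
profile accompanies the assay), configurable in `ReadSimConfig`.
Indels are off by default (`indel_rate` exposes them). Only the top strand
is simulated: amplicon primers fix the strand.

**Mixtures.** A plasma sample is a categorical mixture: each read's source
tissue is drawn with probability equal to the component weight, so the brain
read count per target is Binomial(depth, f). Expected depths follow the
assay: 2,000× per target for tissue validation, 20,000× for plasma.

**Atlas.** 400 probes × (50 brain + 50 non-brain) samples, organised in
5-sample dataset units. Probe beta values are a probe baseline U(0.15, 0.85)
plus N(0, 0.05) noise, clipped to [0, 1] (clipping is logged). Five planted
markers (1 hyper, 4 hypo, mirroring the assay panel) get a brain-vs-other
mean shift of Δβ = 0.6 from baselines chosen so the shift stays in range.
Missingness removes whole (probe, dataset) cells at rate 0.2 — availability
in real atlases fails dataset-wise, not sample-wise. Planted markers receive
disjoint chromatin states (bivalent in brain vs repressed elsewhere), ≥2
flanking CpGs per side and low brain DNase signal. Ten percent of the
remaining probes are **decoys**: chromatin-disjoint but with null
methylation, sparse flanks and high brain DNase — so the differential,
density and DNase stages are all load-bearing and the cascade's exact
recovery of the planted set is a genuine multi-stage property.

**What the generator does not emulate:** fragment-length distributions, PCR
duplicates and amplification bias, batch effects and array normalisation
artefacts in the atlas, cell-type heterogeneity within tissues, and
correlated (regional) methylation noise. Passing tests therefore demonstrate
the pipeline's correctness and statistical behaviour under its stated model,
not performance on real sequencing runs.

**Determinism.** One global integer seed; per-(target, sample) substreams
are derived via CRC-32 of the labels fed to `numpy`'s SeedSequence, so
outputs are reproducible and order-independent. Fixed seed ⇒ byte-identical
FASTQ.

## Marker selection

Stages, in order (each returns a subset of its input):

1. **Chromatin disjointness** — keep probes whose state sets over brain and
   non-brain epigenomes do not intersect; probes with any missing state are
   excluded and logged.
2. **Availability** — keep probes with data in strictly more than 10% of
   units; units are dataset labels when provided, samples otherwise.
3. **Moderated differential methylation** — per probe, a two-group t-test
   with the pooled residual variance shrunk toward a prior fitted by method
   of moments on log variances: with s²_g the probe variances on d_g df,
   e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior df d₀ solves
   ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2) (Newton iteration on the trigamma
   inverse) and s₀² = exp(mean e + ψ(d₀/2) − log(d₀/2)). When the observed
   spread of log variances does not exceed sampling noise, d₀ = ∞ and the
   prior collapses to the arithmetic mean of the variances. The moderated
   statistic is Δ/(s̃·√(1/n₁+1/n₂)) on d_g + d₀ df, capped at the family's
   summed residual df. A test pins this against Bioconductor limma's
   `eBayes` to ~1e-4 relative; forcing the prior weight to zero reproduces
   the classical pooled t exactly. Probes with <2 observations in a group
   are untested and excluded from the BH family (BH at adjusted p < 0.01).
4. **Ranking** — top 20 per direction by |Δβ| among significant probes; ties
   break by smaller adjusted p, then probe id.
5. **CpG density** — ≥2 additional CpGs whose C lies within 140 bp both
   upstream and downstream of the probe C; counts may be precomputed columns
   or derived from a flanking sequence.
6. **DNase prioritisation** — keep candidates whose mean brain DNase signal
   is at or below a threshold; default is the 33rd percentile of the brain
   signal across *all probes in the supplied table*. Judging "low" against
   the probe universe (rather than within the few surviving candidates,
   whose signals are all similar) keeps the stage a prioritisation of
   nuclease-protected regions instead of an arbitrary internal cut. Probes
   without a DNase value are retained with a warning.

## Methylation calling

Demultiplexing uses bisulfite-degenerate identity of the read prefix against
each forward primer (primer C matches read C or T), threshold 0.8 computed
over the primer length; ties are unassigned; reverse-complement retry runs
when forward assignment fails. Length filter: |len(read) − len(amplicon)| /
len(amplicon) ≤ 0.2, boundary inclusive.

Alignment is semi-global (free end gaps on both sequences) against the
unconverted reference with bisulfite-aware scoring: reference C matches read
C and T everywhere (outside CpG context, T is the converted base and C a
conversion failure; at declared CpG offsets both states are legitimate and
the methylation is read out at the calling step). Scores: match +1, mismatch
−1, gap −2; reads scoring below 0.6× the maximum attainable are discarded as
unalignable. Traceback is deterministic: diagonal, then up (gap in read),
then left.

Two numerical shortcuts keep high-depth runs fast without changing results:

* **Identity fast path** — for a read of exactly amplicon length whose
  gap-free score exceeds max − (match − 2·gap) (i.e. at most two mismatching
  columns at the default scores), no alignment containing an indel pair can
  score higher, so the gap-free alignment is returned directly. A
  near-periodic read could in principle prefer a shifted end-gap alignment
  this path does not consider; amplicon references are scrubbed random
  sequences where this does not arise.
* **Batched DP** — remaining equal-length reads are aligned by a dynamic
  programme vectorised across reads, with the left-gap dependency resolved
  by a prefix-max scan; it is pinned to the scalar DP by a unit test.

Calling: at each CpG offset, aligned C → 1, T → 0, anything else (including
a gap) → 2. Under substitution error ε at a CpG, only non-C/T substitutions
produce a 2, so the expected mismatch-symbol rate is 2ε/3 (verified by
simulation).

## Epihaplotype tables

Filter order: primer-CpG trimming, mismatch-read removal, then removal of
epihaplotype classes occurring fewer than twice per (sample, target) —
mismatch removal first so singleton status is decided on clean strings.
Frequencies are computed over the retained reads; (sample, target) pairs
with retained depth < 500 are flagged excluded with an explicit reason. The
depth floor applies to the post-filter depth (the analysis-ready reads);
both raw and retained depths are logged. Filtering is idempotent. Heatmap
export restricts to the 10 most frequent epihaplotypes per target;
clustering uses all retained epihaplotypes by default.

## Clustering with multiscale bootstrap

Complete linkage on Euclidean distances between per-sample epihaplotype
frequency vectors (scipy). Cluster support by multiscale bootstrap:
features (epihaplotypes) are resampled with replacement at 10 scales
r ∈ {0.5, …, 1.4}, 2,000 replicates per scale; BP_r is the fraction of
replicate trees containing the node's exact leaf set. With
z_r = Φ⁻¹(1 − BP_r), weighted least squares fits z_r ≈ v√r + c/√r using
binomial weights n·φ(z_r)²/(BP_r(1−BP_r)), and AU = 1 − Φ(v − c). BP is
clipped to [1/(n+1), 1 − 1/(n+1)] before the probit transform; nodes
recovered never or always at every scale are pinned to AU 0 or 1; fewer than
3 informative scales makes AU fall back to BP with a warning. Features are
the resampling unit because the clustered objects (samples) are fixed and
the epihaplotype columns play the role of the data the tree is inferred
from. With a single scale r = 1 the procedure reduces toward the plain
bootstrap probability.

## Parsimony signatures

The cohort brain fraction p (reference composition 40/141 = 0.28) sets the
percentile pair (100p, 100(1−p)). Per epihaplotype: if the brain median
frequency is ≤ the low percentile of all samples' frequencies (linear
interpolation), the epihaplotype is brain-low and a sample is "Brain" iff
its frequency is strictly below that point; symmetrically brain-high uses
the high percentile with strictly-above. Boundary semantics are ≤/≥ for the
class and </> for the sample signature; an exact tie classifies brain-low
with a logged warning; constant columns are dropped. The percentile is taken
over all samples (not non-brain only); both choices are defensible and the
all-samples form uses the same reference distribution for class and
signature.

Tree search is a parsimony ratchet: greedy stepwise-addition start, then
hill-climbing over nearest-neighbour interchanges, alternating 50 iterations
(default) of 25%-character upweighting (×2) with flat-weight refinement,
keeping the best flat score; deterministic under the mandatory seed. Fitch
scoring uses per-character state bitsets vectorised with numpy; the score is
invariant to the rooting edge. On ≤7 taxa the search provably reaches the
exhaustive optimum in tests.

Topology comparison uses the Robinson–Foulds symmetric difference of
non-trivial splits, normalised by 2(n−3); dendrograms are stripped of
heights first. Splits are canonicalised as the side not containing the first
leaf. The package computes RF itself; dendropy serves as the independent
oracle in tests.

## bcfDNA score and calibration

Per target, the brain percentage is 100× the retained-read fraction whose
trimmed call string equals the brain-specific pattern (strict matching;
`hamming_tolerance` defaults to 0 because relaxing it would also admit
noise-derived near-patterns from non-brain molecules). The score is the
plain sum over the panel (units: summed percentage points, 0–500 for five
targets). A target failing depth QC contributes 0 with a flag; an optional
mode rescales by the number of evaluable targets instead. Group comparison
is the classical pooled two-sample t-test; a group of one sample gets a
descriptive difference only. Calibration uses pure-tissue scores measured
through the same pipeline, f̂ = (score − S_other)/(S_brain − S_other), which
folds conversion-noise leakage into the references.

## Problem sizes used in tests and the acceptance script

Validation panels: 6 brain + 14 non-brain samples at 2,000× per target;
plasma mixtures at 20,000× per target over f ∈ {0, 0.05, 0.1, 0.2, 0.5};
20 seeds per stochastic claim; AU with the full n_boot = 2,000 at all 10
scales. Brain-clade recovery by clustering is asserted for every target and
seed; the AU and parsimony-split checks run on one representative target
(PACRG) per seed with 10 ratchet iterations — the signal at these panel
sizes is strong enough that the search converges immediately, and a
single-seed test covers all five targets in depth.

## Known limitations

* The bisulfite aligner is amplicon-scale (≤170 bp, one reference per
  target); it is not a genome-scale bisulfite mapper and ignores base
  qualities.
* AU values come from the standard two-parameter extrapolation; no higher-
  order correction or hypothesis-testing machinery beyond it.
* The ratchet explores NNI neighbourhoods only; for the panel sizes here
  this reaches the optimum, but very large cohorts may need SPR moves.
* Calibration assumes the pure-tissue reference profiles are stationary
  between calibration and measurement; real plasma adds biological
  variability the mixture model does not represent.
* The atlas simulator plants a single homogeneous effect size; it does not
  model probe-specific effect heterogeneity or cross-probe correlation, so
  the null false-positive rate it measures is the independent-probe one.
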