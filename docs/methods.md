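# Methods

This note documents the models and procedures implemented in `paradel`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Coordinates and inputs

All internal coordinates are 1-based inclusive, the convention of ASCAT-style
segment tables, which are the primary input; BED files are converted at the
boundary (0-based half-open → 1-based inclusive) on read and write. Gene
models are coding spans — first-exon start to last-exon end of the longest
transcript — and only autosomal genes enter any analysis. When transcripts
tie for longest, the one with the smallest start and then lexicographically
smallest id is taken. Segment tables are validated for `start ≤ end` and
`0 ≤ nMinor ≤ nMajor`; common ASCAT header dialects are accepted and extra
columns ignored.

## HD and LOH calling

A homozygous-deletion (HD) segment has major = minor = 0. Book-ended HD
records (gap-free: next start = previous end + 1) are merged before
containment testing, because array/consensus segmentation can split one
physical deletion at probe boundaries and an artificial split would hide a
full-gene deletion; records separated by ≥ 1 bp are never merged. Whether
the original analyses merged is not documented; both behaviors are exposed
(`merge_bookended`), default merged, and full-gene calls are invariant to
re-splitting a segment into gap-free pieces (tested).

A gene is **fully deleted** in a sample iff its whole coding span lies
inside one (merged) HD segment, and **partially deleted** on any overlap.
Samples with more than 100 fully deleted genes are dropped as hyper-deleted
(strictly greater: a sample at exactly 100 is kept); all gene-level counts
are then recomputed on the retained samples.

LOH segments have exactly one allele at zero: copy-loss (total copy 1),
copy-neutral (total 2), other (≥ 3). A segment is *focal* iff its length is
strictly less than half the length of the arm containing its midpoint; arm
lengths derive from the centromere midpoint, and centromere-spanning
segments are assigned to the midpoint arm and flagged. Gene-level LOH uses
the same full-containment rule as HDs so the two frequencies are comparable.

Telomere- and centromere-bound segments are detected against the cohort's
*observed* data boundaries — the first/last covered coordinate per
chromosome and the extreme covered coordinates on each side of the
centromere assembly gap — because assay coverage, not the chromosome ends,
bounds what a segment can reach. Bounds are computed from the full pre-QC
cohort, since they describe the assay rather than the retained tumors.

## Passenger universe and annotations

Drivers (TSGs and oncogenes, consumed as an id list) are excluded, along
with any gene whose coding span intersects a driver's coding span on the
same chromosome; the remaining autosomal genes are passengers. A gene is a
paralog if its annotation table reports ≥ 1 family member at ≥ 20%
reciprocal identity; `big_family` means ≥ 4 such paralogs; sequence
identity is the closest-paralog identity, stored as a fraction in [0.20, 1].
The annotation table is taken as authoritative for whether the 20% filter
precedes family-size counting. Genes missing paralog annotation stay in HD
calling but are dropped (with a logged count) from paralog-specific
analyses. Broadly essential genes from a gene × cell-line fitness matrix are
those scoring below −0.6 in at least 90% of lines with non-missing scores
(both thresholds configurable; the set shrinks monotonically as the score
threshold drops and grows as the required fraction drops — tested).

## Context features and regression

Distance covariates are inverted and capped: `max(0, 10 Mb − d)` where `d`
is the closest edge-to-edge distance between the gene's coding span and the
region (0 when overlapping), so 10 means adjacent and 0 means beyond the cap
or no qualifying region on the chromosome. Edge-to-edge is our choice — the
reference points are not otherwise pinned down — because it makes "right
next to" equal exactly 10 at adjacency. "Recurrently deleted TSG" means
≥ 3 full HDs in the combined (summed across cohorts) data. Telomere
distances use the observed chromosome boundaries; centromere distances use
the assembly-gap interval. Inversion and capping happen before z-scoring;
z-scores are computed over the model's own universe (passengers for the main
model, paralog passengers for the paralog model), booleans stay unscaled,
and a constant continuous column is an explicit error (or dropped with a
warning in `on_constant="drop"` mode, e.g. `dist_tsg` when nothing is
recurrently deleted). One standard deviation of each distance covariate in
Mb is exposed (`dist_sd_mb`) so per-SD odds ratios stay interpretable.

The two logistic models are

    HD ~ Paralog + Gene length + Dist.TSG + Dist.fragile + Dist.centromere + Dist.telomere
    HD ~ WGD + Big family + Seq. identity + Gene length + (the four distances)   [paralogs only]

fit by maximum likelihood (statsmodels Logit, Newton, tolerance 1e-8, up to
100 iterations) with an intercept always included. The outcome is 1+ vs 0 or
3+ vs 0 HDs; the 3+ model excludes genes with 1–2 HDs from its universe.
Confidence intervals are Wald (the CI method for such analyses is often
unstated; Wald is the default reported and noted in output metadata).
Non-convergence, rank deficiency or separation raise an explicit error —
never silent coefficients; orchestration layers may skip an unidentifiable
outcome with a logged warning, which matters only for small cohorts where
the sparse 3+ outcome can separate on TSG-adjacent genes. Nested models are
compared with a chi-squared likelihood-ratio test (df = covariate-count
difference).

A known inferential limitation, demonstrated by the calibration study
below: HD segments delete runs of adjacent genes, so per-gene outcomes are
spatially clustered, and plain-logistic standard errors are anti-conservative
for spatially smooth covariates (the distance terms). Covariates that are
i.i.d. across genes (paralogy and the paralog-property labels) are not
affected. Cluster-robust errors are out of scope here, as they are in the
standard form of this analysis.

## Enrichment statistics

All Fisher tests are two-sided (enrichments in both directions are
expected), and the reported OR is the unconditional sample estimate
`ad/bc`, matching percentage-based presentation; the conditional MLE is
available via `estimator="conditional"`. P-values follow the
point-probability rule over the hypergeometric null; for tables with
N ≤ 500 the hypergeometric weights are compared in exact integer arithmetic
(so probability ties — e.g. symmetric tables — are decided exactly rather
than inside a floating-point tolerance band), with a log-gamma computation
for larger tables. The implementation is verified against scipy on random
tables and against an independent exact enumeration for every table with
N ≤ 60. Per-stratum (cancer-type)
tests use only strata with ≥ 600 samples, compare 0 vs 1+ only, and are
Holm–Bonferroni adjusted. Mann–Whitney U comparisons are exact for small
untied samples and use the tie/continuity-corrected normal approximation
otherwise (scipy's switching rule). The saturation curve subsamples without
replacement, replicate *r* seeded as `seed + r`; the full-cohort point
equals the observed unique-gene count exactly, and the subsample expectation
matches the inclusion–exclusion closed form
`E = Σ_g [1 − C(N−k_g, n)/C(N, n)]` (tested on toy cohorts).

## The synthetic cohort generator

The generator encodes the selection model the analysis is designed to
detect, so the whole pipeline can be exercised and calibrated with no
external data.

**Genome and annotation.** 22 chromosomes × 120 Mb with a central 2 Mb
centromere gap; 20,000 genes packed per arm with Dirichlet gaps, lengths
log-normal (median 25 kb, log-sd 1.0, clipped to [1 kb, 2 Mb]); paralog
fraction 0.62 (the human genome's ">60%"); family sizes geometric with
median 3 (so the big-family fraction is ~35%); closest-paralog identity
0.2 + 0.8·Beta(1.5, 2.2) (mean ≈ 0.52); WGD fraction 0.5 among paralogs;
90 TSGs and 150 other drivers placed uniformly; 15 fragile sites of 1.5 Mb;
essential fractions 0.15 (singletons) and 0.05 (paralogs).

**Events.** Each tumor draws Poisson(λ = 10) candidate HD events. Start
positions are drawn over 200-kb bins with weight
`1 + α·prox_TSG + β·prox_fragile + γ·prox_telcent` (prox = inverted capped
distance / cap; α = β = 5, γ = 2); no event originates inside the
centromere gap. Lengths are exponential with mean 0.34 Mb for events
starting in a fragile site and 0.83 Mb elsewhere (the two reported mean
lengths; the exponential family is our choice, made for oracle
tractability), truncated at the arm boundary. Event origins may also fall in
a 5 Mb margin upstream of each arm, with the surviving part clipped to the
arm: this makes the breakage process stationary across the arm (no
artificial rate dip at arm starts) and is how telomere- and
centromere-bound segments arise, as in real data where breakpoints beyond
the assayed boundary produce bound segments. λ = 10 at 2,000 tumors is
deliberately compressed relative to a >10,000-sample patient cohort so that
per-gene deletion frequencies (~28% of passengers with ≥ 1 HD, a clear 0-HD
majority) match the combined-cohort regime at desk scale.

**Selection.** A candidate survives with probability
`min(1, τ^{#TSGs fully deleted} · Π_g s(g))` over the non-driver genes it
fully deletes — the independent-gene approximation, the simplest form that
produces the paralog/singleton asymmetry with a computable expectation.
Defaults: s_essential = 0.1, s_singleton = 0.5, s_paralog = 1.0, modulated
for paralogs by ×(1 − 0.1·WGD), ×(1 − 0.1·[family < 4]),
×(1 − 0.2·(1 − identity)); τ = 20 (TSG deletion is strongly favored, so
TSG-covering events are almost always accepted). Survival multipliers are
clipped to [0, 1]; drivers themselves carry s = 1 (their effect enters
through τ). Hemizygous events are selection-neutral: Poisson(20) per tumor,
uniform placement, exponential mean 10 Mb, 30% whole-arm (arm-level LOH is
pervasive in tumors and guarantees that every passenger sees LOH at
realistic rates), 40% copy-neutral. Accepted HDs, clipped LOH pieces and the
diploid (1,1) background tile every arm exactly once per sample (tested).

**Determinism.** One numpy Generator seeded from (seed, stage constant)
drives each of annotation, cohort and oracle; identical (config, seed) give
byte-identical outputs. Generation is vectorized across samples rather than
using one named generator per sample; reproducibility is at the cohort
level.

**The expectation oracle.** For a configuration, the oracle computes each
gene's per-event probability of being fully deleted *and* accepted — by
Monte Carlo over the same event law (weighting each drawn event by its
acceptance probability rather than thinning) or by enumeration over a
start × length-quantile grid for small genomes — then converts per-sample
Poisson event counts to `P(gene deleted in ≥ 1 of N samples)` and
`P(≥ 3 samples)` and forms the expected 2×2 table and OR over the passenger
universe. The Monte-Carlo standard error is estimated from batches and can
be made a hard bound (`max_se`). The oracle ignores one second-order effect:
merging of overlapping accepted events within a sample can create
containment neither event had alone; at default rates this is negligible
(the recovered ORs agree with the oracle to ~3% at study scale).

## Calibration and recovery studies (what the tests show)

- **Type-I calibration**: 200 null cohorts (no dispensability differential,
  no context effects, fragile lengths equalized) — the 0 vs 1+ paralogy
  Fisher test rejects at the nominal 5% rate. The regression-coverage
  check additionally uses focal events (mean 0.05 Mb, so events delete at
  most ~1 gene) and fixed gene length: under those conditions every fitted
  covariate's 95% CI covers OR = 1 at the nominal rate. With multi-gene
  events the smooth distance covariates under-cover (the clustering
  limitation above), and with variable lengths the length covariate has a
  genuine containment effect — neither is a null.
- **Recovery**: at the default scale the cohort paralogy OR lands within a
  few percent of the oracle, and the mean log-OR bias over 100 replicate
  cohorts (at a reduced 8,000-gene × 600-tumor scale, chosen to keep the
  replicate suite fast) is ≈ 0.000 ± 0.004, well under 0.02.
- **Structure**: full-gene calls equal a per-base coverage oracle on random
  genomes; emitted segments tile arms exactly; most passengers have 0 HDs
  while the 3+ paralogy enrichment exceeds the 1+ enrichment, reproducing
  the qualitative group structure of real cohorts.

**What passing does not show.** The generator's genes are placed
independently of paralogy, so it cannot reveal confounding between paralog
status and genomic position that may exist in real genomes (the regression
exists precisely to control for that in real data). It has no purity/ploidy
artifacts, no subclonality, no segmentation noise, and the independent-gene
survival model ignores epistasis between co-deleted genes. Tests passing on
synthetic cohorts validate the machinery and its calibration, not the
biological conclusion on any particular real dataset.

## Numerical details

- Fisher on degenerate tables: a zero margin is an error; a single zero cell
  reports OR 0 or ∞ with a finite p-value.
- MWU on all-tied inputs returns p = 1 with a warning.
- Z-scoring uses population (ddof = 0) standard deviation; tolerance on the
  z-scored mean/sd is 1e-9.
- Logistic separation is detected via non-convergence, a singular Hessian,
  or a coefficient norm exceeding 20 on z-scored covariates.
- Subsample seeds: `base_seed + replicate_index`, all below 2^31.
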