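# Methods

This note documents the models and procedures `hrdkit` implements, the
choices made where the underlying methods are underspecified, and what
the synthetic-data generator does and does not emulate.

## Coordinate model

All coordinates are 0-based, half-open base pairs; file readers convert
on ingest. A genome build lists chromosomes with a single centromeric
interval; the p arm is `[0, cen_start)`, the q arm `[cen_end, length)`,
and the centromeric gap belongs to neither arm — probes and segments
inside it are ignored by all scoring. The bundled hg19 table (22
autosomes + X) carries arm boundaries from the standard cytoband
table's centromeric bands; acrocentric p arms are retained as-is. A
3-chromosome toy genome (200 Mb each, centromere at 95–105 Mb) serves
tests and examples. Chromosome X and acrocentric arms are included in
all counts by default — whether to exclude them is a configuration
choice, since the underlying definitions do not settle it.

## Shallow-WGS HRD (LGA counting)

Input is a normalized, binned linear copy-ratio profile (default 50 kb
bins). Log2 input is accepted via a reader flag and converted, so that
level-difference thresholds act additively on one declared scale.

**Segmentation.** Per chromosome, piecewise-constant least-squares
fitting with a constant per-breakpoint penalty. Up to 5,000 bins the
exact optimum is found with PELT (pruned dynamic programming, exact for
constant penalties); longer signals use greedy binary segmentation with
the same cost and stopping rule. The default penalty is
`3·σ̂²·log n` with σ̂ the MAD-based noise estimate from first
differences — insensitive to true level steps, and collapsing to a tiny
floor on noise-free signals so exact recovery is preserved.

**Per-profile cutoff.** The minimal level difference treated as a real
copy-number change is estimated as the first local minimum of a
Gaussian-kernel density estimate over all pairwise level differences of
large (≥ 10 Mb) segments — the valley separating noise-scale
differences from genuine CNA steps. When no valley exists (too few
large segments, or degenerate differences), the fallback is 3× the
median absolute deviation of within-segment bin residuals. The
valley-rule constants (512-point grid, default KDE bandwidth) are this
package's; the upstream method names the construct without specifying
it.

**Merging.** The adjacent same-chromosome pair with the smallest level
difference is merged repeatedly while that difference is below the
cutoff; the merged level is the n\_bins-weighted mean. Note that a
chain of segments can stop merging once the weighted mean drifts out of
range of its neighbour — iterative merging is a fixed-point procedure,
not transitive closure.

**LGA calls.** Per arm: segments are split at the centromere, arm
parts longer than 10 Mb (strict, reading "more than 10 Mb" literally)
are retained, and one LGA is counted per consecutive retained pair with
genomic gap < 3 Mb (strict) and level difference ≥ the cutoff. The gap
is measured end-to-start, so material dropped for being short still
separates its flanks; the excised centromere always exceeds the gap
bound, consistent with per-arm counting. Requiring the cutoff for a
break is an interpretive choice: without it every retained-segment
junction would count and inflate totals. Classification: > 20 LGAs ⇒
HRD, < 18 ⇒ HRP, 18–20 ⇒ borderline. Borderline profiles are flagged
for manual review and never auto-resolved; published re-scorings of
individual samples based on ploidy were judgment calls, not a rule, and
are not algorithmized.

**Probe thinning.** Dense array profiles are reduced to sWGS-like
density by keeping one uniformly chosen probe per 10 kb window per
chromosome, reproducibly under a seed.

## Allele-specific scar scores

Input: integer allele-specific copy-number segments (total = major +
minor, probe counts). Allelic balance is exact equality of major and
minor copy number — input is discretized upstream, so no tolerance is
applied.

**Smoothing (3 Mb).** Like-state neighbours separated by < 3 Mb are
fused, segments shorter than 3 Mb are removed, and fusion is applied
again. Fusing before removal keeps scores invariant under
state-preserving subdivision of a segment (the halves are reassembled
rather than discarded); the operation is idempotent.

**LOH** counts maximal runs of minor = 0 segments (gaps < 3 Mb) whose
span is ≥ 15 Mb but less than the chromosome's assayed extent. Runs are
chromosome-level (they may span the centromere if assayed continuity
allows), matching the definition's chromosome-level wording, and no
distinction is made between deletion and copy-neutral LOH.

**TAI** counts arms whose telomere-anchored run of imbalanced segments
(the run containing the outermost assayed segment) sums to more than
500 probes while the assayed segment nearest the centromere is
balanced. The centromere check uses the single nearest segment; no
window size is defined by the construct. The probe criterion is kept in
probe units because the source assay was array-based; an Mb-based
alternative is available for probe-free input.

**LST** counts consecutive retained (≥ 10 Mb, inclusive) arm-segment
pairs with gap < 3 Mb and different (major, minor) states, after
smoothing.

No HRD threshold is applied to the total — the score is used for
correlation and diagnostic analysis; a user-supplied cutoff flag exists
without a default.

## Tumour response

Volumes from perpendicular caliper diameters: V = a·b²/2 (a ≥ b).
ΔVol\_t = 100·(V\_t − V₀)/V₀ per measured day; RTV = V\_t/V₀.
BestResponse is the minimum ΔVol at t ≥ 14 d; BestAvgResponse is the
minimum over t ≥ 14 d of the unweighted mean of ΔVol over all measured
days from 0 to t, with the day-0 zero included (a literal reading of
"from t = 0"; `--exclude-t0` for sensitivity analysis). "Final volume"
is read as the time-indexed series, consistent with the best-average
construct it feeds. Mice without a day ≥ 14 measurement (e.g. early
sacrifice at the 2,000 mm³ ethical limit) are excluded and counted.
Model-level medians (mean-of-middle-two convention) of both metrics are
classified by the ordered, strictly-inequality rules CR → PR → SD → PD.
Measurement days need not align across mice; nothing is interpolated.

## RAD51 scoring

Foci counts per marker-gated nucleus arrive as a table; imaging is out
of scope. A cell is positive with more than 5 foci (strict; an
inclusive ≥ 5 flag exists because published wordings differ and the
data cannot settle it). A sample's score is the percent of
marker-positive cells that are positive, warning below 100 cells. A
model is HR-deficient when the unweighted mean over cisplatin-treated
xenografts is below 10% (strict); a cell-count-weighted mean is
available by flag. One published sentence inverts the positivity
direction ("less than 5 foci in less than 10% of cells"); it is
internally inconsistent with the positivity definition beside it, and
the figure-consistent reading (percent of cells with > 5 foci below
10%) is implemented.

## Variant filters

The WES cascade evaluates all rules and records every failure per
variant: alternative depth ≥ 2; alternative frequency ≥ 0.25; clinical
significance not benign; not synonymous; exonic or splicing; observed
in fewer than 5 distinct tumours cohort-wide (primary and PDX of one
model count separately); every population frequency ≤ 0.001; and fewer
than 3 of the 5 effect predictors voting a benign-vocabulary label
(Benign/Tolerated/Possibly damaging/Low/Medium/Neutral,
case-insensitive; missing predictions are not votes). The printed
depth/frequency sentence is conjunctive if read literally, which would
keep depth-1 calls at high VAF; the default treats the two minima as
independent filters, with the literal reading behind
`rule1_conjunctive`. The targeted-panel profile rejects on low VAF
(< 5%), low coverage (< 100×) or elevated 1000 Genomes frequency
(> 0.1%) — disjunctive by default, the literal "(low VAF or low
coverage) and high frequency" reading behind a flag. LOH is inferred
from VAF ≥ 0.7 (inclusive); the threshold is this package's default,
as none is published. The bundled cancer-census and DDR gene lists are
small synthetic placeholders (full lists are licensed or require live
ontology queries) and are user-replaceable text files.

## Fusion-derived deletions

Same-chromosome fusions whose partners or spanned genes include a DDR
gene become deletion candidates over the inter-breakpoint region.
Expression counts are depth-normalized by median-of-ratios size factors
(linear-space median of count/geometric-mean over genes positive in
every sample). The verdict requires (A) the candidate sample's region
gene-count sum at or below the 10th percentile of the same sum across
all samples, and (B) every region gene at or below the 10th percentile
of that gene's counts across the *other* samples — each clause read
literally with respect to including the candidate. Quantiles are
inclusive with linear interpolation. The region-sum reference is the
across-sample distribution; a within-sample window alternative was
rejected as size-confounded. Because the criteria are rank-based, a
non-deleted sample passes (B) by chance with probability ≈ 0.1^k for k
region genes — specificity rests on deletions spanning several genes.

## Association statistics

The two-sided Fisher exact test enumerates the hypergeometric
distribution over the observed margins and sums probabilities at or
below the observed table's (probability-mass ordering, relative tie
tolerance 1e-7) — the convention of standard statistical software;
degenerate margins return p = 1 with a warning. Sensitivity is the
biomarker-positive fraction among responders, specificity the
biomarker-negative fraction among non-responders; undefined
denominators yield "not available", never zero. The response grouping
(CR+PR+SD vs PD, or CR+PR vs rest) is always an explicit parameter.
Methylation percentages band as complete (≥ 90), partial (40–60) or
unmethylated (< 10); between-band values classify as partial with a
warning, because the observed data leave those ranges uncalibrated.
Mann–Whitney uses exact enumeration for tie-free samples with
min(n, m) ≤ 10 and the tie-corrected normal approximation otherwise.
Survival uses the product-limit estimator, KM-based medians (respecting
censoring), and the Gehan–Breslow–Wilcoxon test — the log-rank family
with number-at-risk weights — via lifelines' Wilcoxon weighting.

## Synthetic cohort generator

The study's per-sample data are access-restricted, so the generator
produces every input format with recorded truth. Its defaults encode
the study conditions: 55 models, HRD prevalence 30/55, response
probabilities per state calibrated so the expected cross-tab matches
the published table (HRD: CR/PR/SD/PD = 0.30/0.17/0.23/0.30; HRP:
0.04/0/0.28/0.68), LGA counts from a shifted Poisson (min 21, mean
≈ 30) for HRD and a capped Poisson (mean 8, max 17) for HRP, and scar
events scaled from the LGA count so one latent state drives both
scores. Randomness flows from one root seed through named substreams.

Copy-ratio profiles plant alternating 2.0/2.5 levels — each planted
junction is a qualifying break — with Gaussian bin noise (default SD
0.05, i.e. 10% of the step). Allelic profiles lay events out arm by
arm with ≥ 3 Mb unassayed separators so each event scores exactly once:
a balanced telomeric leader prevents accidental TAI, every arm ends
balanced at the centromere, and optional sub-threshold decoys (10 Mb
LOH, 300-probe TAI, 8 Mb LST pairs) exercise the thresholds. Growth
trajectories are exponential (control rates lognormal across mice) with
category-specific treated dynamics chosen to land safely inside each
classification box, multiplicative 10% measurement noise, 8 mice per
arm on a twice-weekly 42-day schedule, and truncation at the 2,000 mm³
ethical limit. Foci counts are Poisson mixtures (deficient mean 1,
proficient mean 9, 200 cells/sample). Variant tables plant exactly one
rule violation per record (or none); the expression generator plants
one deletion (six genes scaled ×0.01) with its matching fusion call.

What this does **not** emulate: GC/mappability structure, replication
timing or wave artefacts in real bins; subclonality and ploidy shifts
(the published manual 4N corrections exist precisely because of these);
correlated foci overdispersion; or annotation noise in variant tables.
Passing recovery tests therefore demonstrates correctness of the
scoring logic under the stated geometry, not robustness to every
artefact of real sequencing data.

## Problem sizes and numerical choices

The test suite and acceptance script run planted-recovery studies on
the toy genome (12,000 bins/profile; hundreds of profiles) and scar
studies on the full hg19 arm table; cohort power uses 300–500 simulated
cohorts of 55 models at the annotation level. The Fisher implementation
is verified against exact-integer enumeration for every margin-
consistent 2×2 table with N ≤ 60. Quantiles are linear-interpolation
inclusive; merge ties break toward the leftmost smallest pair; all
classification inequalities are strict exactly as printed.

At the generator's own response probabilities, the cohort-level
CR+PR-vs-rest association is detected in ≈ 97% of cohorts at the 0.05
level, while the broader CR+PR+SD-vs-PD association — whose expected
table sits near p = 0.007 — is rejected in ≈ 76–77% of cohorts; both
rates are recomputed, and the exact test stays conservative under the
null, in `scripts/acceptance.py`.

## Known limitations

Binary segmentation (used beyond 5,000 bins per chromosome) is greedy
and can mislocate breakpoints that PELT would place exactly. The KDE
valley rule can return a cutoff above the smallest true CNA step when
large-segment level diversity is poor; the residual-MAD fallback then
governs. TAI anchoring and the centromere-balance window are single-
segment interpretations of an array-era construct. The bundled gene
lists are placeholders and must be replaced for any real analysis.
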