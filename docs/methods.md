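# Methods

## The simulated experiment

`simdata` emulates a rapid TF-induction SLAM-seq study. The design is
6 harvests at (0, 0.5, 1, 2, 4, 8) h × 2 arms (induced, control) × 2
replicates. Each of `n_genes` genes occupies a 2 kb locus separated by 5 kb
flanks on chromosome-like contigs (25 genes per contig plus a 30 kb gene-free
tail for decoy peaks), with uniformly random base composition; the counting
window is the 3'-terminal 250 bp of the gene, strand-aware, mirroring the
3'-UTR-anchored quantification of SLAM-seq libraries.

### Kinetics

Per-gene transcription-rate profiles are step functions on the sampled grid;
continuous induction/decay curves are not modeled because only the
per-harvest labeled counts are observable. Responsive genes change by
`effect_size_log2` (default 1.0 — the magnitude of true transcription-rate
changes is a free simulator parameter, not a measured quantity) up or down
with equal probability. Immediate-early (IE) genes shift at an onset drawn
from {0.5, 1} h; the transient subclass reverts to baseline at every
t ≥ 2 h while the sustained subclass stays shifted. Delayed and secondary
onsets are drawn from {2, 4, 8} h and persist, so every harvest is populated
with first-responding genes. The control arm is flat for every gene, and
unresponsive genes are flat in both arms.

### Labeling chemistry

Within the 15-minute s⁴U pulse, degradation is neglected (pulse ≪ typical
mRNA half-life): the pre-existing RNA pool is steady while the nascent pool
scales with the transcription rate r, so per window the total read depth is
Poisson(`mean_depth` × ((1−f₀) + f₀·r)) and each read is labeled with
probability f₀·r / ((1−f₀) + f₀·r), where f₀ = `base_labeled_fraction`
(default 0.8). Consequently the expected labeled count is proportional to
`mean_depth`·f₀·r and the log2 fold change of labeled counts equals the
planted effect exactly. The default f₀ = 0.8 places the bulk per-T
conversion rate f₀·p_conv + background ≈ 2.1% inside the 1.5–3.5% band that
short s⁴U pulses produce in 3'-end libraries, with no-label controls near
0.03% — an order of magnitude under the 0.15% background ceiling such
experiments report.

Labeled reads gain T>C substitutions at convertible positions with
`p_conv` = 0.025 per position (reference T for plus-strand genes; reference
A→G for minus-strand genes, i.e. the transcribed-strand T); all reads gain
background substitutions at `p_err` = 0.001, uniform over the three
alternative bases. A fraction `snp_fraction` = 0.1 of windows carries a
planted homozygous-like variant, deliberately a T→C (A→G) at a convertible
position so it maximally stresses the variant filter. Reads span their
window exactly (read length = window length): alignment is out of scope, so
the simulator removes mapping ambiguity by construction.

### Occupancy

Every bound gene (IE and delayed classes) yields one peak with probability
`peak_detection_rate` (default 1.0; lower values emulate assay sensitivity
and produce IE-unbound/secondary misassignments on purpose). The peak
midpoint falls inside the strand-aware promoter window (−2,000/+500 bp
around the TSS) with probability `promoter_peak_fraction` = 0.612, otherwise
in the gene body at least 100 bp past the promoter edge. Secondary and
unresponsive genes never receive peaks. Optional decoy peaks land in
contig tails ≥ 12 kb from every TSS.

### Determinism

One master seed; per-purpose and per-sample child streams are derived as
`SeedSequence([seed, crc32(name)])`, so any sample can be regenerated
independently and byte-identically.

## Quantification

Variant masking pools mismatch counts across **all** samples of the
experiment (a SNP is a genotype property; pooling maximises power and keeps
the mask identical across contrasts): a position is masked when its pooled
mismatch fraction is ≥ 0.2 — the threshold is inclusive, stated so the
boundary is testable — at pooled coverage ≥ 10. Masked positions contribute
to neither the conversion numerator nor the T count of any read.

A read is *labeled* iff it carries ≥ 2 unmasked T>C conversions. With
`p_err` = 0.001 the chance of ≥ 2 background conversions in a 60-T window is
≈ 0.002, so no background subtraction is applied to labeled counts; the
no-label control conversion rate is reported diagnostically instead. The
per-window conversion rate is the unweighted mean over unmasked convertible
positions with coverage ≥ 1 of (conversions/coverage) — genomic T content
normalisation via per-position rates, each position one vote; windows with
no qualifying position report a missing rate, never 0. Reads only partially
overlapping a window (possible with external SAM input) are clipped to the
overlap; uncovered positions count toward nothing.

## Differential testing

Labeled counts are transformed to log₂-CPM, `log2((k + 0.5)/(L + 1)·1e6)`
with L the per-sample **total**-count library size. Gene-wise OLS uses the
group-means parameterisation over (arm × time) levels, d_g = n − #levels.
The empirical-Bayes step estimates (d₀, s₀²) by method of moments on
log s_g² — closed-form and deterministic, adequate at this scale (the
estimates match limma's `fitFDist` to 4+ digits; see the cross-check test).
When the excess variance of log s_g² is non-positive, d₀ = ∞ and every
moderated variance equals the ensemble mean variance. Zero-variance genes
are excluded from hyperparameter estimation but shrunk normally. Moderated
t is referred to a t distribution on d₀ + d_g df (normal when d₀ = ∞).

Significance per contrast: BH q < 0.05 **and** |log₂FC| > 0.5, both
configurable; the labeling-based assay does not come with published
thresholds, so these defaults are declared, not inferred. Two families are
computed per arm: each time vs 0 h (first-response timing is always read off
this family) and consecutive pairs (used to annotate rapid shut-off). No
precision weights are used: simulated depths are homoscedastic enough that
voom-style mean–variance modeling would be inert.

Note a design-level bias: CPM normalisation shifts log-ratios when many
genes respond in one direction (library inflation ≈ 0.16 log₂ units in the
40-per-class study). The |log₂FC| > 0.5 gate absorbs this for null genes and
the mean absolute recovered effect stays within 0.02 of the planted 1.0.

## Occupancy annotation

Each peak is assigned to the gene with the nearest TSS by **midpoint**
distance (summits are a peak-caller detail, out of scope), capped at
10 kb; equidistant ties break lexicographically by gene id so results are
independent of input order. Features: promoter if the signed distance d
(negative upstream) satisfies −2000 ≤ d ≤ 500; else gene body if the
midpoint is inside the gene span; else intergenic. A gene is *bound* given
≥ 1 assigned peak of any feature class — binary occupancy, not
promoter-restricted.

## Wave classification

Operating on the vs-0h significance matrix of the induced arm, after
removing genes significant anywhere in the control arm (a transparent
filter, rather than an arm × time interaction model):

- first significance at ≤ 1 h: IE_direct (bound) or IE_unbound (unbound);
  *transient* iff non-significant at every t ≥ 2 h, else *sustained*;
- first significance at ≥ 2 h: delayed_direct (bound) or secondary (unbound);
- no significance: unresponsive.

IE_unbound is kept distinct from secondary because early responders without
a detected peak may simply reflect occupancy-assay false negatives.
Direction is the log₂FC sign at the first significant time; later sign flips
are warnings, not classes. *Sustained* means significant at ≥ 2 time points
including one ≥ 2 h. Set overlaps (e.g. bound × regulated) use the exact
upper-tail hypergeometric distribution with BH adjustment across tested
pairs; the default universe is all genes with nonzero total counts.

## Problem sizes and what the tests show

The recovery study runs 200 genes × 24 samples at depth 200 (≈ 1M reads),
the promoter-recovery study 1,250 genes / 1,000 peaks, and the null
calibration 2,000 genes × 10 replicate simulations — sizes chosen so the
full suite exercises every stage end to end in well under a minute each.
Passing recovery tests show the pipeline is unbiased and correctly wired
**under the generator's assumptions**: uniform base composition, exact
window-length reads, step kinetics, position-independent error rates and
homoscedastic depths. They do not certify behaviour under real-data
complications — alignment artefacts, multimappers, 3'-bias, UTR annotation
error, overdispersed counts, batch effects — which are out of scope here.

## Known limitations

- No negative-binomial count model; at labeled counts ≳ 30 the log-CPM
  normal approximation is adequate, but very shallow data would need voom
  weights or a GLM.
- The control-arm filter discards genuinely TF-responsive genes that also
  drift in the control, rather than modeling the difference of differences.
- Variant masking needs pooled coverage ≥ 10; SNPs in very low-expressed
  windows can escape the mask and inflate that window's conversion rate.
- One peak per bound gene; multi-peak architectures and enhancer-range
  (> 10 kb) regulation are not simulated.
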