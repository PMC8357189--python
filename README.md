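# slamwaves

Temporal classification of transcription-factor target genes from
inducible SLAM-seq time courses.

## The problem

Occupancy assays (ChIP-seq, CUT&Tag) say where a transcription factor (TF)
binds, not which genes it actually regulates. A rapid-induction metabolic
labeling design closes that gap: the TF is fused to an ERT2 domain and
activated at t = 0 by 4-hydroxytamoxifen; at each harvest (0, 0.5, 1, 2, 4,
8 h) cells receive a short 4-thiouridine (s⁴U) pulse, and after alkylation
the s⁴U in nascent transcripts reads out as T>C conversions in sequencing
reads. Per-gene *labeled* read counts therefore track transcription rate at
each time point, and integrating their time course with occupancy separates
the TF's regulatory cascade into temporal waves:

| class | bound | first significant change |
|---|---|---|
| immediate-early direct (transient) | yes | 0.5–1 h, reverted by 2 h |
| immediate-early direct (sustained) | yes | 0.5–1 h, persists |
| delayed direct | yes | ≥ 2 h |
| secondary | no | ≥ 2 h (via an intermediary TF) |
| immediate-early unbound | no | 0.5–1 h (possible missed occupancy) |

`slamwaves` implements the full desk-scale pipeline plus a synthetic-study
generator with planted ground truth, so every stage is testable end to end:

- **simdata** — simulates the genome, counting windows, labeled reads
  (T>C chemistry with SNPs and background errors), occupancy peaks and truth;
- **slamquant** — variant masking (pooled mismatch fraction ≥ 0.2), strand-aware
  T>C counting, labeled-read calling (≥ 2 conversions), per-window conversion
  rates, the labeled/total count matrix;
- **difftx** — log₂-CPM, gene-wise OLS, empirical-Bayes moderated t with
  s̃²_g = (d₀s₀² + d_g s_g²)/(d₀ + d_g), BH-adjusted contrasts per time point
  (vs 0 h and consecutive), in both arms;
- **occupancy** — nearest-TSS peak assignment, promoter/gene-body/intergenic
  annotation, the per-gene bound table;
- **waves** — the wave classifier, bound-fraction summaries, exact
  hypergeometric set-overlap tests, and the `run_pipeline` orchestrator.

## Worked example

```python
import slamwaves as sw

cfg = sw.SimConfig(n_genes=200, mean_depth=200,
                   class_mix={c: 0.2 for c in sw.GENE_CLASSES}, seed=7)
res = sw.run_pipeline(cfg)
print(res.report["class_counts"])
print(res.bound_fractions.to_string(index=False))
```

prints

```
{'IE_direct_sustained': 41, 'secondary': 40, 'unresponsive': 40,
 'delayed_direct': 40, 'IE_direct_transient': 39}
 time_h  n_regulated  n_bound  bound_fraction
    0.5           39       39        1.000000
    1.0           41       41        1.000000
    2.0           22        6        0.272727
    4.0           25       19        0.760000
    8.0           33       15        0.454545
```

With 40 genes planted per class the classifier recovers 99.4% of responsive
genes exactly (`res.report["recovery"]["class_recovery_rate"]`), every
regulation direction, and zero confusions between direct and secondary
classes. The bound fractions are 1.0 at 0.5–1 h (every immediate-early gene
is a planted direct target here) and drop at later times where delayed
(bound) and secondary (unbound) genes mix. Mean per-window conversion rates
sit near 2% in labeled samples (`res.report["mean_utr_rate_by_sample"]`),
and the 20 planted SNPs are all masked
(`res.report["n_masked_positions"]`).

The same stages run from the shell:

```sh
slamwaves simulate --seed 7 --outdir sim/
slamwaves quantify --reads sim/reads --reference sim/reference.fa \
    --windows sim/windows.bed --samples sim/samples.tsv --out quant/
slamwaves difftx --counts quant/ --out difftx/
slamwaves annotate --peaks sim/peaks.bed --genes sim/genes.bed --out occ/
slamwaves classify --difftx difftx/ --occupancy occ/ --out classes/
```

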