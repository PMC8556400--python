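# hicdelta

Differential analysis of 3D genome architecture between two conditions —
for example a parental cell line against a knockout of a nuclear scaffold
protein, or an uninduced against a differentiated state.

Chromosome conformation capture (Hi-C) data resolve genome folding at three
scales, and perturbations of architectural proteins (CTCF, the cohesin
complex, nuclear-matrix factors such as Matrin-3) change all three:

* **A/B compartments** — the two-state partition of the genome given by the
  sign of the leading eigenvector (PC1) of the correlation-transformed
  observed/expected contact map; A (PC1 > 0, gene-rich) versus B. Changes
  are quantified on saddle plots: bins ranked by PC1, the obs/exp map
  coarse-grained into quantile blocks, and compartment strength measured as
  the ratio of homotypic to heterotypic corner means (A–A/A–B and B–B/A–B).
* **TADs and insulation** — the diamond insulation score (mean interaction
  in a 250-kb window sliding along the diagonal at 25-kb bins); boundaries
  are score minima with prominence > 0.1, merged across samples into a
  non-redundant set (greedy, 3-bin radius), turned into consensus domains
  (> 50% overlap with a reference TAD set, ≥ 6 bins), and tested per domain
  with a paired two-sided t-test on intra-TAD mean obs/exp with the double
  gate *p* ≤ 0.05 and |log2FC| > 0.15.
* **Loops** — focal contacts scored on distance-normalized interaction
  frequencies, IFnorm(i,j) = IF(i,j) / mean{IF over the same 10-kb distance
  class}, with the donut filter score(i,j) = P(i,j)/maxFlank(i,j); calls are
  calibrated against a distance-controlled permutation null, and
  differential loops flagged by a z-score on diff(score) = score_s1 −
  score_s2 (1.0 where a pixel is not a loop) at |z| > 1.5.

A fourth stage links chromatin binding to transcription: ChIP-seq samples
are normalized via flank-background size factors (median-of-ratios over
±10-kb peak flanks) and binomial downsampling, per-gene scores
s_g = Σ_c f_c / n_c aggregate the −log10 p of differential peaks mapping to
each gene (TSS ± 25 kb), and the ranked gene list is cut into ventiles whose
overlap with differentially expressed genes is tested with the minimum
hypergeometric (mHG) statistic and its exact p-value.

Because the full genome-scale datasets are impractical to re-derive at desk
scale, the package ships a first-class synthetic-data module that plants
recoverable structure — checkerboard compartments on a power-law distance
decay, TADs with tunable boundary insulation, focal loops, Poisson counts,
and a KO-like perturbation (A–A weakened, B–B strengthened, insulation
shallowed, a loop subset and weak ChIP peaks lost, DE genes enriched near
lost peaks) — so every stage is testable end to end against ground truth.

## Worked example

```python
from hicdelta import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, outdir="demo_run"))
c = report["compartments"]
print(f"A strength: {c['parental']['a_strength']:.2f} -> {c['ko']['a_strength']:.2f}")
print(f"B strength: {c['parental']['b_strength']:.2f} -> {c['ko']['b_strength']:.2f}")
print("boundary insulation change:",
      round(report["domains"]["boundary_insulation_change"], 2))
print("loops lost/gained:", report["loops"]["differential"])
```

prints (seed 1):

```
A strength: 2.47 -> 2.05
B strength: 2.48 -> 2.70
boundary insulation change: 0.23
loops lost/gained: {'n_lost': 9, 'n_gained': 12}
```

which is the planted knockout phenotype read back through the full
analysis: A-compartment interactions weaken while B–B interactions
strengthen, cross-boundary insulation weakens (the insulation minimum at
boundaries rises by ~0.23 log2 units), and the differential-loop stage
flags the dropped loops as "lost". The run directory holds every
intermediate (PC1 bedGraph, saddle TSVs, boundary/TAD tables, loop BEDPE,
gene scores, `report.json`).

The same pipeline is scriptable from the shell:

```bash
hicdelta run --seed 1 --outdir demo_run
hicdelta simulate --seed 1 --outdir demo_data
hicdelta domains --bins demo_data/bins.tsv \
    --triples demo_data/contacts_parental_rep1.tsv --out demo_domains
```

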