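# fishmet

Multidimensional metabolomics for drug studies in adult zebrafish: absolute
drug quantitation, whole-body ion imaging, in vivo ¹³C isotope tracing and
untargeted metabolome analysis, in one tested pipeline with a ground-truth
synthetic-data generator.

The package is aimed at metabolomics researchers who combine LC/MS and mass
spectrometry imaging to characterize biodistribution and pharmacodynamics
of a waterborne drug (here hydroxychloroquine, HCQ) in adult zebrafish —
and at methodologists who want the statistical behavior of such a pipeline
to be checkable against simulated data with known truth.

## What it computes

- **Quantitation** — internal-standard calibration (analyte/IS area ratio
  vs nominal concentration, OLS or 1/x² weighted), absolute concentration
  in extract, conversion to µg/mg tissue (40 µl/mg extraction rule) or
  µg/ml serum (1:15 dilution), pooled vs tissue-specific strategy
  comparison (a pooled curve needs 15 injections where 7 organ curves need
  105), replicate RSDs, steady-state assessment, ANOVA + Tukey across
  organs.
- **Isotope tracing** — binomial ¹³C natural-abundance correction
  (p = 0.0107) by non-negative least squares; a three-route model of NAA
  labeling from ¹³C₆-glucose in which NAA M+k = Σᵢ acetyl M+i · aspartate
  M+(k−i), with the acetyl pool `[1−c₂, 0, c₂]` and aspartate
  `[a₀, a₁, a₂, a₃, 0]` (a₃ is the pyruvate-carboxylase route: M+3
  aspartate → M+3 NAA); fractional labeling relative to each animal's
  serum glucose M+6; route-fraction inference with identifiability
  diagnostics; group comparisons per isotopologue.
- **Imaging** — imzML / pixel-grid TSV input, lockmass recalibration, ion
  extraction within a ppm window, per-pixel TIC normalization (zero-TIC
  voids flagged, not NaN), ROI statistics and rankings, PNG/TSV export.
- **Untargeted** — blank filtering, adduct/isotope degeneracy collapsing
  (mass-shift + co-elution + correlation), level-1 annotation (≤10 ppm and
  RT match), equal-variance t-tests with log2 fold changes and BH
  adjustment, per-organ significant counts, fold-change heatmaps, and an
  iterative two-sided Grubbs outlier test.
- **Synthetic data** — every input above, generated from explicit ground
  truth (see `docs/methods.md`).

## Worked example

```python
from fishmet import synthetic, workflow

cfg = synthetic.GeneratorConfig(seed=1)
bundle = workflow.run_study(workflow.RunConfig(generator=cfg,
                                               outdir="example_run"))
stages = bundle.summary["stages"]
print(stages["quant"]["organ_mean_concentration"])
print(stages["trace"]["inferred_pc_route"])
print(stages["image"]["roi_rank_normalized"][:3])
print(stages["untargeted"]["significant_counts"])
```

prints (abridged):

```
{'brain': 0.0393, ..., 'intestine': 0.1623, 'liver': 0.17, 'muscle': 0.041,
 'serum': 15.0641}
{'control': 0.101077, 'hcq': 0.150375}
['intestine', 'liver', 'brain']
{'intestine': 45, 'muscle': 36, 'kidney': 23, 'heart': 22, 'brain': 19,
 'liver': 16, 'eye': 15, 'fin': 14}
```

Reading this: quantified liver and intestine tissue concentrations
(~0.17 µg/mg) are ≈4× the other organs (~0.04 µg/mg), recovering the
generator's hepatic/intestinal accumulation pattern; serum comes out in
µg/ml after its dilution correction. The inferred pyruvate-carboxylase
route fraction rises from 0.10 (control) to 0.15 (treated) — the
generator's ground truth — and the drug-channel ROI ranking puts intestine
and liver on top. The per-organ significant-feature counts track the
configured perturbation sizes (intestine 40 > muscle 30 > …) plus the
expected ~5% false positives. `example_run/` holds the TSV tables, images,
`summary.json` (byte-identical under the same seed) and a rendered
`report.md`.

The same stages are exposed on the command line:

```sh
fishmet simulate --seed 1 --outdir sim
fishmet run --seed 1 --outdir run1
fishmet image sim/desi_grid.tsv --mz 334.1797 --normalize tic --out hcq
fishmet report run1
```

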