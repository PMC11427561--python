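# diame

Post-processing and evaluation toolkit for low-input DIA proteomics
experiments that co-analyze analyte samples with higher-input **matching
enhancer (ME)** runs to boost identification by match-between-runs (MBR).

For proteomics data analysts this package answers three questions about such
designs, using two-proteome entrapment benchmarks and synthetic data with
known ground truth:

* **How often does matching lie?** Per-replicate false-positive rate
  FPR = IDs_entrapment / IDs_total, and false-transfer rate

      FTR = (E_MBR − E_Indiv) / (T_MBR − T_Indiv)

  — the fraction of identifications *gained by matching* that hit the
  entrapment proteome, with the convention that a replicate losing human IDs
  while gaining entrapment IDs is assigned 100%. Plus protein-level FPR, ROC
  curves over any q-value column, and overlap/Jaccard set similarity.
* **Is quantification still accurate?** The prescribed workflow — q-value
  filtering, ME-run exclusion, shift-only re-normalization, ion-trace protein
  summarization — and the quality metrics around it: protein CVs, data
  completeness by abundance bin, deviation from expected spike ratios
  (log2(ρ_b/ρ_a) for the spiked species, log2((1−ρ_b)/(1−ρ_a)) for the base
  species), replicate correlation, PCA, dynamic range.
* **What do single cells co-express?** Two-sided t-test differential
  expression (p < 0.05, |log2 FC| > 0.95 defaults), kNN / minimum-value
  imputation, median-centred Z-scores, and protein co-variation: Pearson
  correlation of proteins observed in ≥ 20 cells with ≥ 20 pairwise
  observations, hierarchically clustered into co- and anti-correlating
  modules.

The synthetic generators (`diame.simulate`) emulate the two-proteome spike-in
design (5–20% w/w foreign proteome, 1–100 ng inputs, logistic detection,
true/false transfer injection) and single-cell matrices with planted
anti-correlated modules — every record carries a ground-truth label, so every
estimator in the package is testable end to end. See `docs/methods.md` for
the full model.

## Worked example

```python
import numpy as np
from diame import entrapment, filtering, quantnorm, simulate

cfg = simulate.SimulationConfig(
    seed=11, conditions=simulate.study_design(), false_transfer_prob=0.05,
)
table, ann, truth = simulate.simulate_two_proteome(cfg)
analyte = ann.loc[ann.role == "analyte", "run_id"].tolist()

est, n = entrapment.pooled_ftr(table, runs=analyte)
print(f"pooled FTR {est:.4f} over {n} gained IDs (injected 0.05)")

analyte_table = filtering.drop_me_runs(table, ann)
normalized, shifts = quantnorm.normalize_traces(analyte_table)
err = np.max(np.abs(-shifts[analyte] + shifts[analyte].mean()
                    - (truth.loading_log2[analyte] - truth.loading_log2[analyte].mean())))
print(f"loading recovery error {err:.3f} log2")
```

prints

```
pooled FTR 0.0503 over 35126 gained IDs (injected 0.05)
loading recovery error 0.018 log2
```

i.e. the FTR estimator recovers the injected 5% false-transfer rate within its
binomial sampling error, and after ME exclusion the normalization recovers the
per-run loading factors to within a hundredth of a log2 unit.

The numbered drivers under `analysis/` run the full story on generated data
(`01_simulate.py` → `04_single_cell.py`), writing their tables under
`results/`. A `diame` command-line interface wraps the same functions
(`diame simulate`, `diame entrapment`, `diame normalize`, `diame run-all`).

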