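# Methods

## Scope and model

This package post-processes long-format precursor report tables from
data-independent-acquisition (DIA) proteomics experiments in which low-input
samples are co-analyzed with higher-input *matching enhancer* (ME) runs so that
the software's match-between-runs (MBR) stage can transfer identifications into
the low-input data. Its three concerns are:

1. **Fidelity of matching**, assessed by a two-proteome entrapment design: a
   foreign proteome is spiked into (or co-analyzed with) pure human samples, so
   every foreign identification in a human-only replicate is a known error.
2. **Quantification** after the prescribed ME-exclusion + re-normalization
   order, with spike-ratio accuracy, CV, completeness, correlation/PCA and
   dynamic-range quality metrics.
3. **Single-cell statistics**: two-group differential expression, imputation,
   Z-scoring, and protein co-variation with cluster extraction.

Everything is exercisable on synthetic report tables with known ground truth;
no raw mass-spectrometry data is required.

## Entrapment statistics

Counts are distinct precursors per replicate, after excluding peptides shared
between the two proteomes and protein groups that mix species (we exclude mixed
groups rather than apply a majority rule — the conservative choice when the
group's species is ambiguous). With `E` entrapment and `T` total
identifications:

* **FPR** = `E / T` per replicate.
* **FTR** = `ΔE / ΔT`, where `Δ` is the difference between the
  matching-enabled and the matching-disabled (first-pass only) analysis of the
  same replicate: the fraction of identifications *gained by matching* that hit
  the entrapment proteome. Degenerate counts follow the convention that a
  replicate losing human identifications while gaining entrapment ones is
  assigned 100%; a replicate gaining nothing has no defined FTR and is reported
  as missing, excluded from means, and tallied. Values above 1 (possible with
  count differences) are clipped to 1 with a logged warning.
* **ROC** curves sweep every observed q-value as an acceptance threshold
  (keep if `q ≤ t`); human records are the positive class, entrapment the
  negative, and the AUROC is the trapezoidal integral. The curve is anchored at
  thresholds 0 and 1 so it runs from (0, 0) to (1, 1). The statistic is
  invariant under any strictly monotone transform of the q-value column.
* **Set similarity** between identification lists uses the
  Szymkiewicz–Simpson overlap coefficient `|A∩B| / min(|A|,|B|)` and the
  Jaccard index `|A∩B| / |A∪B|`.

## Filtering

Default precursor-level filtering keeps records with run-wise q ≤ 0.01, global
q ≤ 0.01 and global protein-group q ≤ 0.01. The run-wise protein-group q is
not part of the default set; when enabled, 0.05 is the recommended moderate
cutoff. Contaminants are removed by exact identifier match within the
semicolon-split protein group. Count-based single-cell filters: cells need at
least 500 observed proteins; proteins need at least 3 replicates per group
(mode `any` by default — a protein testable in one time-point is kept; `all`
is available) and, for imputed analyses, observation in at least 30% of cells.
"Identified" always means a non-missing intensity after q-filtering. All
filters only remove rows and are idempotent; ME-run exclusion must precede
normalization and the pipeline configuration rejects any other order.

## Normalization

Between-run differences in injected amount and loading are modelled as one
additive shift per sample in log2 space. The shift of sample *s* is estimated
against an anchor (the sample with the most observations) as the log2 ratio of
**summed linear intensity over the ions the two samples share**, and the shift
vector is then mean-centred so the dataset keeps its overall scale. Matching
total signal, rather than centring a median of per-ion ratios, is deliberate:
in a two-proteome mixture where the spike replaces a weight fraction ρ of the
base proteome, total mass is conserved across compositions, so shared-ion
totals reflect amount and loading only. Any quantile of the per-ion ratio
distribution instead locks onto the majority (human) species and would flatten
true between-condition ratios — the human log2(0.80/0.95) ratio between 5% and
20% spikes would be normalized away and the entrapment ratio inflated by the
same amount. A `method="median"` variant is provided for comparison, and the
estimator is pluggable should a published implementation be preferred.

The transform is shift-only (within-sample ion ratios are untouched), exactly
idempotent (a second pass yields shifts at floating-point zero), and fails
loudly for a sample sharing no ions with the anchor.

**Why ME rows must be excluded first:** ME runs carry roughly ten-fold the
analyte input and, being deeper, would become the anchor. The mean-centred
shift vector is then contaminated by the ME runs' ~log2(10) offset, and every
analyte quantity is dragged toward the ME scale — on synthetic data the
analyte loading-factor recovery error grows from under 0.05 log2 to about
1 log2. The pipeline therefore hard-codes ME exclusion before normalization.

## Protein summarization

Per protein, each ion's log2 trace is shifted by its median offset to the
protein's consensus trace (the per-sample median across ions) and the protein
value per sample is the median across aligned ions observed in that sample.
Alignment makes the between-sample profile robust to which ions happen to be
observed; the median damps single-sample outlier ions.

## Quantitative quality metrics

* **CV** per protein: sd (n−1) over mean of linear-scale intensities across
  replicate columns, requiring ≥ 2 observations (configurable).
* **Expected spike ratios** between conditions a and b at spike fractions
  ρ_a, ρ_b and amounts m_a, m_b: `log2(ρ_b/ρ_a) + log2(m_b/m_a)` for the
  spiked species and `log2((1−ρ_b)/(1−ρ_a)) + log2(m_b/m_a)` for the base
  species. Observed ratios use medians over replicates (mean by option);
  deviations are observed − expected per protein.
* **Completeness bins**: proteins ranked by median log2 intensity
  (descending, ties broken by identifier for determinism), split into six
  near-equal bins with remainder rows to the top; per-bin fraction of observed
  cells.
* **Sample correlation**: Pearson on pairwise-complete values with a minimum
  pairwise n of 10 by default (undefined below).
* **PCA**: restricted to fully observed proteins, rows mean-centred.
* **Dynamic range**: log10 of max over min median linear protein intensity.

## Single-cell statistics

Differential expression is a two-sided Student's t-test on log2 values with
pooled variance by default (Welch by flag), flagged at p < 0.05 and
|log2 FC| > 0.95 (both configurable; Benjamini–Hochberg correction available
but off by default, matching raw-p flagging). kNN imputation replaces a
missing cell by the mean of the k = 5 nearest protein rows (root-mean-square
distance over shared samples) that observe that sample; observed cells pass
through bit-exactly and rows without any overlapping neighbour stay missing.
It is hand-rolled rather than delegated to a library imputer because of
exactly those two contract points (no fallback fill, no modification of
observed cells). Minimum-value imputation fills with the dataset-wide lowest
observed intensity. Z-scores centre at the row median but divide by the
(n−1) standard deviation about the mean.

Co-variation restricts to proteins observed in ≥ 20 cells, correlates pairs
over their shared cells (Pearson, observed values only — never on imputed
data), and leaves pairs with fewer than 20 shared observations undefined.
Clustering is agglomerative (average linkage by default; single/complete/ward
available) on the Euclidean distance between correlation-profile rows, with
undefined cells treated as 0 — the neutral correlation — for the distance
computation only, never stored. The tree is cut at two clusters by default and
the leaf order is returned for heatmaps.

## Synthetic data

The two-proteome generator works at the report-table level (it does not model
chromatography, ion mobility or spectra). Per feature and run,

    log2 I = unit + log2(amount) + loading + log2(w/S) + base + N(0, σ)

with `w = 1−ρ` (human) or `ρ` (entrapment) and `S` the species' total feature
mass, so a sample's total intensity is proportional to amount × loading
irrespective of composition — the property the spike design gives real w/w
mixtures. Defaults mirror the study conditions: spike fractions 5–20%, inputs
1–100 ng (non-spiked 1-ng analytes, N = 7, with 10× MEs in the benchmark
design), ±30% uniform loading jitter. Desk-scale proteome sizes are 1500 human
and 400 entrapment proteins with geometric peptide counts (mean 8);
per-protein abundance is log-normal (sd 2.5 log2) with log-normal peptide
factors (sd 1.5 log2).

First-pass detection is Bernoulli with a logistic probability in realized log2
intensity; the midpoint default (34.5 on the generator's intensity scale) was
chosen so a 1-ng run identifies roughly half as many features as a 10-ng run,
a qualitative calibration only. Matching recovers analyte features that were
present but undetected and seen in an ME run with probability
`true_transfer_prob` (0.8); their reported intensity is the realized value
conditioned on non-detection, mirroring the slight low bias of recovered IDs.
`false_transfer_prob` (default 0.002, the scale reported for well-controlled
DIA software) is defined as the **expected fraction of matching-gained
identifications that are false**: the per-candidate leak probability is scaled
per run as `f/(1−f)·T/C` (T realized true transfers, C entrapment candidates)
so the pooled false-transfer rate converges to the configured value. q-values
are drawn marginally — Beta(1, 200) for genuine IDs, Uniform(0, 0.05) for
false transfers — so false identifications are not trivially separable by the
default filters; they are not a coherent FDR process, which is why
estimator-recovery properties are evaluated on unfiltered tables (filtering
intentionally depletes false transfers and measures a different quantity).

The single-cell generator plants two protein modules loading with opposite
sign on one latent cell-state score (strong internal correlation, mutual
anti-correlation), an independent treatment-responder set shifted by a
configurable log2 effect, and optional logistic detection. It does not model
cell-size confounding, batch structure, zero-inflation beyond the detection
model, or correlated noise, so passing recovery tests demonstrate estimator
correctness under the stated model, not robustness to every failure mode of
real single-cell data.

Both generators are deterministic given their mandatory seed (single
`numpy` Generator, fixed draw order).

## Numerical choices and limitations

* Problem sizes in tests and drivers (desk scale: ~10⁵ records, ≤ 10⁴
  proteins) are chosen so every analysis runs in seconds on one CPU; all
  recovery tolerances are derived from binomial/Gaussian sampling error at
  those sizes, not tuned.
* Ties in abundance ranking and neighbour selection are broken by identifier
  or stable sort order for determinism.
* Undefined values (FTR without gained IDs, correlations under the pairwise
  minimum, CVs with one observation, zero-variance Z-rows) are NaN, never
  silently filled; each source logs a count.
* The normalization estimator assumes the w/w replacement mixing model; for
  additive spikes the composition-invariance argument does not apply exactly
  (the error is bounded by log2(1+ρ)).
* The q-value model is marginal; analyses of the interplay between FDR
  estimation and matching are out of scope, as are the matching algorithms
  themselves — the generator emulates their output, not their mechanism.
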