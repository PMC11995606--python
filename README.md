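# cfpri — a continuous preeclampsia risk index from cell-free RNA profiles

Preeclampsia (PE) is a hypertensive pregnancy complication that is still
routinely diagnosed late. Circulating cell-free RNA (cfRNA) in maternal
plasma shifts measurably well before symptoms, which makes early-gestation
cfRNA profiles attractive for risk screening. `cfpri` implements a complete
pipeline that turns a genes × samples cfRNA abundance matrix with
normotensive (NP) and preeclamptic (PE) labels into a continuous
**Preeclamptic Risk Index (PRI)** per sample, anchored at 0 (ideal NP) and
1 (ideal PE).

The pipeline has four stages:

1. **Indicator selection.** A gene qualifies as a PE indicator when its
   NP and PE expression ranges are sufficiently distinct: genes with zeros
   in both groups are dropped, genes whose ranges overlap completely are
   dropped, the range-overlap rate (intersection length ÷ smaller range
   length) must fall below 0.6, and the group-mean fold change must reach
   1.5. Each surviving indicator *i* gets a direction:
   up in PE if avg(SP[i]) > avg(SN[i]), down otherwise, where SN/SP are
   the selected-gene expression matrices of the two groups.
2. **Range-constrained data synthesis.** For each of the *N* selected
   indicators, training values are drawn inside the observed envelope
   [min(SN, SP), max(SN, SP)] from a truncated Gaussian centred at the
   midpoint — M = 8000 training and Q = 500 validation profiles by
   default.
3. **Probability ground truth.** Each generated (or observed) profile
   column is mapped to a PE probability by a direction-aware min–max
   transform: y\_i = (x\_i − min x\_i)/(max x\_i − min x\_i) for up
   indicators, and the mirror image for down indicators. The PRI of a
   sample is the unweighted mean of its probability vector.
4. **Network regression.** A 1-D pyramid-pooling convolutional network
   (128 channels, stride-5 feature extractor, multi-bin max-pooled context
   branches upsampled by transposed convolution, logistic output) learns
   the mapping from raw expression vectors to probability vectors with
   Adam on mean-absolute-error loss (lr 5e-4, batch 16). CNN and MLP
   baselines with the same training surface support model comparison.
   The network engine (convolutions, batch norm, dropout, adaptive
   pooling, Adam) is implemented in NumPy within this package.

Evaluation reports two error families — the vector-level MAE of the
probability predictions and the PRI-level maximum-absolute /
peak-to-valley / mean-absolute errors — plus ROC/AUC and
precision/recall/F1 with PE as the positive class.

A seeded cohort simulator (`cfpri.simulate`) generates NP/PE cohorts with
a known injected indicator panel (log-normal background, fold-shifted
differential genes with controlled range overlap, zero inflation), so the
whole pipeline is testable end to end without any data download.

## Worked example

```python
from cfpri import (CohortSpec, simulate_cohort, PreeclampsiaRiskModel,
                   TrainConfig)

matrix, truth = simulate_cohort(CohortSpec(seed=7))   # 60 NP + 25 PE samples
model = PreeclampsiaRiskModel(
    matrix, train_config=TrainConfig(epochs=50, seed=7), M=2000, Q=200,
)
results = model.fit(seed=7)
print(results.summary())
```

prints

```
Preeclamptic Risk Index — pipeline fit
======================================================
window:                early
samples (NP/PE):       60/25
indicators selected:   18  (13 up, 5 down in PE)
architecture:          pspnet  (277309 parameters)
training:              M=2000, Q=200, epochs=50, seed=7
------------------------------------------------------
final validation MAE:  0.0201
vector MAE:            0.0480
calculated PRI means:  NP 0.256 / PE 0.652
predicted PRI means:   NP 0.268 / PE 0.668
PRI errors:            max 0.033, PV 0.036, mean 0.013
classification:        AUC 1.000, precision 1.000, recall 1.000, F1 1.000 @ threshold 0.598
======================================================
```

Reading the output: 18 of the 20 injected differential genes were
recovered as indicators; after 50 epochs the network predicts held-out
probability vectors to within 0.020 MAE; the predicted PRI tracks the
calculated (ground-truth) PRI to a mean absolute error of 0.013 per
sample; and thresholding the predicted PRI separates the simulated PE
from NP samples perfectly (AUC 1.0). `results.predict_pri(x)` scores new
samples; `results.plot_pri()` plots calculated vs predicted PRI.

The same pipeline is scriptable from the shell:

```bash
cfpri simulate --genes 200 --diff 20 --seed 7 --out cohort/
cfpri pipeline --cohort cohort/ --m 2000 --q 200 --epochs 50 --seed 7 --out run/
```

Every command writes a JSON manifest (configuration, seeds, input/output
SHA-256 hashes) next to its outputs.

For real data, `cfpri.read_matrix(matrix.tsv, sheet.tsv)` ingests a
delimited genes × samples table plus a sample sheet with `sample_id`,
`label` (NP/PE) and `window` (early = ≤12 gestational weeks,
mid = 13–20) columns; `read_series_matrix` accepts GEO series-matrix
text files.

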