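# Methods

## Problem setting

Scalp-EEG amplitude tables — one row per sample, one column per channel,
plus a timestamp and a derived continuous cognitive-state index — routinely
arrive with holes: electrodes disconnect, amplifiers clip, subjects move.
Deleting damaged rows wastes data; naive fills (zeros, column means)
destroy the cross-channel structure that downstream models rely on.
`eegimpute` fills the holes with a model that learns that structure, and
quantifies how much better it does than the naive fills, both directly
(against withheld truth) and indirectly (through a downstream forecaster).

## The iterative transformer imputer

The imputer treats each incomplete channel in turn as a regression target.

1. **Bookkeeping.** Every row receives an integer ID; the missingness mask
   is recorded; complete feature columns are moved to the left of the
   table and fully observed rows to the top (both partitions are stable).
2. **Chained loop.** Incomplete columns are processed in ascending order
   of missing-cell count (ties keep the original column order).  For each
   column, a fresh transformer regressor is trained on the rows where the
   column is observed, using the currently complete columns as predictors;
   the rows where it is missing are predicted and written into the table;
   the column — now complete — joins the predictor set of every later
   column.  Ordering by ascending missingness gives the early, easiest
   fits the most training rows and hands the hardest columns the richest
   predictor set.  A single pass is performed (no outer MICE-style
   iterations); an experimental outer loop was considered and rejected
   because a second pass changes predictions only marginally on correlated
   synthetic data while doubling the cost.
3. **Restore.** Rows are sorted back by ID and columns back to the input
   layout, so the output is a drop-in complete replacement for the input.

Degenerate columns are handled totally: a column with fewer than 20
observed values falls back to mean imputation (logged at warning level,
recorded in the trace), and a column that is constant where observed is
filled with that constant directly rather than through a degenerate
regression.

The loop requires at least one complete feature column (the first model
needs predictors) and at least one fully complete row.  Tables where every
feature column has gaps are rejected with a pointer to the baseline
imputers — chained imputation has no uncontaminated starting point there.

## The transformer regressor

One token per numeric feature.  Feature *j*'s scalar is embedded by its
own linear map into d_model dimensions, layer-normalised, and summed with
a fixed sinusoidal positional encoding indexed by column position
(`P[pos,2i] = sin(pos/10000^{2i/d})`, cosine on odd dimensions).  Column
order is the only canonical "position" a tabular row has; the encoding
mainly serves to make tokens distinguishable to the attention heads.

Each encoder layer applies multi-head scaled dot-product self-attention
(`SoftMax(QKᵀ/√d_k)V` per head, heads concatenated and projected by W_O),
a residual connection and LayerNorm, then a position-wise feed-forward
network `max(0, xW₁+b₁)W₂+b₂` with its own residual + LayerNorm.  The
token matrix is pooled to a single vector — mean pooling by default; max
and attention pooling are selectable — and a linear head emits the scalar
prediction.

Training standardises predictors and target by training-set statistics,
minimises MSE with Adam, holds out a validation fraction (10%) for early
stopping, and restores the best-validation weights.  All randomness
(initialisation, shuffling, dropout) derives from the config seed, so a
fit is bit-reproducible when run single-threaded.

Defaults: d_model 32, 4 heads, 2 layers, d_ff 64, dropout 0.1, lr 1e-3,
batch 64, ≤200 epochs with patience 20.  These sizes are deliberately
small: per-feature tabular regression with ~20 predictors saturates well
below language-model scale, and a fresh model is trained per column.

The networks are built on a small reverse-mode automatic-differentiation
tape over numpy arrays written for this package (`eegimpute.autodiff`);
every operation's gradient is validated against central finite differences
in the test suite.  Model arithmetic runs in float32 (the metrics and the
public closed-form oracles stay in float64).

## Baselines

* **Zero** — masked cells become 0.0.
* **Mean** — masked cells become the observed mean of their column.
* **KNN** — the distance between two rows is the nan-aware Euclidean
  distance `sqrt((d/|S|)·Σ_{s∈S}(a_s−b_s)²)` over the features S observed
  in both rows (scikit-learn's `nan_euclidean_distances`); features are
  z-scored from observed cells first so the index column's larger scale
  does not dominate.  Each masked cell takes the unweighted mean of its
  k (default 5) nearest donors — rows where that column is observed —
  with ties broken by smaller row ID for determinism.  Distances are
  computed on the original missingness pattern throughout.  A row sharing
  no observed feature with any donor falls back to the column mean,
  logged.

## Evaluation metrics

MAE, MSE, RMSE, MAPE and R² (=1−SSE/SST, unclipped, so a predictor worse
than the mean goes negative).  MAPE divides by the true value; EEG
amplitudes cross zero, so pairs with |y| ≤ 1e-8 are excluded and the
exclusion count is reported rather than silently dropped.  R² on a
constant truth is refused as an error, not returned as a number.

## Downstream LSTM verification

Imputation quality is also judged by proxy: an LSTM encoder–decoder is
trained to predict the cognitive-state index from the channel amplitudes
using only rows that were observed complete, then tested on the rows whose
gaps each method filled.  The "sequence" is the ordered list of channel
values within one row (the encoder walks across the montage, not across
time): train/test membership is defined row-wise, and a time-window
construction would straddle both sets.  The encoder's final hidden and
cell state initialise a single-step decoder via a repeat vector; a dense
head emits the scalar.  One forecaster is shared by all methods and the
test rows are identical across methods, so metric differences isolate the
imputed values.  Defaults: hidden size 32, 1 layer, lr 1e-3, MSE + Adam,
early stopping as above.

## Synthetic data generator

The generator emulates the tables the method is designed for without any
download.  Four latent band-limited sources (two sinusoids each with
frequencies drawn from 1–30 Hz plus AR(1) roughness, standardised) are
mixed into the channels by a random matrix with unit-norm columns; per-
channel Gaussian sensor noise (sd 0.05) is added and the result passed
through tanh, which guarantees amplitudes in (−1, 1) — matching normalised
EEG amplitude tables.  The cognitive-state index is an affine combination
of the channels rescaled so its realised range is [−2.03, 1.78], plus
Gaussian noise (sd 0.05).  With both noise levels at zero the index is an
exact affine function of the channels, which makes recovery analytically
checkable.  The timestamp advances at 1/256 s per row.

Missingness is injected by one of two mechanisms: **mcar** masks each
eligible cell independently at the configured rate; **burst** plants
contiguous per-channel runs with geometric lengths (a one-parameter
memoryless model of electrode drop-outs) until the target fraction is
reached.  Exempt columns (timestamp, index by default) are never masked;
the whole mask is redrawn (bounded retries) if fewer than the configured
floor of fully complete rows survives, because the pipeline and the
downstream verification both need complete training rows.  Every masked
cell's true value is retained, so imputations are scored on exactly the
cells that were removed.

What the generator does **not** emulate: volume-conduction head geometry,
artifact taxonomies (blinks, EMG), non-stationary seizure dynamics, or
informative missingness (gaps correlated with amplitude).  Passing tests
therefore show that the pipeline recovers strong cross-channel structure
under MCAR/burst loss — not that it handles physiological artifacts or
missing-not-at-random regimes.

## Benchmark scenario and problem sizes

The canonical benchmark (`bench.default_benchmark_config`) simulates
2000 rows × 19 channels and masks 10% of the cells of the even-numbered
channels, leaving the odd-numbered channels complete — the regime the
chained scheme is built for, where part of the montage drops out while
the rest keeps recording.  With ~9 incomplete channels this keeps roughly
a third of rows fully complete for the downstream forecaster.  For these
benchmark runs the transformer uses a lighter single-layer configuration
(lr 3e-3, batch 256, ≤25 epochs, no dropout) and the LSTM ≤40 epochs;
sizes were chosen so a full four-method benchmark completes in about half
a minute on one CPU core while leaving the comparative ordering stable
across seeds.

## Numerical choices

* LayerNorm epsilon 1e-5; softmax computed with a detached row-max shift.
* Forget-gate bias of LSTM cells initialised to 1 (state retention early
  in training).
* Feature/target standardisation guards against zero variance (scale 1).
* KNN neighbour ties broken by row ID; the imputation loop's per-column
  seeds are derived from the run seed by fixed offsets, so column models
  are independent but reproducible.
* Early stopping compares validation loss with a 1e-12 margin; the best
  snapshot is restored even when the epoch budget, not patience, ends
  training.

## Known limitations

* A single imputation is produced; no uncertainty intervals over imputed
  cells (multiple imputation is out of scope).
* Chained single-pass imputation can propagate early errors into later
  columns' predictor sets; the trace records per-column validation
  metrics so such degradation is visible.
* The transformer needs at least one complete feature column; fully
  gap-ridden tables must use the baselines.
* Sequence-across-rows (true temporal) forecasting is deliberately not
  used for verification; a `window` extension would require a different
  train/test split definition.
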