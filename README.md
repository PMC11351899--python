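# eegimpute

Transformer-based iterative imputation of missing values in EEG-amplitude
tables, with zero / mean / KNN baselines and downstream LSTM verification.

## The problem

EEG amplitude datasets — rows of per-channel amplitudes (normalised to
(−1, 1)) with a timestamp and a continuous cognitive-state index — lose
cells to electrode disconnections, artifacts and recording faults.
Simple fills (zeros, column means) ignore the strong cross-channel
correlation of scalp recordings and distort every analysis that follows.
`eegimpute` is for researchers who need those tables complete *and*
faithful: it fills each incomplete channel with a regression model that
learns the inter-channel structure, and it measures what that buys over
the naive fills.

## The method

Each incomplete channel f is imputed by a **tabular transformer
regressor**: every predictor feature becomes one token via a per-feature
linear embedding (plus LayerNorm and a sinusoidal positional encoding
P(pos,2i) = sin(pos/10000^(2i/d))), a stack of encoder layers applies
multi-head self-attention SoftMax(QKᵀ/√d_k)V and a position-wise ReLU
feed-forward network with residual + LayerNorm, the tokens are pooled,
and a linear head predicts f.  The model is trained with MSE + Adam on
the rows where f is observed and predicts the rows where it is missing.

Columns are processed in ascending order of missingness, and every
completed column joins the predictor set of the next — chained
imputation.  Row IDs assigned at the start restore the original order at
the end.  Three baselines (zero, mean, nan-Euclidean KNN) and a
five-metric report (MAE, MSE, RMSE, MAPE, R²) complete the comparison,
and an **LSTM encoder–decoder** trained only on originally complete rows
ranks the methods by how well it predicts the cognitive-state index from
each method's imputed rows.

A synthetic generator produces EEG-like tables (latent 1–30 Hz sources
mixed into tanh-squashed channels, index in [−2.03, 1.78]) with known
ground truth, so the whole pipeline is testable end to end without any
data download.  See `docs/methods.md` for the full model description.

## Worked example

```python
from eegimpute import (SyntheticConfig, MissingnessSpec, TransformerConfig,
                       generate_complete, inject_missingness, run_pipeline,
                       mean_impute, masked_evaluation)

complete = generate_complete(SyntheticConfig(n_rows=2000, n_channels=19,
                                             seed=1))
truth = inject_missingness(complete, MissingnessSpec(
    mechanism="mcar", rate=0.10, seed=104730,
    exempt_cols=("Timestamp", "Cognitive_State_Index",
                 *("Channel_%d" % j for j in range(1, 20, 2)))))

cfg = TransformerConfig(n_layers=1, dropout=0.0, lr=3e-3, max_epochs=25,
                        patience=6, batch_size=256, seed=224738)
imputed, trace = run_pipeline(truth.masked, cfg,
                              id_cols=["Timestamp", "Cognitive_State_Index"])

_, ours = masked_evaluation(truth, imputed)
_, naive = masked_evaluation(truth, mean_impute(truth.masked))
print(f"transformer: MAE {ours.mae:.4f}  RMSE {ours.rmse:.4f}  "
      f"R2 {ours.r2:.4f}  over {ours.n} masked cells")
print(f"mean fill  : MAE {naive.mae:.4f}  RMSE {naive.rmse:.4f}  "
      f"R2 {naive.r2:.4f}")
```

prints

```
transformer: MAE 0.0727  RMSE 0.0981  R2 0.9763  over 1794 masked cells
mean fill  : MAE 0.5696  RMSE 0.6378  R2 -0.0001
```

The transformer recovers the masked amplitudes with an error an order of
magnitude below the mean fill and explains ~98% of their variance; the
mean fill, blind to cross-channel structure, explains none.

The same workflow is available from the shell:

```bash
eegimpute simulate  --config cfg.yaml --out-dir sim/
eegimpute impute    sim/masked.csv out.csv --method transformer --config cfg.yaml
eegimpute evaluate  sim/complete.csv sim/heldout.csv out.csv
eegimpute verify    --original sim/masked.csv --imputed transformer=out.csv
eegimpute benchmark --config cfg.yaml --out-dir bench/   # all of the above
```

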