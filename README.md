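# adaptref

Adaptive reference ranges for longitudinal biomarker monitoring: personalised
intervals that update as new measurements accrue, against which each new
observation is judged normal or abnormal.

Two methods are implemented and compared:

* **Z-score method** (`adaptref.zscore`) — uses only the subject's own
  history. The standardised statistic for a new observation follows a
  Student t distribution with `n - 1` degrees of freedom *exactly* for iid
  Normal data, so the range `mean ± t_{1−α/2,n−1} · sd · sqrt(1 + 1/n)` has
  exact finite-sample coverage. Needs at least two prior observations, so
  flagging starts at the third occasion.
* **LMM method** (`adaptref.lmm`) — a random-intercept linear mixed model
  with subject-specific residual variances, fitted by an EM algorithm on a
  control population. The range centre is a precision-weighted (shrinkage)
  average of the population mean and the subject's history mean; ranges are
  available from the very first occasion.

On top of the two methods:

* `adaptref.simulation` — the data-generating model, the 36-scenario grid
  (12 within/between-SD ratios × 3 between-subject SDs), the
  false-positive-rate study comparing both methods, and a generator of
  hsCRP-like labelled fixtures (log-normal baseline with multiplicative
  spikes).
* `adaptref.evaluation` — sequential flagging of labelled series,
  sensitivity/FPR alpha sweeps stratified by context tag, audit-grade flag
  tables, and the leave-one-subject-out protocol (population parameters
  re-estimated excluding the subject under assessment).
* `adaptref.data_model` — long-format CSV/TSV I/O, streaming per-subject
  summaries, reference-range and flag types.

## CLI

```sh
# fit the population model on a control collection
adaptref fit --control control.csv --out model.json

# per-occasion ranges and verdicts
adaptref range --data data.csv --method zscore --alpha 0.05 --sided two
adaptref range --data data.csv --method lmm --model model.json --sided upper

# the false-positive-rate simulation study (config keys: alpha, master_seed,
# n_subjects_pop, n_sampled, n_control, ratios, between_sds, ...)
adaptref simulate --config sim.yaml --out-dir sim_results/

# sensitivity/FPR report for a labelled file
adaptref evaluate --data labelled.csv --methods zscore,lmm \
    --alphas 0.01:0.2:0.01 --sided upper --loo
```

Long-format input: columns `subject, occasion, value` plus optional
`label` (`normal`/`abnormal`/`unlabelled`) and `context` (e.g. `pre`/`post`);
column names are remappable and a `--log-transform` flag is available for
right-skewed biomarkers.

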