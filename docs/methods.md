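# Methods

## Model

For each target drug the forecaster operates on the drug's 2-hop
neighbourhood in the knowledge graph (the receptive field of a two-layer
GCN). A supervised sample at anchor week *t* consists of T_w = 16 weekly
snapshots; snapshot *s* carries, for every subgraph node, that node's demand
over the 16 weeks ending at snapshot *s*, left-zero-padded inside the sample
(causal padding). The target is the target drug's demand in week *t* + 1.

The forward pass per snapshot is a two-layer graph convolution over the
symmetrically normalised self-looped adjacency,

    Â = D′^(−1/2) (M + I) D′^(−1/2),      H^(l+1) = ReLU(Â H^(l) W^(l) + b^(l)),

followed by a clip that keeps only the target drug's row. The sequence of
clipped embeddings drives a single-layer LSTM; a bias-free dense layer with
ReLU maps the final hidden state to the forecast. ReLU in the head encodes
that demand is non-negative (and min–max scaling keeps training targets
non-negative, so the clamp is consistent rather than restrictive).

Three block-level conventions are fixed by exact parameter accounting at the
reference configuration (window 16, widths 64):

* the GCN layers carry biases: 16·64 + 64 = 1088 and 64·64 + 64 = 4160;
* the LSTM carries recurrent weight matrices and exactly **one** bias vector
  per gate: 4·(64·64 + 64·64 + 64) = 33,024. The two-bias dialect some
  frameworks default to would give 33,280 and is deliberately not used.
  Setting the recurrent matrices to zero recovers input-only gate equations
  as a special case, and a test asserts this;
* the head has no bias: 64, not 65.

Total: 38,336 trainable scalars, verified exactly by
`model_core.count_parameters` and the acceptance suite.

Everything is implemented in NumPy: batched forward over (B, T_w, N, F)
tensors, hand-written backpropagation (validated against central finite
differences at 1e−4 relative tolerance), and an in-package Adam optimizer
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8).

## Training protocol

* **Loss**: MSE over all samples; **optimizer**: Adam, full-batch by default
  (a `batch_size` knob enables mini-batching with seeded shuffling).
* **Early stopping**: validation loss evaluated each epoch with dropout off;
  an improvement is a decrease of at least 1e−8 (a float-noise guard); the
  best-validation weights are restored at the end. With a frozen model the
  loop stops after exactly `patience` epochs.
* **Defaults**: learning rate 0.001, hidden size 64, dropout 0.2 — the
  optimum of the grid {0.0001, 0.001, 0.005} × {16, 32, 64} × {0.1, 0.2,
  0.3, 0.5}, which `grid_search` explores scored by validation SMAPE (ties
  broken by enumeration order). Early stopping monitors validation *loss*
  while grid selection uses validation *SMAPE*; the two are intentionally
  distinct.
* **Dropout placement** (stated rate, unspecified placement): inverted
  dropout on each GCN layer output and on the final temporal representation,
  training only.
* **Initialisation**: uniform fan-in scaling U(−1/√fan, 1/√fan) for every
  block; all randomness (init, dropout, shuffling) derives from one seed via
  named `SeedSequence` streams, so runs are bit-reproducible.
* **Per-drug models**: one model per target drug. A shared-weights
  multi-target mode is out of scope.
* **Evaluation**: the last 8 weeks are the test set, the 4 preceding weeks
  the validation set, the rest training. Test weeks are scored as
  teacher-forced rolling one-step forecasts — each window uses true observed
  history (a recursive multi-step mode is not the default because the
  one-step protocol is the cleanest-defined reading of an 8-week test with
  a one-step head). Per-drug min–max scaling is fitted on training weeks
  only; predictions and targets are inverse-transformed before computing
  MAE/RMSE/SMAPE, so errors are in raw demand units. A SMAPE term with
  y = ŷ = 0 contributes zero.

### Desk-scale experiment sizes

Patience 500 with an epoch cap of 5000 is the faithful default
(`TrainConfig()`). The packaged experiments — the relational-signal recovery
test and `scripts/acceptance.py` — train each per-drug model full-batch for
at most 400 epochs with patience 80, chosen by observing that training loss
plateaus well before 400 full-batch Adam steps on the default panel
(~100 training windows per drug). The experiment panel is the simulator
default: 12 items / 120 weeks, 3 seeds per variant.

## Preprocessing choices

* **Weekly aggregation**: ISO-8601 weeks; the panel spans first-to-last
  transaction week; weeks without sales are zero demand (not missing data)
  and are flagged invalid in the mask.
* **History floor**: a drug needs ≥ 40 valid weeks (weeks with ≥ 1
  transaction) to survive. The boundary is *keep iff ≥ 40*: a 39-valid-week
  drug is dropped, a 40-valid-week drug retained. The threshold is
  configurable.
* **Outlier rule**: within a 16-week window (the same length as the sample
  window — the least arbitrary tying of the two constants), any value
  deviating from the window mean by more than 3 population standard
  deviations is replaced by the mean of the *original* window values.
  Windows slide with stride 1 in a single left-to-right sweep; the first
  window to flag a value supplies its replacement; a constant window (sd 0)
  never fires. By default the correction is applied per sample at assembly
  time, so no window statistic ever crosses the train/test boundary.
  The rule is invariant under the affine min–max scaling, so the order of
  scaling and correction does not matter.
* **Snapshot construction**: causal left-zero padding within the sample is
  the default; a `causal_padding=False` switch makes snapshots reach back
  into raw history (the sample then spans 31 raw weeks). Both readings have
  the same per-snapshot feature width of 16 and therefore identical
  parameter counts.
* **Minimum panel length**: 16 (window) + 1 (target) + 4 (val) + 8 (test)
  = 29 weeks; shorter panels raise an error naming the minimum.

## Ablation variants

`build_variant` exposes: GCN depth 1/2/3 with clip retained; a no-clip
variant that mean-pools node embeddings per snapshot (sum pooling is also
available — the aggregation for "keep all nodes" is genuinely open and the
choice is exposed rather than hidden); LSTM widths 16/32/64; an LSTM-only
model reading the target's raw 16-week window; a KG-GCN-MLP that replaces
the LSTM with a one-hidden-layer 64-unit perceptron reading the final
snapshot's clipped embedding; and a single-node GCN-LSTM whose graph is just
the target (assembled with hop 0), isolating the contribution of the
knowledge-graph *data* from the architecture.

## Synthetic data

The simulator emulates the mechanisms the knowledge graph encodes, with
defaults acting as the reference study conditions (12 items of which 2 are
devices, 3 ATC groups, 2 cross-group DDI pairs, 120 weeks, seed 0):

* **Group seasonality**: each ATC group's demand is
  base·(1 + a·sin(2πt/52 + φ))·exp(ε), base ~ U(120, 320) units/week,
  amplitude a = 0.3, ε ~ N(0, 0.08²).
* **Substitution**: within-group market shares follow a logistic-normal
  random walk (step 0.06); one drug's gain is its substitutes' loss.
* **Co-prescription**: each DDI pair shares an additive latent demand
  component κ·pair_base·(1 + 0.5·sin)·exp(N(0, 0.3²)) added to both
  endpoints; κ = 2 by default, putting the shared component on the same
  order as a drug's own demand so the relational signal is identifiable.
* **Observation noise**: negative-binomial with dispersion r = 8 (demand is
  a count; Gaussian noise would allow negative demand); r = 0 switches noise
  off for degenerate-limit tests.
* **Defects**: outliers with probability 0.01 per cell (multiplier
  U(3, 6)), missing weeks with probability 0.02, and one late-launching
  drug with ~30 active weeks so the 40-week floor is always exercised.
* **Devices**: independent seasonal AR(1) count series, isolated nodes.
* An `independent_demand` switch keeps the catalog's group structure (so the
  graph still has edges) but gives every drug its own independent curve —
  the control condition in which the graph carries no signal.

`emit_transactions` decomposes each weekly quantity into 1–4 dated
transactions that sum exactly to the cell, so weekly aggregation inverts the
decomposition bit for bit.

What the simulator does **not** emulate: price and promotion effects,
holidays, epidemic shocks, catalog churn beyond one late launch, or
calibration to any real pharmacy's demand moments. Passing tests therefore
demonstrate that the pipeline recovers relational signal *of the kind
simulated*, not performance on real sales data.

## Numerical conventions

* Min–max scaling of a constant series maps to all-zeros; the inverse
  restores the constant. Values outside the fit range may scale outside
  [0, 1], which is intentional.
* Oracle tests compare at 1e−6 relative tolerance; adjacency-normalisation
  oracles at 1e−8.
* Degree after self-loops is ≥ 1, so Â is always finite; its eigenvalues lie
  in [−1, 1] (asserted spectrally in tests).
* Checkpoints round-trip every weight block bit-exactly through `.npz`
  archives with an embedded JSON config snapshot.

## Known limitations

* Per-drug models make the method O(drugs) in training cost; the NumPy
  implementation favours transparency and reproducibility over speed.
* The clip discards non-target embeddings rather than attending over them;
  drugs more than 2 hops away never influence a forecast (by construction).
* Univariate input: no exogenous covariates (weather, holidays, epidemics).
* The graph is static; relations do not change over the forecast horizon.
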