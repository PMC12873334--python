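# kgdemand

Knowledge-graph-enhanced forecasting of weekly pharmaceutical demand.

Pharmacy demand for one drug is rarely independent of other drugs: therapeutic
substitutes (same ATC level-4 chemical subgroup) compete for the same demand,
and co-prescribed drugs (drug–drug interaction pairs) move together. `kgdemand`
implements a hybrid forecaster that feeds this relational prior into a
sequence model:

1. **Drug knowledge graph** — nodes are catalog items; an edge links two drugs
   that either share the first five characters of their ATC code
   (*substitution*) or appear together in a DDI table (*combination*). Both
   relations carry uniform weight 1; devices without chemical properties stay
   isolated nodes.
2. **Clipped graph convolution** — for a target drug *A*, its 2-hop subgraph
   adjacency *M* is self-looped and symmetrically normalised,
   *Â = D′^(−1/2)(M + I)D′^(−1/2)*, and two GCN layers
   *H^(l+1) = ReLU(Â H^(l) W^(l) + b^(l))* embed each node's 16-week demand
   history into 64 dimensions. A *clip* then keeps only row *A* of the output,
   so the temporal model sees a single KG-contextualised representation.
3. **LSTM + head** — the 16 weekly snapshot embeddings drive a single-layer
   LSTM (hidden size 64, standard forget/input/candidate/output gates with
   recurrent weights and one bias per gate); a bias-free dense layer with ReLU
   maps the final hidden state to the non-negative one-step forecast
   ŷ_{t+1}.

Training minimises the MSE loss with Adam, full-batch, with patience-based
early stopping on a chronological validation split; evaluation reports MAE,
RMSE and SMAPE (symmetric denominator (|y|+|ŷ|)/2) on the final 8 weeks as
teacher-forced rolling one-step forecasts. At the reference configuration the
trainable parameter counts are exactly 1088 (GCN layer 1), 4160 (GCN layer 2),
33,024 (LSTM) and 64 (head) — 38,336 in total.

Because real pharmacy sales data are proprietary, the package ships a
synthetic pharmacy-sales simulator whose generative structure (group
seasonality, within-group share competition, shared co-prescription demand,
negative-binomial count noise, outliers, missing weeks) exercises exactly the
mechanisms the knowledge graph is meant to exploit. All neural components are
implemented in NumPy with hand-written backpropagation; everything is
deterministic under a seed.

## Worked example

```python
from kgdemand import SimConfig, TrainConfig, generate_dataset, run_experiment
from kgdemand.preprocessing import filter_min_history
from kgdemand.workbench_io import build_graph

data = generate_dataset(SimConfig())            # 12 items, 120 weeks, kappa = 2
graph = build_graph(data.records, data.ddi_pairs)
panel = filter_min_history(data.panel)          # drops the short-history drug
print(f"{graph.n_nodes} nodes, {len(graph.relation_labels)} related pairs; "
      f"{len(panel.drug_ids)} drugs survive the 40-week filter")

config = TrainConfig(max_epochs=400, patience=80)
report = run_experiment(panel, graph, ["D0001"], config, seeds=[0, 1, 2])
print(f"D0001 test metrics over 3 seeds: "
      f"MAE {report.mae:.2f} ± {report.mae_std:.2f}, "
      f"RMSE {report.rmse:.2f} ± {report.rmse_std:.2f}, "
      f"SMAPE {report.smape:.2f}% ± {report.smape_std:.2f}")
```

prints

```
12 nodes, 14 related pairs; 11 drugs survive the 40-week filter
D0001 test metrics over 3 seeds: MAE 21.77 ± 0.56, RMSE 27.03 ± 0.50, SMAPE 39.03% ± 0.75
```

The 14 related pairs are the substitution pairs inside the three ATC groups
plus the two cross-group DDI pairs. D0001's demand averages roughly 60 units
a week under negative-binomial noise, so an MAE of ~22 units and SMAPE of
~39% reflect a forecast tracking the seasonal/share signal down to the noise
floor; the ± values are the spread over three independent training seeds.

A command-line interface chains the stages end to end:

```bash
kgdemand simulate   --seed 0 --data-dir data          # write synthetic CSVs
kgdemand build-graph --data-dir data --out out        # edges.csv + adjacency.mtx
kgdemand preprocess  --data-dir data --out out        # weekly panel + split
kgdemand train       --data-dir data --out out        # per-drug checkpoints
kgdemand evaluate    --data-dir data --out out        # metrics.json / .csv
kgdemand ablate      --data-dir data --out out        # variant comparison table
```

Every artifact is stamped with a hash of (config, seed); identical inputs
reproduce identical outputs byte for byte.

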