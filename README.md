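# cpannet

Counter-propagation neural-network workflow for multiclass QSAR
classification, built around the three-class P-glycoprotein (P-gp) problem:
deciding whether a compound is a P-gp **inhibitor**, a **substrate**, or
**non-active**, from a table of numeric molecular descriptors. P-gp is an
ATP-driven efflux transporter that shapes the ADMET profile of drug
candidates; distinguishing its substrates from its inhibitors — not merely
active from inactive — matters for drug–drug-interaction risk and for
multidrug-resistance reversal, and is hard because both classes bind the
same promiscuous site.

The package is aimed at cheminformaticians who have a curated
compounds × descriptors table (the descriptors themselves are assumed
precomputed) and want the complete, reproducible model-building chain:

* **Preprocessing** — autoscaling x′ = (x − x̄)/s_x, low-variance filter
  (SD < 10⁻⁴), pairwise-correlation filter (|r| ≥ 0.95), and SOM-based
  descriptor reduction (7×7 map on the transposed matrix, two descriptors
  kept per occupied neuron).
* **SOM engine** — Kohonen map on a square non-toroidal grid: winner
  c = argmin_j Σ_i (x_i − w_ji)², triangular neighbourhood update
  Δw_ji = η(t)·a(D_c−D_j)·(x_i − w_ji), learning rate
  η(t) = (a_max − a_min)(t_max − t)/(t_max − 1) + a_min.
* **Structure-driven splitting** — training / test / validation partitions
  drawn cluster-by-cluster from the Kohonen top-map (defaults reproduce a
  1786/341/385 partition of 2512 compounds).
* **CP-ANN classifier** — a supervised output layer over the Kohonen grid,
  updated toward one-hot class targets with the same neighbourhood factor
  (Δu_kj = η(t)·a(D_c−D_j)·(y_i − u_kj)); class scores live in [0, 1] with a
  0.5 membership threshold.
* **GA descriptor selection** — steady-state genetic algorithm (95
  chromosomes, 150 generations, 20 survivors, 2% mutation) with the wrapper
  fitness MCC_TR × MCC_TE.
* **Evaluation** — per-class sensitivity, specificity, precision and MCC,
  plus the class-balanced global indices NER (mean sensitivity) and AvPr
  (mean precision).
* **Applicability domain** — per-compound Euclidean distance to the winning
  neuron, a max-distance boundary taken from the test set, and an
  uncertainty zone around the 0.5 threshold.

A synthetic-data generator produces labelled descriptor tables with the
statistical structure this chain assumes (separated informative columns,
noise, |r| ≥ 0.95 redundant copies, near-constant columns, realistic class
imbalance), so the whole pipeline is testable without any proprietary
descriptor software. The published validation-set confusion matrices of the
reference P-gp classifier ship as exact fixtures. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import cpannet as cp

# a synthetic three-class table: 8 informative descriptors (3-SD class
# separation), 10 noise, 4 redundant, 3 near-constant; 118/48/86 compounds
spec = cp.SyntheticSpec(n_per_class=(118, 48, 86), n_informative=8,
                        n_noise=10, n_redundant=4, n_constant=3,
                        separation=3.0, seed=41)
data = cp.generate_dataset(spec)

config = cp.PipelineConfig(
    split_rows=10, split_cols=10, split_epochs=25,
    reduction_rows=4, reduction_cols=4, reduction_epochs=30,
    ga=cp.GAConfig(population_size=8, generations=6, survivors=3,
                   grid_rows=7, grid_cols=7, epochs=30),
    final_rows=12, final_cols=12, final_epochs=100,
    seed=17, outdir="example_run",
)
artifacts = cp.run_pipeline(config, data)
print(artifacts["reports"]["V"].to_text())
```

prints

```
class           TP    FP    FN    TN     Sn%     Sp%     Pr%    MCC
inhibitor       17     0     0    22   100.0   100.0   100.0   1.00
substrate        7     0     0    32   100.0   100.0   100.0   1.00
non_active      15     0     0    24   100.0   100.0   100.0   1.00
NER = 100.00%   AvPr = 100.00%   n = 39
```

Per class, the row gives the one-vs-rest confusion counts and the derived
sensitivity, specificity, precision and Matthews correlation coefficient on
the held-out validation partition (39 of the 252 compounds; the partition
was fixed on the top-map before any model construction). NER and AvPr are
the arithmetic means of the per-class sensitivities and precisions — at a
3-SD class separation the selected CP-ANN classifies the held-out partition
perfectly. `example_run/` additionally holds the split, the descriptor
reduction report, the GA history, the serialized model, per-partition
prediction tables and the applicability-domain assessment, plus a manifest
with every stage seed.

The same workflow is scriptable from the shell:

```sh
cpannet simulate data.csv --n-per-class 118 48 86 --separation 3 --seed 41
cpannet run config.yaml --input data.csv --outdir run/
```

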