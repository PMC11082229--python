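# deabench

Benchmarking and ensemble inference for proteomics differential expression
analysis (DEA) workflows.

## The problem

Detecting differentially expressed proteins from a protein × sample
expression matrix involves a chain of choices: which expression-matrix type
to use (spectral counts, topN, MaxLFQ, directLFQ, TMT abundance / ratio /
reporter intensities), how to normalize, how to impute missing values, and
which statistical test to apply. Each combination — a *workflow* within a
*quantification setting* (platform + acquisition mode, e.g. FragPipe on
label-free DDA) — can report a substantially different differential
proteome. `deabench` is for computational proteomics researchers who want
to compare workflows against spike-in ground truth, discover which option
combinations are shared by high- or low-performing workflows, and combine
several workflows' results into one ensembled inference.

## What it computes

**Five-metric benchmark.** Against a ground-truth table (which proteins are
truly differential, at what log2 fold change), a workflow's result is scored
by partial AUC of the ROC built from per-protein confidences 1 − q at
FPR caps 0.01 / 0.05 / 0.1 (raw areas), the normalized Matthews correlation
nMCC = (MCC + 1)/2, and the G-mean = √(specificity × recall). A protein is
called differential when |log2FC| ≥ log2(1.5) and q < 0.05, with q the
Benjamini–Hochberg-adjusted p-value.

**Rank aggregation and performance levels.** Per metric, workflows are
ranked (average ties); the final rank is the mean of the five ranks:

    rank_final = (rank_pAUC(0.01) + rank_pAUC(0.05) + rank_pAUC(0.1)
                  + rank_nMCC + rank_Gmean) / 5

Workflows at top 5% / 5–25% / 25–50% / 50–100% of positions get levels
H / RH / RL / L (ceiling-rule boundaries), and ranking_score = N − position.

**Pattern mining.** Workflows are encoded as itemsets of `step=option`
items and mined with FP-growth for frequent patterns (support ratio ≥ 0.1
by default) within the H or L level.

**Validation.** Leave-one-dataset-out cross-validation (Spearman
correlation of workflow ranks between held-out and remaining datasets) and
a Kruskal–Wallis check of rank sensitivity to dataset groupings.

**Ensemble inference.** Member workflows' p-values are combined per protein
by the hurdle model (Σ Φ⁻¹(1−pᵢ)² ~ χ² on t df, t = members observing the
protein; t = 1 returns the lone p), Fisher's method (−2 Σ ln pᵢ ~ χ² on 2t
df), or min / max / median voting; the log2FC of largest magnitude is kept;
combined p-values are BH-adjusted. `ens_multi_quant` combines the best
workflow per quantification view, `ens_topk` the global top-k workflows.

**Spike-in simulator.** A seeded generator of multi-view spike-in datasets:
latent log2 abundances, known spiked fold changes, replicate noise,
correlated quantification views, and intensity-dependent (MNAR) dropout
calibrated to platform-typical missing rates (DDA ≈ 17%, DIA ≈ 3%,
TMT ≈ 0.2%).

## Worked example

```python
import deabench as db

cfg = db.SimulationConfig(n_proteins=2000)          # 10% DE at |log2FC| = 1
ds = db.simulate_spikein(cfg, seed=7)
print("missing rate (dlfq view):", round(db.missing_rate(ds.views["dlfq"]), 3))

spec = db.WorkflowSpec("generic", "dlfq", "none", "MinProb", "modt")
res = db.run_workflow(ds.views, spec, ds.design, seed=7)
mv = db.metric_vector(res, ds.truth)
print("pAUC(0.1) =", round(mv.pauc01, 4))
print("nMCC      =", round(mv.nmcc, 4))
print("G-mean    =", round(mv.gmean, 4))
calls = db.call_de(res)
print("DE calls:", int(calls.sum()), "of", len(calls))
```

prints

```
missing rate (dlfq view): 0.172
pAUC(0.1) = 0.0839
nMCC      = 0.9362
G-mean    = 0.8883
DE calls: 160 of 2000
```

The simulated directLFQ-like view realizes the 17% DDA-typical missing
rate. The workflow (directLFQ view, no normalization, MinProb imputation,
moderated t) reaches pAUC(0.1) = 0.084 — close to the 0.1 ceiling and ~17×
the 0.005 of a random ranker — and recovers 160 of the 200 spiked proteins
at the default thresholds with high specificity (nMCC 0.94).

The same pipeline is scriptable from the shell:

```sh
deabench simulate --seed 7 --out data/
deabench run --matrices data/ --design data/design.tsv \
    --workflow "dlfq|none|MinProb|modt" --seed 7 --out res.tsv
deabench benchmark --grid grid.txt --n-datasets 3 --seed 3 --out results/
deabench mine --ranking results/ranking.tsv --level H --min-sr 0.1 --out patterns.tsv
```

## Layout

- `src/deabench/core.py` — data model, TSV I/O, option registry, contrasts
- `src/deabench/preprocess.py` — normalization and imputation operators
- `src/deabench/stats.py` — DEA statistics, BH, DE calls, workflow runner
- `src/deabench/evaluate.py` — metrics, ranking, levels, LODOCV, comparisons
- `src/deabench/mining.py` — FP-growth over workflow option itemsets
- `src/deabench/ensemble.py` — p-value / log2FC combination, orchestrators
- `src/deabench/simulate.py` — spike-in simulator
- `src/deabench/bench.py` — grid runner and report writer
- `docs/methods.md` — models, assumptions, parameter choices, limitations
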