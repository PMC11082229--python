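# Methods

This note documents the models, numerical choices and limitations behind
`deabench`, in the order the method runs.

## Data model and conventions

Expression matrices are protein × sample tables with a single missing-value
sentinel (NaN). For intensity-type matrices a stored zero means "not
quantified" and becomes missing on read and on log transform; for spectral
counts zero is a valid observation (counts are log-transformed with a +1
offset when an intensity-style test is applied to them). The log2FC sign
convention is mean(group A) − mean(group B). Protein identifiers are opaque
strings; a configurable delimiter (default `;`) marks multi-protein groups.

The option registry is declarative and user-editable. It ships the matrix
types each quantification setting actually provides (five for label-free
DDA, four for DIA, three for FragPipe-TMT, one for MaxQuant-TMT) plus the
built-in normalization/imputation/test options and named plugin slots
(vsn, bpca, mice, missForest, GMS, QRILC, MLE, nbavg, Impseqrob, and the
third-party DEA tools). Plugin options are registered but flagged
unavailable until an implementation is supplied via `register_plugin`; the
shipped registry therefore does not reproduce any particular published
grid cardinality, but can be edited to do so. Compatibility is enforced
declaratively: count-based statistics pair only with counts matrices,
intensity statistics only with intensity matrices.

All emitted orderings (contrast lists, rankings, mined patterns) are
deterministic, with lexicographic tie-breaks, so identical inputs and seeds
reproduce byte-identical outputs.

## Normalization

All scaling corrections are per-sample (column-wise), since normalization
targets cross-sample bias. Scaling methods (`div.mean`, `div.median`,
`total`/`sum`/`TIC`, `max`) act on the raw intensity scale; centering and
regression methods (`center.mean`, `center.median`, `Rlr`, `lossf`) act on
log2 intensities. The workflow runner orders the stages accordingly.

Quantile normalization interpolates each sample's observed empirical
quantile function onto a common grid; the reference distribution is the
per-quantile mean (`quantiles`) or median (`quantiles.robust`); observed
values are replaced by the reference at their average-rank quantile, so
missing entries are skipped and tied values map identically. `MBQN` is
quantile normalization followed by restoring each sample's original mean
(the mean-balanced variant).

`Rlr` and `lossf` regress each sample on the row-median reference profile
(Huber robust line, or a lowess curve with span 2/3) and subtract the
fitted *systematic deviation* fit(ref) − ref rather than the full fitted
line: subtracting the whole fit would zero-center every sample and discard
the intensity scale, while subtracting the deviation is the identity for a
sample that already matches the reference and preserves per-protein group
differences. Normalization never creates or destroys missing values.

## Imputation

`MinDet` fills each sample's missing cells with that sample's q-th observed
quantile (default q = 0.01); `MinProb` draws from a normal centred there
with sd = tune × median per-protein observed sd (defaults tune = 1, floor
1e−6 against degenerate zero-variance draws), seeded. `knn` imputes a
missing cell by the mean of that column's values over the K = 10 nearest
proteins (root-mean-square distance over jointly observed samples, so
distance is comparable across different shared-sample counts; equal
distances break toward the smaller protein index; only donors observed in
the target column qualify). `SeqKNN` processes proteins by ascending
missing rate and lets previously imputed proteins serve as complete
neighbors. `Impseq` uses the same ordering but fills each missing cell by
an ordinary least-squares regression of the target sample on the protein's
observed samples, fitted over the currently complete proteins. Proteins
with no observed values (or no usable donors) fall back to MinDet and the
fallback is recorded in the replayable `PreprocessRecord`. Imputation never
alters an observed value, and every method except `none` leaves no missing
cells.

## DEA statistics

The built-in tests operate on observed log2 values per protein:

- **t-test** — Welch (unequal-variance), chosen as the robust default for
  spike-in designs with few replicates.
- **ANOVA** — one-way F across all design groups; for two groups it equals
  the pooled t-test exactly.
- **Moderated t** — per-protein pooled residual variance s² on d df is
  shrunk to s²_post = (d0·s0² + d·s²)/(d0 + d), with the prior (d0, s0²)
  fitted by method of moments on log s² (digamma/trigamma moment matching;
  trigamma inverted by Newton iteration); the moderated statistic is
  referred to a t distribution on d + d0 df. Proteins with zero residual df
  are excluded from the prior fit; with fewer than 10 usable variances the
  test falls back to Welch with a warning. `prior_df`/`prior_var` overrides
  expose the d0 = 0 (ordinary pooled t) and d0 = ∞ (fixed-variance z)
  limits.

Untestable proteins (fewer than two observations in a group) keep a record
with p = 1 and a flag, so BH adjustment and downstream padding always see
one record per protein. BH is the standard step-up procedure
(statsmodels); missing p-values count as 1. A protein is called
differential when |log2FC| ≥ log2(1.5) and q < 0.05 (weak / strict
inequalities respectively).

Small-sample caveat: Welch's df approximation is only asymptotically
calibrated; at 3 + 3 replicates its null p-values deviate detectably from
uniform at large protein counts. Calibration checks therefore use the
simulator's default of 5 replicates per group.

## Metrics, ranking, levels

pAUC is the raw (unstandardized) trapezoidal ROC area over FPR ∈ [0, c],
c ∈ {0.01, 0.05, 0.1}, on confidences 1 − q; tied confidences move
diagonally (simultaneous step), and the final segment is linearly
interpolated at c. MCC with any zero denominator factor is set to 0 (so
nMCC = 0.5); a zero-denominator specificity or recall contributes 0 to the
G-mean. Ranks use the average-tie convention; the final workflow order
breaks rank ties lexicographically. Level boundaries use the ceiling rule —
position ≤ ⌈0.05N⌉ is H, ≤ ⌈0.25N⌉ RH, ≤ ⌈0.50N⌉ RL, else L — which is the
rule consistent with H-counts of 393 at N = 7852 and 80 at N = 1584
(plain rounding would give 314 and 79).

LODOCV ranks workflows on the mean metrics of all-but-one dataset and on
the held-out dataset alone, comparing final-rank vectors by Spearman
correlation (undefined for constant vectors, which is raised as an error).
The Kruskal–Wallis helper refuses groups smaller than 5. The matched-pair
option comparison varies one step while holding the others fixed, counts
pairwise mean-difference wins per metric, breaks win ties by median
performance, and averages the five per-metric option ranks.

Cross-setting comparison merges all settings' protein lists, removes
multi-protein groups, and pads proteins absent from a setting with
log2FC = 0 and q = 1, so an absent truly-differential protein counts as a
false negative and an absent null protein as a true negative.

## Pattern mining

Workflows are encoded as transactions of `step=option` items (the matrix
item is dropped in settings with a single registered matrix type, where it
is uninformative). The miner is the classic FP-tree construction: items
ordered by support descending (name ascending on ties), recursive
conditional-tree growth; it returns exactly the itemsets with support
ratio ≥ the threshold (default 0.1), singletons included, empty itemset
excluded, ordered by support then lexicographically. Support ratios for
level-restricted mining are relative to the level's workflow count.

## Ensemble inference

The hurdle combiner uses z = Φ⁻¹(1 − p), which is standard normal under the
null, so Σz² ~ χ² with t df where t is the number of members that observed
the protein; t = 1 returns the lone p bit-identically and t = 0 yields
p = 1. Fisher uses −2 Σ ln p ~ χ² with 2t df over the present members.
Voting modes take the min / max / median order statistic (midpoint rule for
even counts), which makes DE calls monotone across modes at any threshold.
p = 0 inputs are clipped to 1e−300 with a warning. Raw member p-values (not
member q-values) are combined, and the combined p-values are BH-adjusted
once over the ensemble's protein list. The integrated log2FC is the member
value of largest magnitude, ties resolved in member order (so this one
combiner is order-sensitive; the p combiners are symmetric).

## Spike-in simulator

Each protein has a latent base log2 abundance ~ N(25, 3) (typical of log2
LFQ intensities); a de_fraction (default 0.1) of proteins is spiked in
group A by a fold change of fixed magnitude (default |log2FC| = 1) with
random sign (optionally N(μ, σ) magnitudes). Replicate noise sd defaults to
0.25 log2 units (~19% CV, technical-replicate scale); 5 replicates per
group. Each quantification view adds its own normal noise (default
0.3 × replicate sd, reflecting that views of one dataset are correlated
but disagree) and is exponentiated to the raw scale; the counts view draws
Poisson counts from the scaled latent intensities (mean ≈ 100) so
count-based plugins are exercisable — it is not calibrated to any real
instrument.

Missingness is modelled as missing-not-at-random with a logistic link:
P(missing | x) = 1/(1 + exp((x − τ)/s)) with steepness s = 0.5 on the log2
scale; τ is calibrated by bisection so the expected rate matches the
per-view target within 1e−4 (targets default to the platform-typical 17%;
3% and 0.2% reproduce DIA- and TMT-like sparsity). A target of 0 disables
dropout (τ = −∞).

Seeding: a master seed plus fixed per-component counters derive child
generators, so adding a view never perturbs the other views, and dataset
collections (for LODOCV) jitter replicate noise and fold-change magnitude
log-normally around the template with independent child seeds.

What the simulator does *not* emulate: peptide-level structure, shared
peptide / protein-inference ambiguity, batch effects, instrument-specific
intensity distributions, or realistic inter-protein correlation. Passing
benchmarks on simulated data therefore demonstrates correctness and
calibration of the machinery, not performance claims about any particular
real platform.

## Problem sizes used in the shipped checks

The test-suite simulations use desk-scale sizes chosen to exercise every
code path while keeping runs quick: 500–5000 proteins per dataset, 3–12
datasets per collection, grids of 2–4 workflows, 20 seeds for the
parameter-recovery study (1000 proteins, 10% DE at |log2FC| = 1, 5 + 5
replicates, 17% MNAR missingness). The level-bin partition identity is
checked exhaustively for N ≤ 1000 and on a dense random sample up to
N = 10 000. The acceptance script exercises ranking and labeling at the
full published grid sizes (7852 and 4720), which is exact and fast.

## Known limitations

- Third-party DEA tools, vsn, and the heavier imputation methods are
  plugin slots, not built-ins; the framework's claims are testable without
  their internals.
- Only two-group contrasts (no covariates, paired designs or multi-factor
  models) are supported by the built-in tests.
- The moderated t assumes the standard scaled-inverse-χ² variance model;
  heavy-tailed variance distributions will shrink suboptimally.
- FP-growth output is exponential in pattern length in the worst case;
  intended for the short transactions (3–4 items) of workflow encodings.
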