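# tdnd — time-delayed gene regulatory network inference

`tdnd` reconstructs a **directed, delay-annotated gene regulatory network**
from a short time-series expression matrix (T time points × N genes). It is
aimed at systems biologists working with the kind of data where GRN
inference is hardest: a handful of genes, a few dozen samples, noisy
measurements, and regulatory effects that appear one or more sampling
intervals after their cause.

The method couples two ideas:

1. **Cross-correlation lag estimation.** For target i and candidate
   regulator j, the unbiased cross-correlation

       C(x_i, x_j, τ) = 1/(T−τ) · Σ_{t=1}^{T−τ} x_{t+τ,i} · x_{t,j},  τ = 0..r

   is maximized in absolute value over lags τ to find the most probable
   regulatory delay l_ij. Time samples are then aligned to those delays
   (T−r usable rows), making regulator and target contemporaneous.

2. **Network deconvolution.** A correlation network mixes direct and
   transitive effects: S_o = S_d + S_d² + S_d³ + … = S_d (I − S_d)⁻¹.
   Because S_o and S_d share eigenvectors, the direct network is recovered
   in closed form by mapping each eigenvalue λ_d = λ_o / (1/α + λ_o)
   (α = 1 is the exact inverse; by default the scaling is chosen so the
   output spectrum is bounded by β = 0.5).

Running the alignment + deconvolution per target gene yields a weight
matrix S (S[i,j]: strength of the direct edge j → i, rescaled to [0, 1])
and a lag matrix D; thresholding S at θ emits the network. The classic
no-delay deconvolution baseline, confusion-matrix / ROC evaluation against
a truth network, and seeded synthetic generators for closed-loop testing
are included.

## Worked example

```python
from tdnd import TimeDelayedND, generate_network, simulate_expression

truth = generate_network(n_genes=6, n_edges=7, max_lag=3,
                         noise_sd=0.1, T=24, seed=11)
x = simulate_expression(truth)            # 24 x 6 expression matrix

res = TimeDelayedND(x, max_lag=3).fit()   # delay-aware inference
print(res.summary(theta=0.5))
```

```
Time-delayed network deconvolution
==========================================
genes:            6
time points:      24
mode:             delayed
max lag r:        3
scaling:          beta=0.5
threshold theta:  0.5
edges >= theta:   12

regulator   target        weight  lag
-------------------------------------
G2          G4             0.953    0
G5          G1             0.906    3
G5          G6             0.896    3
G4          G3             0.883    2
...
```

The top of the edge list shows the strongest direct dependencies with
their inferred delays: `G5 → G1` at lag 3 and `G5 → G6` at lag 3 are
planted edges of the simulated system, recovered with their exact lags.
Scoring against the generating network:

```python
rep = res.evaluate(truth.network, theta=0.5)
print(rep.as_dict())
# {'TP': 6, 'TN': 17, 'FP': 6, 'FN': 1, 'sensitivity': 0.857...,
#  'precision': 0.5, 'f_measure': 0.632..., 'specificity': 0.739..., ...}
print(res.roc(truth.network).auc)         # 0.860...
```

Six of the seven true edges pass the θ = 0.5 cut (sensitivity 0.86), and
the θ-sweep ROC summarizes ranking quality with AUC 0.86. The no-delay
baseline on the same data (`TimeDelayedND(x, mode="no-delay")`) ranks the
true edges notably worse — the gain is exactly what delay awareness buys.

## Command line

The same pipeline is scriptable end to end:

```bash
tdnd simulate --genes 9 --edges 12 --max-lag 3 --t 24 --noise-sd 0.1 \
     --seed 7 --out-expr X.tsv --out-truth truth.tsv
tdnd infer --input X.tsv --max-lag 3 --theta 0.5 \
     --output edges.tsv --weights S.tsv --lags D.tsv
tdnd eval --pred edges.tsv --truth truth.tsv
tdnd roc  --weights S.tsv --truth truth.tsv --grid 101
```

All inputs and outputs are plain TSV (expression: header of gene names,
one row per time point; networks: `regulator  target  weight  lag`).
`--no-delay` switches to the baseline, `--periodic` enables circular
alignment for periodic series, and a JSON/YAML `--config` file can preload
any flag. Given an externally supplied benchmark matrix and truth edge
list, `infer` + `eval` with θ = 0.5 and r = 5 (or r = 3 for longer
switch-off-style series) reproduce the standard benchmark pipeline.

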