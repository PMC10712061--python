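# methylcapso

DNA methylation site prediction (6mA, 4mC, 5hmC) from site-centered sequence
windows, built for researchers who want a fully transparent, gradient-free
baseline: nine multivariate sequence encodings, a small convolution + LSTM
classifier, and training by chaotic accelerated particle swarm optimization
(CAPSO) over the whole packed weight vector.

## The method

A length-L window over {A,C,G,T} is encoded as a channels × L matrix under
any of nine schemes — three time-series codes (spectral integers; chaos game
representation `CGR_i = CGR_{i−1} − (CGR_{i−1} − g_i)/2` inside the square
with vertices A(1,1), G(−1,1), C(1,−1), T(−1,−1); the Z-curve composition
transform with `X=(A+G)−(C+T)`, `Y=(A+C)−(G+T)`, `Z=(A+T)−(C+G)`), three
gene-feature codes (one-hot BPF; nucleotide chemical properties; six
min–max-normalized dinucleotide step parameters), and their row-stacked
fusions, up to the 17-channel hybrid (`code9`).

The classifier applies a rectified valid convolution, non-overlapping max
pooling, a single LSTM pass

    f_t = σ(W_f x_t + U_f h_{t−1} + b_f)        i_t = σ(W_i x_t + U_i h_{t−1} + b_i)
    C'_t = tanh(W_c x_t + U_c h_{t−1} + b_c)    C_t = f_t ∘ C_{t−1} + i_t ∘ C'_t
    o_t = σ(W_o x_t + U_o h_{t−1} + b_o)        h_t = o_t ∘ tanh(C_t)

and a sigmoid head on the final hidden state.  All weights live in one flat
vector that CAPSO minimizes (training-set cross-entropy) with the
velocity-free update `x ← (1−C₂)x + C₂·p_g + C₂·r`, where `C₂` is driven by
the fully chaotic logistic map `d ← 4d(1−d)`.  Several independent swarm
restarts are averaged into a score ensemble, with members ranked on the
validation part.  Evaluation reports SN, SP, ACC (percent), MCC, and the
rank-statistic AUC `(Σ_{i∈pos} rank_i − n_pos(n_pos+1)/2)/(n_pos·n_neg)`
with average ranks for ties.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Train and evaluate on a synthetic motif-planted benchmark (positives carry a
degenerate 8-mer consensus at the window center, 5% per-position mutation;
negatives are composition-matched background):

```python
from methylcapso import (ExperimentConfig, SyntheticConfig, generate_synthetic,
                         split_dataset, train, test)

records = generate_synthetic(SyntheticConfig(n_pos=300, n_neg=300, length=41,
                                             motif="GAGGTAAC", mutation_rate=0.05,
                                             seed=11))
config = ExperimentConfig(scheme="code9",
                          fractions=(400/600, 100/600, 100/600), split_seed=7)
split = split_dataset(records, config.fractions, seed=config.split_seed)
model = train(split.train, split.validation, config)
report = test(model, split.test)
print(f"ACC={report.acc_pct:.1f}%  AUC={report.auc:.3f}  MCC={report.mcc:.3f}")
```

Output:

```
ACC=89.0%  AUC=0.944  MCC=0.784
```

meaning 89% of the 100 held-out windows are called correctly, the ranking of
positives over negatives is near-perfect (AUC 0.944), and the calls correlate
strongly with the truth (MCC 0.784).  The same run under the
single-channel spectral encoding (`scheme="code1"`) reaches AUC 0.930 —
the fused 17-channel encoding ranks at or above every single encoding on
this benchmark.

The same workflow from the shell:

```sh
methylcapso simulate --n-pos 300 --n-neg 300 --mutation-rate 0.05 --seed 11 --out data.fa
methylcapso train --data data.fa --scheme code9 --seed 0 --out model.npz --report val.json
methylcapso test  --model model.npz --data data.fa --out report.json
```

Plus `encode` (write encoding matrices), `ablate` (per-scheme comparison on
one shared split) and `crossval` (k × k cross-dataset train/test matrix,
exported per metric as CSV heatmap tables).

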