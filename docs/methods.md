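# Methods

`methylcapso` predicts DNA base-modification sites (6mA, 4mC, 5hmC) from
fixed-length, site-centered sequence windows.  It combines three ingredients:
a nine-scheme multivariate encoding of the window, a small convolution + LSTM
classifier, and a gradient-free chaotic swarm optimizer that trains the whole
weight vector at once.  This note records the model, its assumptions, the
numerical choices, and what the synthetic benchmark does and does not show.

## Sequence encodings

A window `S = S_1 … S_L` over {A, C, G, T} is mapped to a channels × L real
matrix.  Three codes treat the window as a time series:

- **Spectral (code1, 1 channel)** — the integer series a→1, g→2, c→3, t→4.
  Case-insensitive.
- **Chaos game representation (code2, 2 channels)** — the square with
  vertices A(1,1), G(−1,1), C(1,−1), T(−1,−1); starting from the origin,
  point *i* is the midpoint of point *i−1* and the vertex of base *i*:
  `CGR_i = CGR_{i−1} − (CGR_{i−1} − g_i)/2`.  Both coordinate series are
  emitted as separate channels rather than collapsed to a norm, because the
  quadrant identifies the base (the map is exactly invertible via
  `g_i = 2·CGR_i − CGR_{i−1}`) and a scalar reduction would discard that.
  All points lie strictly inside (−1, 1)².
- **Z-curve (code3, 1 channel)** — with cumulative counts `A_i, C_i, G_i,
  T_i`, the three classic components are `X = (A+G)−(C+T)` (purine excess),
  `Y = (A+C)−(G+T)` (amino excess), `Z = (A+T)−(C+G)` (weak-bond excess).
  Their sum collapses algebraically to `4·A_i − i`, which is negative for
  pyrimidine-rich prefixes, so the emitted series is the signed root
  `sign(s)·sqrt(|s|)`.  The signed root keeps the series real, odd and
  monotone in `s`; a plain square root would be undefined on half the
  inputs and a magnitude would discard the strand-composition sign.

Three codes carry positional and physicochemical structure:

- **BPF (code5, 4 channels)** — one-hot columns in row order A, T, G, C.
- **NCP (code6, 3 channels)** — ring structure (purine {A,G}), hydrogen-bond
  strength (weak {A,T}), functional group (amino {A,C}).
- **DPCP (code7, 6 channels)** — six B-DNA base-pair step parameters
  (twist, tilt, roll in degrees; shift, slide, rise in Å) of the
  dinucleotides flanking each position, min–max normalized per property
  (constant properties map to 0.5) and averaged over the left and right
  flanking steps; the two boundary positions have a single flanking step and
  use it unaveraged, preserving the 6 × L shape.  The packaged table holds
  crystallographic mean step parameters for the 16 dinucleotides,
  complementary-symmetric (angular and translational y-symmetric parameters
  equal under reverse complement, tilt and shift sign-flipped); any 16 × 6
  TSV can be supplied instead, and normalization is always re-applied.

The fusions row-stack: code4 = code1+code2+code3 (4 channels), code8 =
code5+code6+code7 (13), code9 = code4+code8 (17).  Encoding is deterministic
and channel labels survive stacking.

Before entering the network each channel is z-scored with mean and standard
deviation fitted on the training part only and stored in the model.  The
channels otherwise differ in scale by orders of magnitude (spectral in 1–4,
CGR in (−1,1), the Z series grows like √L), which would let a single channel
dominate the convolution.

## Classifier

The network is deliberately small — it is trained without gradients:

1. **Convolution** — K kernels spanning all input channels, width w, valid
   padding, stride 1, ReLU.  Output K × (L−w+1).
2. **Max pooling** — non-overlapping windows of width p along the position
   axis; a trailing remainder window is pooled as-is.
3. **LSTM** — a single forward pass over the pooled feature columns from the
   zero state, with the standard four-gate recurrence
   (forget/input/cell/output; σ for gates, tanh for the cell candidate;
   `C_t = f∘C_{t−1} + i∘C'_t`, `h_t = o∘tanh C_t`).
4. **Head** — `σ(w·h_T + b)`; scores at or above the threshold (default 0.5)
   are called positive.

σ and tanh clip their pre-activations at ±50, so any weight vector the
optimizer proposes yields a finite forward pass.  All parameters (conv
kernels and biases, the four gate triples (W, U, b), head) round-trip to one
flat vector in a fixed documented order; that vector is the search space.

Defaults: K = 4 kernels of width 3, pool width 4, hidden size 8, giving a
633-entry parameter vector for the 17-channel fused encoding.  These sizes
were chosen so that the swarm, which explores the weight space by sampling
rather than by gradients, still makes consistent progress: search efficiency
decays with dimension roughly as 1/√dim, and vectors beyond a few thousand
entries stopped improving over their random initialization in development
runs.  The architecture is fully configurable; a warning is logged above
20 000 parameters.

## Chaotic accelerated particle swarm optimization

The optimizer is velocity-free.  Each particle i carries a chaotic variable
`d_i` advanced once per iteration by the fully chaotic logistic map
`d ← 4d(1−d)`; the fresh value is its mixing coefficient `C2`.  Every
coordinate then updates as

    x ← (1 − C2)·x + C2·p_g + C2·r,

a contraction toward the global best `p_g` plus a perturbation, with `r`
drawn per coordinate from uniform(−r_scale, r_scale).  Seeds in
{0.25, 0.5, 0.75} (and the endpoints) sit on degenerate logistic orbits —
0.75 is a fixed point, 0.5 collapses to 0 in two steps — and are rejected at
configuration time.  There is no personal-best term and no velocity; the
swarm is effectively an annealed best-of-population local search, which is
what makes the chaotic mixing coefficient matter: small `C2` values preserve
the current position, large ones resample near the incumbent.

Numerical/engineering choices:

- **Initialization** uniform in ±0.5: small weights keep σ/tanh units in
  their responsive range.
- **Perturbation scale** r_scale = 0.5 by default with geometric decay 0.99
  per iteration.  The decay is essential, not cosmetic: with a constant
  scale the best-fitness floor is set by the perturbation noise (on a 5-D
  sphere it stalls around 1e-1), while annealing lets the swarm refine the
  incumbent by orders of magnitude.  For network training the pipeline uses
  r_scale = 0.1 with decay 0.993 over 350 iterations of 30 particles — in a
  ~600-dimensional weight space a half-width of 0.5 yields steps whose norm
  (~6) exceeds the weight vector norm itself and nothing useful is ever
  accepted.
- **Non-finite fitness** re-draws the particle uniformly in the
  initialization box and logs it.
- The global best updates on strict improvement only, so with constant
  fitness the first-evaluated particle is retained and the best-fitness
  trace is non-increasing by construction.

## Training, checkpointing and restarts

Fitness is mean binary cross-entropy of the forward pass on the training
part (probabilities clipped to [1e-12, 1−1e-12]).  Every strict improvement
of the global best is checkpointed; after the run the reported model is the
checkpoint with the highest validation accuracy, ties broken by lower
training loss.  This is the only place validation labels enter; test data
never influences training (verified by a test that corrupts test labels and
observes bit-identical trained parameters).

Because a swarm run from one random population has high variance, the
pipeline trains `n_restarts` (default 3) independent swarms whose seeds are
derived deterministically from the base seed (`seed + k·1 000 003 mod
2³¹−1`).  Each run contributes its best checkpoint as one ensemble member,
and the model's score is the mean probability over members.  Averaging was
chosen over picking a single winner because a 100-record validation part
cannot reliably rank runs (its accuracy has a ±3–4 point binomial standard
error), while score averaging both lifts discrimination above the best
member and damps run-to-run variance.  The top-ranked member remains
available as a single network.  Late checkpoints of a long run can overfit
(training loss keeps falling while validation loss rises), which is why
member selection scans all checkpoints rather than taking the final
incumbent.

## Evaluation

Sensitivity, specificity and accuracy are reported as percentages; MCC from
the usual four-product formula; AUC from the rank-sum statistic
`(Σ_{i∈pos} rank_i − n_pos(n_pos+1)/2) / (n_pos·n_neg)` with average ranks
for ties, which makes it exactly the Mann–Whitney all-pairs statistic (half
credit for ties) and invariant under strictly increasing score transforms.
A score exactly at the threshold is called positive.  Metrics with vanishing
denominators (one-sided predictions, single-class folds) are reported as 0
and flagged `degenerate` instead of raising, so cross-dataset sweeps never
abort on a pathological fold.

## Data handling

Datasets are FASTA (labels from a `label=` description token, a `pos`/`neg`
identifier prefix, or an explicit per-file role) or two/three-column
delimited text.  Records containing N are dropped with a logged count by
default — every encoding is defined only on {A,C,G,T} — with flags to drop
silently or to fail.  The 70/15/15 train/validation/test split uses
largest-remainder rounding (residuals to the later part on ties), is
stratified by class by default, and is a pure function of (records,
fractions, seed).

## Synthetic benchmark

The generator emulates the structure of site-centered benchmark datasets:
equal-length windows (default 41, odd, site-centered), positives carrying a
consensus motif (default the 8-mer GAGGTAAC) planted at a fixed offset from
the window center, each motif position independently mutated to a different
base with probability `mutation_rate` (default 0.05), negatives drawn from
the same base composition (default uniform).  Default set sizes are 300+300,
split 400/100/100 — a desk-scale problem a single CPU trains in minutes.

What this emulates: a degenerate, positionally anchored sequence determinant
against composition-matched background, the signal structure assumed by
site-centered methylation predictors.  What it does not emulate: genomic
base composition and repeat structure, multiple or variably positioned
motifs, label noise, class imbalance at genomic scale, and any
species-specific context.  Passing the synthetic recovery tests therefore
shows that the full pipeline can extract a planted, learnable signal through
the nine encodings and the swarm-trained network — not that it matches any
particular performance level on real methylomes.

Cross-dataset transfer has the same reading: two synthetic "species" sharing
a motif should transfer (all four train/test cells perform well), disjoint
motifs should not (diagonal beats off-diagonal), mirroring the qualitative
cross-species behavior of site predictors, not any quantitative claim.

## Known limitations

- The swarm trains weight vectors of at most a few thousand entries well;
  scaling the network up requires a different training strategy and is out
  of scope.
- Single-layer unidirectional LSTM only; no gradient training, no attention,
  no comparator models.
- The DPCP table ships one published parameter set; users with a preferred
  scale should supply their own TSV.
- AUC, MCC and the confusion metrics are point estimates; no confidence
  intervals are computed.
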