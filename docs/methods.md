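# Methods

`coevodist` regresses the full L×L matrix of Cβ–Cβ distances of a
protein from features of its multiple sequence alignment (MSA).  This
note documents the model, the statistics behind the input features, the
synthetic data the package ships for testing, and the numerical and
design choices that were genuinely open.

## Input features

All inputs derive from one MSA whose first row is the ungapped query.

**Sequence weighting and Neff.**  Redundant sequences are down-weighted
by the standard inverse-neighbour-count scheme: sequence *m* gets weight
`1 / |{n : S(m,n) ≥ thr}|`, where the identity `S(m,n)` is the fraction
of matching symbols over columns where the query is non-gap (gap
matching gap counts as a match — the convention matters only for
non-query-gapped columns, which the query-anchored register excludes).
The effective sequence number Neff is the sum of the weights, and
`Neff/L` is the depth measure used for stratified reporting.  The
default identity threshold is 0.8.

**Profile (PSSM + entropy).**  The PSSM is the sequence-weighted
per-column probability over a 21-symbol alphabet (20 amino acids + gap)
with a Laplace pseudocount (default 1.0).  `X`/ambiguous residues
contribute fractionally (1/20 to each amino-acid bin) so columns always
sum to one.  Column entropy is the Shannon entropy (bits) of the
*unsmoothed* weighted column distribution — with a pseudocount the
entropy of a perfectly conserved column would never reach zero.

**Coupling channels.**  External coupling matrices can be ingested from
CCMpred-style square text files and FreeContact-style `i j … score`
records (1-based in the file, 0-based internally, mirrored to
symmetric).  The in-repo covariant-frequency statistic is
sequence-weighted mutual information between column pairs (gap pairs
excluded, `X` treated as a 21st symbol) with average product correction:

    MI_APC(i,j) = MI(i,j) − MI(i,·)·MI(·,j) / MI(·,·)

where the means exclude the diagonal.  APC suppresses the
phylogenetic/entropic background that otherwise dominates raw MI.

**Assembly.**  Per-residue vectors `f_i` (21 PSSM probabilities +
entropy, 22 values) are tiled pairwise as `[f_i ; f_j]` at cell (i,j) —
tiling rather than averaging preserves the ability to learn asymmetric
relations — and concatenated with one channel per coupling matrix:
`C = 2·22 + n_couplings` (45 with the default single MI channel).  The
channel order is recorded in a manifest and is part of the contract.
Coupling channels are z-scored over their off-diagonal entries at
featurisation: coupling scores are unbounded and an order of magnitude
smaller than the probability channels, and without rescaling the
network demonstrably ignores them at small training budgets.

## Architecture

The network maps a `(B, C, L, L)` feature stack to a `(B, 1, L, L)`
distance map at **constant spatial resolution** throughout.

**Perceptive encoder.**  A stem convolution lifts the input to
`base_channels`, followed by `N` residual stages: convolution with
alternating 1×5 / 3×3 kernels → instance normalisation → SiLU → a Mamba
block → residual add.  Instance norm is used because variable-length
proteins are trained at batch size 1.  Per-stage outputs are retained
as skip tensors.  Defaults are N=8 stages at 64 channels; a
`full_scale` preset sets N=64 and a `tiny` preset (2 stages, 16
channels) serves CPU-scale experiments.  Channel width is constant
across stages.

**Mamba block.**  The L×L grid is flattened row-major into a single
length-L² sequence.  After LayerNorm, a gating branch computes
`W₂ = SiLU(Linear(u))` while the state branch computes
`W₁ = LayerNorm(SSM(SiLU(DWConv(Linear(u)))))`; the two are fused by a
Hadamard product, projected back to the block width, added to the input
through a learnable scalar residual scale `s` (init 1.0), then
LayerNorm + a final linear projection produce the output.  The SSM is a
diagonal selective scan: per expanded channel `d` and state lane `n`,

    h_t = exp(Δ_t A) h_{t−1} + Δ_t B_t x_t,    y_t = C_t · h_t + D x_t

with `Δ = softplus(Linear(x))` (bias initialised so Δ starts in
[1e−3, 1e−1]), `B_t`, `C_t` linear in the input, `A = −exp(A_log)` with
`A_log` initialised to `log(1..N)`, and a learnable skip `D`.  This is
a zero-order-hold discretisation of a continuous diagonal system with
negative real poles, so `exp(ΔA) ∈ (0,1)` and the scan is stable.  The
depthwise convolution along the sequence uses same padding (the scan
axis is a spatial raster, not time, so causality is not required).
Scanning is single-direction row-major; bidirectional scanning would be
a straightforward extension.

**Structural refiner.**  At the bottleneck the map is reshaped to a
`(B, L², C)` sequence, passed through a depthwise-separable convolution,
per-channel normalisation over the sequence axis (the batch-norm role at
batch size 1) and ReLU, then a Kolmogorov–Arnold (KAN) layer maps the
channel vector of every position through a matrix of learnable
univariate functions; a residual connection wraps the whole refiner.

**KAN layer.**  Each edge (p→q) carries
`φ_{q,p}(z) = w_base·silu(z) + w_spline·Σ_g c_g B_g(z)` with an order-k
B-spline basis (defaults G=5 intervals, k=3, grid range [−2,2]) on a
per-input-feature knot vector; inputs outside the grid are clamped.
The basis satisfies partition of unity on the grid interior (asserted
to 1e−9).  A dynamic mesh adjustment runs every
`grid_update_interval` (default 200) training steps: knots move to a
0.9·quantile + 0.1·uniform blend of the observed (grid-clamped) inputs
and the spline coefficients are re-fit by least squares on the same
batch.  The refit is exact for spline states representable on any knot
vector (e.g. polynomial components) and a least-squares best
approximation otherwise; constant features and batches smaller than the
basis keep their grid.

**Prediction decoder.**  N−1 stages of stride-1 transposed convolution
(at constant resolution this is the adjoint channel mixer of the
encoder convs), concatenation of the matching encoder skip, and a
depthwise-separable convolution with instance norm + SiLU; finally a
1×1 convolution to one channel and Softplus, so every predicted
distance is strictly positive.  The final bias is initialised to 15 so
initial predictions sit near a typical Cβ–Cβ distance instead of
softplus(0) ≈ 0.7 Å, which removes a large transient from early
training.  The output is symmetrised, `(M + Mᵀ)/2` (flag, default on);
symmetrisation happens inside the forward pass so the training loss
sees the symmetric map.

## Training objective

The regression loss is an inverse-residual log-cosh,

    L = (1/N) Σ_{i,j} log cosh( 100/(D̂_ij + ε) − 100/(D_ij + ε) ),

evaluated with the overflow-safe identity
`log cosh(u) = |u| + log1p(e^{−2|u|}) − log 2`.  The 100/(d+ε)
transform concentrates the penalty on short (contact-forming) distances
while the log-cosh envelope bounds the gradient magnitude by
`100/(D̂+ε)²` (the tanh factor), which is what makes the loss robust to
large residuals.  ε defaults to 1e−8.

One cell class needs care: the transform is singular at zero true
distance, which is exactly the self-pair diagonal of every ground-truth
map (with ε = 1e−8 each diagonal cell would contribute ~1e10 and drown
the objective).  The training objective therefore applies the inverse
transform to off-diagonal cells and a plain log-cosh on raw distances
for diagonal cells, which trains the diagonal toward zero without the
singularity.  The bare formula remains available (`metrics.
inv_log_cosh_loss`, and `diagonal="inverse"` in the trainer's loss) for
inputs without zero entries.

Optimisation is Adam (default lr 1e−3) with global-norm gradient
clipping (default 1.0), per-sample steps (batch 1, no padding or
masking), best-on-validation checkpointing, and early stopping after 20
evaluations without improvement.  The monitoring MAE logged during
training is the element-wise mean absolute error over all L² cells;
it is deliberately distinct from (and typically lower than) the top-K
MAE computed on the hardest prediction regions.  Training is bitwise
reproducible under a fixed seed on a single CPU thread; all arithmetic
is float64.

## Evaluation

All metrics score the upper triangle at a minimum sequence separation
(default 6; 24 for the long-range "Seq-24" variants; 0 available by
flag — the headline default is a package convention, reported with
every result).  Contacts are strict `d < 8 Å`, diagonal excluded.

- **precision@{L/5, L/2, L}**: rank eligible pairs by ascending
  predicted distance (ties broken lexicographically by (i,j)), take the
  top `ceil(fraction·L)`, report the fraction with true distance < 8 Å.
  If fewer eligible pairs exist than requested, all are scored and the
  report is flagged.
- **MAE@K**: mean |D̂ − D| over the same top-K selection.
- **Pearson r** over all eligible pairs (error on zero variance).
- **lDDT**: mean over tolerances {0.5, 1, 2, 4} Å of the fraction of
  eligible pairs with |D̂ − D| < t (equivalently the printed double sum
  divided by |T|·#pairs).
- **MCC** of the 8 Å contact classification, with the zero-denominator
  convention MCC = 0.

Ground truth comes from Cβ coordinates (Cα for glycine) read from PDB
ATOM records.  Dataset assembly applies a 50–500 residue length gate
with an override flag.

## Synthetic data

The generator produces self-contained targets so the whole stack is
testable without downloads; it emulates the *statistical* structure the
features assume, not protein physics.

**Structures** are compact self-avoiding chains of one Cβ-proxy point
per residue: alternating helix-like segments (radius 2.3 Å, rise
1.5 Å, 100°/residue — consecutive spacing ≈ 3.8 Å) and extended
segments (3.8 Å steps), joined by random-rotation linkers whose
orientation is re-drawn until the segment avoids clashes (< 3.0 Å
non-adjacent approach) and, preferentially, stays inside a confinement
radius `3.4·L^{1/3}` Å of the chain centroid.  Whole-chain rejection
re-sampling enforces consecutive spacing in [3.0, 4.5] Å and
self-avoidance; the resulting long-range contact density
(|i−j| ≥ 6, < 8 Å) lies in (0.01, 0.2) across seeds.

**Pseudo-MSAs** evolve M sequences from a random ancestor: 10% of
positions are planted as conserved; every other column mutates
independently at `mutation_rate`; every contact pair not touching a
conserved column is assigned a two-state covarying letter repertoire
applied per descendant with probability
`min(1, coupling_strength · mutation_rate)` — a compensatory-mutation
scheme chosen over a Potts sampler because it is desk-scale, seedable,
and sufficient to make MI-based features informative about contacts.
Defaults: L ∈ [50, 120], M = 100, mutation_rate 0.15,
coupling_strength 3.  Everything is deterministic under
(params, seed), with sub-streams split via `SeedSequence`.

What the generator does *not* emulate: realistic fold topologies,
phylogenetic correlation between sequences, alignment errors, gap
patterns from insertions/deletions, or higher-order epistasis.  Tests
passing on this data show that information flows correctly through the
implementation — not that the trained model would reach literature
accuracy on real proteins, which requires corpus-scale training data
and external coupling predictors.

**Fixture trees** (`targets/<id>/{msa.fasta, truth.mat, model.pdb,
manifest.json}`) round-trip through the public readers; PDB coordinates
carry 3 decimals, which bounds the reconstructed-distance error by
about 2e−3 Å (worst case of ±5e−4 per coordinate), observed ≈ 8e−4.

## Experiment scales in the shipped tests and acceptance script

CPU-scale runs use the `tiny` model preset.  The held-out
generalisation experiment trains on 24 of 30 targets (L ∈ [50, 70],
M = 120, coupling_strength 5 — a strong-coevolution cohort matching the
coupling-validity checks) for 600 steps at lr 3e−3 and evaluates
precision@L/5 on the remaining 6 against the random-ranking baseline
(the empirical contact density).  The single-target memorisation run
uses a 2-stage, 16-channel model at L = 50 for up to 500 steps at
lr 2e−3.  These sizes are the package's chosen desk-scale defaults;
both experiments re-run from scratch in `scripts/acceptance.py`.

## Known limitations

- The selective scan is single-direction row-major; column-major or
  bidirectional scans are unexplored here.
- Per-stage channel progression is constant; widening schedules are a
  documented alternative.
- Whether the PSSM should be probabilities or log-odds is a
  representational choice; probabilities are exposed (log-odds can be
  derived from them and a background distribution).
- The KAN grid refit preserves the layer function exactly only for
  knot-vector-representable states; from arbitrary states it is the
  least-squares best approximation on the update batch.
- Training at batch size 1 makes no use of cross-protein batching;
  throughput on CPU is the binding constraint.
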