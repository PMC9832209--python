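# Methods

## The model

`sarn` classifies subjects (control vs. addicted) from dynamic functional
brain networks and ranks region-level biomarkers. The pipeline has four
stages.

**Network construction.** A subject's scan is an N × T matrix of ROI
signals. It is split into `n_steps` equal, contiguous windows (default 4).
For each window we compute the N × N Pearson correlation matrix A^t
(functional connectivity), keep for every region its top-`knn` partners by
|r| plus a mandatory self-loop (default knn = 10; ties broken by region
index), and compute hop distances ψ(i, j) on the symmetrized k-NN graph,
capped at `max_dist` (default 5) with one extra bucket for unreachable
pairs. Degenerate constant rows get correlation 0 with a warning; no
significance thresholding is applied — sparsification is top-k only.

**Encoder.** Per snapshot, three graph spatial attention (GSA) layers
embed the regions. The attention logit for a pair (i, j ∈ N(i)) is

    e_ij = tanh([h_i W, h_j W] · c + s[ψ(i, j)])

— a shared linear score over the transformed pair features plus a learned
scalar bias indexed by the pair's capped shortest-path distance (the
spatial encoding; one table shared by all layers and snapshots, zero
initialized). α is the softmax of e over N(i), and the layer output is
ELU(Σ_j α_ij h_j W). Layer widths are D → 64 → 64 → 32. Across snapshots a
recurrent unit with a single forget gate updates the hidden state: each
region's current embedding Z^t attends (scaled dot product, single head,
no value projection) over the slots [Z^t, H^{t−1}, …, H^{t−w}] (FIFO
window, default w = 3), giving a context C; then

    f = σ(Z W_f + C U_f + b_f),  H̃ = tanh(Z W_h + C U_h + b_h),
    H^t = f ⊙ H^{t−1} + (1 − f) ⊙ H̃.

H^0 is the zero matrix; attention runs over however many slots exist. The
final H^T (N × 32) carries the spatial and temporal features.

**Bayesian region selector.** A free logit per region defines a selection
probability z = σ(logit), initialized at z = 0.5. During training a relaxed
Bernoulli mask is drawn per subject per epoch by logistic
reparameterization, b = σ((logit z + logit u) / r) with temperature r
(default 0.5), and a KL penalty to a sparse prior Ber(s) (default s = 0.1,
weight 1) pushes uninformative probabilities down. At inference,
*prediction* uses the mean-field mask b = z — the deterministic
expectation of the gate the model was trained under — while *selection*
(which regions count as chosen for biomarker statistics) uses the hard
threshold b = 1[z > 0.5]. Predicting through the hard mask instead would
collapse to a constant output whenever no gate crosses 0.5, which happens
under weak signal or small cohorts where the sparsity prior dominates;
the expectation has no such failure mode and no train/test mask
distribution shift.

**Head and loss.** Masked embeddings are mean-pooled over regions, passed
through a logistic readout, then a one-hidden-layer MLP (64 ELU units)
yields the addiction probability. The loss is binary cross-entropy summed
over subjects (matching the summed form of the objective) plus the KL
penalty. Training is full-batch Adam, lr 0.001, weight decay 0.01, with a
dedicated gate learning rate (below). 1000 epochs is the fidelity profile;
200 is the desk-scale default.

## Design choices that were genuinely open

**Model input features.** Two representations are available
(`feature_mode`): the z-scored raw window per region (`"signal"`) and the
region's functional-connectivity profile — its row of A^t
(`"connectivity"`, the default). Raw windows are per-subject noise
realizations: a time-domain filter can separate training subjects but
carries no region information that transfers across subjects, and in our
experiments models trained on raw windows memorize (training loss → 0)
while held-out accuracy stays at chance. Connectivity profiles are stable
in region identity across subjects and are the representation brain-network
classifiers conventionally use; with them, held-out accuracy on planted
data is near-perfect. The snapshot container stores both.

**Mask placement.** `mask_stage="input"` (default) zeroes region rows of
the model input; `"embedding"` masks the encoder output H before readout.
We default to input masking because after three rounds of neighborhood
message passing class information is spread over all region rows, so
masking H rows removes almost nothing — the gates then feel only the
uniform KL force, never differentiate, and carry no biomarker signal (we
verified this directly: with embedding masking the z spread stays ~10⁻³
with no alignment to planted regions at any temperature or KL weight).
Masking the input makes selection causal: dropping a region genuinely
removes its information, so gradients defend exactly the informative
regions. This is also the reading under which "selecting brain regional
features" has its plain meaning.

**Gate learning rate.** Adam moves each coordinate by at most ≈ lr per
step, so at lr 0.001 and a few hundred epochs the selection logits could
move only ±0.2 — never reaching the hard-selection threshold from their
z = 0.5 start. Gates therefore use their own Adam instance with
`gate_lr = 0.05` (gate-specific learning rates are standard practice for
stochastic-gate feature selection); all other parameters keep lr 0.001.

**Other fixed choices.** σ in the GSA aggregation is ELU; the gate
nonlinearity is logistic (gate semantics need (0,1)); the candidate state
uses tanh as printed. Single attention head; no value projection (the
context is a convex combination of raw slots). Glorot-uniform
initialization, zero biases, zero spatial table. Readout σ is logistic.
BCE is summed, not averaged (the objective's Σ). Stratified folds
(unstratified folds degenerate under 16/8-style imbalance); repeats
reshuffle folds with repeat-indexed seeds; undefined precision/recall is
reported as 0 with a warning. Training runs in float32 (the usual deep
learning precision); the autodiff engine defaults to float64 for exact
op-level checks.

## Biomarker ranking

Each completed training run contributes its z vector and hard mask. Per
region: mean z across runs, selection frequency (fraction of runs with
hard b = 1), and the cumulative score = frequency × mean z. Regions are
ranked by score, with mean z as the secondary key (so the cumulative
probability weight still orders regions when few runs cross the hard
threshold) and region index as the final tie-break.

## The synthetic-data generator

Real rat fMRI of the kind this method targets is not redistributable, so
the generator emulates its shape: N regions × T timepoints per subject,
two classes. Every region loads on `n_latent` shared AR(1) background
factors (φ = 0.5, unit marginal variance; loadings drawn once per dataset
so the background connectivity is common to all subjects) plus private
Gaussian noise (sd `noise_sd`). In addicted subjects only, the k planted
regions are coupled: a fraction β²/(1+β²) of each planted region's private
noise variance is replaced by one shared AR(1) factor. This raises their
mutual correlations while leaving every region's marginal variance
unchanged, so the class difference is strictly confined to the couplings
within the planted set — an additive factor would instead dilute the
correlations of *all* regions to the planted ones through the variance
increase, leaking the effect outside the planted set. Planted regions
additionally receive a constant mean shift δ, which is visible to the
audit (raw means) but deliberately invisible to the classifier (Pearson
correlation and z-scoring are shift-invariant). β = 0, δ = 0 gives an
exact null: both classes follow the same law.

What the generator does not emulate: hemodynamic response functions,
scanner drift and physiological artifacts, spatial autocorrelation of a
real atlas, and site/batch effects. Passing tests therefore demonstrate
that the method recovers region-confined coupling differences under
idealized noise — not that it would do so at real-data effect sizes.

The audit (`effect_audit`) runs two Welch t-tests per region across
subjects — raw mean level, and mean correlation to the planted set —
Bonferroni-corrected over 2N tests at α = 0.01, and reports which regions
are flagged versus planted.

## Test and experiment profiles

Experiments in the test suite and acceptance script use desk-scale sizes
chosen once as the package's test profile: planted-recovery runs use 30
regions (5 planted, coupling β = 2.0), 20+20 subjects, 200 timepoints, 4
steps, fourfold CV at 200 epochs across 10 generator seeds; the ablation
uses 60 regions, weak coupling β = 0.8, 8+8 subjects, 60 epochs; the null
control uses 20 regions, 8+8 subjects. A full-shape smoke run (150 regions
× 800 timepoints × 24 subjects) verifies the pipeline at the atlas scale
with a short 20-epoch budget.

At the ablation's nuisance level the planted signal is near the edge of
learnability for these cohort sizes: the no-selector model tends to
overfit the 55 nuisance regions (held-out accuracy at or below chance),
while the selector's stochastic gating regularizes training and its
learned gates down-weight nuisance at inference, keeping the selector arm
modestly above chance — the selector ≥ no-selector ordering reflects both
effects.

## Numerical notes and limitations

- Attention logits pass through tanh and are therefore bounded in (−1, 1):
  attention can never concentrate more sharply than a factor e² between
  two neighbors. This is faithful to the printed formulation (classic
  graph attention uses LeakyReLU instead).
- Masked softmax assigns exactly zero weight outside N(i); the mandatory
  self-loop guarantees a nonempty support. Probabilities entering the BCE
  are clamped to [1e-7, 1 − 1e-7].
- Relaxed masks with u exactly 0 or 1 are rejected (logit undefined);
  training draws u in [1e-6, 1 − 1e-6].
- Pearson correlation of constant rows is defined as 0 (warned), and
  z-scoring of a constant row yields zeros.
- All randomness (generator, parameter init, fold shuffling, mask
  sampling) flows from explicit integer seeds; fixed seeds give
  bit-identical runs.
- Cohorts are tiny by deep-learning standards; full-batch training and
  these capacity settings are tuned to that regime, and results on
  hundreds of subjects may favor different profiles.
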