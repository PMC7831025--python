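# Methods

## Gating model and synthetic recordings

Single-channel activity is modelled as a continuous-time Markov chain over
channel conformations.  The default profiles are two-state (closed ⇌ open)
schemes with rate-theory voltage dependence,

    k_open(U)  = k0 · exp(+(U − V½)/(2s)),
    k_close(U) = k0 · exp(−(U − V½)/(2s)),      k0 = 1/τ_open(V½),

which gives the Boltzmann stationary open probability
p_op(U) = 1/(1 + exp(−(U − V½)/s)) and exponential dwell times in both
states.  Simulation is exact: Gillespie event sampling of the embedded
chain, started from the stationary distribution, then zero-order-hold
resampling at the recording rate, so dwell statistics are independent of
the sampling step.  Rendering adds the open-channel current
i = g·(U − E_rev) with g = 300 pS (the hallmark mitoBK conductance,
18 pA at +60 mV), baseline offset, Gaussian instrument noise
(default SD 0.8 pA) and, optionally, a causal single-pole low-pass at a
configurable corner (1 kHz for realism runs; off by default so unit tests
see the unfiltered two-level signal).

Two profile sets are shipped, sharing the three cell-type labels:

| profile set | endothelium | fibroblast | hippocampus |
|---|---|---|---|
| `default_profiles` (Boltzmann) | V½ +5 mV, s 12 mV, τ 2 ms | V½ −20 mV, s 14 mV, τ 6 ms | V½ −30 mV, s 10 mV, τ 4 ms |
| `well_separated_profiles` (voltage-independent) | p_op 0.1, τ_open 1.5 ms | p_op 0.5, τ_open 4 ms | p_op 0.9, τ_open 10 ms |

The Boltzmann set mirrors the real system's structure: activation curves
converge at extreme potentials (all p_op near 0 or 1) while fibroblast and
hippocampus are deliberately similar in both midpoint and dwell scale and
endothelium is right-shifted and faster — so class separation must come
from the fluctuation texture, and the fibroblast–hippocampus pair is the
nearest pair in the latent space.  The voltage-independent set is the
clearly-classifiable benchmark: open probabilities 0.1/0.5/0.9 with
distinct dwell times at every potential.  Each recording defaults to
N = 2×10⁵ current values at 4.00 kHz over the six pipette potentials
{−60, −40, −20, +20, +40, +60} mV, with 3 or more independent recordings
per (cell type, potential).

**Planted anomalies** substitute a perturbed scheme for extra recordings:
the stationary p_op is shifted (default 0.3) towards the balanced regime
and the dwell-time scale slowed ×5, emulating a channel stuck in an
aberrant long-lived kinetic mode.  Both perturbations *increase* the
window-scale fluctuation of the trace, which is what the reconstruction-
error detector can see (below).

## Kinetic analysis

The threshold current TC separating conducting from non-conducting samples
is located on the log–log amplitude density: an Epanechnikov-kernel KDE of
log|I| (Silverman-style bandwidth, 512-point log grid, a half-grid-step
offset guarding log 0), the two conductance modes, and the intersection of
two straight-line (power-law) least-squares fits placed on the widest
grid windows flanking the inter-modal valley whose rolling linear fit
reaches R² ≥ 0.98.  When no such window pair exists the estimator falls
back to the arithmetic midpoint of the two mode amplitudes (logged).

Mode detection is the numerically delicate part.  The dominant mode is the
density maximum; a partner mode must (a) be separated from it by a valley
dipping ≥ 1.5 log-units (an ≥ 4.5-fold density dip) below both peaks and
(b) keep at least 0.1% of the samples on its own side of the valley.
The dip test rejects KDE raggedness inside a single mode; the mass test
rejects sparse-tail wiggle that would otherwise mimic a second state.  A
recording that fails both (the channel effectively never leaves one state)
is reported by `estimate_open_probability` as p_op 0 or 1, decided by
whether the dominant mode sits at open-channel amplitude (median |I| above
half the maximum magnitude).  Working on |I| makes one rule cover both
voltage signs.  p_op is the fraction of samples with |I| > TC, and
activation curves are least-squares Boltzmann fits
p_op(U) = p_max/(1 + exp(−(U−V½)/s)) with bounds 0 < p_max ≤ 1 (an
active p_max bound triggers a fixed-p_max Levenberg–Marquardt polish).

## Preprocessing and cross-validation

Truncate to the shortest recording (keeps every class contributing the
same number of windows), window (l = 1000, r = 200, exactly ⌊(L−l)/r⌋
windows at offsets 0, r, 2r, …), PAA to w = 200 (l must divide evenly),
min–max scale to [0, 1].  The scaler is fitted on the fold's training
values only and applied to the test set with clipping (counted and
reported); a `joint` normalization scope reproduces the alternative
reading in which all data are scaled together before the split.  The
cross-validation iterates over the full Cartesian product of per-class
test-recording choices (3×3×3 = 27 folds for three recordings per class);
truncation length is computed over train and test together, since all
recordings must share one window count.

## Autoencoder

A plain-numpy MLP: sigmoid activation on every layer (a linear output
layer is available as a switch), Glorot-uniform initialization, Adam
(lr 10⁻³, β 0.9/0.999), minibatch 64, default 200 epochs, fully
deterministic per seed.  The training log records the full-data
reconstruction error J at initialization and after every epoch; the
returned weights are those of the best epoch, so the final J never exceeds
the initial one.  Backpropagation is verified against finite differences
(relative error < 10⁻⁴ on a 2–3–2 network) in the test suite.  On a 1-D
manifold embedded in 200 dimensions (sine curves of varying phase) the
200–100–50–2 architecture reaches J ≈ 0.18 at learning rate 0.03 after
600 epochs, i.e. ~99% of the signal energy through a 2-D bottleneck; that
frozen oracle run sets the regression threshold in the tests.

## Anomaly detection

Per (cell type, potential) category one bottleneck-2 autoencoder (100
epochs) is trained on the pooled windows of all recordings — the suspect
included — and each recording is scored by the mean J over its own
windows.  Flagging uses the modified z-score
(score − median)/(1.4826·max(MAD, 0.10·median)) > 3.5.  The 10%-of-median
floor on the robust scale matters: with only three recordings per
category the MAD collapses whenever two scores nearly coincide, and the
recording-to-recording spread of mean J in low-p_op categories is ~25%
even without any anomaly; at the floored scale a flag requires a score
~50% above the category median, while genuinely aberrant patches score
about 3× the median.  A Tukey fence (Q3 + 1.5 IQR) covers the exact
zero-scale corner.  The flagged call can be confirmed by the
J-versus-bottleneck-dimension sweep: an outlier's curve lies above the
typical recording's at every tested width.

Known limitation: the score is a *mean reconstruction error*, so only
perturbations that make windows harder to reconstruct (higher fluctuation
or chunkier dwell structure) are detectable by the one-sided rule; an
anomaly that makes a balanced (p_op ≈ 0.5) channel *quieter* lowers its
error and stays invisible.  The planted-anomaly validation therefore hosts
anomalies in the unbalanced classes, where a 0.3 shift towards p = 0.5 is
reliably caught (sensitivity 1.0, zero false flags over 20 seeded
datasets).

## Classification and latent geometry

KNN (K = 5, Euclidean) always runs on the 200-dimensional samples, never
on the 2-D embedding.  Distances use the BLAS Gram-matrix identity with
an argpartition preselection; ranking ties are resolved by stable training
order, voting ties by the smaller summed neighbor distance, then
lexicographic class order — predictions are verified identical to a
brute-force all-pairs oracle.  Accuracy is the diagonal fraction of the
summed confusion matrix, in percent; the per-fold mean is reported
alongside.

For the latent geometry, the fold's pooled test samples are compressed by
a bottleneck-2 autoencoder (100 epochs), clustered by K-means (K = number
of classes, Lloyd iterations from random data-point initialization, best
of 10 restarts, via scikit-learn), clusters mapped to their majority class
(collisions resolved by exhaustive maximum-agreement permutation), and the
three pairwise centroid distances recorded.  The default report averages
distances over the cross-validation folds; a single-shot mode embeds all
data once.  Distances are in latent units and are not comparable across
potentials, since each potential gets an independently trained network.

## Problem sizes and runtime

Classification and kinetics validation runs use the full experimental
trace length, N = 2×10⁵ values per recording (995 windows each): on the
benchmark fixture the cross-validated accuracy is ≥ 95% at every potential
there, whereas 10× shorter traces lose 2–5 accuracy points to training-set
sparsity (the high-variance p = 0.5 class leaks towards its quieter
neighbours).  The anomaly-sensitivity study and the permutation control
use 2×10⁴-point traces (95 windows per recording), where detection is
already saturated, and the fold-averaged latent distances use
5×10⁴-point traces to keep 27 autoencoder trainings affordable.  The full
test suite runs in ~10 minutes on one CPU; `scripts/acceptance.py` in
~15 minutes.

## What the synthetic data do and do not show

The generator reproduces the statistical skeleton of the experiment —
two-level stochastic gating with exponential dwells, voltage-scaled
amplitude, Gaussian noise, class-specific kinetics, occasional aberrant
patches — so passing tests demonstrate that the pipeline's stages are
implemented correctly and that the method separates classes whose gating
differs in the designed ways.  They do not show performance on real
mitoBK data: real traces contain subconductance states, baseline drift,
flicker noise, multi-channel stacking and non-Markovian (long-memory)
gating that the two-state simulator deliberately omits, and the published
accuracies for the experimental recordings are not reproducible here
because those data are available only on request.
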