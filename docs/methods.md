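# Methods

## Pattern model

Spontaneous ensemble activity is binarized in non-overlapping 10-ms bins
(half-open [t, t+dt); a spike exactly on a boundary belongs to the later
bin), σᵢ = +1 iff unit i spiked in the bin, −1 otherwise. The ±1 alphabet
is used everywhere because the fitted biases and couplings are
convention-dependent. The canonical ordering of the 2^N patterns is binary
counting with −1 ↔ 0 and unit 1 as the most significant bit; parameters and
observables share the ordering [h₁…h_N, J₁₂, J₁₃, …] (row-major upper
triangle).

The pairwise maximum-entropy model is the Boltzmann distribution
P(σ) ∝ exp(Σhᵢσᵢ + ½ΣJᵢⱼσᵢσⱼ). Fitting is plain gradient descent on the
moment discrepancies with simultaneous updates of all N + N(N−1)/2
parameters:

* learning rate α = 0.1; tolerance 0.005 on the max-abs discrepancy over
  all constrained moments; at most 100 iterations (a fit stopping at the
  cap is retained with `converged_ = False`);
* initialization at the independent solution, h = atanh(⟨σᵢ⟩) with rates
  clipped to ±(1 − 10⁻⁴) for degenerate units, J = 0;
* model moments by exact enumeration for N ≤ 20 (the default for N = 10;
  deterministic) or by Metropolis Monte Carlo (100 000 recorded sweeps)
  when `moment_method="metropolis"` is requested.

The independent model runs the same loop with J frozen at zero; its closed
form is hᵢ = atanh(⟨σᵢ⟩).

Metropolis sampling uses single-site flip proposals, acceptance
min(1, e^{−ΔE}), one sweep = N proposals, a uniform random initial pattern,
1000 burn-in sweeps, and one recorded sample per sweep; the kernel is
numba-jitted with all random numbers pre-drawn from a seeded
`numpy.random.Generator`, so sample streams are reproducible bit-for-bit.
Recorded sweeps are autocorrelated; effective sample sizes are below the
nominal count, which matters only for error bars, not for correctness.

Goodness of fit uses the Jensen–Shannon divergence (natural log) between
the empirical pattern distribution and the model's; the Kullback–Leibler
ratio R = (D₁ − D₂)/D₁ uses D_k = D_KL(P_data ‖ P_model_k). The latter
argument order is the only finite choice, since a fitted model assigns mass
to patterns the data never shows.

## Fisher information and sensitivity

The FIM is computed as the covariance of the observable vector under the
model (exact enumeration by default; Metropolis with 500 000 recorded
sweeps as an option). Eigenvalues are sorted descending with stable
tie-breaks; tiny negative eigenvalues from Monte Carlo noise are floored at
zero with a warning; each eigenvector's sign is fixed so its
largest-magnitude component is positive. Because the eigenvector sign is
arbitrary, the first-eigenvector sensitivity uses absolute components,
s_ne,i = (1/NE) Σ_t |ν_{t,1}(i)|; the weighted variant averages
|ν_{t,k}(i)| over all k with weights a_{t,k}/Σ_k a_{t,k}.

Population-level sensitivities average s_ne over the random ensembles
covering each unit or pair; uncovered elements are reported missing and
excluded from median splits and correlations (coverage counts are stored).
The stiff/sloppy median split sends exact-median ties to sloppy; an
all-equal degenerate input labels everything sloppy with a warning.

Parameter trajectories Ω(t′) are projected raw (uncentered) onto the
eigenvectors of the FIM at each reference epoch t; the per-rank variance
over t′ ≠ t uses the population (1/n) variance so the two-epoch case is
defined, and is averaged over reference epochs and ensembles.

Stationary surrogates redraw 5000 patterns per surrogate epoch from one
fixed reference model, refit with the same controls, and recompute FIMs; by
construction all parameter fluctuation across surrogate epochs is
estimation error. Two properties of this construction are worth stating
explicitly. First, the tolerance-stopped fit carries a small systematic
parameter offset (the fit stops once moments are within 0.005, approaching
from the independent-solution side), so surrogate parameter means track the
reference closely but are not exactly unbiased. Second, for a
moment-matched exponential family the estimation-error covariance is
approximately FIM⁻¹/M, i.e. estimation noise itself concentrates in sloppy
dimensions; the surrogate projection-variance profile therefore *rises*
steeply with rank. On the synthetic data the observed profile exceeds the
surrogate profile at every rank — genuine drift is present throughout — with
the largest excess at rank 1, where the state process moves stiff
parameters. Consequently the rank-55/rank-1 variance ratio of the data does
not exceed the surrogate's here; the per-rank data-vs-surrogate excess is
the informative comparison, and both profiles and both ratios are reported.

## Cortical state, evoked responses, network

Silence density CS(t) is the fraction of empty 20-ms bins within an epoch's
spontaneous windows, merging single- and multi-unit spikes; evoked bins are
excluded, since state is a property of spontaneous activity. Observable
time series pair each single unit's firing rate (Hz over spontaneous
windows) with Pearson correlations of the ±1 binarized trains at 10 ms;
rcs is the absolute Pearson correlation of each observable with CS(t)
across epochs (missing below 3 valid epochs). The rcs-vs-s relation is
reported three ways: element-level Pearson correlation with 95% CI, a
Welch two-sample test of rcs for stiff vs sloppy elements, and a paired
t-test across ensembles of within-ensemble stiff/sloppy means.

The modulation index uses 0.5-s pre/post-stimulus spike counts averaged
within epochs; MI = 0 when both counts are zero (an unresponsive unit),
and the response sign (excited/suppressed/null) is pooled over the session.
ΔMI(CS) uses 8 equal-width bins over the observed CS range, dropping bins
with fewer than 3 epochs. The eigenvector–MI relation maps a 55-element
first eigenvector to the ensemble's 10 units through its h-block
components.

The functional graph tests, per pair of single units, whether the NE
epoch-wise correlations differ from zero (one-sample t-test, Bonferroni
over all pairs, corrected p < 0.05, sign-agnostic); a zero-variance nonzero
series is treated as significant with a warning. Betweenness centrality is
unnormalized shortest-path centrality over unordered pairs (computed via
networkx; an independent path-counting oracle checks it in the tests).
Neuron-to-population coupling correlates each unit's ±1 train with the
co-active count of the other single units per 10-ms bin, averaged over
epochs. Class separations use the rank-statistic AUC (ties half credit;
AUC = 1 ⇔ stiff entirely above sloppy) with an add-one-smoothed two-sided
permutation p-value (1000 resamples by default; the smallest attainable p
is 1/(n_perm+1)).

## Synthetic generator

The generator emulates a ~2-h anesthetized auditory-cortex recording in
statistical outline, not biophysics. Defaults: 60 single units (30% core)
plus 20 multi-units (each the merge of two hidden units, used only for
silence density), 3000 s (NE = 30 epochs of 100 s), clicks every 3.5 s
(≈28 per epoch, hence ≈42 s of 1.5-s pre-stimulus windows per epoch),
baseline rates 5–15 Hz (core) and 0.5–4 Hz (periphery). Spikes are
Bernoulli per 10-ms bin with probability
logistic(bᵢ + wᵢ·u(t) + Σ_f λ_{i,f} z_f(t) + evoked).

* State: a latent AR(1) process g(t) (coefficient 0.999 per 20-ms step,
  mean −0.5, stationary SD 2.0) sets through a logistic link the
  probability that each 20-ms step is a population *down* state; the
  realized excitability u(t) is 0 in up steps and −4 log-odds in down
  steps, scaled per unit by its state loading (core 0.9–1.1, periphery
  0.5–0.8). Synchronized stretches thus show high silence density *and*
  strong pairwise correlations, as cortical up/down alternation does. The
  AR(1) mean/SD were calibrated once so epoch-level CS spans roughly
  0.1–0.55.
* Fast correlations: two shared factors, refreshed independently every
  bin, with loadings 0.8–1.5 on the core and 0.1–0.3 on the periphery.
* Non-stationarity: periphery biases follow a per-epoch random walk (step
  SD 0.1 log-odds).
* Evoked responses: a per-unit log-odds gain applied for 0.5 s after each
  click; periphery |log-gain| 0.8–1.6 (60% excited, 40% suppressed), core
  0.0–0.2.

What the generator does *not* emulate: refractoriness and spike-train
autocorrelation beyond the 20-ms telegraph, heavy-tailed rate
distributions, genuine synaptic connectivity (correlations are all common
input), stimulus adaptation, and spike-sorting artifacts. Passing tests on
this generator show the pipeline recovers imposed structure of realistic
magnitude; they do not certify the neuroscientific conclusions on any real
recording.

A second ground-truth mode draws patterns directly from random 10-unit
Ising models (h uniform in [−1.5, −0.5], Jᵢⱼ normal with SD 0.1 — sparse
activity, weak coupling) via Metropolis, for exact (h, J) recovery tests.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the full pipeline on
2000-s recordings (NE = 20) with Q = 8 ensembles of N = 10, two generator
seeds, exact-moment fits and exact FIMs; ground-truth recovery uses ten
seeds of 5000 Metropolis patterns refit with the iteration cap raised to
1000 so the 0.005 tolerance is actually reached (at the default cap of 100
the discrepancy stalls near 0.007–0.01; all other controls at their
defaults). These sizes were chosen as the smallest at which the epoch-level
pair statistics are no longer noise-dominated: at NE = 12 the null scale of
an epoch-course correlation (≈0.23 absolute) swamps the pair-level rcs
signal. Calibration studies use 400 simulations each (permutation-p
uniformity; Bonferroni family-wise false-edge rate).

Known limitations: fits at the default 100-iteration cap usually stop
before tolerance on strongly correlated epochs (retained, flagged); the
N ≤ 20 enumeration bound is enforced, larger ensembles require the
Metropolis path; divergences involving empirical distributions are computed
on the full 2^N support with zeros allowed (JS stays finite); and the
package deliberately excludes spike sorting, proprietary formats,
higher-order maximum-entropy models, and graph drawing.
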