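# Methods

`confacc` models protracted perceptual decisions in a two-category
orientation task (a weather-prediction-style paradigm) and provides the
analysis machinery — behavioural, model-based, and neural-decoding — needed
to test whether observers commit to perceptual decisions covertly while
continuing to accumulate evidence for confidence.

## The task and the optimal observer

On each trial a sequence of oriented stimuli is shown; each orientation
θ ∈ (−π/2, π/2] is drawn from one of two axial Von Mises distributions with
means ∓45° from vertical and concentration κ,

    p(θ | ψ) = exp(κ cos 2(θ − μ_ψ)) / (π I₀(κ)),     ψ ∈ {1, 2}.

κ defaults to 0.5, which makes the categories overlap heavily: single samples
are weakly informative and accuracy grows with sequence length.  The optimal
observer accumulates the per-sample log-likelihood difference

    ℓ_n = κ [cos 2(θ_n − μ₁) − cos 2(θ_n − μ₂)] = −2κ sin 2θ_n,
    L_N = Σ_{n≤N} ℓ_n,

and chooses category 1 iff the terminal L is positive.  Sampling treats
orientation as an axial variable: φ = 2θ is drawn from a Von Mises with mean
2μ_ψ and concentration κ, then halved, which realises the density above on
the half-open support.

A session consists of 100 predefined sequences of up to 40 samples (half per
category), each repeated three times in the Free task, where the observer
responds whenever ready.  In the Replay task the sequence stops after a
prescribed number of samples derived from the same observer's Free-task
behaviour on that sequence: two fewer than the minimum of the three response
counts (Less; floored at one sample), the median (Same), or four more than
the maximum (More).  A 4-point confidence rating follows each Replay choice.

## The suboptimal observer

The generative model corrupts each update with i.i.d. Gaussian inference
noise ε_n ~ N(0, σ²) and integrates with a leak/primacy weight α,

    A_N = α A_{N−1} + (ℓ_N + ε_N),

so that sample n carries terminal weight α^(T−n) (α > 1 primacy, α < 1
recency).  We use this recursive form throughout, so a bound check at sample
N sees weights α^(N−n) — the only causal formulation consistent with online
commitment.  The observer responds when |A_N| exceeds a collapsing bound.
The bound's printed form is ambiguous between an additive and a
multiplicative reading; the default is the additive parse

    bound(n) = n·a + b·exp(−n·λ),

with the multiplicative parse n·(a + b·exp(−n·λ)) selectable via
`bound_form="multiplicative"`.  In the Free task the key press follows the
crossing after a Gaussian non-decision time (truncated at zero); the response
is attributed to the sample interval containing the key press.  In the Replay
task the same bound can operate *covertly* (`covert_bound=True`): a crossing
before the cue freezes the choice and later samples are ignored for the
perceptual decision.  Choice and confidence bias and lapse parameters are
omitted from the model.

Confidence is read from a second accumulator over the same noisy evidence
with its own integration weight α_c and extra per-sample noise of SD ε_c
(a single terminal noise draw is available via `conf_noise_locus`).  The
terminal confidence evidence, signed by the perceptual choice, is partitioned
into ratings 1–4 by three increasing collapsing bounds of the same functional
family as the decision bound, sharing one linear coefficient and decline rate
with three increasing scales.  Confidence accumulation never stops at the
covert bound — this partial dissociation is the architecture under test.

Default parameters (σ = 0.6, α = 1.0, bound a = 0.15, b = 3.0, λ = 0.12,
non-decision time 0.35 ± 0.08 s at a 3 Hz sample rate, ε_c = 0.4,
confidence scales 0.5/2.0/4.0 with a_c = 0.18, λ_c = 0.1) were chosen once so
that the simulated Free task shows accuracy ≈ 0.86, a mean response sample
≈ 10 with few forced 40-sample trials, a graded four-point confidence usage,
and a strong confidence–accuracy association — the regime in which the
Less/Same/More manipulation is informative.

## Fitting and model comparison

Trial likelihoods have no closed form; the probability of an observed
outcome — (response sample, choice) in the Free task, cue-time choice (and
optionally rating) in the Replay task — is its relative frequency over
Monte-Carlo draws of the inference noise (default 1000 per trial), floored
at 1/(2·n_mc).  Over all possible (sample, choice) outcomes of a trial the
unfloored frequencies sum to one by construction, which the tests verify
against an independent per-draw tally.

The summed negative log-likelihood is minimised by Nelder-Mead within box
bounds.  Two stabilisers tame the stochastic objective: *common random
numbers* (the standard-normal draws are frozen per fit and rescaled by the
candidate σ, making the objective a deterministic function of the
parameters), and *multistart* from a deterministic start list whose first k
entries are shared for any larger k, so adding starts can only (weakly)
improve the result.  Fits ending on a box edge are flagged, not raised.

Cross-validated comparison assigns folds at the sequence level (all repeats
of a sequence stay together) and scores held-out trials with a fresh
Monte-Carlo seed shared between the variants, so identical variants give
exactly zero per-trial difference.  The covert-bound question is answered
the way the architecture demands: the bound is identified where it is overt
— the Free task response-sample distribution — and the comparison asks
whether applying that fitted bound covertly predicts held-out Replay choices
better than accumulating to the cue (`covert_bound_comparison`).  A
choice-only comparison that refits both variants on Replay data alone is
also provided (`crossval_compare`) but discriminates weakly, because a
primacy α mimics commitment.  Significance uses a percentile bootstrap over
per-trial log-likelihood differences.

## Behavioural analyses

Sensitivity is d′ = z(hit) − z(false alarm) with rates clipped to
[1/(2N), 1 − 1/(2N)].  The optimal-confidence label is high iff the evidence
for the chosen category exceeds its median over trials (ties low).  The
evidence GLMs regress the choice (probit link) or the binarised rating
(High = 3–4, evidence signed by the choice) on the optimal accumulated
evidence, per subject, condition, and horizon: the full sequence vs the
sequence truncated four samples before the cue (floored at one sample).  The
evidence regressor is z-scored within each cell, so coefficients measure
predictive strength per SD of evidence and are comparable across horizons
whose raw evidence variances differ; a cell showing (near-)separation falls
back to an L2-penalised logistic fit rescaled to the probit scale and is
flagged.  The condition-by-horizon interaction is a within-subject
repeated-measures ANOVA on the per-subject coefficients.

## Neural decoding

Stimulus-locked epochs are reduced to band-limited analytic-signal features
(zero-phase Butterworth 1–8 Hz, Hilbert transform, real and imaginary parts)
and decoded with ridge regression (penalty 1, 10-fold cross-validation).
Precision is the Fisher z of the Pearson correlation between held-out
predictions and the encoding variable, pooled over folds.  Predictions and
targets are centred within fold before pooling: the pooled statistic
otherwise inherits a negative bias from each fold's training-set mean.  Even
so, the pooled r under joint train-and-score target shuffling is
over-dispersed relative to the analytic null (every fold's weights are
trained on targets scored in other folds); significance of a precision value
is therefore referred to the permutation null of fixed held-out predictions
against fresh null targets (`null_precision_distribution`), which matches
the Fisher null SD 1/√(n−3) exactly.  Orientation is decoded as the
(sin 2θ, cos 2θ) pair with precision computed on the reconstructed angle via
a circular correlation.  Temporal generalisation applies weights trained at
one time point to every other; its diagonal reproduces the per-time decoder
exactly because folds and fits are shared.

Response classification uses LDA on motor-band power (wavelet convolution,
25% fractional bandwidth, unit-energy tapers so white noise is flat across
frequencies; power averaged over 8–26 Hz), scored by ROC AUC.  Per-trial
prediction strength is the relative normalised distance to the class means
in discriminant space (0.5 = equidistant).  In practice the strength is
estimated from power averaged over a window around the response
(−0.25 to 0.1 s), which is substantially less noisy than a single time
point.  The strength-vs-evidence regression z-scores the evidence per cell,
as in the behavioural GLMs.

Precision contrasts (outcome 2×2 cells; More−Less on the final four samples
of each trial) are tested with subject-level sign-flip cluster-mass
permutation (threshold at the two-sided t critical value, 10³–10⁴ flips).

## Scan statistic

To isolate signals reflecting the observer's internal evidence L* rather
than the presented evidence L, per-(electrode, time) representation errors
are tested for variance inflation on epochs leading to non-optimal
responses: H1 puts error variance σ_meas² + σ_behav² in non-optimal epochs
against σ_meas² everywhere under H0, with Gaussian likelihoods and
method-of-moments variances (cells with fewer than 10 epochs per group are
masked).  Cells whose log-likelihood ratio exceeds −log(prior odds) are
grown into spatio-temporally contiguous clusters (electrodes within an
adjacency radius that defaults to 1.5× the median nearest-neighbour
distance; time contiguity with 8-neighbour growth); a cluster is reported
when prior_odds^|cells| · exp(Σ LLR) > 1.  The per-cell prior (default
10⁻³) is the single sensitivity parameter; it was calibrated under a
pure-noise null so the family-wise false-cluster rate stays below 0.05 on
grids of a few hundred cells, and raising it can only add clusters.

Representation errors must be deviations of the decoded value from its
*expectation given L*, not from L itself: the raw deviation confounds
decoder imprecision with the target's own variance, which differs between
behavioural groups (non-optimal responses concentrate where |L| is small).
`representation_errors` residualises predictions on the target per cell,
optionally within groups (e.g. condition × commitment × sample position) to
absorb systematic gain changes — such as the attenuation that follows a
covert commitment — that would otherwise masquerade as representation noise.
Cluster-level decoding refits ridge weights on the cluster's cells only and
ranks epochs into Noise Min / Noise Max quartiles by absolute representation
error.

## The synthetic cohort generator

The generator emulates the study end to end and is the test bed for every
stage.  Behaviour: per-subject parameters drawn from uniform priors
(σ ∈ [0.2, 1.0], α ∈ [0.85, 1.2] by default), three Free-task repeats of the
predefined sequences, Replay lengths derived from the subject's own Free
responses, Replay choices and ratings from the accumulator with or without
the covert bound.  All randomness descends from one master seed;
regeneration is byte-identical.

Neural epochs follow a linear forward model with three encoding variables,
each with a Gaussian temporal kernel and a smooth scalp loading map on a
deterministic spiral montage: a transient orientation code over posterior
channels (100–200 ms), a sustained decision-update code over central
channels (400–600 ms), and a long-lived accumulated-evidence code over
frontal+occipital channels (600–800 ms), on top of white sensor noise.
Epoch-level representation noise is injected into the accumulated-evidence
code inside a fixed (electrode, time) mask, with its SD doubled on trials
whose response deviates from the optimal observer — the ground-truth effect
the scan statistic recovers.  After a covert commitment the
accumulated-evidence encoding gain drops to 10% for the remaining samples.
Response-locked epochs carry a motor-band (20 Hz) oscillation over left and
right motor channel groups whose amplitude over the hemisphere contralateral
to the response hand is suppressed (desynchronisation) from the decision
time on — the covert commitment in committed Replay trials, shortly before
the key press otherwise — with suppression depth increasing in the decision
evidence at that moment.  The forward gains and noise SDs were calibrated
once so that each downstream analysis operates at a realistic
signal-to-noise ratio: single-channel decoding of accumulated evidence
attains r ≈ 0.4, multichannel precision z ≈ 0.5–1, response classification
AUC ≈ 0.95+, and the injected scan effect is recoverable.

What the generator does *not* emulate: real EEG artefacts (blinks, line
noise, volume-conduction channel mixing from a head model), autocorrelated
background activity, non-stationary noise, or motor dynamics beyond the
amplitude envelope.  Passing tests therefore demonstrate that the analyses
recover the structures they target at plausible SNR — not that they are
robust to real-recording artefacts, which the out-of-scope pre-processing
stack would have to remove first.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen as the package's own defaults for a single-CPU workflow: parameter
recovery uses 20 simulated observers × 300 Replay trials with 200
Monte-Carlo draws and two starts; covert-bound recovery uses six 2-subject
cohorts with 2-fold cross-validation; the end-to-end cohort has 16 subjects
× 80 sequences with 16-channel epochs at 64 Hz; scan calibration uses 200
null runs on a 16-electrode × 20-time grid with 200 epochs.  Directional
hypothesis tests are evaluated at α = 0.05.  Degenerate inputs fail loudly
(single-class responses, constant targets, empty cells, too-small clusters);
probabilities are floored rather than allowed to reach log 0; ties at the
optimal-confidence median count as low.

## Known limitations

- The exact functional form of the confidence bounds and the locus of the
  confidence noise in the original architecture are under-determined by the
  available description; both are implemented with explicit switches.
- The scan statistic is a reconstruction (Gaussian variance-inflation LLR,
  greedy contiguous growth, per-cell prior); it is isolated behind one
  interface so alternatives can be swapped in.
- The Replay-task likelihood uses the cue-time outcome only; per-sample
  Replay response dynamics are not modelled.
- Cohort-level inference in the desk-scale comparisons bootstraps pooled
  per-trial log-likelihood differences; with 20+ subjects a
  bootstrap-over-participants is the better choice and is what the
  full-scale configuration intends.
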