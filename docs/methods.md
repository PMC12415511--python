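# Methods

`feedbacklearn` implements a complete, simulation-testable version of a
trial-level analysis pipeline for active and observational probabilistic
feedback learning in a three-group clinical design (OCD, healthy controls,
social anxiety disorder).  This note documents the models, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Task model

A session has 400 trials: four 60-trial learning blocks alternating with
four 30-trial test blocks, then a 40-trial transfer phase.  Three stimulus
pairs with reciprocal win-feedback contingencies (A/B = 80/20, C/D = 70/30,
E/F = 60/40) appear equally often within each learning/test block; the
transfer phase re-pairs A and B with the four stimuli each has not been
seen with (8 novel pairs, 5 presentations each).  Feedback (win = +20
points, loss = −10) is delivered only on learning trials; test and transfer
trials end with the choice.  Within-block pair order is an unconstrained
seeded shuffle and left/right placement is randomized per trial, as no
ordering constraints are part of the design.

Observational sessions are yoked: the learning phase replays a completed
active session's choices and outcomes verbatim, the observer learns
vicariously, and catch prompts are flagged after learning trials at a
configurable rate (default 0.2).  Test and transfer responding is the
observer's own.  In the cohort simulator each participant observes the
previous participant's active session; session order (active first vs.
observational first) is counterbalanced across the roster.

Simulated reaction times are normal (mean 470 ms, sd 120 ms, clipped at
50 ms), so roughly 1–2 % of responses fall under the 200-ms validity
cutoff; no-responses occur independently at 0.5 %.  Together these produce
an invalid-trial rate near the ~2 % seen in comparable empirical data, and
they give the validity filter real work in end-to-end tests.

## Reinforcement-learning model family

Values are win probabilities: Q ∈ [0, 1], initialized at q0 = 0.5
(uninformative), with rewards coded r = 1 (win) / 0 (loss).  With this
coding, gating the learning rate on feedback valence is identical to gating
it on the sign of the prediction error r − Q.  The family crosses:

* **learning rates** — one shared α, or separate α+ (win) and α− (loss),
  applied as a delta rule Q ← Q + α(r − Q) on the chosen (own or observed)
  stimulus;
* **feedback-free dynamics**, applied after every valid test or transfer
  choice — *static* (no change), *decay* (both pair members relax toward q0
  at rate γ), or *cipc* (choice-induced preference change: the chosen
  value moves toward 1 and the unchosen toward 0 at rate ε:
  Qc ← Qc + ε(1 − Qc), Qu ← Qu − εQu).

The CIPC form is a bounded spreading-of-alternatives update; it is isolated
behind one function so alternative parameterizations can be swapped in.  It
is applied in both test and transfer phases, since the likelihood covers
both.

**Fitting.**  The likelihood covers only valid feedback-free choices
(test + transfer; at most 160 per session), so active and observational
sessions are fitted by one identical procedure: learning-phase outcomes
drive the value updates and the model is scored on
−Σ log p(choice) with p the logistic (softmax) of β·ΔQ.  Sessions are
fitted separately per agency.  Optimization is bounded L-BFGS-B (bounds:
rates in [0, 1], β in [0, 50]) from 20 Latin-hypercube starting points
(seeded; β starts confined to [0.2, 15]); the best converged start wins and
all start NLLs are retained.  The likelihood core is numba-compiled; a pure
brute-force re-implementation in the test suite guards its correctness to
1e−10.  Model comparison uses BIC = k·ln(n) + 2·NLL with n the session's
valid likelihood-trial count, summed over participants.

**Latent traces** per trial: Q of chosen/unchosen option (before the
trial's update), signed PE = r − Q_chosen on feedback trials, its absolute
value SPE (surprise), and ΔQ = Q_chosen − Q_unchosen (predictive accuracy).
SPE is also returned mean-centered for use as a regressor.

### Parameter identifiability under the held-out likelihood

Recovery simulations (100 agents, default task, parameters drawn once from
a priori plausible ranges: α ~ U(0.05, 0.7), β ~ U(1, 10),
ε ~ U(0.05, 0.5)) show that with the likelihood restricted to feedback-free
choices the learning rates and β are only weakly identified: generating-
vs-recovered correlations are ≈ 0.45–0.50 for α+, α− and β, and ≈ 0.7 for
ε.  This is a property of the procedure, not of the optimizer — the
multistart fits reliably reach NLLs below the generating parameters' own
NLL, quintupling the likelihood-trial count raises the correlations only
to ≈ 0.45–0.55, and adding the learning-phase choices to the likelihood
(which the held-out design deliberately excludes, to keep active and
observational fitting identical) raises them to ≈ 0.75–0.9.  The CIPC
dynamics are the main culprit: they saturate values toward 0/1 during test
blocks, masking the learning trajectory the alphas shaped.  Model
*selection* is far better behaved: the generating dual-rate + CIPC variant
wins the summed-BIC ranking in essentially all simulated cohorts against
static and decaying alternatives.  The corresponding recovery test asserts
the stricter correlation thresholds and documents this limitation when it
fails; ε recovery and BIC model recovery pass.

## Behavioral coding

* **Validity** — a trial is invalid if no response was made or RT < 200 ms
  (strict; 200 ms exactly is valid).  Negative RTs are data errors.
* **Accuracy** — correct iff the chosen stimulus has the higher win
  probability in its pair.
* **Win-stay/lose-shift** — per pair, each valid encounter is compared with
  the most recent valid prior encounter (invalid encounters are skipped,
  not treated as shifts); that prior encounter supplies the previous
  feedback valence and its authenticity: *authentic* iff valence matches
  the choice's correctness (win∧correct or loss∧incorrect), else
  *misleading*.  Δ sensitivity scores are shift-rate(misleading) −
  shift-rate(authentic) per valence; adaptive behavior gives Δwin > 0 and
  Δloss < 0.
* **Learning status** — per participant × pair, a sliding window over the
  ordered valid learning trials finds the first trial whose 10 preceding
  trials exceed 90 % mean accuracy (strict >0.9, which a 10-trial window
  makes 10/10); the candidate is accepted only if mean accuracy over all
  remaining trials exceeds 65 %, otherwise the search continues.  Without
  an accepted breakpoint all trials stay pre-learning.  Both thresholds and
  the window length are configurable, and the windows are computed over
  learning trials only by default (config-switchable to include test
  trials).  Post-learning trials always form a suffix.

## Synthetic EEG and ERP scoring

Epochs cover −200…600 ms around feedback or response onset over the
fronto-central cluster (Fz, FCz, FC1, FC2, Cz) at a default 500 Hz (1 kHz
in runs that must resolve 1-ms peak latencies).  Each epoch is a shared
cluster signal — a negative Gaussian deflection (width 25 ms) at a
configurable latency (FRN default 261 ms, +10 ms for observational trials;
ERN/CRN 19 ms) — plus shared and per-electrode white noise and an optional
random drift.  The deflection kernel is normalized so its mean over the
±30 ms window at its latency equals one; amplitude parameters (component
depth, loss-vs-win condition effect, observational gain on that effect,
SPE coupling slope, participant offsets) are therefore expressed directly
in scored microvolts, which makes the noiseless identity between configured
and recovered effects exact.  Artifact injection can corrupt a configurable
fraction of epochs in ways that violate each QC rule.

Scoring follows a hierarchical, condition-blind procedure:

1. **Baseline correction** — subtract each trial × electrode's mean over
   the pre-event samples (t < 0); idempotent.
2. **QC** — reject an epoch if, on any cluster electrode: |V| > 100 μV;
   peak-to-peak < 0.5 μV within any 100-ms span; peak-to-peak > 200 μV
   within any 200-ms span; or a step > 50 μV between consecutive samples.
   QC runs after baseline correction; a log names every rule fired.
3. **Composite waveform** — pool the cluster electrodes, form each
   condition's grand average (mean over participants of per-participant
   means), and average the two condition waveforms with equal weight
   regardless of trial counts.
4. **Peak search** — the composite's minimum within the a priori window
   (FRN 200–350 ms post-feedback; ERN/CRN 0–100 ms post-response); ties
   break to the earliest latency and window-edge minima are permitted
   (a strict-local-only mode can be enabled by the caller via the search
   window).  The extraction window is peak ± 30 ms, converted to samples by
   rounding half up.
5. **Single-trial scores** — mean voltage over the extraction window per
   trial × electrode.

The procedure runs separately per agency (the observer FRN peaks later) but
never differs between groups or valences.  With the default generator the
active FRN window comes out 231–291 ms, the observational window
241–301 ms, and the ERN/CRN window −11…49 ms.

## Trial-level statistics

Categorical predictors are deviation coded as indicator − 1/k against a
declared reference (two levels → −0.5/+0.5; the three-level group factor
referenced to OCD yields two columns whose coefficients are directly
OCD-vs-HC and OCD-vs-SAD mean differences).  Continuous predictors are
centered (block around 2.5; SPE around its mean; pair contingency mapped to
−1/0/1), so the intercept is the grand mean.  Fixed effects are the full
factorial crossing unless capped.

Models attempt the maximal random-effects structure — by-participant
intercept plus correlated slopes for every within-participant fixed term,
plus a by-electrode intercept for ERP outcomes — and back off
deterministically on non-convergence or singularity (a variance component
below 1e−4 of the outcome variance, or a boundary correlation): first the
slope correlations (slopes become independent variance components), then
slopes by descending interaction order, never the participant intercept.
The accepted structure and full backoff path are logged.  Gaussian
outcomes use REML MixedLM; binomial outcomes use the variational Bayes
binomial mixed model with random intercepts only (a solver limitation,
recorded in the backoff log).  Fixed-effect inference uses the normal
approximation in both families; calibration simulations therefore use
enough participants (≥ 80) that the difference from a t reference is
negligible, and the planned-contrast type-I error sits in the 3–7 % band
over 500 null replicates.  Benjamini–Hochberg FDR is applied within each
declared contrast family.

## Problem sizes used in the standard runs

Simulation-based checks use sizes chosen to give stable Monte-Carlo
estimates: 1e5 feedback draws for contingency fidelity (binomial 3σ ≈
0.4 %); 50 random sessions for the likelihood oracle; 100 agents for
parameter recovery and 100 four-participant cohorts for model recovery;
5,000+ trials for the SPE-slope regression; 500 null replicates (83
simulated participants each) for contrast calibration.

## Known limitations

* The synthetic EEG has no ocular or muscle artifacts, no 1/f background,
  no channel-specific topography — passing tests show the *scoring and
  statistics* behave as specified, not that the generator mimics real
  recordings.  Raw-EEG preprocessing (filtering, re-referencing, ICA,
  interpolation) is out of scope.
* The CIPC update equation is one defensible parameterization of
  choice-induced preference change; alternatives plug in behind
  `feedbackfree_update`.
* No hierarchical/Bayesian estimation of RL parameters; per-session maximum
  likelihood only, with the identifiability caveat above.
* Binomial mixed models carry approximate (variational) uncertainty and no
  random slopes.
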