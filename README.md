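# feedbacklearn

Simulation and trial-level analysis of **active and observational
probabilistic feedback learning**, built for studies that compare
performance monitoring across clinical groups (OCD, healthy controls,
social anxiety) with both behavior and single-trial EEG.

The package covers the full analysis chain, each stage runnable on
synthetic data so every downstream step is testable without recordings:

1. **Task simulation** (`feedbacklearn.task`) — the 400-trial probabilistic
   selection task (3 pairs with 80/20, 70/30, 60/40 win contingencies; four
   60-trial learning blocks alternating with four 30-trial test blocks plus
   a 40-trial transfer phase), RL-governed active agents, yoked
   observational sessions, and whole-cohort generation (27 OCD / 27 HC /
   29 SAD by default).
2. **RL modeling** (`feedbacklearn.rl`) — a model family crossing one vs.
   two delta-rule learning rates (α⁺, α⁻) with static, decaying, or
   choice-induced-preference-change (CIPC, ε) value dynamics in the absence
   of feedback; softmax choice (β); maximum-likelihood fitting on the
   feedback-free (test + transfer) choices via seeded multistart L-BFGS-B;
   BIC comparison (k·ln n + 2·NLL); per-trial latents Q, PE = r − Q,
   SPE = |PE|, ΔQ = Q_chosen − Q_unchosen.
3. **Behavioral coding** (`feedbacklearn.behavior`) — validity filtering
   (no response, RT < 200 ms), accuracy, win-stay/lose-shift with previous
   feedback authenticity (authentic vs. misleading), Δ sensitivity scores,
   and sliding-window learning-status segmentation (>90 % over 10 trials,
   stable >65 % thereafter).
4. **Synthetic EEG** (`feedbacklearn.eegsim`) — feedback- and
   response-locked single-trial epochs (−200…600 ms, fronto-central cluster
   Fz/FCz/FC1/FC2/Cz) with configurable FRN/ERN structure: valence effect,
   agency gain, SPE coupling, noise and injectable artifacts.
5. **ERP scoring** (`feedbacklearn.scoring`) — epoch QC (±100 μV, 0.5 μV
   flatline, 200 μV drift, 50 μV step rules), baseline correction, the
   condition-unweighted composite waveform COMP = (GA_win + GA_loss)/2,
   peak search in a priori windows (FRN 200–350 ms, ERN/CRN 0–100 ms), and
   single-trial mean amplitudes in the peak ± 30 ms window.
6. **Statistics** (`feedbacklearn.stats`) — deviation/centered coding with
   OCD-referenced group contrasts, (G)LMMs with a deterministic
   random-effects backoff, planned contrasts with CIs, and
   Benjamini–Hochberg FDR.

See `docs/methods.md` for the models, defaults and known limitations.

## Worked example

```python
from feedbacklearn import task, rl, behavior

# one active session of the default 400-trial design
schedule = task.build_design(seed=0)
agent = task.AgentParams(alpha_pos=0.35, alpha_neg=0.30, beta=5.0, epsilon=0.15)
session = task.simulate_active_session(schedule, agent, seed=42)

coded = behavior.code_accuracy(behavior.filter_valid(session))
print("test accuracy:", round(coded.loc[coded.phase == "test", "accuracy"].mean(), 3))

fit = rl.fit_model(session, rl.MODELS["dual_cipc"], n_starts=20, seed=0)
print("fitted:", {k: round(v, 3) for k, v in fit.params.items()})
print("NLL:", round(fit.nll, 2), "BIC:", round(fit.bic, 2),
      "likelihood trials:", fit.n_likelihood_trials)
```

prints

```
test accuracy: 0.908
fitted: {'alpha_pos': 0.637, 'alpha_neg': 0.217, 'beta': 4.647, 'epsilon': 0.154}
NLL: 38.53 BIC: 97.23 likelihood trials: 155
```

The agent learned the contingencies well enough to pick the better
stimulus on 91 % of test trials; 155 of its 160 feedback-free choices were
valid and entered the likelihood, and the fitted dual-rate + CIPC model
explains them far better than chance (chance NLL would be
155·ln 2 ≈ 107.4).

A cohort-level run is one call each:

```python
cohort = task.simulate_cohort(task.CohortSpec(seed=1))        # 83 x 2 sessions
ranking = rl.compare_models(cohort, [rl.MODELS[m] for m in
                            ("dual_static", "dual_decay", "dual_cipc")])
```

A thin CLI mirrors the main steps:

```bash
feedbacklearn simulate --seed 1 --out cohort.csv
feedbacklearn fit --model dual_cipc --trials cohort.csv --out fits.csv
feedbacklearn code --trials cohort.csv --out coded.csv
```

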