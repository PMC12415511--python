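"""Reinforcement-learning model family, fitting and latent-trace extraction.

The model family crosses one vs. two delta-rule learning rates with three
feedback-free value dynamics: *static* (values frozen outside learning),
*decay* (values relax toward their initial level at rate gamma), and *cipc*
(choice-induced preference change: after every feedback-free choice the
chosen option's value moves toward 1 and the unchosen option's toward 0 at
rate epsilon).  The likelihood covers only the feedback-free (test and
transfer) choices, so the same fitting procedure applies to active and
observational sessions: learning-phase outcomes — own or observed — drive
the value updates, and the model is judged on how well it predicts the
choices made without feedback.  Models are compared by BIC,
``k * ln(n) + 2 * NLL``, with ``n`` the number of valid likelihood trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from .task import STIM_INDEX, STIMULI

__all__ = [
    "ModelSpec",
    "FitResult",
    "MODELS",
    "q_update",
    "feedbackfree_update",
    "choice_prob",
    "session_nll",
    "fit_model",
    "compare_models",
    "extract_latents",
]

Q0 = 0.5
BETA_MAX = 50.0
MIN_RT_MS = 200.0

DYN_STATIC, DYN_DECAY, DYN_CIPC = 0, 1, 2
_DYN_CODE = {"static": DYN_STATIC, "decay": DYN_DECAY, "cipc": DYN_CIPC}


@dataclass(frozen=True)
class ModelSpec:
    """One RL model variant: learning-rate count and feedback-free dynamics."""

    name: str
    n_learning_rates: int
    dynamics: str

    def __post_init__(self):
        if self.n_learning_rates not in (1, 2):
            raise ValueError("n_learning_rates must be 1 or 2")
        if self.dynamics not in _DYN_CODE:
            raise ValueError(f"unknown dynamics {self.dynamics!r}")

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["alpha_pos", "alpha_neg"] if self.n_learning_rates == 2 else ["alpha"]
        names.append("beta")
        if self.dynamics == "cipc":
            names.append("epsilon")
        elif self.dynamics == "decay":
            names.append("gamma")
        return tuple(names)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            (0.0, BETA_MAX) if p == "beta" else (0.0, 1.0) for p in self.param_names
        )

    @property
    def k(self) -> int:
        return len(self.param_names)

    def unpack(self, theta) -> tuple[float, float, float, float, float]:
        """Return (alpha_pos, alpha_neg, beta, epsilon, gamma) from a vector."""
        d = dict(zip(self.param_names, theta))
        if self.n_learning_rates == 1:
            ap = an = d["alpha"]
        else:
            ap, an = d["alpha_pos"], d["alpha_neg"]
        return ap, an, d["beta"], d.get("epsilon", 0.0), d.get("gamma", 0.0)


MODELS: dict[str, ModelSpec] = {
    s.name: s
    for s in (
        ModelSpec("single_static", 1, "static"),
        ModelSpec("single_decay", 1, "decay"),
        ModelSpec("single_cipc", 1, "cipc"),
        ModelSpec("dual_static", 2, "static"),
        ModelSpec("dual_decay", 2, "decay"),
        ModelSpec("dual_cipc", 2, "cipc"),
    )
}


def q_update(q: float, r: int, alpha_pos: float, alpha_neg: float) -> float:
    """Delta-rule update with valence-gated learning rate.

    With rewards coded 1 (win) / 0 (loss) and q in [0, 1], gating on
    feedback valence is equivalent to gating on the sign of the prediction
    error r - q.
    """
    if r not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {r}")
    if not (0.0 <= q <= 1.0 and 0.0 <= alpha_pos <= 1.0 and 0.0 <= alpha_neg <= 1.0):
        raise ValueError("q and learning rates must lie in [0, 1]")
    alpha = alpha_pos if r == 1 else alpha_neg
    return q + alpha * (r - q)


def feedbackfree_update(
    q_chosen: float, q_unchosen: float, spec: ModelSpec, theta
) -> tuple[float, float]:
    """Value change after a choice made without external feedback."""
    _, _, _, eps, gamma = spec.unpack(theta)
    if spec.dynamics == "static":
        return q_chosen, q_unchosen
    if spec.dynamics == "decay":
        return q_chosen + gamma * (Q0 - q_chosen), q_unchosen + gamma * (Q0 - q_unchosen)
    return q_chosen + eps * (1.0 - q_chosen), q_unchosen - eps * q_unchosen


def choice_prob(q_left: float, q_right: float, beta: float) -> float:
    """Softmax (logistic) probability of choosing the left option."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = -beta * (q_left - q_right)
    return 1.0 / (1.0 + math.exp(min(700.0, max(-700.0, x))))


def _encode_session(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten one participant-session into integer arrays for the NLL core.

    Per trial: kind (0 = learning feedback, 1 = likelihood choice,
    2 = ignored), chosen index, unchosen index, reward (win=1/loss=0,
    -1 where absent).
    """
    if trials["participant_id"].nunique() > 1 or trials["agency"].nunique() > 1:
        raise ValueError("session_nll expects trials from a single participant-session")
    if not trials["trial"].is_monotonic_increasing:
        raise ValueError("trials must be time-ordered")
    n = len(trials)
    kind = np.full(n, 2, dtype=np.int64)
    chosen = np.zeros(n, dtype=np.int64)
    unchosen = np.zeros(n, dtype=np.int64)
    reward = np.full(n, -1, dtype=np.int64)
    for i, row in enumerate(trials.itertuples(index=False)):
        if row.chosen_stimulus is None or (isinstance(row.chosen_stimulus, float) and np.isnan(row.chosen_stimulus)):
            continue
        c = STIM_INDEX[row.chosen_stimulus]
        u = STIM_INDEX[row.stim_left if row.chosen_stimulus == row.stim_right else row.stim_right]
        if row.phase == "learning":
            if row.feedback in ("win", "loss"):
                kind[i], chosen[i], unchosen[i] = 0, c, u
                reward[i] = 1 if row.feedback == "win" else 0
        else:
            # feedback-free likelihood trial; skip invalid (rushed) responses
            if not (isinstance(row.rt, float) and not np.isnan(row.rt) and row.rt < MIN_RT_MS):
                kind[i], chosen[i], unchosen[i] = 1, c, u
    return kind, chosen, unchosen, reward


@njit(cache=False)
def _nll_core(kind, chosen, unchosen, reward, ap, an, beta, eps, gamma, dyn, n_stim, record):
    q = np.full(n_stim, Q0)
    nll = 0.0
    n_like = 0
    n = kind.shape[0]
    qc = np.full(n, np.nan)
    qu = np.full(n, np.nan)
    for i in range(n):
        k = kind[i]
        if k == 2:
            continue
        c, u = chosen[i], unchosen[i]
        if record:
            qc[i] = q[c]
            qu[i] = q[u]
        if k == 0:
            r = reward[i]
            alpha = ap if r == 1 else an
            q[c] += alpha * (r - q[c])
        else:
            x = -beta * (q[c] - q[u])
            p = 1.0 / (1.0 + np.exp(min(700.0, max(-700.0, x))))
            nll -= np.log(max(p, 1e-300))
            n_like += 1
            if dyn == 1:
                q[c] += gamma * (Q0 - q[c])
                q[u] += gamma * (Q0 - q[u])
            elif dyn == 2:
                q[c] += eps * (1.0 - q[c])
                q[u] -= eps * q[u]
    return nll, n_like, qc, qu


def session_nll(
    trials: pd.DataFrame, spec: ModelSpec, theta, return_latents: bool = False
):
    """Negative log-likelihood of one session's feedback-free choices.

    Q-values start at 0.5 for every stimulus; learning-phase outcomes (own
    or observed) update them by the delta rule; every valid test/transfer
    choice contributes ``-log p(choice)`` and then triggers the model's
    feedback-free dynamics.  No-response and rushed (< 200 ms) choices
    contribute nothing.  With ``return_latents`` also returns a per-trial
    table of Q_chosen, Q_unchosen, PE, SPE and dQ (values *before* the
    trial's update).
    """
    arrays = _encode_session(trials)
    ap, an, beta, eps, gamma = spec.unpack(theta)
    nll, n_like, qc, qu = _nll_core(
        *arrays, ap, an, beta, eps, gamma, _DYN_CODE[spec.dynamics], len(STIMULI), return_latents
    )
    if not return_latents:
        return nll, n_like
    kind, chosen, unchosen, reward = arrays
    lat = trials[["participant_id", "agency", "phase", "block", "trial", "pair"]].copy()
    lat["q_chosen"] = qc
    lat["q_unchosen"] = qu
    pe = np.where(kind == 0, reward - qc, np.nan)
    lat["pe"] = pe
    lat["spe"] = np.abs(pe)
    lat["dq"] = qc - qu
    return nll, n_like, lat.reset_index(drop=True)


@dataclass
class FitResult:
    """Best multistart fit of one model to one participant-session."""

    spec: ModelSpec
    params: dict[str, float]
    nll: float
    n_likelihood_trials: int
    start_nlls: np.ndarray
    converged: np.ndarray
    participant_id: str = ""
    agency: str = ""

    @property
    def bic(self) -> float:
        return self.spec.k * math.log(self.n_likelihood_trials) + 2.0 * self.nll

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[p] for p in self.spec.param_names])


def fit_model(
    trials: pd.DataFrame, spec: ModelSpec, n_starts: int = 20, seed: int = 0
) -> FitResult:
    """Fit one model to one participant-session by bounded multistart L-BFGS-B.

    Starting points are a seeded Latin-hypercube over the box bounds; the
    best converged start is returned along with all start NLLs.
    """
    arrays = _encode_session(trials)
    n_like = int((arrays[0] == 1).sum())
    if n_like == 0:
        raise ValueError("no valid likelihood (test/transfer) trials to fit")
    dyn = _DYN_CODE[spec.dynamics]

    def objective(theta):
        ap, an, beta, eps, gamma = spec.unpack(theta)
        return _nll_core(*arrays, ap, an, beta, eps, gamma, dyn, len(STIMULI), False)[0]

    bounds = np.array(spec.bounds)
    sampler = qmc.LatinHypercube(d=spec.k, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), bounds[:, 0], bounds[:, 1])
    # keep beta starts in a plausible range rather than spread to the box edge
    beta_ix = spec.param_names.index("beta")
    starts[:, beta_ix] = 0.2 + starts[:, beta_ix] * (15.0 - 0.2) / BETA_MAX

    results = []
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=spec.bounds)
        results.append(res)
    nlls = np.array([r.fun for r in results])
    ok = np.array([r.success for r in results])
    if not ok.any():
        raise RuntimeError(f"all {n_starts} starts failed: {[r.message for r in results]}")
    best = results[int(np.where(ok, nlls, np.inf).argmin())]
    return FitResult(
        spec=spec,
        params=dict(zip(spec.param_names, map(float, best.x))),
        nll=float(best.fun),
        n_likelihood_trials=n_like,
        start_nlls=nlls,
        converged=ok,
        participant_id=str(trials["participant_id"].iloc[0]),
        agency=str(trials["agency"].iloc[0]),
    )


def compare_models(
    trials: pd.DataFrame,
    specs: list[ModelSpec],
    n_starts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit several models per participant-session and rank them by summed BIC.

    ``trials`` may contain many participants and both agencies; each
    participant-session is fitted separately and BICs are summed per model.
    Returns the ranking frame (one row per model, lowest summed BIC first,
    winner flagged) with per-fit results attached in ``.attrs['fits']``.
    """
    if len(specs) < 2:
        raise ValueError("need at least two model specs to compare")
    fits: list[FitResult] = []
    rows = []
    for (pid, agency), sess in trials.groupby(["participant_id", "agency"], sort=True):
        sess = sess.sort_values("trial")
        for spec in specs:
            fit = fit_model(sess, spec, n_starts=n_starts, seed=seed)
            fits.append(fit)
            rows.append({"model": spec.name, "participant_id": pid, "agency": agency,
                         "nll": fit.nll, "bic": fit.bic})
    per_fit = pd.DataFrame(rows)
    ranking = (
        per_fit.groupby("model", sort=False)["bic"].sum().sort_values().reset_index()
    )
    ranking = ranking.rename(columns={"bic": "summed_bic"})
    ranking["winner"] = False
    ranking.loc[0, "winner"] = True
    ranking.attrs["fits"] = fits
    ranking.attrs["per_fit"] = per_fit
    return ranking


def extract_latents(fit: FitResult, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial latent traces under a fitted model.

    Adds ``spe_centered``: SPE minus its mean over feedback trials, the form
    entered as a continuous regressor (negative = more expected feedback,
    positive = more surprising).
    """
    _, _, lat = session_nll(trials, fit.spec, fit.theta, return_latents=True)
    lat["spe_centered"] = lat["spe"] - lat["spe"].mean(skipna=True)
    return lat
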