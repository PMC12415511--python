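"""Trial-level behavioral coding: validity, accuracy, win-stay/lose-shift
with feedback authenticity, delta sensitivity scores, and the sliding-window
learning-status segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TaskDesign

__all__ = [
    "filter_valid",
    "code_accuracy",
    "code_wsls",
    "delta_sensitivity",
    "learning_status",
    "LearningBreakpoint",
]

MIN_RT_MS = 200.0


def filter_valid(trials: pd.DataFrame, min_rt_ms: float = MIN_RT_MS) -> pd.DataFrame:
    """Flag invalid trials: no response, or a rushed response (RT < 200 ms).

    A response at exactly the cutoff is valid (the rule is a strict
    inequality).  Negative RTs indicate corrupt data and raise.
    """
    rt = pd.to_numeric(trials["rt"], errors="coerce")
    if (rt < 0).any():
        raise ValueError("negative reaction times in input")
    no_response = trials["chosen_stimulus"].isna() if "chosen_stimulus" in trials else rt.isna()
    out = trials.copy()
    out["valid"] = ~(no_response | rt.isna() | (rt < min_rt_ms))
    return out


def code_accuracy(trials: pd.DataFrame, design: TaskDesign | None = None) -> pd.DataFrame:
    """Mark each responded trial correct iff the chosen stimulus has the
    higher win probability within its pair."""
    design = design or TaskDesign()
    correct_of_pair = {}
    for p in tuple(design.pairs) + tuple(design.transfer_pairs):
        correct_of_pair[p.label] = design.correct_stimulus(p)
    out = trials.copy()
    target = out["pair"].map(correct_of_pair)
    out["accuracy"] = np.where(
        out["chosen_stimulus"].isna(), np.nan, (out["chosen_stimulus"] == target).astype(float)
    )
    return out


def code_wsls(trials: pd.DataFrame) -> pd.DataFrame:
    """Win-stay/lose-shift coding of one active participant's learning trials.

    For each stimulus pair, every valid encounter after the first valid one
    is compared with the most recent valid prior encounter of the same pair
    (invalid encounters in between are skipped): ``shift`` = 1 if the choice
    switched.  The previous encounter also supplies the previous feedback
    valence and its authenticity — authentic iff the valence aligns with
    that choice's accuracy (win after a correct choice, or loss after an
    incorrect one), misleading otherwise.
    """
    req = {"valid", "accuracy"}
    if not req <= set(trials.columns):
        raise ValueError("run filter_valid and code_accuracy first")
    out = trials.copy()
    out["shift"] = np.nan
    out["prev_feedback_valence"] = pd.Series([None] * len(out), dtype=object)
    out["prev_feedback_authenticity"] = pd.Series([None] * len(out), dtype=object)

    learning = out[out["phase"] == "learning"].sort_values("trial")
    last: dict[str, tuple] = {}  # pair -> (chosen, feedback, accuracy)
    for ix, row in learning.iterrows():
        if not row["valid"] or row["feedback"] not in ("win", "loss"):
            continue
        prev = last.get(row["pair"])
        if prev is not None:
            p_chosen, p_fb, p_acc = prev
            out.at[ix, "shift"] = float(row["chosen_stimulus"] != p_chosen)
            out.at[ix, "prev_feedback_valence"] = p_fb
            aligned = (p_fb == "win") == (p_acc == 1.0)
            out.at[ix, "prev_feedback_authenticity"] = "authentic" if aligned else "misleading"
        last[row["pair"]] = (row["chosen_stimulus"], row["feedback"], row["accuracy"])
    return out


def delta_sensitivity(coded: pd.DataFrame) -> dict[str, float]:
    """Delta scores of feedback sensitivity: shift-rate(misleading) minus
    shift-rate(authentic), separately after win and after loss feedback.

    Adaptive responding yields ``delta_win > 0`` (shifting more after a
    misleading win) and ``delta_loss < 0`` (shifting less after a
    misleading loss).  An empty cell produces NaN with a warning.
    """
    rows = coded.dropna(subset=["shift"])
    scores = {}
    for valence in ("win", "loss"):
        cells = {}
        for auth in ("misleading", "authentic"):
            sel = rows[
                (rows["prev_feedback_valence"] == valence)
                & (rows["prev_feedback_authenticity"] == auth)
            ]
            if sel.empty:
                warnings.warn(f"no {auth} {valence} encounters; delta_{valence} is NaN")
                cells[auth] = np.nan
            else:
                cells[auth] = sel["shift"].mean()
        scores[f"delta_{valence}"] = cells["misleading"] - cells["authentic"]
    return scores


@dataclass(frozen=True)
class LearningBreakpoint:
    """First post-learning trial position for one participant x pair.

    ``position`` indexes into the pair's ordered valid-trial sequence
    (0-based); None means the contingency was never stably learned and all
    trials stay pre-learning.
    """

    participant_id: str
    pair: str
    position: int | None


def _find_breakpoint(acc: np.ndarray, window: int, crit: float, stability: float) -> int | None:
    """Earliest index t such that mean(acc[t-window:t]) > crit and
    mean(acc[t:]) > stability; the stability check is vacuously true when no
    trials remain after t."""
    n = len(acc)
    for t in range(window, n + 1):
        if acc[t - window : t].mean() > crit:
            rest = acc[t:]
            if len(rest) == 0 or rest.mean() > stability:
                return t if t < n else None
    return None


def learning_status(
    trials: pd.DataFrame,
    pair: str,
    window: int = 10,
    criterion: float = 0.9,
    stability: float = 0.65,
    learning_only: bool = True,
) -> tuple[LearningBreakpoint, pd.Series]:
    """Segment one participant's trials of one pair into pre/post-learning.

    A sliding window scans the ordered valid trials of the pair: the first
    trial whose preceding ``window`` trials exceed ``criterion`` mean
    accuracy is a candidate breakpoint, accepted only if mean accuracy over
    all remaining trials exceeds ``stability``; otherwise the search
    continues.  Without a valid breakpoint every trial stays pre-learning.
    Returns the breakpoint and a per-row status Series ('pre'/'post',
    indexed like ``trials``; NaN-accuracy rows inherit the status of their
    position in time).
    """
    pid = str(trials["participant_id"].iloc[0])
    sel = trials[trials["pair"] == pair]
    if learning_only:
        sel = sel[sel["phase"] == "learning"]
    sel = sel.sort_values("trial")
    if sel.empty:
        raise ValueError(f"no trials for pair {pair!r}")
    valid = sel[sel["valid"] & sel["accuracy"].notna()]
    acc = valid["accuracy"].to_numpy(dtype=float)
    pos = _find_breakpoint(acc, window, criterion, stability)

    status = pd.Series("pre", index=sel.index, dtype=object)
    if pos is not None:
        first_post_trial = valid["trial"].iloc[pos]
        status[sel["trial"] >= first_post_trial] = "post"
    return LearningBreakpoint(pid, pair, pos), status
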