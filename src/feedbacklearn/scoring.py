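"""Epoch QC, baseline correction, composite-waveform peak search and
single-trial amplitude extraction.

Components are scored data-driven but condition-blind: a composite waveform
— the unweighted mean of the condition-wise grand averages of the pooled
fronto-central cluster signal — locates each component's peak latency (the
minimum, both FRN and ERN/CRN being negative deflections) inside an a
priori search window (FRN: 200-350 ms post-feedback; ERN/CRN: 0-100 ms
post-response).  Single-trial amplitudes are then the mean voltage in a
+/-30 ms window around that peak, per electrode and trial.  The procedure
runs separately per agency condition (the observer FRN peaks later) but
never differs between groups or feedback valences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .eegsim import EpochSet

__all__ = [
    "SEARCH_WINDOWS",
    "ScoringWindow",
    "baseline_correct",
    "qc_epochs",
    "composite_waveform",
    "find_peak_window",
    "score_trials",
]

#: A priori component search windows, ms relative to the locking event.
SEARCH_WINDOWS = {"FRN": (200.0, 350.0), "ERN_CRN": (0.0, 100.0)}

HALF_WIDTH_MS = 30.0


@dataclass(frozen=True)
class ScoringWindow:
    """A located component peak and its +/-30 ms extraction window."""

    component: str
    agency: str
    search_window: tuple[float, float]
    peak_ms: float

    @property
    def extraction_window(self) -> tuple[float, float]:
        return (self.peak_ms - HALF_WIDTH_MS, self.peak_ms + HALF_WIDTH_MS)


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial x electrode's mean over the pre-event interval
    (samples with t < 0).  Idempotent."""
    pre = epochs.times < 0.0
    if not pre.any():
        raise ValueError("epochs contain no pre-event interval")
    data = epochs.data - epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochSet(data, epochs.times, epochs.electrodes, epochs.lock, epochs.sfreq,
                    epochs.trials.copy())


def _window_samples(ms: float, sfreq: float) -> int:
    # round half up when converting a ms span to samples
    return int(np.floor(ms * sfreq / 1000.0 + 0.5))


def qc_epochs(
    epochs: EpochSet,
    amp_limit: float = 100.0,
    flat_limit: float = 0.5,
    flat_span_ms: float = 100.0,
    diff_limit: float = 200.0,
    diff_span_ms: float = 200.0,
    step_limit: float = 50.0,
) -> tuple[EpochSet, pd.DataFrame]:
    """Reject epochs violating any artifact rule on any cluster electrode.

    Rules: absolute amplitude beyond +/-100 uV; peak-to-peak activity below
    0.5 uV within any 100-ms span (flatline); peak-to-peak difference above
    200 uV within any 200-ms span; or a voltage step > 50 uV between
    consecutive samples.  Returns the retained epochs and a log naming every
    rule fired per rejected epoch.
    """
    d = epochs.data
    n = d.shape[0]
    fired: list[list[str]] = [[] for _ in range(n)]

    amp = (np.abs(d) > amp_limit).any(axis=(1, 2))

    def ptp_windows(span_ms: float) -> np.ndarray:
        size = _window_samples(span_ms, epochs.sfreq) + 1
        size = min(size, d.shape[2])
        return maximum_filter1d(d, size, axis=2, mode="nearest") - minimum_filter1d(
            d, size, axis=2, mode="nearest"
        )

    flat = (ptp_windows(flat_span_ms) < flat_limit).any(axis=(1, 2))
    diff = (ptp_windows(diff_span_ms) > diff_limit).any(axis=(1, 2))
    step = (np.abs(np.diff(d, axis=2)) > step_limit).any(axis=(1, 2))

    for name, mask in (("amplitude", amp), ("flatline", flat), ("diff", diff), ("step", step)):
        for i in np.flatnonzero(mask):
            fired[i].append(name)
    rejected = amp | flat | diff | step
    log = pd.DataFrame(
        {
            "epoch": np.flatnonzero(rejected),
            "rules": ["+".join(fired[i]) for i in np.flatnonzero(rejected)],
        }
    )
    return epochs.select(~rejected), log


def composite_waveform(
    epochs: EpochSet, condition: str | pd.Series, conditions: tuple[str, str] | None = None
) -> np.ndarray:
    """Condition-unweighted composite of the pooled cluster signal.

    Pools (averages) the cluster electrodes per epoch, forms each
    condition's grand average (mean over participants of per-participant
    trial means), then averages the two condition waveforms with equal
    weight regardless of their trial counts.
    """
    labels = epochs.trials[condition] if isinstance(condition, str) else condition
    levels = conditions or tuple(pd.unique(labels.dropna()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    pooled = epochs.data.mean(axis=1)  # (n_trials, n_samples)
    gas = []
    pids = epochs.trials["participant_id"]
    for lev in levels:
        sel = (labels == lev).to_numpy()
        if not sel.any():
            raise ValueError(f"no retained epochs in condition {lev!r}")
        per_p = [pooled[sel & (pids == p).to_numpy()].mean(axis=0)
                 for p in pd.unique(pids[sel])]
        gas.append(np.mean(per_p, axis=0))
    return (gas[0] + gas[1]) / 2.0


def find_peak_window(
    times: np.ndarray,
    composite: np.ndarray,
    component: str,
    agency: str = "active",
    search_window: tuple[float, float] | None = None,
) -> ScoringWindow:
    """Locate the component peak (minimum) in its a priori search window.

    Ties break to the earliest latency; a monotone composite yields the
    window edge.  The extraction window is peak +/- 30 ms.
    """
    lo, hi = search_window or SEARCH_WINDOWS[component]
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"search window {lo}-{hi} ms outside epoch time base")
    seg_t = times[mask]
    seg = composite[mask]
    peak = float(seg_t[int(np.argmin(seg))])
    return ScoringWindow(component, agency, (lo, hi), peak)


def score_trials(epochs: EpochSet, window: ScoringWindow) -> pd.DataFrame:
    """Mean amplitude over the extraction window, per trial x electrode.

    Returns a long frame with the trial linkage keys, ``electrode`` and
    ``amplitude`` (uV).
    """
    lo, hi = window.extraction_window
    tol = 0.5 * 1000.0 / epochs.sfreq  # half-sample tolerance at the edges
    mask = (epochs.times >= lo - 1e-9) & (epochs.times <= hi + 1e-9)
    if epochs.times[0] > lo + tol or epochs.times[-1] < hi - tol:
        raise ValueError(
            f"extraction window {lo}-{hi} ms exceeds epoch extent "
            f"{epochs.times[0]}-{epochs.times[-1]} ms"
        )
    means = epochs.data[:, :, mask].mean(axis=2)  # (n_trials, n_electrodes)
    n, n_el = means.shape
    keys = epochs.trials.reset_index(drop=True)
    out = keys.loc[keys.index.repeat(n_el)].reset_index(drop=True)
    out["electrode"] = np.tile(epochs.electrodes, n)
    out["component"] = window.component
    out["amplitude"] = means.ravel()
    return out
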