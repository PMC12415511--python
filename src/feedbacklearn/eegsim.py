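"""Synthetic single-trial EEG epochs with FRN/ERN structure.

Each epoch is a slow baseline drift plus a negative Gaussian deflection at a
configurable latency over a five-electrode fronto-central cluster
(Fz, FCz, FC1, FC2, Cz), plus noise.  The deflection's amplitude carries
the effects the trial-level analysis targets: a condition effect (loss vs.
win feedback, or incorrect vs. correct response), an agency gain on that
effect for observational trials, a linear surprise (SPE) coupling, and a
per-participant random offset.  The deflection kernel is normalised so that
its mean over the +/-30 ms extraction window around the latency equals one:
all amplitude parameters are therefore expressed directly in scored
microvolts.  A configurable fraction of epochs is injected with artifacts
that violate each epoch-QC rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet", "ErpGenModel", "generate_epochs", "save_epochs", "load_epochs"]

CLUSTER = ("Fz", "FCz", "FC1", "FC2", "Cz")


@dataclass
class EpochSet:
    """Per-trial voltage arrays with electrode and time metadata.

    ``data`` has shape (n_trials, n_electrodes, n_samples) in microvolts;
    ``times`` is the common time base in ms relative to the locking event
    (feedback or response onset); ``trials`` carries the linkage keys and
    condition columns of each epoch, aligned row-for-row with ``data``.
    """

    data: np.ndarray
    times: np.ndarray
    electrodes: tuple[str, ...]
    lock: str
    sfreq: float
    trials: pd.DataFrame

    def __post_init__(self):
        if self.data.shape[1] != len(self.electrodes):
            raise ValueError("electrode axis mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("every epoch must link to exactly one trial row")

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.data[mask],
            self.times,
            self.electrodes,
            self.lock,
            self.sfreq,
            self.trials.loc[np.asarray(mask)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class ErpGenModel:
    """Generative model of the component structure of one epoch family.

    Amplitudes are in scored microvolts (mean over the +/-30 ms window at
    the component latency).  ``deflection_uv`` is the component amplitude in
    the reference condition (negative for FRN/ERN); ``condition_effect_uv``
    is added in the non-reference condition (loss feedback, or incorrect
    response), so it equals the loss-minus-win (or incorrect-minus-correct)
    scored difference.  ``obs_gain`` scales the condition effect on
    observational trials (1 = identical coding across agency);
    ``obs_latency_shift_ms`` delays the observer component.  ``spe_slope_uv``
    couples amplitude linearly to the centered SPE.
    """

    latency_ms: float = 261.0
    obs_latency_shift_ms: float = 10.0
    width_ms: float = 25.0
    deflection_uv: float = -5.0
    condition_effect_uv: float = -3.0
    obs_gain: float = 0.6
    spe_slope_uv: float = 0.0
    participant_sd_uv: float = 1.0
    drift_uv: float = 0.0
    noise_sd_uv: float = 8.0
    electrode_noise_sd_uv: float = 1.0
    sfreq: float = 500.0
    artifact_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.width_ms, self.participant_sd_uv, self.noise_sd_uv,
               self.electrode_noise_sd_uv) < 0:
            raise ValueError("widths and standard deviations must be >= 0")
        if not 0.0 <= self.obs_gain <= 1.0:
            raise ValueError("obs_gain must lie in [0, 1]")


def _kernel(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    """Gaussian bump normalised to unit mean over latency +/- 30 ms."""
    g = np.exp(-0.5 * ((times - latency) / width) ** 2)
    win = (times >= latency - 30.0) & (times <= latency + 30.0)
    return g / g[win].mean()


_ARTIFACTS = ("amplitude", "flatline", "step", "diff")


def generate_epochs(
    coded_trials: pd.DataFrame,
    gen: ErpGenModel,
    latents: pd.DataFrame | None = None,
    seed: int = 0,
    lock: str = "feedback",
    tmin: float = -200.0,
    tmax: float = 600.0,
    electrodes: tuple[str, ...] = CLUSTER,
) -> EpochSet:
    """Generate one epoch per row of ``coded_trials``.

    ``lock='feedback'`` uses the ``feedback`` column (win/loss) as the
    condition and the ``agency`` column for the observer gain and latency
    shift; ``lock='response'`` uses the ``accuracy`` column
    (correct/incorrect) with no agency modulation.  ``latents`` must be
    row-aligned with ``coded_trials`` and supply ``spe_centered`` when the
    SPE coupling is nonzero.
    """
    if lock not in ("feedback", "response"):
        raise ValueError("lock must be 'feedback' or 'response'")
    if latents is not None and len(latents) != len(coded_trials):
        raise ValueError("latents not aligned with trials")
    rng = np.random.default_rng(seed)
    n_samp = int(round((tmax - tmin) * gen.sfreq / 1000.0)) + 1
    times = tmin + np.arange(n_samp) * 1000.0 / gen.sfreq
    n = len(coded_trials)
    n_el = len(electrodes)

    if lock == "feedback":
        nonref = (coded_trials["feedback"] == "loss").to_numpy()
        observational = (coded_trials["agency"] == "observational").to_numpy()
    else:
        nonref = (coded_trials["accuracy"] == 0).to_numpy()
        observational = np.zeros(n, dtype=bool)

    gain = np.where(observational, gen.obs_gain, 1.0)
    amp = gen.deflection_uv + gen.condition_effect_uv * gain * nonref
    if gen.spe_slope_uv:
        if latents is None or "spe_centered" not in latents:
            raise ValueError("SPE coupling requested but no centered SPE supplied")
        amp = amp + gen.spe_slope_uv * latents["spe_centered"].fillna(0.0).to_numpy()

    p_off = {
        pid: rng.normal(0.0, gen.participant_sd_uv)
        for pid in pd.unique(coded_trials["participant_id"])
    }
    amp = amp + coded_trials["participant_id"].map(p_off).to_numpy()

    k_act = _kernel(times, gen.latency_ms, gen.width_ms)
    k_obs = _kernel(times, gen.latency_ms + gen.obs_latency_shift_ms, gen.width_ms)
    kernels = np.where(observational[:, None], k_obs[None, :], k_act[None, :])
    signal = amp[:, None] * kernels  # (n, n_samp) shared cluster signal

    data = np.empty((n, n_el, n_samp))
    data[:] = signal[:, None, :]
    if gen.drift_uv:
        slope = rng.normal(0.0, gen.drift_uv, size=n)
        data += (slope[:, None] * (times - times[0]) / (times[-1] - times[0]))[:, None, :]
    if gen.noise_sd_uv:
        data += rng.normal(0.0, gen.noise_sd_uv, size=(n, 1, n_samp))
    if gen.electrode_noise_sd_uv:
        data += rng.normal(0.0, gen.electrode_noise_sd_uv, size=(n, n_el, n_samp))

    artifact = pd.Series([""] * n, dtype=object)
    for rule in _ARTIFACTS:
        rate = gen.artifact_rates.get(rule, 0.0)
        if rate <= 0:
            continue
        hits = np.flatnonzero(rng.random(n) < rate)
        for i in hits:
            el = rng.integers(n_el)
            if rule == "amplitude":
                data[i, el, rng.integers(n_samp)] += 150.0
            elif rule == "flatline":
                data[i, el, :] = data[i, el, 0]
            elif rule == "step":
                j = rng.integers(1, n_samp)
                data[i, el, j:] += 80.0
            elif rule == "diff":
                span = max(2, int(round(0.15 * gen.sfreq)))
                j = rng.integers(0, max(1, n_samp - span))
                data[i, el, j : j + span] += np.linspace(0.0, 250.0, span)
            artifact.iloc[i] = (artifact.iloc[i] + "+" + rule).lstrip("+")

    trials = coded_trials.reset_index(drop=True).copy()
    trials["injected_artifact"] = artifact.to_numpy()
    return EpochSet(data, times, tuple(electrodes), lock, gen.sfreq, trials)


def save_epochs(path: str, epochs: EpochSet) -> None:
    """Write an EpochSet to HDF5 (voltages + time base + trial table)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("times", data=epochs.times)
        f.attrs["electrodes"] = list(epochs.electrodes)
        f.attrs["lock"] = epochs.lock
        f.attrs["sfreq"] = epochs.sfreq
        g = f.create_group("trials")
        for col in epochs.trials.columns:
            vals = epochs.trials[col]
            if vals.dtype == object or str(vals.dtype).startswith("string"):
                g.create_dataset(col, data=vals.astype(str).fillna("").to_numpy(dtype="S"))
            else:
                g.create_dataset(col, data=vals.to_numpy())


def load_epochs(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        cols = {}
        for col, ds in f["trials"].items():
            arr = ds[()]
            if arr.dtype.kind == "S":
                arr = np.char.decode(arr, "utf-8")
            cols[col] = arr
        return EpochSet(
            f["data"][()],
            f["times"][()],
            tuple(f.attrs["electrodes"]),
            str(f.attrs["lock"]),
            float(f.attrs["sfreq"]),
            pd.DataFrame(cols),
        )
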