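"""Synthetic epoched iEEG with the statistical structure the analysis assumes.

Each trial is the sum of 1/f background noise, optional phase-locked evoked
deflections, and condition-dependent oscillatory bursts whose carrier phase
is randomized per trial.  Random-phase bursts are *induced* activity: they
raise trial-wise spectral power but cancel in the across-trial voltage
average, so with burst-only effects the time-frequency arm of the pipeline
should detect them while the ERP arm should not.  Evoked components are
injected separately to exercise the ERP arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .design import EventTable, EVENT_COLUMNS

__all__ = [
    "Burst",
    "Evoked",
    "EffectSpec",
    "NoiseSpec",
    "Epochs",
    "simulate_epochs",
    "inject_artifacts",
    "one_over_f_noise",
    "save_epochs",
    "load_epochs",
    "burst_amplitude_for_log_effect",
]

DEFAULT_CHANNELS = (("LTP", "left"), ("RTP", "right"))


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Burst:
    """Condition-dependent oscillatory burst (induced gamma activity).

    ``time_fwhm_ms`` is the FWHM of the Gaussian amplitude envelope;
    ``freq_bandwidth_hz`` the FWHM of the per-trial carrier-frequency jitter
    around ``center_freq_hz``.  ``condition`` maps event-table columns to
    required values (e.g. ``{"stimulus_type": "eyes"}``); ``hemispheres``
    restricts the channels receiving the burst.
    """

    center_time_ms: float
    center_freq_hz: float
    time_fwhm_ms: float = 22.0
    freq_bandwidth_hz: float = 40.0
    amplitude_uv: float = 10.0
    condition: dict = field(default_factory=dict)
    hemispheres: tuple[str, ...] = ("left", "right")


@dataclass(frozen=True)
class Evoked:
    """Phase-locked monophasic deflection (exercises the ERP arm)."""

    latency_ms: float
    width_ms: float = 80.0
    amplitude_uv: float = 3.0
    condition: dict = field(default_factory=dict)
    hemispheres: tuple[str, ...] = ("left", "right")


@dataclass(frozen=True)
class EffectSpec:
    bursts: tuple[Burst, ...] = ()
    evoked: tuple[Evoked, ...] = ()
    amplitude_jitter_cv: float = 0.2

    def validate(self, fs_hz: float) -> None:
        for b in self.bursts:
            if b.amplitude_uv < 0:
                raise SimulationConfigError("burst amplitude must be >= 0")
            if b.center_freq_hz + b.freq_bandwidth_hz >= fs_hz / 2:
                raise SimulationConfigError(
                    f"burst at {b.center_freq_hz} Hz (+ jitter band "
                    f"{b.freq_bandwidth_hz} Hz) reaches the Nyquist "
                    f"frequency {fs_hz / 2} Hz")
        for e in self.evoked:
            if e.amplitude_uv < 0:
                raise SimulationConfigError("evoked amplitude must be >= 0")
        if self.amplitude_jitter_cv < 0:
            raise SimulationConfigError("amplitude_jitter_cv must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background plus optional line noise.

    ``one_over_f_exponent`` is the power-spectrum slope alpha in
    S(f) ~ 1/f^alpha; ``background_sd_uv`` the marginal SD of the background
    in microvolts.
    """

    one_over_f_exponent: float = 1.0
    background_sd_uv: float = 30.0
    line_noise: tuple[float, float] | None = None  # (freq_hz, amplitude_uv)

    def validate(self) -> None:
        if self.one_over_f_exponent < 0:
            raise SimulationConfigError("one_over_f_exponent must be >= 0")
        if self.background_sd_uv < 0:
            raise SimulationConfigError("background_sd_uv must be >= 0")


@dataclass
class Epochs:
    """Trials x channels x samples voltage array with timing metadata.

    ``t0_ms`` is the time of the first sample relative to the locked
    (first-stimulus) onset; sample ``k`` is at ``t0_ms + 1000 * k / fs_hz``.
    """

    data: np.ndarray
    fs_hz: float
    t0_ms: float
    channels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    participant_id: str
    events: EventTable

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")
        if len(self.hemispheres) != len(self.channels):
            raise ValueError("hemisphere tags do not match channels")
        if len(self.events) and len(self.events) != self.data.shape[0]:
            raise ValueError("events do not match trial count")
        if not np.isfinite(self.data).all():
            raise ValueError("data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.t0_ms + 1000.0 * np.arange(n) / self.fs_hz

    def select_trials(self, idx) -> "Epochs":
        idx = np.asarray(idx)
        ev = EventTable(self.events.df.iloc[idx].reset_index(drop=True)) \
            if len(self.events) else self.events
        return Epochs(self.data[idx], self.fs_hz, self.t0_ms, self.channels,
                      self.hemispheres, self.participant_id, ev)

    def relock(self, shift_ms: float) -> "Epochs":
        """Re-reference the time axis (e.g. to the second-stimulus onset)."""
        return Epochs(self.data, self.fs_hz, self.t0_ms - shift_ms,
                      self.channels, self.hemispheres, self.participant_id,
                      self.events)


def one_over_f_noise(shape: tuple, exponent: float, sd: float, fs_hz: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with S(f) ~ 1/f^exponent.

    White noise is shaped in the frequency domain; the filter gain is scaled
    so the expected marginal SD equals ``sd`` exactly (no per-draw
    renormalization, keeping draws independent across trials).
    """
    n = shape[-1]
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if exponent == 0:
        return sd * white
    f = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(white, axis=-1) * gain
    x = np.fft.irfft(spec, n=n, axis=-1)
    # variance of filtered unit white noise = mean squared two-sided gain
    g2 = np.concatenate([gain ** 2, gain[1:-1][::-1] ** 2]) if n % 2 == 0 \
        else np.concatenate([gain ** 2, gain[1:][::-1] ** 2])
    x *= sd / np.sqrt(g2.mean())
    return x


def _matches(row: pd.Series, condition: dict) -> bool:
    for key, val in condition.items():
        allowed = (val,) if isinstance(val, str) else tuple(val)
        if row[key] not in allowed:
            return False
    return True


def simulate_epochs(schedule: EventTable, effects: EffectSpec,
                    noise: NoiseSpec, n_participants: int, seed: int,
                    fs_hz: float = 1000.0,
                    window_ms: tuple[float, float] = (-1000.0, 2000.0),
                    channels: tuple[tuple[str, str], ...] = DEFAULT_CHANNELS,
                    ) -> list[Epochs]:
    """Simulate one :class:`Epochs` per participant for a trial schedule.

    Every trial is ``1/f noise + selected evoked components + selected
    bursts``; burst carriers get an independent uniform phase per trial and
    both bursts and evoked components get multiplicative amplitude jitter
    with coefficient of variation ``effects.amplitude_jitter_cv``.
    Reproducible: the same ``seed`` yields bit-identical data.
    """
    if len(schedule) == 0:
        raise SimulationConfigError("schedule is empty")
    noise.validate()
    effects.validate(fs_hz)

    t_lo, t_hi = window_ms
    n_samples = int(round((t_hi - t_lo) * fs_hz / 1000.0)) + 1
    times_s = (t_lo + 1000.0 * np.arange(n_samples) / fs_hz) / 1000.0
    labels = tuple(c[0] for c in channels)
    hemis = tuple(c[1] for c in channels)
    n_ch = len(channels)

    out = []
    children = np.random.SeedSequence(seed).spawn(n_participants)
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        data = one_over_f_noise((len(schedule), n_ch, n_samples),
                                noise.one_over_f_exponent,
                                noise.background_sd_uv, fs_hz, rng)
        if noise.line_noise is not None:
            f_line, a_line = noise.line_noise
            phase = rng.uniform(0, 2 * np.pi, size=(len(schedule), n_ch, 1))
            data += a_line * np.sin(2 * np.pi * f_line * times_s + phase)
        for i, (_, row) in enumerate(schedule.df.iterrows()):
            for b in effects.bursts:
                # draws are consumed per (trial, burst) regardless of match so
                # effect selectors do not perturb the noise stream
                f_c = b.center_freq_hz + rng.normal(0.0, b.freq_bandwidth_hz / 2.355)
                phase = rng.uniform(0, 2 * np.pi)
                amp = b.amplitude_uv * max(0.0, 1.0 + effects.amplitude_jitter_cv * rng.normal())
                if not _matches(row, b.condition) or amp == 0:
                    continue
                sigma = b.time_fwhm_ms / 2.355 / 1000.0
                t_c = b.center_time_ms / 1000.0
                env = amp * np.exp(-0.5 * ((times_s - t_c) / sigma) ** 2)
                wave = env * np.cos(2 * np.pi * f_c * (times_s - t_c) + phase)
                for c, h in enumerate(hemis):
                    if h in b.hemispheres:
                        data[i, c] += wave
            for e in effects.evoked:
                amp = e.amplitude_uv * max(0.0, 1.0 + effects.amplitude_jitter_cv * rng.normal())
                if not _matches(row, e.condition) or amp == 0:
                    continue
                sigma = e.width_ms / 2.355 / 1000.0
                t_c = e.latency_ms / 1000.0
                wave = amp * np.exp(-0.5 * ((times_s - t_c) / sigma) ** 2)
                for c, h in enumerate(hemis):
                    if h in e.hemispheres:
                        data[i, c] += wave
        out.append(Epochs(data, fs_hz, t_lo, labels, hemis, f"sub-{p + 1:02d}",
                          EventTable(schedule.df.copy())))
    return out


def inject_artifacts(epochs: Epochs, n_trials: int, peak_uv: float,
                     seed: int, width_ms: float = 10.0,
                     ) -> tuple[Epochs, list[int]]:
    """Add a high-amplitude transient spike to ``n_trials`` random trials.

    Returns the modified epochs and the list of affected trial indices.
    """
    if peak_uv < 0:
        raise SimulationConfigError("peak_uv must be >= 0")
    if n_trials > epochs.n_trials:
        raise SimulationConfigError(
            f"n_trials={n_trials} exceeds total {epochs.n_trials}")
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(epochs.n_trials, size=n_trials, replace=False).tolist())
    data = epochs.data.copy()
    half = max(1, int(round(width_ms / 2 * epochs.fs_hz / 1000.0)))
    spike = peak_uv * np.hanning(2 * half + 1)
    n_samp = data.shape[2]
    for i in chosen:
        ch = rng.integers(epochs.data.shape[1])
        center = rng.integers(half, n_samp - half)
        data[i, ch, center - half:center + half + 1] += spike
    out = Epochs(data, epochs.fs_hz, epochs.t0_ms, epochs.channels,
                 epochs.hemispheres, epochs.participant_id, epochs.events)
    return out, chosen


def save_epochs(epochs: Epochs, path, sidecar: bool = True) -> None:
    """Write epochs to an HDF5 container (+ JSON sidecar with the metadata)."""
    meta = dict(fs_hz=epochs.fs_hz, t0_ms=epochs.t0_ms,
                channels=list(epochs.channels),
                hemispheres=list(epochs.hemispheres),
                participant_id=epochs.participant_id)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        for k, v in meta.items():
            f.attrs[k] = v
        f.attrs["events_tsv"] = epochs.events.df.to_csv(sep="\t", index=False)
    if sidecar:
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def load_epochs(path) -> Epochs:
    import io

    with h5py.File(path, "r") as f:
        data = f["data"][()]
        attrs = dict(f.attrs)
    df = pd.read_csv(io.StringIO(attrs["events_tsv"]), sep="\t")
    df["is_target"] = df["is_target"].astype(bool)
    events = EventTable(df[EVENT_COLUMNS]) if len(df) else EventTable()
    return Epochs(data, float(attrs["fs_hz"]), float(attrs["t0_ms"]),
                  tuple(attrs["channels"]), tuple(attrs["hemispheres"]),
                  str(attrs["participant_id"]), events)


def burst_amplitude_for_log_effect(noise: NoiseSpec, burst: Burst,
                                   target_log_effect: float,
                                   fs_hz: float = 1000.0,
                                   n_cycles: float = 7.0) -> float:
    """Burst amplitude giving a target log-power effect at the burst locus.

    Solves ``ln((P0 + g A^2) / P0) = target`` where ``P0`` is the mean
    Morlet power of the background at the burst's center frequency
    (estimated from a fixed internal set of noise draws) and ``g`` the
    deterministic wavelet power gain of a unit-amplitude burst (averaged
    over carrier phase).  The realized mean *log*-power effect is somewhat
    smaller than the target because the log of a noisy power is concave.
    """
    from .tfr import WaveletParams, morlet_kernel

    p = WaveletParams(n_cycles=n_cycles,
                      freqs_hz=np.array([burst.center_freq_hz]), fs_hz=fs_hz)
    kern = morlet_kernel(burst.center_freq_hz, p)
    rng = np.random.default_rng(12345)
    m = 48
    n = int(round(3.0 * fs_hz))
    bg = one_over_f_noise((m, n), noise.one_over_f_exponent,
                          noise.background_sd_uv, fs_hz, rng)
    mid = n // 2
    coef = np.array([np.vdot(kern[::-1].conj(),
                             x[mid - len(kern) // 2: mid + len(kern) // 2 + 1])
                     / fs_hz for x in bg])
    p0 = float(np.mean(np.abs(coef) ** 2))
    if p0 <= 0:
        raise SimulationConfigError("background power is zero at the locus")

    sigma = burst.time_fwhm_ms / 2.355 / 1000.0
    t = (np.arange(n) - mid) / fs_hz
    gains = []
    for phase in np.linspace(0, np.pi, 4, endpoint=False):
        w = np.exp(-0.5 * (t / sigma) ** 2) * np.cos(
            2 * np.pi * burst.center_freq_hz * t + phase)
        c = np.vdot(kern[::-1].conj(),
                    w[mid - len(kern) // 2: mid + len(kern) // 2 + 1]) / fs_hz
        gains.append(np.abs(c) ** 2)
    g = float(np.mean(gains))
    return float(np.sqrt(p0 * np.expm1(target_log_effect) / g))
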