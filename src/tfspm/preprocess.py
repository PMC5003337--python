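"""Epoch extraction and artifact rejection.

Two rejection rules are applied per participant:

1. absolute threshold — any trial containing a sample whose absolute
   voltage exceeds ``abs_thresh_uv`` (default 800 uV) on any channel;
2. distributional outliers — per electrode, the per-trial peak absolute
   amplitude is compared against its across-trial distribution and a trial
   is rejected when the peak exceeds center + ``sd_thresh`` * SD, with both
   the mean- and median-centered variants checked (the stricter union).

Rule 2 runs once on the rule-1 survivors; a degenerate distribution
(SD = 0) rejects nothing.  A trial flagged on any channel is dropped
entirely so the hemisphere pairing of observations stays intact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .design import EventTable
from .simulate import Epochs

__all__ = ["RejectionReport", "reject_artifacts", "extract_epochs"]


class PreprocessError(ValueError):
    pass


@dataclass
class RejectionReport:
    """Which trials each rule removed, and the thresholds used."""

    rejected_abs: list[int]
    rejected_sd: list[int]
    n_total: int
    abs_thresh_uv: float
    sd_thresh: float
    center: str
    rejection_fraction_by_condition: dict[str, float] = field(default_factory=dict)

    @property
    def rejected_ids(self) -> list[int]:
        return sorted(set(self.rejected_abs) | set(self.rejected_sd))

    @property
    def fraction_rejected(self) -> float:
        return len(self.rejected_ids) / self.n_total if self.n_total else 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def reject_artifacts(epochs: Epochs, abs_thresh_uv: float = 800.0,
                     sd_thresh: float = 5.0, center: str = "both",
                     ) -> tuple[Epochs, RejectionReport]:
    """Apply both artifact-rejection rules; return kept epochs and a report.

    ``center`` selects the rule-2 centering: ``"mean"``, ``"median"``, or
    ``"both"`` (reject if the peak exceeds either center + sd_thresh * SD).
    """
    if epochs.n_trials == 0:
        raise PreprocessError("epochs are empty")
    if center not in ("mean", "median", "both"):
        raise PreprocessError(f"unknown center {center!r}")

    peaks = np.abs(epochs.data).max(axis=2)  # trials x channels
    rej_abs = np.where((peaks > abs_thresh_uv).any(axis=1))[0]

    keep1 = np.setdiff1d(np.arange(epochs.n_trials), rej_abs)
    rej_sd: set[int] = set()
    if keep1.size:
        sub = peaks[keep1]  # survivors x channels
        sd = sub.std(axis=0, ddof=1) if keep1.size > 1 else np.zeros(sub.shape[1])
        centers = []
        if center in ("mean", "both"):
            centers.append(sub.mean(axis=0))
        if center in ("median", "both"):
            centers.append(np.median(sub, axis=0))
        for c in centers:
            bad = (sub > c + sd_thresh * sd) & (sd > 0)
            rej_sd.update(keep1[bad.any(axis=1)].tolist())

    kept = np.setdiff1d(keep1, sorted(rej_sd))
    if kept.size == 0:
        raise PreprocessError("all trials rejected: empty after rejection")

    frac = {}
    if len(epochs.events):
        df = epochs.events.df
        rejected = set(rej_abs.tolist()) | rej_sd
        for cond, grp in df.groupby("stimulus_type"):
            idx = set(grp.index.tolist())
            frac[str(cond)] = len(idx & rejected) / len(idx)

    report = RejectionReport(rejected_abs=rej_abs.tolist(),
                             rejected_sd=sorted(rej_sd),
                             n_total=epochs.n_trials,
                             abs_thresh_uv=abs_thresh_uv,
                             sd_thresh=sd_thresh, center=center,
                             rejection_fraction_by_condition=frac)
    return epochs.select_trials(kept), report


def extract_epochs(signal: np.ndarray, fs_hz: float, events: EventTable,
                   window_ms: tuple[float, float] = (-1000.0, 2000.0),
                   channels: tuple[str, ...] = ("chan",),
                   hemispheres: tuple[str, ...] = ("unknown",),
                   participant_id: str = "sub-01") -> Epochs:
    """Cut stimulus-locked epochs out of a continuous recording.

    ``signal`` is (channels, samples) or (samples,).  Raises an error naming
    the trial if any window overruns the recording edge.
    """
    sig = np.atleast_2d(np.asarray(signal, float))
    n = sig.shape[1]
    lo, hi = window_ms
    n_samp = int(round((hi - lo) * fs_hz / 1000.0)) + 1
    out = np.empty((len(events), sig.shape[0], n_samp))
    for k, (_, row) in enumerate(events.df.iterrows()):
        start = int(round((row["onset_ms"] + lo) * fs_hz / 1000.0))
        stop = start + n_samp
        if start < 0 or stop > n:
            raise PreprocessError(
                f"epoch window for trial {int(row['trial_id'])} "
                f"(samples {start}..{stop}) overruns the recording (0..{n})")
        out[k] = sig[:, start:stop]
    return Epochs(out, fs_hz, lo, channels, hemispheres, participant_id,
                  EventTable(events.df.copy()))
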