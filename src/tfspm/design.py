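"""Trial schedule construction for the two-stimulus gaze paradigm.

The experiment presents a first stimulus (eye region or luminance-matched
mosaic, gaze averted or straight) for 500 ms, immediately followed by the
same stimulus with the opposite direction for 1000 ms, after a 500 ms
fixation cross.  Interspersed target trials (a red cross requiring a button
press) keep attention on the screen but are excluded from analysis.  The
four analysed condition sequences cross stimulus type (eyes / mosaic) with
first-presentation direction (averted / straight); the second direction is
always the opposite of the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSetConfig",
    "EventTable",
    "build_trial_schedule",
    "write_events",
    "read_events",
    "DEFAULT_SEQUENCES",
]

#: (first_direction, second_direction, stimulus_type) for the four analysed
#: condition sequences: each stimulus type is shown averted-then-straight or
#: straight-then-averted.
DEFAULT_SEQUENCES: tuple[tuple[str, str, str], ...] = (
    ("averted", "straight", "eyes"),
    ("straight", "averted", "eyes"),
    ("averted", "straight", "mosaic"),
    ("straight", "averted", "mosaic"),
)

EVENT_COLUMNS = [
    "trial_id",
    "onset_ms",
    "duration_ms",
    "stimulus_type",
    "first_direction",
    "second_direction",
    "model_id",
    "is_target",
]


class ScheduleConfigError(ValueError):
    """Raised for an invalid stimulus-set configuration."""


class EventsParseError(ValueError):
    """Raised when an events TSV cannot be parsed."""


@dataclass(frozen=True)
class StimulusSetConfig:
    """Stimulus set and timing of the paradigm.

    Defaults reproduce the study design: 7 female + 7 male identities, each
    sequence repeated 3 times per identity (42 trials per sequence), 15
    target trials, 183 trials in total per participant.
    """

    n_models_female: int = 7
    n_models_male: int = 7
    n_repetitions: int = 3
    n_target_trials: int = 15
    condition_sequences: tuple[tuple[str, str, str], ...] = DEFAULT_SEQUENCES
    iti_range_ms: tuple[float, float] = (2000.0, 5000.0)
    fixation_ms: float = 500.0
    first_ms: float = 500.0
    second_ms: float = 1000.0

    @property
    def n_models(self) -> int:
        return self.n_models_female + self.n_models_male

    def validate(self) -> None:
        for name in ("n_models_female", "n_models_male", "n_repetitions",
                     "n_target_trials"):
            if getattr(self, name) < 0:
                raise ScheduleConfigError(f"{name} must be >= 0")
        for first, second, stype in self.condition_sequences:
            if first == second:
                raise ScheduleConfigError(
                    f"first and second direction must differ in sequence "
                    f"({first}, {second}, {stype})")
        lo, hi = self.iti_range_ms
        if not 0 <= lo <= hi:
            raise ScheduleConfigError("invalid iti_range_ms")


@dataclass
class EventTable:
    """One row per trial: condition factors, onset and target flag.

    Backed by a :class:`pandas.DataFrame` with the columns in
    ``EVENT_COLUMNS``.  Non-target rows carry both stimulus directions
    (always differing); target rows use the sentinel ``"none"``.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        self.df = self.df[EVENT_COLUMNS].reset_index(drop=True)
        if len(self.df) and self.df["trial_id"].duplicated().any():
            raise ValueError("trial_ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        if len(self) != len(other):
            return False
        if len(self) == 0:
            return True
        a, b = self.df, other.df
        for col in EVENT_COLUMNS:
            if a[col].dtype.kind == "f":
                if not np.allclose(a[col], b[col]):
                    return False
            elif not (a[col].values == b[col].values).all():
                return False
        return True

    @property
    def analysis(self) -> pd.DataFrame:
        """Non-target rows (the trials entering any analysis)."""
        return self.df[~self.df["is_target"]]


def build_trial_schedule(cfg: StimulusSetConfig, seed: int) -> EventTable:
    """Build a randomized trial schedule.

    One trial per (identity, repetition, condition sequence) plus the target
    trials, shuffled uniformly; onsets accumulate fixation + stimulus timing
    plus a uniform inter-trial interval draw.

    Parameters
    ----------
    cfg : StimulusSetConfig
    seed : int
        Seeds both the shuffle and the ITI draws.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    for first, second, stype in cfg.condition_sequences:
        for model in range(cfg.n_models):
            for _ in range(cfg.n_repetitions):
                rows.append(dict(stimulus_type=stype, first_direction=first,
                                 second_direction=second, model_id=model,
                                 is_target=False))
    for _ in range(cfg.n_target_trials):
        rows.append(dict(stimulus_type="target", first_direction="none",
                         second_direction="none", model_id=-1, is_target=True))

    order = rng.permutation(len(rows))
    trial_dur = cfg.first_ms + cfg.second_ms
    onsets = np.empty(len(rows))
    t = 0.0
    for k in range(len(rows)):
        t += cfg.fixation_ms
        onsets[k] = t
        t += trial_dur + rng.uniform(*cfg.iti_range_ms)

    records = []
    for k, idx in enumerate(order):
        r = dict(rows[idx])
        r["trial_id"] = k
        r["onset_ms"] = onsets[k]
        r["duration_ms"] = trial_dur
        records.append(r)
    if not records:
        return EventTable()
    return EventTable(pd.DataFrame.from_records(records))


def write_events(events: EventTable, path) -> None:
    """Serialize an event table to a BIDS-style TSV."""
    df = events.df.copy()
    df["is_target"] = df["is_target"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventTable:
    """Read an event table TSV written by :func:`write_events`.

    Raises
    ------
    EventsParseError
        If a line is malformed; the message names the offending line.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in EVENT_COLUMNS if c not in header]
        if missing:
            raise EventsParseError(f"line 1: missing columns {missing}")
        n_fields = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                raise EventsParseError(
                    f"line {lineno}: expected {n_fields} fields")
    df = pd.read_csv(path, sep="\t",
                     dtype={"stimulus_type": str, "first_direction": str,
                            "second_direction": str})
    if len(df) == 0:
        return EventTable()
    try:
        df["trial_id"] = df["trial_id"].astype(int)
        df["model_id"] = df["model_id"].astype(int)
        df["is_target"] = df["is_target"].astype(bool)
        df["onset_ms"] = df["onset_ms"].astype(float)
        df["duration_ms"] = df["duration_ms"].astype(float)
    except (KeyError, ValueError) as exc:
        raise EventsParseError(f"cannot coerce column types: {exc}") from exc
    return EventTable(df)
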