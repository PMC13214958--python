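"""Event-level eye-tracking records: reading, validation, cleaning, writing.

The package takes segmented eye-movement events as given (fixations,
saccades, blinks and raw gaze samples); it does not perform event
detection.  Records are exchanged in a plain-text event CSV dialect
(UTF-8, comma-separated, one header row) with the columns

``subject_id, group, trial_id, image_id, category_id, event_type,
onset_ms, duration_ms, x_px, y_px, amplitude_deg, velocity_dps, pupil,
x_res, y_res``

where ``event_type`` is one of ``fixation``, ``saccade``, ``blink`` or
``sample`` and inapplicable cells are left empty.  For ``sample`` rows
``onset_ms`` holds the sample timestamp; an empty ``pupil`` cell marks an
invalid (e.g. blink-corrupted) sample.  Screen geometry is supplied by the
caller (default 800x600 px, origin top-left, half-open bounds); the trial
recording duration is derived from the latest event end / sample
timestamp.

Cleaning follows the acquisition protocol's artifact-rejection rules:
fixations outside the display area are removed, saccades below the
microsaccade amplitude threshold (1 deg) are removed, and fixations
shorter than 80 ms or longer than 2000 ms are removed.  Removals are
attributed to exactly one rule, in the documented order
outside-display -> amplitude -> duration.  A per-saccade "1-2 Hz
frequency" criterion is not well defined for segmented events; with
``apply_frequency_filter`` enabled the trial-level saccade rate is
annotated on the cleaning stats instead (no events are removed by it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "BlinkEvent",
    "GazeSample",
    "TrialRecord",
    "CleaningConfig",
    "CleaningStats",
    "ValidationError",
    "FormatError",
    "read_trials",
    "write_trials",
    "clean_trial",
    "EVENT_CSV_COLUMNS",
]


class ValidationError(ValueError):
    """An event or trial violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not conform to the event CSV dialect."""


EVENT_CSV_COLUMNS = [
    "subject_id",
    "group",
    "trial_id",
    "image_id",
    "category_id",
    "event_type",
    "onset_ms",
    "duration_ms",
    "x_px",
    "y_px",
    "amplitude_deg",
    "velocity_dps",
    "pupil",
    "x_res",
    "y_res",
]

_GROUPS = ("SZ", "HC")


@dataclass(frozen=True)
class FixationEvent:
    """A fixation with trial-local onset, gaze centroid and pupil summary."""

    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float
    x_res: float = 0.0  # tracker resolution, units per degree
    y_res: float = 0.0
    pupil: float = 0.0  # mean pupil size, device arbitrary units

    def validate(self) -> None:
        if not self.duration_ms > 0:
            raise ValidationError(f"fixation duration must be > 0, got {self.duration_ms}")
        if self.onset_ms < 0:
            raise ValidationError(f"fixation onset must be >= 0, got {self.onset_ms}")


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    duration_ms: float
    amplitude_deg: float
    velocity_dps: float  # average velocity, deg/s

    def validate(self) -> None:
        if not self.duration_ms > 0:
            raise ValidationError(f"saccade duration must be > 0, got {self.duration_ms}")
        if self.amplitude_deg < 0 or self.velocity_dps < 0:
            raise ValidationError("saccade amplitude and velocity must be >= 0")


@dataclass(frozen=True)
class BlinkEvent:
    onset_ms: float
    duration_ms: float

    def validate(self) -> None:
        if not self.duration_ms > 0:
            raise ValidationError(f"blink duration must be > 0, got {self.duration_ms}")


@dataclass(frozen=True)
class GazeSample:
    timestamp_ms: float
    x_px: float
    y_px: float
    pupil: float
    valid: bool = True


@dataclass
class TrialRecord:
    """One subject x image viewing with its events and screen geometry."""

    subject_id: str
    group: str
    trial_id: int
    image_id: int
    category_id: int | None = None
    screen_width: int = 800
    screen_height: int = 600
    duration_ms: float | None = None
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    blinks: list[BlinkEvent] = field(default_factory=list)
    samples: list[GazeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_ms is None:
            self.duration_ms = self.derived_duration()

    def derived_duration(self) -> float:
        """Recording duration implied by the latest event end / sample."""
        ends = [e.onset_ms + e.duration_ms for e in self.events()]
        ends += [s.timestamp_ms for s in self.samples]
        return max(ends, default=0.0)

    def events(self):
        return [*self.fixations, *self.saccades, *self.blinks]

    def validate(self) -> None:
        if self.group not in _GROUPS:
            raise ValidationError(f"unknown group label {self.group!r}, expected one of {_GROUPS}")
        if self.screen_width <= 0 or self.screen_height <= 0:
            raise ValidationError("screen geometry must be positive")
        if self.category_id is not None and not 1 <= self.category_id <= 20:
            raise ValidationError(f"category id must be in 1..20, got {self.category_id}")
        for ev in self.events():
            ev.validate()
            if ev.onset_ms > self.duration_ms:
                raise ValidationError(
                    f"event onset {ev.onset_ms} outside recording [0, {self.duration_ms}]"
                )
        ts = [s.timestamp_ms for s in self.samples]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValidationError("gaze sample timestamps must be strictly increasing")


@dataclass(frozen=True)
class CleaningConfig:
    """Artifact-rejection thresholds of the acquisition protocol."""

    min_fix_duration_ms: float = 80.0
    max_fix_duration_ms: float = 2000.0
    min_sac_amplitude_deg: float = 1.0
    apply_frequency_filter: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_fix_duration_ms < self.max_fix_duration_ms:
            raise ValidationError("cleaning requires 0 < min fixation duration < max")


@dataclass
class CleaningStats:
    """Counts of events removed, attributed to exactly one rule each."""

    outside_display: int = 0
    microsaccade_amplitude: int = 0
    fixation_too_short: int = 0
    fixation_too_long: int = 0
    saccade_rate_hz: float | None = None  # annotation only, see module docstring

    @property
    def total_removed(self) -> int:
        return (
            self.outside_display
            + self.microsaccade_amplitude
            + self.fixation_too_short
            + self.fixation_too_long
        )


def _inside(x: float, y: float, width: int, height: int) -> bool:
    # half-open display bounds, origin top-left
    return 0 <= x < width and 0 <= y < height


def clean_trial(
    trial: TrialRecord, config: CleaningConfig | None = None
) -> tuple[TrialRecord, CleaningStats]:
    """Apply the artifact-rejection rules to one trial.

    Returns a new :class:`TrialRecord` with offending events removed and a
    :class:`CleaningStats` accounting for every removal.  Idempotent:
    cleaning a cleaned trial removes nothing further.  Outside-display
    fixations are removed here but remain observable to the feature
    extractor via the original (pre-cleaning) record, which is how the
    outside-fixation-count feature is computed.
    """
    config = config or CleaningConfig()
    stats = CleaningStats()
    fixations: list[FixationEvent] = []
    for fx in trial.fixations:
        if not _inside(fx.x_px, fx.y_px, trial.screen_width, trial.screen_height):
            stats.outside_display += 1
        elif fx.duration_ms < config.min_fix_duration_ms:
            stats.fixation_too_short += 1
        elif fx.duration_ms > config.max_fix_duration_ms:
            stats.fixation_too_long += 1
        else:
            fixations.append(fx)
    saccades: list[SaccadeEvent] = []
    for sc in trial.saccades:
        if sc.amplitude_deg < config.min_sac_amplitude_deg:
            stats.microsaccade_amplitude += 1
        else:
            saccades.append(sc)
    if config.apply_frequency_filter and trial.duration_ms:
        stats.saccade_rate_hz = 1000.0 * len(trial.saccades) / trial.duration_ms
    cleaned = replace(trial, fixations=fixations, saccades=saccades)
    return cleaned, stats


# ---------------------------------------------------------------------------
# CSV reader / writer


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return repr(float(value))  # shortest exact round-trip repr
    return str(value)


def _row(trial: TrialRecord, event_type: str, **cells) -> list[str]:
    base = {
        "subject_id": trial.subject_id,
        "group": trial.group,
        "trial_id": trial.trial_id,
        "image_id": trial.image_id,
        "category_id": trial.category_id,
        "event_type": event_type,
    }
    base.update(cells)
    return [_fmt(base.get(col)) for col in EVENT_CSV_COLUMNS]


def write_trials(trials: list[TrialRecord], path) -> None:
    """Write trials to the event CSV dialect (round-trips via :func:`read_trials`)."""
    lines = [",".join(EVENT_CSV_COLUMNS)]
    for trial in trials:
        for fx in trial.fixations:
            lines.append(
                ",".join(
                    _row(
                        trial,
                        "fixation",
                        onset_ms=fx.onset_ms,
                        duration_ms=fx.duration_ms,
                        x_px=fx.x_px,
                        y_px=fx.y_px,
                        pupil=fx.pupil,
                        x_res=fx.x_res,
                        y_res=fx.y_res,
                    )
                )
            )
        for sc in trial.saccades:
            lines.append(
                ",".join(
                    _row(
                        trial,
                        "saccade",
                        onset_ms=sc.onset_ms,
                        duration_ms=sc.duration_ms,
                        amplitude_deg=sc.amplitude_deg,
                        velocity_dps=sc.velocity_dps,
                    )
                )
            )
        for bl in trial.blinks:
            lines.append(
                ",".join(_row(trial, "blink", onset_ms=bl.onset_ms, duration_ms=bl.duration_ms))
            )
        for sm in trial.samples:
            lines.append(
                ",".join(
                    _row(
                        trial,
                        "sample",
                        onset_ms=sm.timestamp_ms,
                        x_px=sm.x_px,
                        y_px=sm.y_px,
                        pupil=sm.pupil if sm.valid else None,
                    )
                )
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def read_trials(path, screen_size: tuple[int, int] = (800, 600)) -> list[TrialRecord]:
    """Read an event CSV into one validated :class:`TrialRecord` per (subject, trial).

    Events are sorted by onset within each trial.  Malformed rows raise
    :class:`ValidationError` naming the offending line; a missing mandatory
    column raises :class:`FormatError` naming the column.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "event_type": str},
        float_precision="round_trip",
    )
    missing = [c for c in EVENT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event CSV missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        return []
    bad_groups = sorted(set(df["group"].dropna()) - set(_GROUPS))
    if bad_groups:
        raise ValidationError(f"unknown group label(s): {', '.join(map(str, bad_groups))}")
    width, height = screen_size
    trials: list[TrialRecord] = []
    errors: list[str] = []
    for (subject, trial_id), rows in df.groupby(["subject_id", "trial_id"], sort=True):
        first = rows.iloc[0]
        category = first["category_id"]
        trial = TrialRecord(
            subject_id=str(subject),
            group=str(first["group"]),
            trial_id=int(trial_id),
            image_id=int(first["image_id"]),
            category_id=None if pd.isna(category) else int(category),
            screen_width=width,
            screen_height=height,
        )
        for idx, row in rows.iterrows():
            line = idx + 2  # header + 1-based
            kind = row["event_type"]
            try:
                if kind == "fixation":
                    ev = FixationEvent(
                        onset_ms=float(row["onset_ms"]),
                        duration_ms=float(row["duration_ms"]),
                        x_px=float(row["x_px"]),
                        y_px=float(row["y_px"]),
                        x_res=float(row["x_res"]) if pd.notna(row["x_res"]) else 0.0,
                        y_res=float(row["y_res"]) if pd.notna(row["y_res"]) else 0.0,
                        pupil=float(row["pupil"]) if pd.notna(row["pupil"]) else 0.0,
                    )
                    ev.validate()
                    trial.fixations.append(ev)
                elif kind == "saccade":
                    ev = SaccadeEvent(
                        onset_ms=float(row["onset_ms"]),
                        duration_ms=float(row["duration_ms"]),
                        amplitude_deg=float(row["amplitude_deg"]),
                        velocity_dps=float(row["velocity_dps"]),
                    )
                    ev.validate()
                    trial.saccades.append(ev)
                elif kind == "blink":
                    ev = BlinkEvent(
                        onset_ms=float(row["onset_ms"]), duration_ms=float(row["duration_ms"])
                    )
                    ev.validate()
                    trial.blinks.append(ev)
                elif kind == "sample":
                    valid = pd.notna(row["pupil"])
                    trial.samples.append(
                        GazeSample(
                            timestamp_ms=float(row["onset_ms"]),
                            x_px=float(row["x_px"]) if pd.notna(row["x_px"]) else float("nan"),
                            y_px=float(row["y_px"]) if pd.notna(row["y_px"]) else float("nan"),
                            pupil=float(row["pupil"]) if valid else float("nan"),
                            valid=valid,
                        )
                    )
                else:
                    raise ValidationError(f"unknown event_type {kind!r}")
            except (ValidationError, ValueError, TypeError) as exc:
                errors.append(f"line {line}: {exc}")
        if errors:
            continue
        trial.fixations.sort(key=lambda e: e.onset_ms)
        trial.saccades.sort(key=lambda e: e.onset_ms)
        trial.blinks.sort(key=lambda e: e.onset_ms)
        trial.samples.sort(key=lambda s: s.timestamp_ms)
        trial.duration_ms = trial.derived_duration()
        trial.validate()
        trials.append(trial)
    if errors:
        raise ValidationError("malformed event rows: " + "; ".join(errors))
    return trials
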