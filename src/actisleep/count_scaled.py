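"""The count-scaled automatic sleep-wake scoring algorithm.

Pipeline for one nocturnal recording of per-epoch activity counts:

1. aggregate 15-s epochs to minutes (the algorithm reasons per minute);
2. scale the recording by the mean of its non-zero values, so one
   threshold transfers across devices and placements;
3. for each minute compare a weighted sum over the current minute, the
   preceding 4 and the following 2 minutes against a threshold of 1
   (< 1 = sleep);
4. detect sleep events (start of 15 continuous sleep minutes preceded by
   5 wake minutes) and wake events (last minute of 15 continuous sleep
   minutes followed by 5 wake minutes);
5. anchor sleep onset at the bedtime flag (19:30 by default): take the
   first sleep event within 3 h after the flag, else the last within 2 h
   before it, else the flag itself; mirror with wake events at the
   waketime flag (06:00) for sleep offset.

Minute labels are finally broadcast back to the source 15-s epochs for
epoch-by-epoch comparison against PSG.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import (
    AlgorithmConfig,
    CoverageError,
    EpochCountSeries,
    ScaledSeries,
    SleepWakeSeries,
    ValidationError,
    resolve_flag,
)

__all__ = [
    "MinuteActivitySeries",
    "SleepEventList",
    "aggregate_to_minutes",
    "scale_counts",
    "weighted_activity",
    "weighted_activity_profile",
    "classify_sleep_wake",
    "detect_events",
    "locate_sleep_onset",
    "locate_sleep_offset",
    "score_night",
]


@dataclass(frozen=True)
class MinuteActivitySeries:
    """Per-minute activity totals derived from an epoch count series."""

    start_time: datetime
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("minute series must be non-empty and 1-d")
        if np.any(arr < 0):
            raise ValidationError("minute activity values must be non-negative")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def time_at(self, index: int) -> datetime:
        return self.start_time + timedelta(minutes=index)


@dataclass(frozen=True)
class SleepEventList:
    """Candidate sleep-onset and wake events, as clock datetimes."""

    onset_events: tuple[datetime, ...]
    wake_events: tuple[datetime, ...]

    def __post_init__(self) -> None:
        for name in ("onset_events", "wake_events"):
            evts = tuple(getattr(self, name))
            if any(b <= a for a, b in zip(evts, evts[1:])):
                raise ValidationError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, evts)


def aggregate_to_minutes(series: EpochCountSeries) -> MinuteActivitySeries:
    """Sum constituent epochs into whole minutes; a trailing partial minute
    is dropped.  Epoch length 60 s passes through unchanged."""
    ep = series.epoch_length_s
    if 60 % ep != 0:
        raise ValidationError(f"epoch length {ep}s does not divide 60 s")
    per = 60 // ep
    n_full = len(series) // per
    if n_full < 1:
        raise ValidationError("series spans less than one whole minute")
    values = series.counts[: n_full * per].reshape(n_full, per).sum(axis=1)
    return MinuteActivitySeries(start_time=series.start_time, values=values)


def scale_counts(minutes: MinuteActivitySeries) -> ScaledSeries:
    """Divide by the mean of all strictly positive values.

    An all-zero recording scales by 1 (identity): the mean of an empty set
    is undefined and identity is the only neutral choice.
    """
    v = minutes.values
    nonzero = v[v > 0]
    factor = float(nonzero.mean()) if nonzero.size else 1.0
    scaled = v / factor
    out = ScaledSeries(
        start_time=minutes.start_time,
        step_s=60,
        scale_factor=factor,
        scaled=scaled,
        source=minutes,
    )
    if nonzero.size:
        assert np.isclose(scaled[scaled > 0].mean(), 1.0, rtol=1e-9)
    return out


def weighted_activity_profile(
    scaled: ScaledSeries, config: AlgorithmConfig
) -> np.ndarray:
    """Weighted window sum at every minute.

    At the recording edges the window truncates and the surviving weights
    are renormalised to the full-window weight total, so edge minutes are
    not biased toward sleep by the missing neighbours.
    """
    w = config.weights
    b, a = config.window_before_min, config.window_after_min
    v = scaled.scaled
    width = b + 1 + a
    padded = np.pad(v, (b, a))
    inside = np.pad(np.ones(len(v)), (b, a))
    num = sliding_window_view(padded, width) @ w
    den = sliding_window_view(inside, width) @ w
    return num / den * w.sum()


def weighted_activity(scaled: ScaledSeries, t: int, config: AlgorithmConfig) -> float:
    """Weighted window sum at minute ``t`` (see :func:`weighted_activity_profile`)."""
    if not 0 <= t < len(scaled):
        raise ValidationError(f"minute index {t} out of range")
    return float(weighted_activity_profile(scaled, config)[t])


def classify_sleep_wake(
    scaled: ScaledSeries, config: AlgorithmConfig, subject_id: str = ""
) -> SleepWakeSeries:
    """Label each minute SLEEP iff its weighted activity is strictly below
    the threshold (default 1).

    Values within one part in 1e9 of the threshold are snapped to it
    before the comparison, so a weighted sum that equals the threshold in
    real arithmetic (e.g. a constant recording under uniform weights) is
    classified wake even when floating-point rounding leaves it an ulp
    below.
    """
    profile = weighted_activity_profile(scaled, config)
    tol = 1e-9 * max(1.0, abs(config.threshold))
    return SleepWakeSeries(
        subject_id=subject_id,
        start_time=scaled.start_time,
        epoch_length_s=60,
        asleep=profile < config.threshold - tol,
        algorithm="count-scaled",
        params=config.as_dict(),
    )


def _run_starts(asleep: np.ndarray, length: int, value: bool) -> np.ndarray:
    """Boolean mask: position i starts a run of ``length`` epochs equal to
    ``value`` (True = sleep)."""
    match = (asleep == value).astype(int)
    if len(match) < length:
        return np.zeros(len(match), dtype=bool)
    csum = np.concatenate(([0], np.cumsum(match)))
    window = csum[length:] - csum[:-length]
    out = np.zeros(len(match), dtype=bool)
    out[: len(window)] = window == length
    return out


def detect_events(labels: SleepWakeSeries, config: AlgorithmConfig) -> SleepEventList:
    """Scan minute labels for sleep and wake events.

    A sleep event is the start of ``sleep_run_min`` continuous sleep
    minutes preceded by ``wake_run_min`` wake minutes; a wake event is the
    last minute of such a sleep run followed by ``wake_run_min`` wake
    minutes.  A series too short for either window yields empty lists.
    """
    if labels.epoch_length_s != 60:
        raise ValidationError("event detection requires minute-resolution labels")
    s, wk = config.sleep_run_min, config.wake_run_min
    asleep = labels.asleep
    n = len(asleep)
    sleep_start = _run_starts(asleep, s, True)
    wake_start = _run_starts(asleep, wk, False)

    onset_idx = [
        i
        for i in range(wk, n - s + 1)
        if sleep_start[i] and wake_start[i - wk]
    ]
    wake_idx = [
        j
        for j in range(s - 1, n - wk)
        if sleep_start[j - s + 1] and wake_start[j + 1]
    ]
    return SleepEventList(
        onset_events=tuple(labels.time_at(i) for i in onset_idx),
        wake_events=tuple(labels.time_at(j) for j in wake_idx),
    )


def _locate(
    events: tuple[datetime, ...],
    flag: datetime,
    forward_h: float,
    backward_h: float,
) -> datetime:
    forward = [e for e in events if flag <= e <= flag + timedelta(hours=forward_h)]
    if forward:
        return forward[0]
    backward = [e for e in events if flag - timedelta(hours=backward_h) <= e < flag]
    if backward:
        return backward[-1]
    return flag


def locate_sleep_onset(
    events: SleepEventList, flag: datetime, config: AlgorithmConfig
) -> datetime:
    """First sleep event within ``forward_search_h`` after the bedtime flag,
    else the last within ``backward_search_h`` before it, else the flag."""
    return _locate(
        events.onset_events, flag, config.forward_search_h, config.backward_search_h
    )


def locate_sleep_offset(
    events: SleepEventList, flag: datetime, config: AlgorithmConfig
) -> datetime:
    """Mirror of :func:`locate_sleep_onset` on wake events at the waketime flag."""
    return _locate(
        events.wake_events, flag, config.forward_search_h, config.backward_search_h
    )


def score_night(
    series: EpochCountSeries, config: AlgorithmConfig | None = None
) -> tuple[SleepWakeSeries, datetime, datetime]:
    """Run the full scorer on one recording.

    Returns epoch-resolution labels (each minute's label copied to its
    constituent epochs), the located sleep onset and the located sleep
    offset.  The recording must span the bedtime flag through the
    following waketime flag.
    """
    config = config or AlgorithmConfig()
    bed_flag = resolve_flag(config.bedtime_flag, series.start_time)
    wake_flag = resolve_flag(config.waketime_flag, bed_flag)
    if not (series.start_time <= bed_flag and wake_flag <= series.end_time):
        raise CoverageError(
            f"recording {series.start_time}..{series.end_time} does not cover "
            f"the {bed_flag.time()} bedtime and {wake_flag.time()} waketime flags"
        )

    if config.scaling_resolution == "epoch":
        raw = series.counts
        nonzero = raw[raw > 0]
        factor = float(nonzero.mean()) if nonzero.size else 1.0
        minutes = aggregate_to_minutes(series)
        scaled = ScaledSeries(
            start_time=minutes.start_time,
            step_s=60,
            scale_factor=factor,
            scaled=minutes.values / factor,
            source=series,
        )
    else:
        scaled = scale_counts(aggregate_to_minutes(series))

    minute_labels = classify_sleep_wake(scaled, config, subject_id=series.subject_id)
    events = detect_events(minute_labels, config)
    onset = locate_sleep_onset(events, bed_flag, config)
    offset = locate_sleep_offset(events, wake_flag, config)

    per = 60 // series.epoch_length_s
    epoch_labels = SleepWakeSeries(
        subject_id=series.subject_id,
        start_time=series.start_time,
        epoch_length_s=series.epoch_length_s,
        asleep=np.repeat(minute_labels.asleep, per),
        algorithm="count-scaled",
        params={**config.as_dict(), "device": series.device, "site": series.site},
    )
    return epoch_labels, onset, offset
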