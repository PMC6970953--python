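"""Shared domain types for actigraphy sleep-wake scoring and PSG validation.

Everything downstream (scoring, outcome derivation, validation, simulation)
is expressed in terms of a small set of containers defined here:

* :class:`EpochCountSeries` — per-epoch activity counts from one device at
  one body site (vertical axis, 15-s epochs canonically).
* :class:`Hypnogram` — 30-s AASM sleep stages from polysomnography.
* :class:`SleepWakeSeries` — binary sleep/wake labels produced by a scoring
  algorithm, with full provenance.
* :class:`SleepOutcomes` — the six night-level variables (onset, offset,
  sleep period time, WASO, total sleep time, efficiency).
* :class:`AlgorithmConfig` — every tunable of the count-scaled scorer.
* :class:`ConfusionTable` / :class:`AgreementStats` / :class:`BlandAltman` —
  epoch- and outcome-level agreement statistics against PSG.

All timestamps are time-zone-naive local clock times: the scoring rules
(bedtime/waketime flags, onset/offset search windows) operate entirely in
local time, and a "night" is a recording spanning one bedtime flag and the
following waketime flag.  Sleep is the positive class throughout, so
sensitivity means sleep agreement and specificity wake agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from datetime import datetime, time, timedelta
from typing import Any, Mapping, Optional, Sequence

import numpy as np

SLEEP = "SLEEP"
WAKE = "WAKE"
STAGES = ("W", "N1", "N2", "N3", "R")
SITES = ("hip", "wrist")


class ActisleepError(ValueError):
    """Base class for all domain errors raised by this package."""


class ValidationError(ActisleepError):
    """A value violates a domain invariant."""


class FormatError(ActisleepError):
    """A file does not parse under the declared dialect."""


class GapError(ActisleepError):
    """Timestamps are not uniformly spaced (missing epochs are never imputed)."""


class CoverageError(ActisleepError):
    """A recording does not span the interval an operation requires."""


class AlignmentError(ActisleepError):
    """Two series do not share a compatible epoch grid or overlap."""


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def resolve_flag(clock: time, at_or_after: datetime) -> datetime:
    """First datetime with clock time ``clock`` at or after ``at_or_after``."""
    candidate = at_or_after.replace(
        hour=clock.hour, minute=clock.minute, second=clock.second, microsecond=0
    )
    if candidate < at_or_after:
        candidate += timedelta(days=1)
    return candidate


@dataclass(frozen=True)
class EpochCountSeries:
    """Timestamped per-epoch activity counts from one device at one site."""

    subject_id: str
    device: str
    site: str
    start_time: datetime
    epoch_length_s: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if not (self.epoch_length_s > 0 and 60 % self.epoch_length_s == 0):
            raise ValidationError(
                f"epoch length {self.epoch_length_s}s must divide 60 s"
            )
        arr = _as_float_array(self.counts, "counts")
        if arr.size < 1:
            raise ValidationError("count series must contain at least one epoch")
        if np.any(arr < 0):
            idx = int(np.flatnonzero(arr < 0)[0])
            raise ValidationError(f"negative count at epoch index {idx}")
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=len(self) * self.epoch_length_s)

    def time_at(self, index: int) -> datetime:
        return self.start_time + timedelta(seconds=index * self.epoch_length_s)

    def times(self) -> list[datetime]:
        return [self.time_at(i) for i in range(len(self))]


@dataclass(frozen=True)
class ScaledSeries:
    """A minute (or epoch) activity series divided by its non-zero mean.

    ``scale_factor`` is the mean over strictly positive values at the scaling
    resolution, so after scaling the non-zero values average 1 and a single
    threshold applies across devices and placements.  All-zero input scales
    by 1 (identity), the only neutral choice when the non-zero set is empty.
    """

    start_time: datetime
    step_s: int
    scale_factor: float
    scaled: np.ndarray
    source: Any = None

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValidationError("scale factor must be positive")
        arr = _as_float_array(self.scaled, "scaled")
        if np.any(arr < 0):
            raise ValidationError("scaled values must be non-negative")
        arr.flags.writeable = False
        object.__setattr__(self, "scaled", arr)

    def __len__(self) -> int:
        return int(self.scaled.size)


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch PSG stage sequence (30-s epochs, AASM five-stage alphabet)."""

    subject_id: str
    start_time: datetime
    stages: tuple[str, ...]
    epoch_length_s: int = 30
    lights_out: Optional[datetime] = None
    lights_on: Optional[datetime] = None

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if len(stages) < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        for i, s in enumerate(stages):
            if s not in STAGES:
                raise ValidationError(f"unknown stage {s!r} at epoch index {i}")
        object.__setattr__(self, "stages", stages)
        if self.lights_out is not None and self.lights_on is not None:
            if not self.lights_out < self.lights_on:
                raise ValidationError("lights_out must precede lights_on")
        for name in ("lights_out", "lights_on"):
            t = getattr(self, name)
            if t is not None and not (self.start_time <= t <= self.end_time):
                raise ValidationError(f"{name} falls outside the recording span")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=len(self) * self.epoch_length_s)

    def time_at(self, index: int) -> datetime:
        return self.start_time + timedelta(seconds=index * self.epoch_length_s)


@dataclass(frozen=True)
class SleepWakeSeries:
    """Per-epoch binary sleep/wake labels with provenance.

    ``asleep`` is a boolean array (True = SLEEP); ``labels`` exposes the
    symbolic form.  ``algorithm`` and ``params`` record exactly how the
    labels were produced.
    """

    subject_id: str
    start_time: datetime
    epoch_length_s: int
    asleep: np.ndarray
    algorithm: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.asleep, dtype=bool)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("label series must be a non-empty 1-d sequence")
        arr.flags.writeable = False
        object.__setattr__(self, "asleep", arr)
        object.__setattr__(self, "params", dict(self.params))

    def __len__(self) -> int:
        return int(self.asleep.size)

    @property
    def labels(self) -> list[str]:
        return [SLEEP if a else WAKE for a in self.asleep]

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=len(self) * self.epoch_length_s)

    def time_at(self, index: int) -> datetime:
        return self.start_time + timedelta(seconds=index * self.epoch_length_s)


@dataclass(frozen=True)
class SleepOutcomes:
    """The six night-level sleep variables.

    SPT is the elapsed time between sleep onset and offset, WASO the minutes
    scored awake in between, TST = SPT − WASO, and efficiency
    100·TST/SPT.  The identities are enforced on construction.
    """

    onset: datetime
    offset: datetime
    spt_min: float
    waso_min: float
    tst_min: float
    efficiency_pct: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValidationError("sleep onset must precede sleep offset")
        span = (self.offset - self.onset).total_seconds() / 60.0
        if not math.isclose(self.spt_min, span, rel_tol=1e-9, abs_tol=1e-6):
            raise ValidationError("SPT must equal offset minus onset in minutes")
        if not (0.0 <= self.waso_min <= self.spt_min + 1e-9):
            raise ValidationError("WASO must lie between 0 and SPT")
        if not math.isclose(
            self.tst_min, self.spt_min - self.waso_min, rel_tol=1e-9, abs_tol=1e-6
        ):
            raise ValidationError("TST must equal SPT minus WASO")
        expected_eff = 100.0 * self.tst_min / self.spt_min
        if not math.isclose(
            self.efficiency_pct, expected_eff, rel_tol=1e-9, abs_tol=1e-6
        ):
            raise ValidationError("efficiency must equal 100·TST/SPT")

    @classmethod
    def from_components(
        cls, onset: datetime, offset: datetime, waso_min: float
    ) -> "SleepOutcomes":
        if not onset < offset:
            raise ValidationError("sleep onset must precede sleep offset")
        spt = (offset - onset).total_seconds() / 60.0
        tst = spt - waso_min
        return cls(
            onset=onset,
            offset=offset,
            spt_min=spt,
            waso_min=waso_min,
            tst_min=tst,
            efficiency_pct=100.0 * tst / spt,
        )


def _default_weights() -> np.ndarray:
    return np.full(7, 1.0 / 7.0)


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunables of the count-scaled automatic sleep-wake scorer.

    Defaults reproduce the published configuration: 19:30 / 06:00 time
    flags, a weighted sum over the current minute, the preceding 4 and the
    following 2 minutes compared against a threshold of 1 (< 1 = sleep),
    sleep events as 15 continuous sleep minutes preceded by 5 wake minutes
    (mirrored for wake events), and a 3-h-forward / 2-h-backward search
    anchored at each flag.  The weight vector itself is not published;
    the default is the uniform windowed mean, recorded in provenance.
    """

    bedtime_flag: time = time(19, 30)
    waketime_flag: time = time(6, 0)
    threshold: float = 1.0
    window_before_min: int = 4
    window_after_min: int = 2
    weights: np.ndarray = field(default_factory=_default_weights)
    sleep_run_min: int = 15
    wake_run_min: int = 5
    forward_search_h: float = 3.0
    backward_search_h: float = 2.0
    waso_min_bout_min: float = 1.0
    scaling_resolution: str = "minute"

    def __post_init__(self) -> None:
        w = _as_float_array(self.weights, "weights")
        expected = self.window_before_min + 1 + self.window_after_min
        if w.size != expected:
            raise ValidationError(
                f"weights must have length {expected} "
                f"(window_before + 1 + window_after), got {w.size}"
            )
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("weights must be non-negative with positive sum")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        for name in (
            "sleep_run_min",
            "wake_run_min",
            "forward_search_h",
            "backward_search_h",
            "waso_min_bout_min",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.window_before_min < 0 or self.window_after_min < 0:
            raise ValidationError("window extents must be non-negative")
        if self.scaling_resolution not in ("minute", "epoch"):
            raise ValidationError("scaling_resolution must be 'minute' or 'epoch'")

    def as_dict(self) -> dict[str, Any]:
        return {
            "bedtime_flag": self.bedtime_flag.strftime("%H:%M:%S"),
            "waketime_flag": self.waketime_flag.strftime("%H:%M:%S"),
            "threshold": self.threshold,
            "window_before_min": self.window_before_min,
            "window_after_min": self.window_after_min,
            "weights": [float(w) for w in self.weights],
            "sleep_run_min": self.sleep_run_min,
            "wake_run_min": self.wake_run_min,
            "forward_search_h": self.forward_search_h,
            "backward_search_h": self.backward_search_h,
            "waso_min_bout_min": self.waso_min_bout_min,
            "scaling_resolution": self.scaling_resolution,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AlgorithmConfig":
        kwargs: dict[str, Any] = dict(data)
        for key in ("bedtime_flag", "waketime_flag"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = time.fromisoformat(kwargs[key])
        if "weights" in kwargs:
            kwargs["weights"] = np.asarray(kwargs["weights"], dtype=float)
        valid = {f.name for f in fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass(frozen=True)
class ConfusionTable:
    """Epoch-by-epoch confusion counts against PSG (sleep = positive class)."""

    true_sleep: int
    false_sleep: int
    true_wake: int
    false_wake: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{f.name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.true_sleep + self.false_sleep + self.true_wake + self.false_wake

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.true_sleep + other.true_sleep,
            self.false_sleep + other.false_sleep,
            self.true_wake + other.true_wake,
            self.false_wake + other.false_wake,
        )


CI = tuple[float, float]


@dataclass(frozen=True)
class AgreementStats:
    """Sensitivity / specificity / accuracy (percent) and PABAK.

    A metric whose denominator is empty (e.g. specificity with no PSG wake
    epochs) is ``None`` — flagged undefined, never silently zero.  When
    accuracy is defined, PABAK = 2·(accuracy/100) − 1 holds exactly.
    """

    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]
    accuracy_pct: Optional[float]
    pabak: Optional[float]
    sensitivity_ci: Optional[CI] = None
    specificity_ci: Optional[CI] = None
    accuracy_ci: Optional[CI] = None
    pabak_ci: Optional[CI] = None

    def __post_init__(self) -> None:
        for name in ("sensitivity_pct", "specificity_pct", "accuracy_pct"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100]")
        if self.pabak is not None:
            if not (-1.0 - 1e-12 <= self.pabak <= 1.0 + 1e-12):
                raise ValidationError("PABAK must lie in [-1, 1]")
            if self.accuracy_pct is not None and not math.isclose(
                self.pabak, 2.0 * self.accuracy_pct / 100.0 - 1.0, abs_tol=1e-9
            ):
                raise ValidationError("PABAK must equal 2·accuracy − 1")


@dataclass(frozen=True)
class BlandAltman:
    """Bias and 95% limits of agreement for one outcome (device − PSG)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("Bland-Altman requires at least two pairs")
        if not math.isclose(
            self.loa_low, self.mean_diff - 1.96 * self.sd_diff, abs_tol=1e-9
        ):
            raise ValidationError("lower limit must equal mean − 1.96·SD")
        if not math.isclose(
            self.loa_high, self.mean_diff + 1.96 * self.sd_diff, abs_tol=1e-9
        ):
            raise ValidationError("upper limit must equal mean + 1.96·SD")
        if not self.loa_low <= self.mean_diff <= self.loa_high:
            raise ValidationError("limits must bracket the mean difference")


@dataclass(frozen=True)
class EmissionParams:
    """Count-emission law for one (state, site) pair in the simulator.

    ``mean_count`` and ``dispersion`` parameterise a negative binomial per
    15-s epoch; ``zero_prob`` is the zero-inflation mass.  ``dispersion``
    of ``None`` makes the non-zero emission deterministic at ``mean_count``.
    """

    mean_count: float
    dispersion: Optional[float] = 1.0
    zero_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValidationError("mean_count must be non-negative")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValidationError("dispersion must be positive (or None)")
        if not (0.0 <= self.zero_prob <= 1.0):
            raise ValidationError("zero_prob must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Generative description of a cohort of paired actigraphy/PSG nights.

    Clock-time distributions (bedtime, final wake) are normal in minutes,
    settling latency lognormal, wake-bout counts Poisson and durations
    shifted-exponential.  ``emission`` maps (state, site) to the count law;
    states are ``active_wake`` (up and about), ``settling_wake`` (in bed,
    before sleep onset), ``waso_wake`` (night waking) and ``sleep``.
    """

    n_subjects: int = 28
    record_start: datetime = datetime(2023, 6, 1, 17, 0)
    record_end: datetime = datetime(2023, 6, 2, 9, 0)
    bedtime_mean: time = time(20, 10)
    bedtime_sd_min: float = 30.0
    latency_mean_min: float = 25.0
    latency_sd_min: float = 15.0
    offset_mean: time = time(6, 50)
    offset_sd_min: float = 38.0
    waso_bout_rate: float = 3.0
    waso_bout_mean_min: float = 12.0
    waso_bout_min_min: float = 0.0
    bout_margin_after_onset_min: float = 20.0
    bout_margin_before_offset_min: float = 60.0
    grid_snap_s: int = 15
    emission: Mapping[tuple[str, str], EmissionParams] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")
        if not self.record_start < self.record_end:
            raise ValidationError("record_start must precede record_end")
        for name in (
            "bedtime_sd_min",
            "latency_mean_min",
            "latency_sd_min",
            "offset_sd_min",
            "waso_bout_rate",
            "waso_bout_mean_min",
            "waso_bout_min_min",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.grid_snap_s <= 0 or 60 % self.grid_snap_s != 0:
            raise ValidationError("grid_snap_s must divide 60")
        bed = resolve_flag(self.bedtime_mean, self.record_start)
        off = resolve_flag(self.offset_mean, bed)
        if not (self.record_start <= bed < off <= self.record_end):
            raise ValidationError(
                "record span must cover the bedtime and offset distributions"
            )
        object.__setattr__(self, "emission", dict(self.emission))
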