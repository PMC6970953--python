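"""Night-level sleep outcome variables and cohort summaries.

Given scored sleep/wake labels plus located onset and offset, derive the
six standard variables: onset, offset, sleep period time (SPT), wake after
sleep onset (WASO), total sleep time (TST = SPT − WASO) and sleep
efficiency (100·TST/SPT).  WASO counts the wake-labelled epochs between
onset and offset; a minimum-bout rule (commonly 5 min in paediatric
actigraphy practice) is available via ``waso_min_bout_min``, with the
default of 1 counting every wake minute as the definitions state.

Sleep latency is deliberately not computed: the automated scorer has no
lights-out marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np

from .core import (
    AlgorithmConfig,
    SleepOutcomes,
    SleepWakeSeries,
    ValidationError,
)

__all__ = ["CohortSummary", "compute_outcomes", "summarize_cohort", "wake_bouts"]


@dataclass(frozen=True)
class CohortSummary:
    """One summary row: mean (SD) or median (IQR) of one variable.

    For ``mean_sd`` the spread bounds are centre ∓ SD; for ``median_iqr``
    they are the 25th and 75th percentiles (linear interpolation).  A
    single observation has no sample SD; it is reported as 0 with
    ``small_n`` set.
    """

    variable: str
    summary_kind: str
    center: float
    spread_low: float
    spread_high: float
    n: int
    small_n: bool = False

    def __post_init__(self) -> None:
        if self.summary_kind not in ("mean_sd", "median_iqr"):
            raise ValidationError("summary_kind must be 'mean_sd' or 'median_iqr'")
        if self.n < 1:
            raise ValidationError("summary requires n >= 1")
        if self.summary_kind == "median_iqr" and not (
            self.spread_low <= self.center <= self.spread_high
        ):
            raise ValidationError("IQR bounds must bracket the median")


def wake_bouts(asleep: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of wake epochs in a label array."""
    wake = ~np.asarray(asleep, dtype=bool)
    padded = np.concatenate(([False], wake, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def compute_outcomes(
    labels: SleepWakeSeries,
    onset: datetime,
    offset: datetime,
    config: AlgorithmConfig | None = None,
) -> SleepOutcomes:
    """Derive the six outcome variables for one scored night.

    WASO is the total duration of wake bouts lying between onset and
    offset whose length is at least ``config.waso_min_bout_min`` minutes
    (default 1 minute, i.e. all scored wake).
    """
    config = config or AlgorithmConfig()
    if onset >= offset:
        raise ValidationError("sleep onset must precede sleep offset")
    if onset < labels.start_time or offset > labels.end_time:
        raise ValidationError("onset/offset must fall within the label span")

    ep = labels.epoch_length_s
    start = labels.start_time
    i0 = int(np.ceil((onset - start).total_seconds() / ep))
    i1 = int(np.floor((offset - start).total_seconds() / ep))
    between = labels.asleep[i0:i1]

    waso_min = 0.0
    if between.size:
        min_epochs = int(np.ceil(config.waso_min_bout_min * 60.0 / ep))
        for _, length in wake_bouts(between):
            if length >= min_epochs:
                waso_min += length * ep / 60.0
    spt = (offset - onset).total_seconds() / 60.0
    waso_min = min(waso_min, spt)
    return SleepOutcomes.from_components(onset, offset, waso_min)


def summarize_cohort(
    values: np.ndarray | list[float], variable: str, summary_kind: str = "mean_sd"
) -> CohortSummary:
    """Mean (sample SD) or median (IQR) of one outcome variable over a cohort."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValidationError("cannot summarise an empty collection")
    if summary_kind == "mean_sd":
        center = float(arr.mean())
        small = arr.size == 1
        sd = 0.0 if small else float(arr.std(ddof=1))
        return CohortSummary(
            variable=variable,
            summary_kind="mean_sd",
            center=center,
            spread_low=center - sd,
            spread_high=center + sd,
            n=int(arr.size),
            small_n=small,
        )
    if summary_kind == "median_iqr":
        q25, q50, q75 = np.percentile(arr, [25, 50, 75])
        return CohortSummary(
            variable=variable,
            summary_kind="median_iqr",
            center=float(q50),
            spread_low=float(q25),
            spread_high=float(q75),
            n=int(arr.size),
        )
    raise ValidationError("summary_kind must be 'mean_sd' or 'median_iqr'")
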