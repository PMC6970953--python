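"""Shared builders for the test suite.

Fixtures construct inputs programmatically; nothing is read from disk
except files the tests themselves write into tmp_path.
"""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from actisleep.core import AlgorithmConfig, EpochCountSeries, SleepWakeSeries

T0 = datetime(2023, 6, 1, 17, 0)


@pytest.fixture
def config() -> AlgorithmConfig:
    return AlgorithmConfig()


def make_series(
    counts,
    *,
    start: datetime = T0,
    epoch_length_s: int = 15,
    subject: str = "s1",
    device: str = "actigraph",
    site: str = "hip",
) -> EpochCountSeries:
    return EpochCountSeries(
        subject_id=subject,
        device=device,
        site=site,
        start_time=start,
        epoch_length_s=epoch_length_s,
        counts=np.asarray(counts, dtype=float),
    )


def minute_labels(asleep, *, start: datetime = T0, algorithm="test") -> SleepWakeSeries:
    return SleepWakeSeries(
        subject_id="s1",
        start_time=start,
        epoch_length_s=60,
        asleep=np.asarray(asleep, dtype=bool),
        algorithm=algorithm,
    )


def deterministic_night(
    *,
    record_start: datetime = T0,
    record_hours: float = 16.0,
    sleep_start: datetime = datetime(2023, 6, 1, 20, 0),
    sleep_end: datetime = datetime(2023, 6, 2, 6, 30),
    wake_count: float = 200.0,
) -> EpochCountSeries:
    """A fully deterministic night at 15-s resolution.

    Wake epochs emit a constant count; sleep minutes alternate between a
    single tiny 2-count epoch and silence — the small movement floor that,
    as in real recordings, keeps the non-zero mean well below waking
    activity (scaled wake sits near 2 here).
    """
    n = int(record_hours * 3600 // 15)
    counts = np.full(n, wake_count)
    for i in range(n):
        t = record_start + timedelta(seconds=15 * i)
        if sleep_start <= t < sleep_end:
            minute_idx = int((t - sleep_start).total_seconds() // 60)
            within = int((t - sleep_start).total_seconds() % 60) // 15
            counts[i] = 2.0 if (minute_idx % 2 == 0 and within == 0) else 0.0
    return make_series(counts, start=record_start)
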