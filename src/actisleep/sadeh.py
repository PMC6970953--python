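"""Sadeh sleep-index scoring on 1-min epochs (the comparator algorithm).

The sleep index of minute ``t`` is a linear function of four activity
summaries:

    SI(t) = b0 + b_mu·MU + b_nat·NAT + b_sigma·SD + b_logact·LOGACT

where MU is the mean activity over the 11-min window centred on ``t``,
NAT the number of minutes in that window with activity in [50, 100),
SD the sample standard deviation over the last 6 minutes (ending at and
including ``t``), and LOGACT = ln(activity(t) + 1).  The minute is scored
sleep when SI >= 0.  Windows truncate at the recording edges.

The coefficients here default to the published 1994 wrist-actigraphy
values (7.601, -0.065, -1.08, -0.056, -0.703); they are parameters
because variant coefficient sets circulate.  Counts are capped at 300
before scoring by default — the standard preprocessing step — and the cap
is toggleable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EpochCountSeries, SleepWakeSeries, ValidationError

__all__ = [
    "SadehParams",
    "reintegrate_to_60s",
    "cap_counts",
    "sadeh_index",
    "sadeh_scores",
    "sadeh_classify",
]


@dataclass(frozen=True)
class SadehParams:
    intercept: float = 7.601
    coef_mu: float = -0.065
    coef_nat: float = -1.08
    coef_sigma: float = -0.056
    coef_logact: float = -0.703
    count_cap: Optional[float] = 300.0
    window_half_width_min: int = 5
    sigma_lookback_min: int = 6

    def __post_init__(self) -> None:
        if self.count_cap is not None and self.count_cap <= 0:
            raise ValidationError("count cap must be positive (or None to disable)")
        if self.window_half_width_min < 0:
            raise ValidationError("window half-width must be non-negative")
        if self.sigma_lookback_min < 1:
            raise ValidationError("sigma lookback must be at least 1 minute")


def reintegrate_to_60s(series: EpochCountSeries) -> EpochCountSeries:
    """Sum sub-minute epochs into 60-s epochs; trailing partial minute dropped."""
    ep = series.epoch_length_s
    if 60 % ep != 0:
        raise ValidationError(f"epoch length {ep}s does not divide 60 s")
    if ep == 60:
        return series
    per = 60 // ep
    n_full = len(series) // per
    if n_full < 1:
        raise ValidationError("series spans less than one whole minute")
    counts = series.counts[: n_full * per].reshape(n_full, per).sum(axis=1)
    return EpochCountSeries(
        subject_id=series.subject_id,
        device=series.device,
        site=series.site,
        start_time=series.start_time,
        epoch_length_s=60,
        counts=counts,
    )


def cap_counts(series: EpochCountSeries, params: SadehParams) -> EpochCountSeries:
    """Clip every epoch at ``params.count_cap`` (idempotent; no-op when None)."""
    if params.count_cap is None:
        return series
    return EpochCountSeries(
        subject_id=series.subject_id,
        device=series.device,
        site=series.site,
        start_time=series.start_time,
        epoch_length_s=series.epoch_length_s,
        counts=np.minimum(series.counts, params.count_cap),
    )


def _sigma(window: np.ndarray) -> float:
    # sample SD; a single-minute window has no dispersion information
    return float(np.std(window, ddof=1)) if window.size >= 2 else 0.0


def sadeh_index(
    minutes: np.ndarray, t: int, params: SadehParams = SadehParams()
) -> float:
    """Sleep index of minute ``t`` of a capped 60-s activity series."""
    v = np.asarray(minutes, dtype=float)
    if not 0 <= t < v.size:
        raise ValidationError(f"minute index {t} out of range")
    h = params.window_half_width_min
    centered = v[max(0, t - h) : t + h + 1]
    mu = float(centered.mean())
    nat = int(np.count_nonzero((centered >= 50) & (centered < 100)))
    sigma = _sigma(v[max(0, t - params.sigma_lookback_min + 1) : t + 1])
    logact = math.log(v[t] + 1.0)
    return (
        params.intercept
        + params.coef_mu * mu
        + params.coef_nat * nat
        + params.coef_sigma * sigma
        + params.coef_logact * logact
    )


def sadeh_scores(minutes: np.ndarray, params: SadehParams = SadehParams()) -> np.ndarray:
    """Sleep index at every minute (vector form of :func:`sadeh_index`)."""
    v = np.asarray(minutes, dtype=float)
    return np.array([sadeh_index(v, t, params) for t in range(v.size)])


def sadeh_classify(
    series: EpochCountSeries, params: SadehParams = SadehParams()
) -> SleepWakeSeries:
    """Score a count series per minute: reintegrate to 60 s, cap, then SI >= 0 = sleep."""
    minutes = cap_counts(reintegrate_to_60s(series), params)
    si = sadeh_scores(minutes.counts, params)
    return SleepWakeSeries(
        subject_id=series.subject_id,
        start_time=minutes.start_time,
        epoch_length_s=60,
        asleep=si >= 0.0,
        algorithm="sadeh",
        params={
            "intercept": params.intercept,
            "coef_mu": params.coef_mu,
            "coef_nat": params.coef_nat,
            "coef_sigma": params.coef_sigma,
            "coef_logact": params.coef_logact,
            "count_cap": params.count_cap,
            "window_half_width_min": params.window_half_width_min,
            "sigma_lookback_min": params.sigma_lookback_min,
            "device": series.device,
            "site": series.site,
        },
    )
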