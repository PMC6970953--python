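"""Agreement of actigraphy against polysomnography.

Epoch level: collapse the hypnogram to sleep/wake (W → wake, any of
N1/N2/N3/R → sleep), split each 30-s PSG epoch into two 15-s epochs to
match the actigraphy grid, trim to the overlapping span, and tabulate
true/false sleep/wake.  From the confusion table come sensitivity
(% sleep agreement), specificity (% wake agreement), accuracy, and the
prevalence-adjusted bias-adjusted kappa PABAK = 2·p_o − 1, which corrects
plain kappa for the extreme sleep/wake prevalence imbalance of overnight
recordings (healthy nights are ~85%+ sleep).  Kappa-type values are
labelled on the Landis–Koch scale.

Outcome level: Bland–Altman bias and 95% limits of agreement
(mean difference ± 1.96·SD) plus paired tests — paired t for normally
distributed outcomes, Wilcoxon signed-rank for skewed ones such as WASO.

Confidence intervals: PABAK uses the normal approximation on the observed
agreement p_o; subject-level sensitivity/specificity/accuracy use a seeded
nonparametric bootstrap over subjects (the published tables print CIs
without naming a method, so both pooled and subject-level summaries are
reported and the methods are declared in the report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    SLEEP,
    WAKE,
    AgreementStats,
    AlignmentError,
    BlandAltman,
    ConfusionTable,
    Hypnogram,
    SleepWakeSeries,
    ValidationError,
)

__all__ = [
    "AlignedPairSeries",
    "PairedTestResult",
    "collapse_hypnogram",
    "psg_minute_labels",
    "align_to_15s",
    "confusion_table",
    "agreement_stats",
    "pabak",
    "pabak_from_accuracy",
    "interpret_kappa",
    "bland_altman",
    "bland_altman_plot",
    "paired_tests",
    "per_subject_summary",
]

LANDIS_KOCH_BANDS = (
    (0.0, "poor agreement"),
    (0.20, "slight agreement"),
    (0.40, "fair agreement"),
    (0.60, "moderate agreement"),
    (0.80, "substantial agreement"),
    (1.0, "almost perfect agreement"),
)


@dataclass(frozen=True)
class AlignedPairSeries:
    """Paired (PSG, actigraphy) sleep/wake labels on a shared 15-s grid."""

    subject_id: str
    span_start: datetime
    span_end: datetime
    psg_asleep: np.ndarray
    act_asleep: np.ndarray
    epoch_length_s: int = 15

    def __post_init__(self) -> None:
        psg = np.asarray(self.psg_asleep, dtype=bool)
        act = np.asarray(self.act_asleep, dtype=bool)
        if psg.size != act.size or psg.size < 1:
            raise ValidationError("paired series must be non-empty and equal length")
        for name, arr in (("psg_asleep", psg), ("act_asleep", act)):
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return int(self.psg_asleep.size)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [
            (SLEEP if p else WAKE, SLEEP if a else WAKE)
            for p, a in zip(self.psg_asleep, self.act_asleep)
        ]


@dataclass(frozen=True)
class PairedTestResult:
    """Result of a paired comparison of device vs PSG outcome values."""

    statistic: float
    p_value: float
    n: int
    method: str
    zero_variance: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value must lie in [0, 1]")
        if self.method not in ("paired_t", "wilcoxon_signed_rank"):
            raise ValidationError("unknown paired-test method")


def collapse_hypnogram(
    h: Hypnogram,
) -> tuple[SleepWakeSeries, datetime, datetime]:
    """Dichotomise stages to sleep/wake and locate PSG onset and offset.

    Onset is the first sleep epoch at or after lights-out (series start
    when no lights-out is recorded); offset is the end of the last sleep
    epoch.  A hypnogram with no sleep at all is an error.
    """
    asleep = np.array([s != "W" for s in h.stages], dtype=bool)
    sleep_idx = np.flatnonzero(asleep)
    if sleep_idx.size == 0:
        raise ValidationError("hypnogram contains no sleep epochs")
    threshold = h.lights_out or h.start_time
    onset_idx = None
    for i in sleep_idx:
        if h.time_at(int(i)) >= threshold:
            onset_idx = int(i)
            break
    if onset_idx is None:
        raise ValidationError("no sleep epoch at or after lights-out")
    onset = h.time_at(onset_idx)
    offset = h.time_at(int(sleep_idx[-1])) + timedelta(seconds=h.epoch_length_s)
    sw = SleepWakeSeries(
        subject_id=h.subject_id,
        start_time=h.start_time,
        epoch_length_s=h.epoch_length_s,
        asleep=asleep,
        algorithm="psg-collapse",
        params={"lights_out": h.lights_out.isoformat() if h.lights_out else None},
    )
    return sw, onset, offset


def psg_minute_labels(psg: SleepWakeSeries) -> SleepWakeSeries:
    """Collapse 30-s PSG labels to 1-min by the wake-wins rule.

    A minute containing any scored wake is wake.  Used only to compare
    minute-resolution scorers (Sadeh) at outcome level; a trailing
    half-minute is dropped.
    """
    if psg.epoch_length_s != 30:
        raise ValidationError("expected 30-s PSG labels")
    n_full = len(psg) // 2
    pairs = psg.asleep[: n_full * 2].reshape(n_full, 2)
    return SleepWakeSeries(
        subject_id=psg.subject_id,
        start_time=psg.start_time,
        epoch_length_s=60,
        asleep=pairs.all(axis=1),
        algorithm=psg.algorithm + "+wake-wins-minute",
        params=dict(psg.params),
    )


def align_to_15s(
    psg: SleepWakeSeries, act: SleepWakeSeries, subject_id: str | None = None
) -> AlignedPairSeries:
    """Duplicate each 30-s PSG label into two 15-s labels and trim both
    series to their overlapping span.

    Both start times must sit on a shared 15-s grid; comparison is
    restricted to the PSG/actigraphy overlap (no extrapolation).
    """
    if psg.epoch_length_s != 30 or act.epoch_length_s != 15:
        raise ValidationError("expected 30-s PSG labels and 15-s actigraphy labels")
    shift = (psg.start_time - act.start_time).total_seconds()
    if shift % 15 != 0:
        raise AlignmentError(
            f"label grids misaligned by {shift % 15:g}s (not a multiple of 15 s)"
        )
    span_start = max(psg.start_time, act.start_time)
    span_end = min(psg.end_time, act.end_time)
    if (span_end - span_start).total_seconds() < 60:
        raise AlignmentError("PSG and actigraphy overlap by less than one minute")
    # clip the overlap to whole PSG epochs so duplicated labels stay paired
    lead = (span_start - psg.start_time).total_seconds()
    span_start = psg.start_time + timedelta(seconds=math.ceil(lead / 30) * 30)
    tail = (span_end - psg.start_time).total_seconds()
    span_end = psg.start_time + timedelta(seconds=math.floor(tail / 30) * 30)

    psg15 = np.repeat(psg.asleep, 2)
    p0 = int((span_start - psg.start_time).total_seconds() // 15)
    p1 = int((span_end - psg.start_time).total_seconds() // 15)
    a0 = int((span_start - act.start_time).total_seconds() // 15)
    a1 = int((span_end - act.start_time).total_seconds() // 15)
    return AlignedPairSeries(
        subject_id=subject_id or psg.subject_id or act.subject_id,
        span_start=span_start,
        span_end=span_end,
        psg_asleep=psg15[p0:p1],
        act_asleep=act.asleep[a0:a1],
    )


def confusion_table(pairs: AlignedPairSeries) -> ConfusionTable:
    """Tabulate true/false sleep/wake epochs (PSG is truth)."""
    p, a = pairs.psg_asleep, pairs.act_asleep
    return ConfusionTable(
        true_sleep=int(np.sum(p & a)),
        false_sleep=int(np.sum(~p & a)),
        true_wake=int(np.sum(~p & ~a)),
        false_wake=int(np.sum(p & ~a)),
    )


def pabak(table: ConfusionTable) -> tuple[float, tuple[float, float]]:
    """PABAK = 2·p_o − 1 with a normal-approximation 95% CI on p_o."""
    if table.total < 1:
        raise ValidationError("PABAK requires at least one pair")
    p_o = (table.true_sleep + table.true_wake) / table.total
    se = math.sqrt(p_o * (1.0 - p_o) / table.total)
    lo = max(-1.0, 2.0 * (p_o - 1.96 * se) - 1.0)
    hi = min(1.0, 2.0 * (p_o + 1.96 * se) - 1.0)
    return 2.0 * p_o - 1.0, (lo, hi)


def pabak_from_accuracy(accuracy_pct: float) -> float:
    """PABAK implied by an observed percent agreement (internal-consistency check)."""
    if not 0.0 <= accuracy_pct <= 100.0:
        raise ValidationError("accuracy must lie in [0, 100]")
    return 2.0 * accuracy_pct / 100.0 - 1.0


def agreement_stats(table: ConfusionTable) -> AgreementStats:
    """Sensitivity, specificity, accuracy (percent) and PABAK from one table.

    A metric with an empty denominator is None (undefined), never 0.
    """
    ts, fs, tw, fw = (
        table.true_sleep,
        table.false_sleep,
        table.true_wake,
        table.false_wake,
    )
    sens = 100.0 * ts / (ts + fw) if ts + fw > 0 else None
    spec = 100.0 * tw / (tw + fs) if tw + fs > 0 else None
    if table.total > 0:
        acc = 100.0 * (ts + tw) / table.total
        pab, pab_ci = pabak(table)
    else:
        acc, pab, pab_ci = None, None, None
    return AgreementStats(
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=acc,
        pabak=pab,
        pabak_ci=pab_ci,
    )


def interpret_kappa(value: float) -> str:
    """Landis–Koch verbal band for a kappa-type coefficient.

    <= 0 poor; (0, 0.20] slight; (0.20, 0.40] fair; (0.40, 0.60] moderate;
    (0.60, 0.80] substantial; (0.80, 1.0] almost perfect.
    """
    if not -1.0 <= value <= 1.0:
        raise ValidationError("kappa-type coefficients lie in [-1, 1]")
    for upper, label in LANDIS_KOCH_BANDS:
        if value <= upper:
            return label
    return LANDIS_KOCH_BANDS[-1][1]


def bland_altman(
    device_values: Sequence[float], psg_values: Sequence[float]
) -> BlandAltman:
    """Bias and 95% limits of agreement of device − PSG differences."""
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(psg_values, dtype=float)
    if dev.size != ref.size:
        raise ValidationError("paired value vectors must have equal length")
    if dev.size < 2:
        raise ValidationError("Bland-Altman requires at least two pairs")
    diffs = dev - ref
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(dev.size),
    )


def bland_altman_plot(
    device_values: Sequence[float],
    psg_values: Sequence[float],
    ax=None,
    label: str = "",
):
    """Difference-vs-mean plot with bias and limit lines (needs matplotlib)."""
    import matplotlib.pyplot as plt  # optional dependency

    ba = bland_altman(device_values, psg_values)
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(psg_values, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((dev + ref) / 2.0, dev - ref, s=18, alpha=0.8)
    ax.axhline(0.0, color="tab:blue", lw=1)
    ax.axhline(ba.mean_diff, color="black", lw=1.5)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="black", ls="--", lw=1)
    ax.set_xlabel("mean of device and PSG")
    ax.set_ylabel("device − PSG")
    if label:
        ax.set_title(label)
    return ax


def paired_tests(
    device_values: Sequence[float],
    psg_values: Sequence[float],
    method: str = "paired_t",
) -> PairedTestResult:
    """Two-sided paired comparison of device vs PSG outcome values.

    ``paired_t`` is the paired t-test; ``wilcoxon_signed_rank`` drops zero
    differences and uses the normal approximation with continuity
    correction.  All-zero differences yield p = 1 with a zero-variance
    flag instead of an undefined statistic.
    """
    dev = np.asarray(device_values, dtype=float)
    ref = np.asarray(psg_values, dtype=float)
    if dev.size != ref.size:
        raise ValidationError("paired value vectors must have equal length")
    diffs = dev - ref
    if method == "paired_t":
        if dev.size < 2:
            raise ValidationError("paired t-test requires at least two pairs")
        if np.allclose(diffs, 0.0):
            return PairedTestResult(0.0, 1.0, int(dev.size), method, True)
        res = sps.ttest_rel(dev, ref)
        return PairedTestResult(
            float(res.statistic), float(res.pvalue), int(dev.size), method
        )
    if method == "wilcoxon_signed_rank":
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            return PairedTestResult(0.0, 1.0, int(dev.size), method, True)
        res = sps.wilcoxon(
            nonzero, zero_method="wilcox", correction=True, method="approx"
        )
        return PairedTestResult(
            float(res.statistic), float(res.pvalue), int(dev.size), method
        )
    raise ValidationError(f"unknown paired-test method {method!r}")


def _metrics(table: ConfusionTable) -> dict[str, Optional[float]]:
    s = agreement_stats(table)
    return {
        "sensitivity_pct": s.sensitivity_pct,
        "specificity_pct": s.specificity_pct,
        "accuracy_pct": s.accuracy_pct,
        "pabak": s.pabak,
    }


def per_subject_summary(
    tables: Mapping[str, ConfusionTable] | Iterable[ConfusionTable],
    seed: int = 0,
    n_boot: int = 2000,
) -> dict[str, AgreementStats]:
    """Pooled and subject-level agreement over a cohort.

    ``pooled`` sums the confusion cells before computing metrics (PABAK CI
    by normal approximation); ``subject_mean`` averages per-subject metrics
    with a seeded nonparametric bootstrap (percentile 95% CI, resampling
    subjects).  Subjects whose metric is undefined are dropped from that
    metric's mean.
    """
    if isinstance(tables, Mapping):
        tabs = list(tables.values())
    else:
        tabs = list(tables)
    if not tabs:
        raise ValidationError("at least one subject is required")

    pooled_table = tabs[0]
    for t in tabs[1:]:
        pooled_table = pooled_table + t
    pooled = agreement_stats(pooled_table)

    per = [_metrics(t) for t in tabs]
    rng = np.random.default_rng(seed)
    means: dict[str, Optional[float]] = {}
    cis: dict[str, Optional[tuple[float, float]]] = {}
    for key in ("sensitivity_pct", "specificity_pct", "accuracy_pct", "pabak"):
        vals = np.array([m[key] for m in per if m[key] is not None], dtype=float)
        if vals.size == 0:
            means[key], cis[key] = None, None
            continue
        means[key] = float(vals.mean())
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot = vals[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        cis[key] = (float(lo), float(hi))
    subject_mean = AgreementStats(
        sensitivity_pct=means["sensitivity_pct"],
        specificity_pct=means["specificity_pct"],
        accuracy_pct=means["accuracy_pct"],
        pabak=means["pabak"],  # PABAK is linear in accuracy, so the identity survives averaging
        sensitivity_ci=cis["sensitivity_pct"],
        specificity_ci=cis["specificity_pct"],
        accuracy_ci=cis["accuracy_pct"],
        pabak_ci=cis["pabak"],
    )
    return {"pooled": pooled, "subject_mean": subject_mean}
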