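"""Synthetic paired actigraphy/PSG nights.

The generator separates the *truth* of a night from what devices observe:

* a :class:`NightStructure` — bedtime, true sleep onset (end of settling),
  disjoint night-waking (WASO) bouts, and final morning wake — drawn from
  clock-time distributions (normal bedtime and final wake, lognormal
  settling latency, Poisson bout count with shifted-exponential durations);
* a :class:`~actisleep.core.Hypnogram` rendered from the structure on the
  30-s PSG grid (wake outside the sleep period and inside bouts, a
  cosmetic N1-N2-N3-N2-R cycle elsewhere);
* per-site 15-s count series emitted conditionally independently given the
  behavioural state, with site-dependent parameters capturing the
  asymmetry that drives placement effects: the trunk (hip) lies still
  while a child settles to sleep but the hands (wrist) keep moving, and
  hands also move more than the trunk during night wakings and sleep.

Truth outcomes come from the structure, never from re-scored data, so any
recovery error is attributable to the scorer alone.  One seeded stream
per cohort with deterministically derived per-subject substreams makes
every artefact reproducible byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    EmissionParams,
    EpochCountSeries,
    Hypnogram,
    SimulationParams,
    SleepOutcomes,
    ValidationError,
    resolve_flag,
)
from .io import write_counts_csv, write_hypnogram_csv, write_outcomes

__all__ = [
    "NightStructure",
    "SubjectRecord",
    "scenario_params",
    "sample_night_structure",
    "structure_to_hypnogram",
    "state_at",
    "emit_counts",
    "truth_outcomes",
    "simulate_cohort",
    "write_cohort",
]

STATES = ("active_wake", "settling_wake", "waso_wake", "sleep")
_SLEEP_CYCLE = ("N1", "N2", "N3", "N2", "R")


@dataclass(frozen=True)
class NightStructure:
    """Ground truth of one night: when the subject was actually asleep."""

    bedtime: datetime
    settle_end: datetime
    waso_bouts: tuple[tuple[datetime, float], ...]  # (start, duration_min)
    final_wake: datetime

    def __post_init__(self) -> None:
        if not self.bedtime <= self.settle_end < self.final_wake:
            raise ValidationError("bedtime <= sleep onset < final wake is required")
        bouts = tuple(self.waso_bouts)
        prev_end = self.settle_end
        total = 0.0
        for start, dur in bouts:
            if dur <= 0:
                raise ValidationError("bout durations must be positive")
            if start < prev_end:
                raise ValidationError("WASO bouts must be disjoint and ordered")
            end = start + timedelta(minutes=dur)
            if end > self.final_wake:
                raise ValidationError("WASO bouts must end before final wake")
            prev_end = end
            total += dur
        spt = (self.final_wake - self.settle_end).total_seconds() / 60.0
        if total >= spt:
            raise ValidationError("total WASO must be smaller than the sleep period")
        object.__setattr__(self, "waso_bouts", bouts)

    @property
    def waso_min(self) -> float:
        return sum(d for _, d in self.waso_bouts)


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated subject: truth, PSG, and all device count series."""

    subject_id: str
    structure: NightStructure
    hypnogram: Hypnogram
    counts: Mapping[tuple[str, str], EpochCountSeries]  # (device, site) -> series
    truth: SleepOutcomes


# ---------------------------------------------------------------------------
# scenario presets
#
# Count magnitudes per 15-s epoch are order-of-magnitude choices (no raw
# count statistics are published for the study cohort): a few hundred for
# ambulatory wake, tens for fidgeting, tiny frequent twitches in sleep.
# The sleep movement floor matters structurally, not just cosmetically:
# real recordings contain many low-count epochs that depress the non-zero
# mean, which is what puts scaled waking activity well above the threshold
# (here near 2, the regime in which the 7-min uniform window resolves
# state transitions to about a minute).  The "default" scenario encodes
# the site asymmetry (quiet hip / moving wrist while settling, hands
# freer than trunk during night wakings and sleep); the "noise-free"
# scenario additionally makes wake emission deterministic to isolate the
# event/locator logic from emission noise.

_DEFAULT_EMISSION: dict[tuple[str, str], EmissionParams] = {
    ("active_wake", "hip"): EmissionParams(180.0, 1.5, 0.05),
    ("active_wake", "wrist"): EmissionParams(200.0, 1.5, 0.05),
    ("settling_wake", "hip"): EmissionParams(25.0, 1.0, 0.93),
    ("settling_wake", "wrist"): EmissionParams(180.0, 1.5, 0.10),
    ("waso_wake", "hip"): EmissionParams(80.0, 1.0, 0.55),
    ("waso_wake", "wrist"): EmissionParams(180.0, 1.5, 0.10),
    ("sleep", "hip"): EmissionParams(10.0, 1.0, 0.82),
    ("sleep", "wrist"): EmissionParams(20.0, 1.0, 0.75),
}

_NOISE_FREE_EMISSION: dict[tuple[str, str], EmissionParams] = {
    (state, site): EmissionParams(200.0, None, 0.0)
    for state in ("active_wake", "settling_wake", "waso_wake")
    for site in ("hip", "wrist")
}
_NOISE_FREE_EMISSION.update(
    {(("sleep"), site): EmissionParams(2.0, None, 0.775) for site in ("hip", "wrist")}
)

_RESTLESS_WRIST_EMISSION = dict(_DEFAULT_EMISSION)
_RESTLESS_WRIST_EMISSION.update(
    {
        ("sleep", "wrist"): EmissionParams(40.0, 0.8, 0.60),
        ("waso_wake", "wrist"): EmissionParams(220.0, 1.5, 0.05),
    }
)

SCENARIOS = ("default", "noise-free", "restless-wrist")


def scenario_params(
    name: str = "default", *, n_subjects: int = 28, seed: int = 0
) -> SimulationParams:
    """Named parameter presets.

    ``default`` — a realistic primary-school night (bedtime ~20:10,
    settling ~25 min, final wake ~06:50 with SD 38 min, ~3 wake bouts of
    ~12 min) with the quiet-hip/moving-wrist emission asymmetry.
    ``noise-free`` — deterministic wake emission, minute-snapped truth,
    bouts of at least 4 min kept clear of sleep onset and the morning
    rise; for clean parameter-recovery checks.
    ``restless-wrist`` — the default night with heavy wrist movement in
    sleep and night wakings.
    """
    if name == "default":
        return SimulationParams(
            n_subjects=n_subjects, seed=seed, emission=_DEFAULT_EMISSION
        )
    if name == "noise-free":
        from datetime import time

        return SimulationParams(
            n_subjects=n_subjects,
            seed=seed,
            bedtime_mean=time(20, 15),
            bedtime_sd_min=12.0,
            latency_mean_min=15.0,
            latency_sd_min=4.0,
            offset_mean=time(6, 30),
            offset_sd_min=12.0,
            waso_bout_rate=1.0,
            waso_bout_mean_min=10.0,
            waso_bout_min_min=4.0,
            bout_margin_after_onset_min=20.0,
            bout_margin_before_offset_min=60.0,
            grid_snap_s=60,
            emission=_NOISE_FREE_EMISSION,
        )
    if name == "restless-wrist":
        return SimulationParams(
            n_subjects=n_subjects, seed=seed, emission=_RESTLESS_WRIST_EMISSION
        )
    raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def _snap(t: datetime, anchor: datetime, snap_s: int) -> datetime:
    k = round((t - anchor).total_seconds() / snap_s)
    return anchor + timedelta(seconds=k * snap_s)


def _lognormal_minutes(rng: np.random.Generator, mean: float, sd: float) -> float:
    if mean <= 0:
        return 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def sample_night_structure(
    params: SimulationParams, rng: np.random.Generator
) -> NightStructure:
    """Draw one night's truth from the configured distributions.

    Bedtime and final wake are truncated to the recording span; bouts are
    rejection-placed (uniform starts, no overlap) inside the sleep period
    with guard margins after onset and before final wake.  All times are
    snapped to the ``grid_snap_s`` grid anchored at the recording start.
    """
    anchor = params.record_start
    bed_center = resolve_flag(params.bedtime_mean, anchor)
    for _ in range(1000):
        bedtime = bed_center + timedelta(
            minutes=float(rng.normal(0.0, params.bedtime_sd_min))
        )
        latency = _lognormal_minutes(
            rng, params.latency_mean_min, params.latency_sd_min
        )
        settle_end = bedtime + timedelta(minutes=latency)
        wake_center = resolve_flag(params.offset_mean, settle_end)
        final_wake = wake_center + timedelta(
            minutes=float(rng.normal(0.0, params.offset_sd_min))
        )
        bedtime = _snap(bedtime, anchor, params.grid_snap_s)
        settle_end = _snap(settle_end, anchor, params.grid_snap_s)
        final_wake = _snap(final_wake, anchor, params.grid_snap_s)
        feasible = (
            anchor + timedelta(minutes=30) <= bedtime
            and bedtime <= settle_end
            and settle_end + timedelta(hours=2) <= final_wake
            and final_wake <= params.record_end - timedelta(minutes=30)
        )
        if feasible:
            break
    else:
        raise ValidationError(
            "could not draw a feasible night in 1000 attempts "
            "(latency or clock-time distributions exceed the sleep opportunity)"
        )

    lo = settle_end + timedelta(minutes=params.bout_margin_after_onset_min)
    hi = final_wake - timedelta(minutes=params.bout_margin_before_offset_min)
    n_bouts = int(rng.poisson(params.waso_bout_rate))
    placed: list[tuple[datetime, float]] = []
    if hi > lo:
        window_min = (hi - lo).total_seconds() / 60.0
        for _ in range(n_bouts):
            scale = max(params.waso_bout_mean_min - params.waso_bout_min_min, 0.0)
            dur = params.waso_bout_min_min + (
                float(rng.exponential(scale)) if scale > 0 else 0.0
            )
            dur = max(
                params.grid_snap_s / 60.0,
                round(dur * 60.0 / params.grid_snap_s) * params.grid_snap_s / 60.0,
            )
            if dur >= window_min:
                continue
            for _ in range(1000):
                start = lo + timedelta(
                    minutes=float(rng.uniform(0.0, window_min - dur))
                )
                start = _snap(start, anchor, params.grid_snap_s)
                end = start + timedelta(minutes=dur)
                if start < lo or end > hi:
                    continue
                if all(
                    end <= s or start >= s + timedelta(minutes=d)
                    for s, d in placed
                ):
                    placed.append((start, dur))
                    break
    placed.sort()
    return NightStructure(
        bedtime=bedtime,
        settle_end=settle_end,
        waso_bouts=tuple(placed),
        final_wake=final_wake,
    )


def state_at(night: NightStructure, t: datetime) -> str:
    """Behavioural state at clock time ``t``."""
    if t < night.bedtime or t >= night.final_wake:
        return "active_wake"
    if t < night.settle_end:
        return "settling_wake"
    for start, dur in night.waso_bouts:
        if start <= t < start + timedelta(minutes=dur):
            return "waso_wake"
    return "sleep"


def structure_to_hypnogram(
    night: NightStructure,
    span_start: datetime,
    span_end: datetime,
    subject_id: str = "",
) -> Hypnogram:
    """Render the truth on the 30-s PSG grid.

    Epochs outside (sleep onset, final wake) and inside WASO bouts are W;
    sleep epochs cycle N1-N2-N3-N2-R (cosmetic — the cycle collapses to
    sleep for every analysis here).  Lights-out is recorded at bedtime.
    """
    start = _snap(span_start, span_start, 30)
    n = int((span_end - start).total_seconds() // 30)
    if n < 1:
        raise ValidationError("hypnogram span must cover at least one 30-s epoch")
    stages = []
    cycle = 0
    for i in range(n):
        t = start + timedelta(seconds=30 * i)
        if state_at(night, t) == "sleep":
            stages.append(_SLEEP_CYCLE[cycle % len(_SLEEP_CYCLE)])
            cycle += 1
        else:
            stages.append("W")
    lights_out = night.bedtime if start <= night.bedtime else None
    lights_on = night.final_wake if night.final_wake <= span_end else None
    return Hypnogram(
        subject_id=subject_id,
        start_time=start,
        stages=tuple(stages),
        epoch_length_s=30,
        lights_out=lights_out,
        lights_on=lights_on,
    )


def _draw_counts(
    emission: EmissionParams, size: int, rng: np.random.Generator
) -> np.ndarray:
    if emission.dispersion is None:
        vals = np.full(size, float(emission.mean_count))
    elif emission.mean_count == 0:
        vals = np.zeros(size)
    else:
        k = emission.dispersion
        p = k / (k + emission.mean_count)
        vals = rng.negative_binomial(k, p, size=size).astype(float)
    if emission.zero_prob > 0:
        vals[rng.random(size) < emission.zero_prob] = 0.0
    return vals


def emit_counts(
    night: NightStructure,
    site: str,
    device: str,
    params: SimulationParams,
    rng: np.random.Generator,
    subject_id: str = "",
) -> EpochCountSeries:
    """Emit a 15-s count series over the whole recording span.

    Counts are conditionally independent given the state at each epoch's
    start; the (state, site) emission law comes from ``params.emission``.
    The device name is a label tagging the series — placement, not brand,
    carries the emission asymmetry.
    """
    n = int((params.record_end - params.record_start).total_seconds() // 15)
    times = [params.record_start + timedelta(seconds=15 * i) for i in range(n)]
    states = np.array([state_at(night, t) for t in times])
    counts = np.zeros(n)
    for state in STATES:
        mask = states == state
        if not mask.any():
            continue
        try:
            emission = params.emission[(state, site)]
        except KeyError as exc:
            raise ValidationError(
                f"no emission parameters for state {state!r} at site {site!r}"
            ) from exc
        counts[mask] = _draw_counts(emission, int(mask.sum()), rng)
    return EpochCountSeries(
        subject_id=subject_id,
        device=device,
        site=site,
        start_time=params.record_start,
        epoch_length_s=15,
        counts=counts,
    )


def truth_outcomes(night: NightStructure) -> SleepOutcomes:
    """The outcomes implied by the generative structure itself."""
    return SleepOutcomes.from_components(
        night.settle_end, night.final_wake, night.waso_min
    )


def simulate_cohort(
    params: SimulationParams,
    devices: Sequence[str] = ("actigraph", "actical"),
    sites: Sequence[str] = ("hip", "wrist"),
) -> list[SubjectRecord]:
    """Simulate ``params.n_subjects`` independent subjects.

    Substreams are derived deterministically from the cohort seed
    (``[seed, subject, stream]``), so regenerating any subject — or the
    whole cohort — with the same seed is bit-identical.
    """
    emission = params.emission or _DEFAULT_EMISSION
    params = SimulationParams(
        **{**params.__dict__, "emission": emission}
    )
    records = []
    for i in range(params.n_subjects):
        sid = f"sim{i:03d}"
        night = sample_night_structure(
            params, np.random.default_rng([params.seed, i, 0])
        )
        hyp = structure_to_hypnogram(
            night,
            max(params.record_start, night.bedtime - timedelta(minutes=30)),
            min(params.record_end, night.final_wake + timedelta(minutes=30)),
            subject_id=sid,
        )
        counts = {}
        stream = 1
        for device in devices:
            for site in sites:
                counts[(device, site)] = emit_counts(
                    night,
                    site,
                    device,
                    params,
                    np.random.default_rng([params.seed, i, stream]),
                    subject_id=sid,
                )
                stream += 1
        records.append(
            SubjectRecord(
                subject_id=sid,
                structure=night,
                hypnogram=hyp,
                counts=counts,
                truth=truth_outcomes(night),
            )
        )
    return records


def write_cohort(records: Sequence[SubjectRecord], out_dir: str | Path) -> Path:
    """Write per-subject count and hypnogram CSVs, a truth-outcome table,
    and a manifest listing every file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    truth_rows = []
    for rec in records:
        hp = out / f"{rec.subject_id}_psg.csv"
        write_hypnogram_csv(rec.hypnogram, hp)
        written.append(hp.name)
        for (device, site), series in rec.counts.items():
            cp = out / f"{rec.subject_id}_{device}_{site}.csv"
            write_counts_csv(series, cp)
            written.append(cp.name)
        truth_rows.append(
            (
                {"subject": rec.subject_id, "device": "truth", "site": "", "algorithm": "generative"},
                rec.truth,
            )
        )
    tp = out / "truth_outcomes.csv"
    write_outcomes(truth_rows, tp)
    written.append(tp.name)
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"files": written}, indent=2) + "\n")
    return out
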