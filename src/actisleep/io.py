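"""Readers and writers for the file formats the pipeline touches.

Count CSVs come in two documented dialects:

* ``plain`` — comma-separated ``timestamp,counts`` rows, ISO-8601
  timestamps, dot decimals.
* ``actilife_export`` — a metadata banner (terminated by a line of
  dashes, or a fixed number of lines when ``header_lines_to_skip`` is
  given) followed by axis columns; the first vertical-axis column
  ("Axis1") supplies the counts, and start time / epoch length are read
  from the banner when present.

Hypnograms are ``epoch_start,stage`` CSVs (30-s epochs, stages W/N1/N2/
N3/R) with optional ``# lights_out=...`` / ``# lights_on=...`` header
comments.  Outcome tables are flat CSVs; validation reports are JSON at
full double precision.  Every reader rejects malformed input — gaps,
unknown stages, negative counts — rather than silently repairing it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    EpochCountSeries,
    FormatError,
    GapError,
    Hypnogram,
    SleepOutcomes,
    ValidationError,
)

__all__ = [
    "CountCsvDialect",
    "PLAIN",
    "ACTILIFE",
    "read_counts_csv",
    "write_counts_csv",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "write_outcomes",
    "read_outcomes",
    "write_validation_report",
    "read_validation_report",
]


@dataclass(frozen=True)
class CountCsvDialect:
    """How a count CSV is laid out (see module docstring)."""

    name: str = "plain"
    header_lines_to_skip: Optional[int] = None
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ("plain", "actilife_export"):
            raise ValidationError("dialect must be 'plain' or 'actilife_export'")
        object.__setattr__(self, "column_map", dict(self.column_map))

    def column(self, logical: str, default: str) -> str:
        return self.column_map.get(logical, default)


PLAIN = CountCsvDialect("plain")
ACTILIFE = CountCsvDialect("actilife_export")

_BANNER_END = re.compile(r"^-{8,}\s*$")


def _check_spacing(times: pd.Series, epoch_length_s: Optional[int]) -> int:
    if len(times) < 2:
        if epoch_length_s is None:
            raise FormatError(
                "single-row file: epoch length cannot be inferred and must be supplied"
            )
        return epoch_length_s
    deltas = times.diff().dropna().dt.total_seconds()
    step = float(deltas.iloc[0])
    if step <= 0:
        raise GapError(f"non-increasing timestamp at {times.iloc[1]}")
    bad = deltas[deltas != step]
    if len(bad):
        raise GapError(f"non-uniform epoch spacing first seen at {times[bad.index[0]]}")
    if epoch_length_s is not None and step != epoch_length_s:
        raise GapError(
            f"timestamp spacing {step:g}s contradicts stated epoch length {epoch_length_s}s"
        )
    if not step.is_integer():
        raise GapError(f"non-integer epoch spacing {step}s")
    return int(step)


def _parse_banner(lines: list[str]) -> dict[str, Any]:
    """Pull start time and epoch period out of an export banner, when present."""
    meta: dict[str, Any] = {}
    date_s = time_s = None
    for ln in lines:
        m = re.search(r"Epoch Period.*?(\d{2}):(\d{2}):(\d{2})", ln)
        if m:
            h, mi, s = map(int, m.groups())
            meta["epoch_length_s"] = h * 3600 + mi * 60 + s
        m = re.search(r"Start Time\s+(\d{1,2}:\d{2}:\d{2})", ln)
        if m:
            time_s = m.group(1)
        m = re.search(r"Start Date\s+(\S+)", ln)
        if m:
            date_s = m.group(1)
    if date_s and time_s:
        for fmt in ("%d/%m/%Y %H:%M:%S", "%m/%d/%Y %H:%M:%S", "%Y-%m-%d %H:%M:%S"):
            try:
                meta["start_time"] = datetime.strptime(f"{date_s} {time_s}", fmt)
                break
            except ValueError:
                continue
    return meta


def read_counts_csv(
    path: str | Path,
    dialect: CountCsvDialect = PLAIN,
    *,
    subject_id: str = "",
    device: str = "",
    site: str = "hip",
    epoch_length_s: Optional[int] = None,
    start_time: Optional[datetime] = None,
) -> EpochCountSeries:
    """Parse a count CSV into an :class:`EpochCountSeries`.

    Gaps in the timestamp grid are rejected, never imputed.  Negative
    counts raise with the offending row index.
    """
    path = Path(path)
    if dialect.name == "plain":
        df = pd.read_csv(path)
        ts_col = dialect.column("timestamp", "timestamp")
        ct_col = dialect.column("counts", "counts")
        for col in (ts_col, ct_col):
            if col not in df.columns:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        times = pd.to_datetime(df[ts_col])
        step = _check_spacing(times, epoch_length_s)
        counts = pd.to_numeric(df[ct_col], errors="coerce")
        if counts.isna().any():
            raise FormatError(
                f"{path.name}: non-numeric count at row {int(counts.isna().idxmax())}"
            )
        neg = counts < 0
        if neg.any():
            raise ValidationError(
                f"{path.name}: negative count at row {int(neg.idxmax())}"
            )
        return EpochCountSeries(
            subject_id=subject_id,
            device=device,
            site=site,
            start_time=times.iloc[0].to_pydatetime(),
            epoch_length_s=step,
            counts=counts.to_numpy(dtype=float),
        )

    # actilife-style export: banner, then axis columns
    text = path.read_text().splitlines()
    if dialect.header_lines_to_skip is not None:
        skip = dialect.header_lines_to_skip
    else:
        skip = None
        for i, ln in enumerate(text):
            if _BANNER_END.match(ln):
                skip = i + 1
                break
        if skip is None:
            raise FormatError(
                f"{path.name}: no banner terminator found; "
                "set header_lines_to_skip for this export variant"
            )
    banner_meta = _parse_banner(text[:skip])
    df = pd.read_csv(path, skiprows=skip)
    axis_col = dialect.column("axis1", "Axis1")
    if axis_col not in df.columns:
        candidates = [c for c in df.columns if c.strip().lower() == "axis1"]
        if not candidates:
            raise FormatError(f"{path.name}: missing required column {axis_col!r}")
        axis_col = candidates[0]
    counts = pd.to_numeric(df[axis_col], errors="coerce")
    if counts.isna().any():
        raise FormatError(
            f"{path.name}: non-numeric count at row {int(counts.isna().idxmax())}"
        )
    if (counts < 0).any():
        raise ValidationError(
            f"{path.name}: negative count at row {int((counts < 0).idxmax())}"
        )
    ep = epoch_length_s or banner_meta.get("epoch_length_s")
    st = start_time or banner_meta.get("start_time")
    if ep is None or st is None:
        raise FormatError(
            f"{path.name}: start time and epoch length must come from the banner or be supplied"
        )
    return EpochCountSeries(
        subject_id=subject_id,
        device=device,
        site=site,
        start_time=st,
        epoch_length_s=int(ep),
        counts=counts.to_numpy(dtype=float),
    )


def write_counts_csv(series: EpochCountSeries, path: str | Path) -> Path:
    """Write a count series in the plain dialect."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": [t.isoformat() for t in series.times()],
            "counts": series.counts,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_hypnogram_csv(path: str | Path, subject_id: str = "") -> Hypnogram:
    """Parse a 30-s staging CSV into a :class:`Hypnogram`."""
    path = Path(path)
    header_meta: dict[str, datetime] = {}
    lines = path.read_text().splitlines()
    data_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            m = re.match(r"#\s*(lights_out|lights_on)\s*=\s*(\S+)", ln)
            if m:
                header_meta[m.group(1)] = datetime.fromisoformat(m.group(2))
            data_start = i + 1
        else:
            break
    df = pd.read_csv(path, skiprows=data_start)
    for col in ("epoch_start", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    times = pd.to_datetime(df["epoch_start"])
    if len(times) >= 2:
        deltas = times.diff().dropna().dt.total_seconds()
        bad = deltas[deltas != 30.0]
        if len(bad):
            raise GapError(
                f"{path.name}: non-30-s spacing first seen at {times[bad.index[0]]}"
            )
    stages = []
    for i, s in enumerate(df["stage"].astype(str)):
        s = s.strip()
        if s not in ("W", "N1", "N2", "N3", "R"):
            raise ValidationError(f"{path.name}: unknown stage {s!r} at row {i}")
        stages.append(s)
    return Hypnogram(
        subject_id=subject_id,
        start_time=times.iloc[0].to_pydatetime(),
        stages=tuple(stages),
        epoch_length_s=30,
        lights_out=header_meta.get("lights_out"),
        lights_on=header_meta.get("lights_on"),
    )


def write_hypnogram_csv(h: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        if h.lights_out is not None:
            fh.write(f"# lights_out={h.lights_out.isoformat()}\n")
        if h.lights_on is not None:
            fh.write(f"# lights_on={h.lights_on.isoformat()}\n")
        fh.write("epoch_start,stage\n")
        for i, s in enumerate(h.stages):
            fh.write(f"{h.time_at(i).isoformat()},{s}\n")
    return path


OUTCOME_COLUMNS = [
    "subject",
    "device",
    "site",
    "algorithm",
    "onset",
    "offset",
    "spt_min",
    "waso_min",
    "tst_min",
    "efficiency_pct",
]


def write_outcomes(
    rows: Sequence[tuple[Mapping[str, str], SleepOutcomes]], path: str | Path
) -> Path:
    """One CSV row per subject × device × site, with provenance columns.

    ``rows`` pairs a metadata mapping (subject/device/site/algorithm) with
    the outcomes; an empty collection writes a header-only file.
    """
    path = Path(path)
    records = []
    for meta, oc in rows:
        records.append(
            {
                "subject": meta.get("subject", ""),
                "device": meta.get("device", ""),
                "site": meta.get("site", ""),
                "algorithm": meta.get("algorithm", ""),
                "onset": oc.onset.isoformat(),
                "offset": oc.offset.isoformat(),
                "spt_min": repr(oc.spt_min),
                "waso_min": repr(oc.waso_min),
                "tst_min": repr(oc.tst_min),
                "efficiency_pct": repr(oc.efficiency_pct),
            }
        )
    pd.DataFrame(records, columns=OUTCOME_COLUMNS).to_csv(path, index=False)
    return path


def read_outcomes(
    path: str | Path,
) -> list[tuple[dict[str, str], SleepOutcomes]]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        meta = {k: row[k] for k in ("subject", "device", "site", "algorithm")}
        oc = SleepOutcomes(
            onset=datetime.fromisoformat(row["onset"]),
            offset=datetime.fromisoformat(row["offset"]),
            spt_min=float(row["spt_min"]),
            waso_min=float(row["waso_min"]),
            tst_min=float(row["tst_min"]),
            efficiency_pct=float(row["efficiency_pct"]),
        )
        out.append((meta, oc))
    return out


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if isinstance(o, (datetime,)):
            return o.isoformat()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        return super().default(o)


def write_validation_report(report: Mapping[str, Any], path: str | Path) -> Path:
    """Serialise a validation report to JSON at full double precision."""
    path = Path(path)
    path.write_text(json.dumps(report, cls=_ReportEncoder, indent=2) + "\n")
    return path


def read_validation_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
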