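"""Corneal wound-healing percentage from serial wound-area measurements.

Healing at time t is the fractional reduction of the wound area relative to
time 0, times 100. Only area ratios matter, so the unit (mm² or pixels) is
the caller's choice as long as it is consistent within a series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = ["WoundSeries", "healing_percent", "summarize_groups", "read_wound_table"]


@dataclass
class WoundSeries:
    """Wound areas over time for one subject.

    ``areas`` maps time in hours to wound area; time 0 must be present with
    a positive area. ``group`` is the treatment group for summaries.
    """

    subject_id: str
    areas: dict[float, float]
    group: str | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise DataError(f"negative wound area for subject {self.subject_id}")
        if 0 not in self.areas:
            raise DataError(f"subject {self.subject_id} has no time-0 measurement")
        if self.areas[0] <= 0:
            raise DataError(f"subject {self.subject_id} has zero initial wound area")


def healing_percent(series: WoundSeries, t: float) -> float:
    """Percent of the initial wound area closed by time t.

    (area_0 − area_t) / area_0 × 100; negative if the wound grew.
    """
    if t not in series.areas:
        raise DataError(f"subject {series.subject_id} has no measurement at {t} h")
    a0 = series.areas[0]
    at = series.areas[t]
    return (a0 - at) / a0 * 100.0


def summarize_groups(series_list: Iterable[WoundSeries], t: float) -> pd.DataFrame:
    """Per-group mean ± SEM of healing percentage at time t.

    SEM = sd / sqrt(n) with the sample (n−1) standard deviation; a group of
    fewer than two subjects has no SEM and is an error.
    """
    groups: dict[str, list[float]] = {}
    for series in series_list:
        group = series.group if series.group is not None else "all"
        groups.setdefault(group, []).append(healing_percent(series, t))

    rows = []
    for group in sorted(groups):
        values = groups[group]
        n = len(values)
        if n < 2:
            raise DataError(f"group {group!r} has {n} subject(s); SEM needs at least 2")
        mean = sum(values) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
        rows.append(
            {
                "group": group,
                "time_h": t,
                "n": n,
                "mean_healing_pct": mean,
                "sem": sd / math.sqrt(n),
            }
        )
    return pd.DataFrame(rows)


def read_wound_table(path: str | Path) -> list[WoundSeries]:
    """Read a long-format TSV with columns subject, group, time_h, area."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"wound table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    required = {"subject", "group", "time_h", "area"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"wound table lacks column(s) {sorted(missing)}")
    out = []
    for (subject, group), sub in frame.groupby(["subject", "group"]):
        areas = {float(r.time_h): float(r.area) for r in sub.itertuples()}
        out.append(WoundSeries(subject_id=str(subject), areas=areas, group=str(group)))
    return out
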