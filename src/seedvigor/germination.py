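"""Germination-test metrics: germination rate and seed-vitality index.

A germination test follows a batch of seeds for 7 days; a seed counts as
germinated once its germ reaches 1 cm.  Two summary numbers are computed per
group:

* germination rate  GR = GN / (GN + SN) * 100, the percentage of tested seeds
  that germinated (GN germinated, SN not, GN + SN seeds tested);
* vitality index    VI = S * sum_t (G_t / D_t), where G_t seeds germinated on
  day D_t and S is the mean germ length in cm.  Early germination is weighted
  up, so VI rewards vigour, not just viability.

A product form S * sum_t (G_t * D_t) exists in parts of the seed-testing
literature and is available via ``form="product"``; the speed-weighted form
is the default because it decreases when germination shifts later, which is
the stated role of germination days as a vigour standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TEST_DAYS = 7


@dataclass
class GerminationRecord:
    """Daily germination counts for one seed group over a 7-day test."""

    daily_counts: np.ndarray  # G_t for days 1..7
    SN: int                   # seeds not germinated by day 7
    germ_length: float        # S, mean germ length in cm
    group: str = ""

    def __post_init__(self) -> None:
        self.daily_counts = np.asarray(self.daily_counts, dtype=int)
        if self.daily_counts.ndim != 1 or self.daily_counts.size > TEST_DAYS:
            raise ValueError(f"daily_counts must be 1-D with at most {TEST_DAYS} days")
        if np.any(self.daily_counts < 0) or self.SN < 0:
            raise ValueError("counts must be non-negative")
        if self.germ_length < 0:
            raise ValueError("germ length must be non-negative")

    @property
    def GN(self) -> int:
        """Total germinated seeds (sum of the daily counts)."""
        return int(self.daily_counts.sum())

    @property
    def n_tested(self) -> int:
        return self.GN + self.SN


def germination_rate(record: GerminationRecord) -> float:
    """GR = GN / (GN + SN) * 100, rounded to 2 decimals.

    The denominator is the total number of seeds tested.
    """
    total = record.n_tested
    if total <= 0:
        raise ValueError("no seeds tested: GN + SN must be positive")
    return round(record.GN / total * 100.0, 2)


def vitality_index(record: GerminationRecord, form: str = "speed") -> float:
    """VI = S * sum_t (G_t / D_t) (default) or S * sum_t (G_t * D_t)."""
    days = np.arange(1, record.daily_counts.size + 1, dtype=float)
    if form == "speed":
        total = float(np.sum(record.daily_counts / days))
    elif form == "product":
        total = float(np.sum(record.daily_counts * days))
    else:
        raise ValueError(f"unknown vitality-index form {form!r}")
    return record.germ_length * total


def read_counts_csv(path: str | Path) -> list[GerminationRecord]:
    """Read a long-format count table: columns group, day, count, germ_length.

    Rows with day 0 (or a missing day) give the non-germinated count SN.
    """
    df = pd.read_csv(path)
    required = {"group", "day", "count", "germ_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    records = []
    for group, sub in df.groupby("group", sort=False):
        counts = np.zeros(TEST_DAYS, dtype=int)
        sn = 0
        for _, row in sub.iterrows():
            day = int(row["day"])
            if day == 0:
                sn += int(row["count"])
            elif 1 <= day <= TEST_DAYS:
                counts[day - 1] += int(row["count"])
            else:
                raise ValueError(f"day {day} outside the {TEST_DAYS}-day test")
        records.append(GerminationRecord(
            daily_counts=counts, SN=sn,
            germ_length=float(sub["germ_length"].iloc[0]), group=str(group),
        ))
    return records


def germination_report(records: list[GerminationRecord]) -> pd.DataFrame:
    """Per-group summary table: GN, SN, GR (%) and VI."""
    rows = [
        {
            "group": r.group,
            "germination_number": r.GN,
            "non_germination_number": r.SN,
            "germination_rate": germination_rate(r),
            "vitality_index": round(vitality_index(r), 2),
        }
        for r in records
    ]
    return pd.DataFrame(rows)
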