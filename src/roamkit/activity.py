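"""15-minute activity binning and the colony activity heatmap.

An animal counts as active in a quarter-hour bin when it contacted at least
two *different* antennas within that bin — a single antenna read repeatedly
(e.g. an animal sleeping on a ring antenna) does not qualify.  Bins are
aligned to the wall clock (00:00, 00:15, ...), half-open, 96 per day.
Summing the boolean matrix over animals gives the day x bin heatmap of how
many colony members were active at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .rfid_io import EventLog

__all__ = ["BINS_PER_DAY", "ActivityMatrix", "activity_matrix", "active_count_heatmap"]

BINS_PER_DAY = 96  # 24 h / 15 min


@dataclass
class ActivityMatrix:
    """Boolean (animal, day, bin) activity flags for a colony."""

    animals: list[str]
    days: list[date]
    active: np.ndarray  # shape (n_animals, n_days, 96), bool

    def __post_init__(self) -> None:
        expected = (len(self.animals), len(self.days), BINS_PER_DAY)
        if self.active.shape != expected:
            raise ValueError(f"active must have shape {expected}")

    def to_long(self) -> pd.DataFrame:
        """Long-format ``animal_id,date,bin,bin_start,active`` table."""
        rows = []
        for ai, a in enumerate(self.animals):
            for di, d in enumerate(self.days):
                for b in range(BINS_PER_DAY):
                    rows.append((a, d, b, f"{b // 4:02d}:{15 * (b % 4):02d}",
                                 bool(self.active[ai, di, b])))
        return pd.DataFrame(rows, columns=["animal_id", "date", "bin", "bin_start", "active"])


def activity_matrix(
    log: EventLog,
    animals: Sequence[str] | None = None,
    days: Sequence[date] | None = None,
) -> ActivityMatrix:
    """Apply the two-distinct-antennas-per-15-min rule per animal per bin.

    Raw (non-debounced) events are the intended input: distinct-antenna
    counting is insensitive to same-antenna repeats.
    """
    if animals is None:
        animals = log.animals
    animals = list(animals)
    df = log.events
    if days is None:
        if len(df) == 0:
            raise ValueError("days must be given for an empty log")
        d0 = df["timestamp"].min().date()
        d1 = df["timestamp"].max().date()
        days = [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]
    days = list(days)

    active = np.zeros((len(animals), len(days), BINS_PER_DAY), dtype=bool)
    if len(df) == 0:
        return ActivityMatrix(animals, days, active)

    a_index = {a: i for i, a in enumerate(animals)}
    d_index = {d: i for i, d in enumerate(days)}

    ts = df["timestamp"]
    work = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "antenna_id": df["antenna_id"],
            "day": ts.dt.date,
            "bin": (ts.dt.hour * 4 + ts.dt.minute // 15).astype(np.int16),
        }
    )
    distinct = (
        work.groupby(["animal_id", "day", "bin"], sort=False)["antenna_id"]
        .nunique()
        .reset_index(name="n_antennas")
    )
    hit = distinct[distinct["n_antennas"] >= 2]
    for animal, day, b in hit[["animal_id", "day", "bin"]].itertuples(index=False):
        ai = a_index.get(animal)
        di = d_index.get(day)
        if ai is not None and di is not None:
            active[ai, di, b] = True
    return ActivityMatrix(animals, days, active)


def active_count_heatmap(matrix: ActivityMatrix) -> pd.DataFrame:
    """Day x bin counts of simultaneously active animals (rows=days, cols=bins)."""
    counts = matrix.active.sum(axis=0).astype(int)
    return pd.DataFrame(counts, index=pd.Index(matrix.days, name="date"),
                        columns=[f"{b // 4:02d}:{15 * (b % 4):02d}" for b in range(BINS_PER_DAY)])
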