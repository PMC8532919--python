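"""Roaming entropy: antenna-contact distributions, RE, cRE and group summaries.

The roaming entropy of animal *i* over period *t* is the Shannon entropy of
its antenna-contact probability vector, normalised by the maximum attainable
entropy over the ``k`` installed antennas::

    RE_{i,t} = - sum_j p_{i,j,t} * log(p_{i,j,t}) / log(k)

with ``p_{i,j,t}`` the fraction of the animal's contacts that hit antenna
``j`` and the usual convention ``0 * log 0 = 0``.  RE is 0 when all contacts
hit one antenna, 1 for uniform use of all ``k``, and is invariant to the
logarithm base (numerator and denominator share it; natural log is used
internally).  The cumulative roaming entropy cRE is the running sum of
nightly RE values; its slope reflects sustained spatial activity and its
cross-animal spread behavioural individuality.

Nights on which an animal produced no contacts have an undefined RE; they are
reported as missing, excluded from group summaries, and contribute 0 to cRE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd

from .rfid_io import EventLog, LightSchedule, iter_nights
from .stats import OlsFit, ols

__all__ = [
    "ContactDistribution",
    "RoamingSeries",
    "SummaryStats",
    "contact_distribution",
    "roaming_entropy",
    "cumulative_re",
    "group_summary",
    "variance_trajectory",
    "nightly_re_table",
]


@dataclass
class ContactDistribution:
    """Per-animal, per-period antenna contact counts and probabilities."""

    animal_id: str
    period_label: str
    counts: np.ndarray  # length k, non-negative integers
    k: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.k,):
            raise ValueError(f"counts must have length k={self.k}")
        if (self.counts < 0).any():
            raise ValueError("negative contact counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def empty(self) -> bool:
        return self.total == 0

    @property
    def p(self) -> np.ndarray:
        """Probability vector ``counts / total`` (NaN-free; zeros when empty)."""
        if self.empty:
            return np.zeros(self.k)
        return self.counts / self.total


def contact_distribution(
    night_log: EventLog, animal_id: str, k: int, period_label: str = ""
) -> ContactDistribution:
    """Tally one animal's contacts per antenna over an already-sliced log."""
    if k < night_log.layout_k:
        raise ValueError(f"k={k} smaller than layout_k={night_log.layout_k}")
    ants = night_log.for_animal(animal_id)["antenna_id"].to_numpy()
    if ants.size and ants.max() > k:
        raise ValueError(f"observed antenna {int(ants.max())} exceeds k={k}")
    counts = np.bincount(ants, minlength=k + 1)[1:]  # antenna ids are 1-based
    return ContactDistribution(animal_id, period_label, counts, k)


def _normalized_entropy(p: np.ndarray, k: int) -> float:
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    # A probability vector's entropy lies in [0, log k]; the clip only removes
    # ~1e-16 float noise (e.g. the uniform vector at k=27).
    return float(np.clip(h / np.log(k), 0.0, 1.0)) + 0.0  # +0.0 normalises -0.0


def roaming_entropy(dist: ContactDistribution | np.ndarray, k: int | None = None) -> float:
    """Normalised Shannon entropy of a contact distribution; NaN when empty.

    Accepts a :class:`ContactDistribution` or a raw probability vector with an
    explicit ``k`` (the number of installed antennas, not the number
    contacted).
    """
    if isinstance(dist, ContactDistribution):
        if dist.k <= 1:
            raise ValueError("k must exceed 1: log(k) = 0 leaves RE undefined")
        if dist.empty:
            return float("nan")
        return _normalized_entropy(dist.p, dist.k)
    p = np.asarray(dist, dtype=float)
    if k is None:
        k = p.size
    if k <= 1:
        raise ValueError("k must exceed 1: log(k) = 0 leaves RE undefined")
    if p.size > k or (p < 0).any():
        raise ValueError("invalid probability vector")
    s = p.sum()
    if s == 0:
        return float("nan")
    if abs(s - 1.0) > 1e-8:
        raise ValueError("probability vector must sum to 1")
    return _normalized_entropy(p, k)


def cumulative_re(re_values, missing_policy: str = "skip") -> np.ndarray:
    """Running sum of nightly RE; missing nights contribute 0 under ``skip``."""
    if missing_policy != "skip":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    re = np.asarray(re_values, dtype=float)
    if re.size == 0:
        return np.array([])
    finite = re[np.isfinite(re)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("RE values must lie in [0, 1]")
    return np.cumsum(np.where(np.isfinite(re), re, 0.0))


@dataclass(frozen=True)
class SummaryStats:
    """Mean ± sd with CV%, range and n, as activity tables are reported."""

    mean: float
    sd: float
    cv_percent: float
    max: float
    min: float
    n: int

    def __str__(self) -> str:
        return (
            f"{self.mean:.3f} ± {self.sd:.3f} (CV = {self.cv_percent:.1f}%, "
            f"max = {self.max:.3f}, min = {self.min:.3f}, n = {self.n})"
        )


def group_summary(values) -> SummaryStats:
    """Cross-animal summary of a metric: mean, sample sd, CV%, max, min, n."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no non-missing values to summarise")
    if v.size < 2:
        raise ValueError("sd/CV need at least 2 non-missing values")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    cv_percent = 100.0 * sd / mean if mean > 0 else float("nan")
    return SummaryStats(mean, sd, cv_percent, float(v.max()), float(v.min()), int(v.size))


@dataclass
class RoamingSeries:
    """One animal's nightly RE trajectory and its cumulative sum."""

    animal_id: str
    dates: list
    re: np.ndarray
    cre: np.ndarray = field(init=False)
    missing_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.re = np.asarray(self.re, dtype=float)
        if len(self.dates) != self.re.size:
            raise ValueError("dates and re must align")
        self.missing_mask = ~np.isfinite(self.re)
        self.cre = cumulative_re(self.re)


def variance_trajectory(re_matrix) -> tuple[np.ndarray, OlsFit]:
    """Cross-animal variance of RE per night, with its OLS trend over nights.

    ``re_matrix`` is animals x nights; missing values (NaN) are ignored per
    night, but every night must retain at least 2 animals.
    """
    m = np.asarray(re_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("re_matrix must be 2-D (animals x nights)")
    n_valid = np.sum(np.isfinite(m), axis=0)
    if (n_valid < 2).any():
        raise ValueError("every night needs >= 2 animals with non-missing RE")
    with np.errstate(invalid="ignore"):
        var = np.nanvar(m, axis=0, ddof=1)
    if m.shape[1] < 3:
        raise ValueError("trend needs at least 3 nights")
    trend = ols(np.arange(m.shape[1], dtype=float), var)
    return var, trend


def nightly_re_table(
    log: EventLog,
    sched: LightSchedule,
    night_dates: Sequence[date],
    animals: Sequence[str] | None = None,
    k: int | None = None,
) -> pd.DataFrame:
    """Nightly RE and cRE for every animal: ``animal_id,date,re,cre,missing``.

    The log should already be deduplicated if debounced contacts are wanted;
    slicing to each night's dark phase happens here.
    """
    if animals is None:
        animals = log.animals
    if k is None:
        k = log.layout_k
    re_by_animal: dict[str, list[float]] = {a: [] for a in animals}
    for night, night_log in iter_nights(log, sched, night_dates):
        for a in animals:
            dist = contact_distribution(night_log, a, k, period_label=str(night))
            re_by_animal[a].append(roaming_entropy(dist))
    frames = []
    for a in animals:
        series = RoamingSeries(a, list(night_dates), np.array(re_by_animal[a]))
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": a,
                    "date": list(night_dates),
                    "re": series.re,
                    "cre": series.cre,
                    "missing": series.missing_mask,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
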