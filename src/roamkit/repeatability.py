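"""Sliding-window repeatability (ICC) of nightly roaming entropy.

Repeatability R is the fraction of total variance in nightly RE attributable
to consistent between-animal differences,

    R = sigma2_among / (sigma2_among + sigma2_within),

estimated from the one-way ANOVA variance components with the animal as the
grouping factor.  For ``a`` animals with group sizes ``n_i`` (N total)::

    sigma2_within = MS_W
    sigma2_among  = (MS_A - MS_W) / n0,   n0 = (N - sum(n_i^2)/N) / (a - 1)

(n0 reduces to the common group size for balanced designs); a negative
among-group component is truncated to 0, so R is always in [0, 1].

Uncertainty comes from a cluster bootstrap — whole animals are resampled with
replacement, because animals are the exchangeable units for a between-animal
variance ratio — and significance from a permutation test that shuffles
observations across animals while preserving group sizes.  Windows of four
weeks advance one week at a time across the RE series, so 20 analysed weeks
give 17 windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import OlsFit, ols

__all__ = [
    "RepeatabilityWindow",
    "RepeatabilityResult",
    "sliding_windows",
    "estimate_repeatability",
    "bootstrap_ci",
    "permutation_pvalue",
    "repeatability_trend",
    "windowed_repeatability",
]

NIGHTS_PER_WEEK = 7


@dataclass(frozen=True)
class RepeatabilityWindow:
    """One 4-week analysis window, in 1-based weeks from the series start."""

    index: int
    first_week: int
    last_week: int


@dataclass(frozen=True)
class RepeatabilityResult:
    R: float
    ci: tuple[float, float]
    p_perm: float
    n_groups: int
    n_obs: int


def sliding_windows(
    n_weeks: int, width_weeks: int = 4, step_weeks: int = 1
) -> list[RepeatabilityWindow]:
    """Enumerate width-week windows advancing step weeks over an n-week series."""
    if width_weeks < 1 or step_weeks < 1:
        raise ValueError("width_weeks and step_weeks must be >= 1")
    if n_weeks < width_weeks:
        raise ValueError(f"series of {n_weeks} weeks shorter than window of {width_weeks}")
    return [
        RepeatabilityWindow(index=i, first_week=start + 1, last_week=start + width_weeks)
        for i, start in enumerate(range(0, n_weeks - width_weeks + 1, step_weeks))
    ]


def _clean_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if g.size:
            out.append(g)
    return out


def estimate_repeatability(groups: Sequence[np.ndarray]) -> float:
    """One-way ANOVA ICC of per-animal value groups, truncated to [0, 1].

    Missing values are dropped; groups may be unbalanced.  Fully degenerate
    data (zero variance everywhere) returns 0.
    """
    gs = _clean_groups(groups)
    a = len(gs)
    if a < 2:
        raise ValueError("repeatability needs at least 2 groups")
    sizes = np.array([g.size for g in gs], dtype=float)
    if not (sizes >= 2).any():
        raise ValueError("at least one group needs >= 2 observations")
    N = sizes.sum()
    grand = float(np.concatenate(gs).mean())
    means = np.array([g.mean() for g in gs])
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    ms_among = ss_among / (a - 1)
    df_within = N - a
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    n0 = (N - float(np.sum(sizes**2)) / N) / (a - 1)
    sigma_among = max(0.0, (ms_among - ms_within) / n0)
    denom = sigma_among + ms_within
    if denom == 0.0:
        return 0.0
    return float(np.clip(sigma_among / denom, 0.0, 1.0))


def bootstrap_ci(
    groups: Sequence[np.ndarray], n_boot: int = 500, seed: int | None = None
) -> tuple[float, float]:
    """Cluster-bootstrap (2.5%, 97.5%) interval for R, resampling whole animals."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    gs = _clean_groups(groups)
    rng = np.random.default_rng(seed)
    a = len(gs)
    reps = np.empty(n_boot)
    overall_var = float(np.var(np.concatenate(gs)))
    for b in range(n_boot):
        idx = rng.integers(0, a, size=a)
        sample = [gs[i] for i in idx]
        pooled = np.concatenate(sample)
        # A resample of clones of one animal has no between/within structure:
        # R is undefined there (unless the data were constant to begin with).
        if overall_var > 0 and np.var(pooled) == 0:
            reps[b] = np.nan
            continue
        try:
            reps[b] = estimate_repeatability(sample)
        except ValueError:
            reps[b] = np.nan
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_pvalue(
    groups: Sequence[np.ndarray], n_perm: int = 100, seed: int | None = None
) -> float:
    """Permutation p-value: shuffle observations across animals, keep sizes.

    Uses the +1 correction ``p = (1 + #{R_perm >= R_obs}) / (1 + n_perm)`` so
    a finite number of permutations can never report p = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    gs = _clean_groups(groups)
    r_obs = estimate_repeatability(gs)
    # Sorting the pool makes the seeded permutation stream invariant to how
    # the animals were ordered (for equal group sizes, exactly so).
    pooled = np.sort(np.concatenate(gs))
    sizes = [g.size for g in gs]
    edges = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if estimate_repeatability(np.split(perm, edges)) >= r_obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def repeatability_trend(r_values: Sequence[float]) -> OlsFit:
    """OLS trend of window repeatability estimates on window index."""
    r = np.asarray(r_values, dtype=float)
    if r.size < 3:
        raise ValueError("trend needs at least 3 windows")
    return ols(np.arange(r.size, dtype=float), r)


def windowed_repeatability(
    re_table: pd.DataFrame,
    n_weeks: int | None = None,
    width_weeks: int = 4,
    step_weeks: int = 1,
    n_boot: int = 500,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sliding-window repeatability over a nightly RE table.

    ``re_table`` is the long ``animal_id,date,re`` format produced by
    :func:`roamkit.entropy.nightly_re_table`.  Weeks are anchored to the
    first night of the series; partial trailing weeks are dropped.  Returns
    ``window_index,week_start,week_end,R,ci_low,ci_high,p_perm``.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    dates = np.sort(re_table["date"].unique())
    night_index = {d: i for i, d in enumerate(dates)}
    if n_weeks is None:
        n_weeks = len(dates) // NIGHTS_PER_WEEK
    windows = sliding_windows(n_weeks, width_weeks, step_weeks)
    animals = sorted(re_table["animal_id"].unique())

    rows = []
    rng = np.random.default_rng(seed)
    for w in windows:
        lo = (w.first_week - 1) * NIGHTS_PER_WEEK
        hi = w.last_week * NIGHTS_PER_WEEK
        sel = re_table[
            re_table["date"].map(lambda d: lo <= night_index[d] < hi)
            & np.isfinite(re_table["re"])
        ]
        groups = [sel.loc[sel["animal_id"] == a, "re"].to_numpy() for a in animals]
        groups = [g for g in groups if g.size]
        r = estimate_repeatability(groups)
        boot_seed, perm_seed = rng.integers(0, 2**31 - 1, size=2)
        ci = bootstrap_ci(groups, n_boot=n_boot, seed=int(boot_seed))
        p = permutation_pvalue(groups, n_perm=n_perm, seed=int(perm_seed))
        rows.append(
            {
                "window_index": w.index,
                "week_start": w.first_week,
                "week_end": w.last_week,
                "R": r,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_perm": p,
                "n_groups": len(groups),
                "n_obs": int(sum(g.size for g in groups)),
            }
        )
    return pd.DataFrame(rows)
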