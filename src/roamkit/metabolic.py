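"""Resting metabolic rate from indirect-calorimetry V̇O₂ traces.

A resting mouse and an active mouse occupy two distinct V̇O₂ regimes, so the
cumulative frequency curve of a 9-10 h trace is S-shaped: a steep rise
through the resting mode, a shallow stretch across the gap, and a second rise
through the active mode.  Fitting a continuous two-segment line

    y = b0 + b1*x + b2*(x - psi)+

to (V̇O₂, cumulative %) and taking the breakpoint ``psi`` as the
rest/activity threshold separates the regimes without any manual cutoff; the
RMR is then the mean of all V̇O₂ samples strictly below the threshold, in
mL min⁻¹ kg⁻¹.

The breakpoint is found by an RSS grid search over interior x-quantiles
followed by golden-section refinement — deterministic, and global over the
searched range, unlike iterative-linearisation schemes that need a starting
guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Vo2Trace",
    "SegmentedFit",
    "RmrResult",
    "BreakpointError",
    "cumulative_frequency",
    "segmented_fit",
    "resting_metabolic_rate",
]


class BreakpointError(ValueError):
    """No admissible breakpoint (too few points, or none with 3 per side)."""


@dataclass
class Vo2Trace:
    """One animal's oxygen-consumption series, mL min⁻¹ kg⁻¹."""

    animal_id: str
    times: np.ndarray  # seconds, strictly increasing
    vo2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.times.shape != self.vo2.shape or self.times.ndim != 1:
            raise ValueError("times and vo2 must be 1-D of equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.vo2 <= 0).any():
            raise ValueError("vo2 must be positive")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, animal_id: str, mass_g: float | None = None
    ) -> "Vo2Trace":
        """Build from a ``time_s,vo2_ml_min_kg`` table, or ``time_s,vo2_ml_min``
        plus body mass in grams for mass-specific conversion."""
        if "vo2_ml_min_kg" in df.columns:
            vo2 = df["vo2_ml_min_kg"].to_numpy(dtype=float)
        elif "vo2_ml_min" in df.columns:
            if mass_g is None:
                raise ValueError("absolute vo2_ml_min needs mass_g for conversion")
            vo2 = df["vo2_ml_min"].to_numpy(dtype=float) / (mass_g / 1000.0)
        else:
            raise ValueError("need a vo2_ml_min_kg or vo2_ml_min column")
        return cls(animal_id, df["time_s"].to_numpy(dtype=float), vo2)


def cumulative_frequency(vo2) -> tuple[np.ndarray, np.ndarray]:
    """Empirical cumulative frequency in percent against sorted V̇O₂.

    Returns ``(x, y)`` with ``x`` the ascending distinct values and ``y`` the
    percentage of samples at or below each; ties share the highest rank.
    """
    v = np.asarray(vo2, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    sv = np.sort(v)
    x = np.unique(sv)
    y = 100.0 * np.searchsorted(sv, x, side="right") / v.size
    return x, y


@dataclass(frozen=True)
class SegmentedFit:
    psi: float
    intercept: float
    slopes: tuple[float, float]  # left and right segment slopes
    rss: float
    rss_single: float
    n_left: int
    n_right: int

    y_scale: float = 1.0  # sum of squared responses, for the degeneracy floor

    @property
    def no_material_breakpoint(self) -> bool:
        """True when the kink buys < 1% RSS over the best single line."""
        floor = 1e-12 * max(1.0, self.y_scale)
        if self.rss_single <= floor:
            return True  # a single line already fits to numerical precision
        return (self.rss_single - self.rss) / self.rss_single < 0.01


def _rss_at(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def segmented_fit(
    x,
    y,
    n_grid: int = 200,
    quantile_range: tuple[float, float] = (0.02, 0.98),
    min_per_side: int = 3,
    refine_tol: float = 1e-9,
) -> SegmentedFit:
    """Continuous two-segment least squares with grid + golden-section breakpoint.

    Candidates are ``n_grid`` quantiles of ``x`` between the 2nd and 98th
    percentile (by default); each must leave at least ``min_per_side`` points
    on both sides.  The best grid candidate is refined by golden-section
    search between its neighbours; RSS ties go to the smaller breakpoint.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 6:
        raise BreakpointError("segmented fit needs at least 6 points")
    if (np.diff(x) < 0).any():
        raise ValueError("x must be sorted ascending")

    qs = np.linspace(quantile_range[0], quantile_range[1], n_grid)
    candidates = np.unique(np.quantile(x, qs))
    admissible = [
        c
        for c in candidates
        if np.sum(x <= c) >= min_per_side and np.sum(x > c) >= min_per_side
    ]
    if not admissible:
        raise BreakpointError("no admissible breakpoint: fewer than "
                              f"{min_per_side} points on one side of every candidate")

    rss_grid = np.array([_rss_at(x, y, c)[0] for c in admissible])
    best = int(np.argmin(rss_grid))  # argmin takes the first = smallest psi on ties

    lo = admissible[best - 1] if best > 0 else admissible[0]
    hi = admissible[best + 1] if best < len(admissible) - 1 else admissible[-1]
    a, b = float(lo), float(hi)
    # Golden-section on the bracket around the best grid candidate.
    c1 = b - _GOLDEN * (b - a)
    c2 = a + _GOLDEN * (b - a)
    f1, f2 = _rss_at(x, y, c1)[0], _rss_at(x, y, c2)[0]
    while b - a > refine_tol * max(1.0, abs(b)):
        if f1 <= f2:  # prefer the left half on ties -> smaller psi
            b, c2, f2 = c2, c1, f1
            c1 = b - _GOLDEN * (b - a)
            f1 = _rss_at(x, y, c1)[0]
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + _GOLDEN * (b - a)
            f2 = _rss_at(x, y, c2)[0]
    psi = 0.5 * (a + b)
    rss_ref, beta_ref = _rss_at(x, y, psi)
    if rss_grid[best] < rss_ref:  # keep whichever is better
        psi = float(admissible[best])
        rss_ref, beta_ref = _rss_at(x, y, psi)

    ones = np.column_stack([np.ones_like(x), x])
    beta1, *_ = np.linalg.lstsq(ones, y, rcond=None)
    resid1 = y - ones @ beta1
    rss_single = float(resid1 @ resid1)

    b0, b1, b2 = beta_ref
    return SegmentedFit(
        psi=float(psi),
        intercept=float(b0),
        slopes=(float(b1), float(b1 + b2)),
        rss=rss_ref,
        rss_single=rss_single,
        n_left=int(np.sum(x <= psi)),
        n_right=int(np.sum(x > psi)),
        y_scale=float(y @ y),
    )


@dataclass(frozen=True)
class RmrResult:
    animal_id: str
    threshold: float
    rmr: float
    n_below: int
    rss_two_segment: float
    rss_single_line: float
    degenerate: bool = False


def resting_metabolic_rate(trace: Vo2Trace, min_samples: int = 50) -> RmrResult:
    """Threshold a V̇O₂ trace on its cumulative-frequency breakpoint.

    ``rmr`` is the arithmetic mean of samples strictly below the threshold.
    Traces too degenerate to support a breakpoint (e.g. constant V̇O₂) return
    a result flagged ``degenerate`` with the trace mean as RMR.
    """
    v = trace.vo2
    if v.size < min_samples:
        raise ValueError(f"trace has {v.size} samples; need >= {min_samples}")
    x, y = cumulative_frequency(v)
    try:
        fit = segmented_fit(x, y)
    except BreakpointError:
        return RmrResult(
            animal_id=trace.animal_id,
            threshold=float(np.max(v)),
            rmr=float(np.mean(v)),
            n_below=int(v.size),
            rss_two_segment=float("nan"),
            rss_single_line=float("nan"),
            degenerate=True,
        )
    below = v[v < fit.psi]
    if below.size == 0:
        raise ValueError("no V̇O₂ samples below the fitted threshold")
    return RmrResult(
        animal_id=trace.animal_id,
        threshold=fit.psi,
        rmr=float(np.mean(below)),
        n_below=int(below.size),
        rss_two_segment=fit.rss,
        rss_single_line=fit.rss_single,
        degenerate=fit.no_material_breakpoint,
    )
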