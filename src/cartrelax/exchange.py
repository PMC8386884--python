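"""Hydration dependence of relaxation: linear trends and fast exchange.

During drying, the observed relaxation rate of the liquid-like pool is a
population-weighted average of bulk and surface contributions
(``1/T_i = p_a/T_i,surf + (1 - p_a)/T_i,bulk ~ S/V * rho_i + 1/T_i,bulk``).
Two complementary parameterizations are fitted and reported side by side:
the empirical linear dependence of T_i on total sample weight, and the
fast-exchange form with the rate linear in the inverse free-water measure
(weight minus dry weight).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .models import ParameterError

__all__ = [
    "HydrationSeries",
    "DEFAULT_BULK_TIME_S",
    "fit_linear_weight",
    "fit_fast_exchange",
    "drying_summary",
]

#: Bulk relaxation time of the brine phase, seconds.
DEFAULT_BULK_TIME_S: float = 2.0


@dataclass(frozen=True)
class HydrationSeries:
    """Relaxation times of one sample tracked over hydration stages."""

    labels: tuple
    sample_weight: np.ndarray  # g
    T1: np.ndarray  # ms
    T2: np.ndarray  # ms
    water_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.sample_weight, dtype=float)
        t1 = np.asarray(self.T1, dtype=float)
        t2 = np.asarray(self.T2, dtype=float)
        if not (len(self.labels) == w.size == t1.size == t2.size):
            raise ParameterError("series fields must have equal length")
        if w.size < 3:
            raise ParameterError("need at least 3 hydration stages for fitting")
        if np.any(w <= 0) or np.any(t1 <= 0) or np.any(t2 <= 0):
            raise ParameterError("weights and relaxation times must be > 0")
        object.__setattr__(self, "sample_weight", w)
        object.__setattr__(self, "T1", t1)
        object.__setattr__(self, "T2", t2)


def fit_linear_weight(series: HydrationSeries, which: str = "T2") -> dict:
    """Ordinary least squares of T_i (ms) against sample weight (g).

    Returns slope (ms/g), intercept (ms), and R^2.  Linearity in weight is
    an empirical description; deviations from it (R^2 < 1) are expected
    when the underlying dependence is the fast-exchange rate law.
    """
    if which not in ("T1", "T2"):
        raise ParameterError("which must be 'T1' or 'T2'")
    x = series.sample_weight
    y = series.T1 if which == "T1" else series.T2
    if np.allclose(x, x[0]):
        raise ParameterError("degenerate weights: all stages have the same weight")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "slope_err": float(res.stderr),
    }


def fit_fast_exchange(
    series: HydrationSeries,
    dry_weight: float,
    bulk_time: float = DEFAULT_BULK_TIME_S,
    which: str = "T2",
) -> dict:
    """Fit the fast-exchange surface term from a drying series.

    Regresses ``1/T_i - 1/T_bulk`` (1/s) on the inverse free-water measure
    ``1/(weight - dry_weight)`` (1/g); the slope is the surface term
    (proportional to S/V * rho_i).  Stages at or below the dry weight have
    no free water and are rejected.
    """
    if which not in ("T1", "T2"):
        raise ParameterError("which must be 'T1' or 'T2'")
    if bulk_time <= 0:
        raise ParameterError("bulk_time must be > 0")
    free = series.sample_weight - dry_weight
    if np.any(free <= 0):
        raise ParameterError(
            "all stages must lie above the dry weight (free water measure > 0)"
        )
    T_s = (series.T1 if which == "T1" else series.T2) / 1000.0  # s
    y = 1.0 / T_s - 1.0 / bulk_time
    x = 1.0 / free
    if np.allclose(x, x[0]):
        raise ParameterError("degenerate weights: all stages have the same weight")
    res = stats.linregress(x, y)
    return {
        "surface_term": float(res.slope),  # (1/s) * g
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "surface_term_err": float(res.stderr),
    }


def _trend(values: np.ndarray, flat_cv: float = 0.2, tie_tol: float = 0.02) -> str:
    """Classify a stage series: flat when the coefficient of variation is
    below ``flat_cv``; otherwise monotone up/down with a ``tie_tol``-of-span
    slack for near-ties."""
    v = np.asarray(values, dtype=float)
    mean = np.abs(v).mean()
    if mean == 0 or np.std(v) / mean < flat_cv:
        return "flat"
    d = np.diff(v)
    slack = tie_tol * (v.max() - v.min())
    if np.all(d <= slack) and np.any(d < -slack):
        return "decreasing"
    if np.all(d >= -slack) and np.any(d > slack):
        return "increasing"
    return "non-monotone"


def drying_summary(table: pd.DataFrame) -> dict:
    """Trend report over a drying table of per-stage peak values.

    Expects columns ``sample``, ``weight_g``, ``T1_main_ms``, ``T2_main_ms``,
    ``I_main``, ``T1_sec_ms``, ``T2_sec_ms``, ``I_sec`` (a Table-2-like
    layout).  Returns per-column monotonicity flags and the stage values;
    in a drying series the main-peak T1 and T2 decrease with weight loss
    while the secondary-peak T2 stays flat at a few tens of microseconds.
    """
    required = [
        "sample", "weight_g", "T1_main_ms", "T2_main_ms", "I_main",
        "T1_sec_ms", "T2_sec_ms", "I_sec",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParameterError(f"missing columns: {missing}")
    if len(table) < 2:
        raise ParameterError("need at least 2 stages for a trend report")
    trends = {
        col: _trend(table[col].to_numpy())
        for col in required[1:]
    }
    sec_frac = table["I_sec"].to_numpy() / (
        table["I_main"].to_numpy() + table["I_sec"].to_numpy()
    )
    return {
        "stages": list(table["sample"]),
        "trends": trends,
        "secondary_fraction": sec_frac.tolist(),
        "secondary_fraction_trend": _trend(sec_frac),
    }
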