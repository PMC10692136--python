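"""Factorial detrend × deseason preprocessing and the unit-range scaler.

Detrending options: ``none``, ``linear`` (OLS residuals on time), ``loess``
(residuals of a local linear regression, span 0.5) and ``gaussian``
(residuals of a Gaussian-kernel weighted moving average).  Deseasoning
options for monthly series: ``none``, ``average`` (subtract the calendar-month
mean), ``decompose`` (subtract the classical additive seasonal component) and
``stl`` (subtract the STL seasonal component).  Yearly series admit no
deseasoning, so the factorial grid has 4×4 = 16 monthly combinations and
4 yearly ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.tsa.seasonal import STL, seasonal_decompose

__all__ = [
    "DETREND_METHODS",
    "DESEASON_METHODS",
    "PreprocessSpec",
    "ScaledSeries",
    "detrend",
    "deseason",
    "apply_pipeline",
    "scale_unit_range",
    "factorial_grid",
    "OPTIMAL_SPECS",
    "load_spec_config",
]

DETREND_METHODS = ("none", "linear", "loess", "gaussian")
DESEASON_METHODS = ("none", "average", "decompose", "stl")

MIN_POINTS_DETREND = 8
MIN_POINTS_DESEASON = 24


@dataclass(frozen=True)
class PreprocessSpec:
    """One cell of the factorial preprocessing grid."""

    detrend: str = "none"
    deseason: str = "none"
    loess_span: float = 0.5
    gaussian_bandwidth: float | str = "silverman"
    order: str = "detrend_first"

    def __post_init__(self):
        if self.detrend not in DETREND_METHODS:
            raise ValueError(f"unknown detrend method {self.detrend!r}")
        if self.deseason not in DESEASON_METHODS:
            raise ValueError(f"unknown deseason method {self.deseason!r}")
        if self.order not in ("detrend_first", "deseason_first"):
            raise ValueError("order must be detrend_first or deseason_first")

    @property
    def label(self) -> str:
        return f"{self.detrend}+{self.deseason}"


def factorial_grid(resolution: str = "monthly") -> list[PreprocessSpec]:
    """All detrend × deseason combinations valid for the resolution."""
    if resolution == "monthly":
        return [
            PreprocessSpec(d, s) for d, s in product(DETREND_METHODS, DESEASON_METHODS)
        ]
    return [PreprocessSpec(d, "none") for d in DETREND_METHODS]


#: preprocessing combinations that maximised warning skill per EWS method
#: class in the cross-method comparison; yearly series admit no deseasoning
OPTIMAL_SPECS: dict[str, dict[str, PreprocessSpec]] = {
    "monthly": {
        "uni_rolling": PreprocessSpec("linear", "stl"),
        "uni_expanding": PreprocessSpec("linear", "decompose"),
        "multi_rolling": PreprocessSpec("gaussian", "none"),
        "multi_expanding": PreprocessSpec("gaussian", "average"),
        "ml": PreprocessSpec("gaussian", "none"),
    },
    "yearly": {
        "uni_rolling": PreprocessSpec("linear", "none"),
        "uni_expanding": PreprocessSpec("linear", "none"),
        "multi_rolling": PreprocessSpec("gaussian", "none"),
        "multi_expanding": PreprocessSpec("gaussian", "none"),
        "ml": PreprocessSpec("gaussian", "none"),
    },
}


def load_spec_config(path) -> dict[str, PreprocessSpec]:
    """Read a YAML mapping of EWS method name to {detrend, deseason, ...}."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {name: PreprocessSpec(**(fields or {})) for name, fields in raw.items()}


def _silverman_bandwidth(t: np.ndarray) -> float:
    n = len(t)
    sd = np.std(t, ddof=1)
    return 0.9 * sd * n ** (-0.2)


def detrend(series: pd.Series, method: str = "linear", *, loess_span: float = 0.5,
            gaussian_bandwidth: float | str = "silverman") -> pd.Series:
    """Remove the long-term trend, returning the residual series.

    Missing values are excluded from the trend fit and stay missing in the
    output.  The time axis is the positional index (equally spaced sampling).
    """
    if method not in DETREND_METHODS:
        raise ValueError(f"unknown detrend method {method!r}")
    if method == "none":
        return series.copy()
    y = series.to_numpy(dtype=float)
    t = np.arange(len(y), dtype=float)
    ok = np.isfinite(y)
    if ok.sum() == 0:
        raise ValueError("series is all-missing")
    if ok.sum() < MIN_POINTS_DETREND:
        raise ValueError(
            f"need >= {MIN_POINTS_DETREND} finite points, got {int(ok.sum())}"
        )
    out = np.full_like(y, np.nan)
    if method == "linear":
        slope, intercept = np.polyfit(t[ok], y[ok], 1)
        out[ok] = y[ok] - (slope * t[ok] + intercept)
    elif method == "loess":
        trend = lowess(y[ok], t[ok], frac=loess_span, return_sorted=False)
        out[ok] = y[ok] - trend
    else:  # gaussian
        bw = (
            _silverman_bandwidth(t[ok])
            if gaussian_bandwidth == "silverman"
            else float(gaussian_bandwidth)
        )
        bw = max(bw, 1e-12)
        diff = (t[ok][:, None] - t[ok][None, :]) / bw
        W = np.exp(-0.5 * diff**2)
        trend = (W @ y[ok]) / W.sum(axis=1)
        out[ok] = y[ok] - trend
    return pd.Series(out, index=series.index, name=series.name)


def _month_numbers(series: pd.Series) -> np.ndarray:
    idx = series.index
    if hasattr(idx, "month"):
        return np.asarray(idx.month)
    return (np.arange(len(series)) % 12) + 1


def deseason(series: pd.Series, method: str = "average") -> pd.Series:
    """Remove the annual cycle from a monthly series.

    ``average`` subtracts the mean of all observations sharing the calendar
    month; ``decompose`` subtracts the classical additive seasonal component
    (centred moving-average trend, month-mean seasonal); ``stl`` subtracts the
    loess-estimated seasonal component (periodic seasonal window).
    """
    if method not in DESEASON_METHODS:
        raise ValueError(f"unknown deseason method {method!r}")
    if method == "none":
        return series.copy()
    if len(series) < MIN_POINTS_DESEASON:
        raise ValueError(
            f"deseasoning needs >= {MIN_POINTS_DESEASON} monthly points, "
            f"got {len(series)}"
        )
    y = series.to_numpy(dtype=float)
    months = _month_numbers(series)
    if method == "average":
        out = y.copy()
        for m in range(1, 13):
            sel = months == m
            if sel.any():
                out[sel] = y[sel] - np.nanmean(y[sel])
        return pd.Series(out, index=series.index, name=series.name)
    filled = pd.Series(y).interpolate(limit_direction="both").to_numpy()
    if method == "decompose":
        seasonal = seasonal_decompose(filled, period=12, model="additive").seasonal
    else:  # stl
        seasonal = STL(filled, period=12, seasonal=13, robust=False).fit().seasonal
    out = y - np.asarray(seasonal)
    return pd.Series(out, index=series.index, name=series.name)


def apply_pipeline(matrix: pd.DataFrame, spec: PreprocessSpec) -> pd.DataFrame:
    """Apply the spec's detrend and deseason to every genus column.

    The spec is recorded in ``result.attrs["preprocess"]``.  Deseasoning a
    yearly matrix (no month structure) is a resolution error.
    """
    idx = matrix.index
    monthly = hasattr(idx, "month") or (
        hasattr(idx, "freqstr") and str(getattr(idx, "freqstr", "")).startswith("M")
    )
    if spec.deseason != "none" and not monthly:
        raise ValueError(
            f"deseason={spec.deseason!r} requires a monthly index; "
            "yearly series admit no deseasoning"
        )

    def _one(col: pd.Series) -> pd.Series:
        steps = (
            ("detrend", "deseason")
            if spec.order == "detrend_first"
            else ("deseason", "detrend")
        )
        for step in steps:
            if step == "detrend":
                col = detrend(
                    col,
                    spec.detrend,
                    loess_span=spec.loess_span,
                    gaussian_bandwidth=spec.gaussian_bandwidth,
                )
            else:
                col = deseason(col, spec.deseason)
        return col

    out = matrix.apply(_one, axis=0)
    out.attrs["preprocess"] = spec
    return out


@dataclass
class ScaledSeries:
    """A series normalised into [1, 2]: s = 1 + (x − x_min)/(x_max − x_min)."""

    s: np.ndarray
    x_min: float
    x_max: float
    x: np.ndarray = field(repr=False, default=None)


def scale_unit_range(series) -> ScaledSeries:
    """Scale a non-constant series into the range [1, 2]."""
    x = np.asarray(series, dtype=float)
    finite = x[np.isfinite(x)]
    if len(finite) == 0:
        raise ValueError("cannot scale an all-missing series")
    x_min, x_max = float(finite.min()), float(finite.max())
    if x_max == x_min:
        raise ValueError("unit-range scaling undefined for a constant series")
    return ScaledSeries(s=1.0 + (x - x_min) / (x_max - x_min), x_min=x_min,
                        x_max=x_max, x=x)
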