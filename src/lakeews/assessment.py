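"""Rolling- and expanding-window assessment engines and binary warning rules.

Rolling windows of half the series length slide along the series; the Kendall
tau of indicator value against window index is the statistic of interest, and
a warning fires when the observed tau is positive and at or above the 95th
percentile of taus from time-permuted surrogates.  Expanding windows
recompute the indicator on all data up to t, standardise it against its own
running mean and standard deviation,

    EWS_t = (ews_t − mean(ews_{1:t})) / sd(ews_{1:t}),

and warn when the standardized value exceeds 2σ at two or more time points
after a burn-in of half the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import kendalltau

from lakeews import indicators as ind

__all__ = [
    "AssessmentConfig",
    "RollingTrace",
    "ExpandingTrace",
    "rolling_assessment",
    "trend_tau",
    "permutation_warning",
    "expanding_assessment",
    "exceedance_warning",
    "assess_series",
    "assess_community",
]


@dataclass(frozen=True)
class AssessmentConfig:
    window_fraction: float = 0.5
    burn_in_fraction: float = 0.5
    threshold_sigma: float = 2.0
    min_exceedances: int = 2
    n_permutations: int = 1000
    permutation_quantile: float = 0.95
    consecutive: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.window_fraction < 1:
            raise ValueError("window_fraction must be in (0,1)")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in (0,1)")
        if self.threshold_sigma <= 0:
            raise ValueError("threshold_sigma must be positive")
        if self.min_exceedances < 1:
            raise ValueError("min_exceedances must be >= 1")


def _window_length(T: int, fraction: float) -> int:
    return int(np.floor(fraction * T + 0.5))  # round half up


def _as_array(data) -> np.ndarray:
    if isinstance(data, (pd.Series, pd.DataFrame)):
        return data.to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def _rolling_values_fast(x: np.ndarray, wlen: int, name: str) -> np.ndarray:
    """Vectorized rolling ar1/SD/skew for a clean univariate series."""
    W = sliding_window_view(x, wlen)
    if name == "SD":
        return W.std(axis=1, ddof=1)
    if name == "ar1":
        a, b = W[:, :-1], W[:, 1:]
        am = a.mean(axis=1, keepdims=True)
        bm = b.mean(axis=1, keepdims=True)
        cov = ((a - am) * (b - bm)).mean(axis=1)
        sa, sb = a.std(axis=1), b.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = cov / (sa * sb)
        out[(sa == 0) | (sb == 0)] = np.nan
        return out
    if name == "skew":
        n = wlen
        m = W.mean(axis=1, keepdims=True)
        d = W - m
        m2 = (d**2).mean(axis=1)
        m3 = (d**3).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            g1 = m3 / m2**1.5
        g1[m2 == 0] = np.nan
        return g1 * np.sqrt(n * (n - 1)) / (n - 2)
    raise KeyError(name)


def _rolling_values(data: np.ndarray, wlen: int, indicator: str) -> np.ndarray:
    if data.ndim == 1 and indicator in ("ar1", "SD", "skew") and np.isfinite(
        data
    ).all():
        return _rolling_values_fast(data, wlen, indicator)
    n_win = data.shape[0] - wlen + 1
    out = np.empty(n_win)
    for i in range(n_win):
        window = data[i : i + wlen]
        if data.ndim == 1:
            w = window[np.isfinite(window)]
            out[i] = (
                ind.univariate_indicator(w, indicator) if len(w) >= 4 else np.nan
            )
        else:
            out[i] = ind.multivariate_indicator(window, indicator)
    return out


@dataclass
class RollingTrace:
    window_ends: np.ndarray
    values: np.ndarray
    tau: float
    window_length: int
    warning: bool | None = None
    null_taus: np.ndarray | None = field(repr=False, default=None)


def rolling_assessment(data, indicator: str, config: AssessmentConfig) -> RollingTrace:
    """Indicator on every contiguous window of round(fraction·T) points.

    Returns the per-window values and the Kendall tau of value against window
    index (NaN when undefined, e.g. a constant indicator).
    """
    arr = _as_array(data)
    T = arr.shape[0]
    wlen = _window_length(T, config.window_fraction)
    if wlen < 4:
        raise ValueError(
            f"series too short: window of {wlen} < 4 points "
            f"(need T >= {int(np.ceil(4 / config.window_fraction))})"
        )
    values = _rolling_values(arr, wlen, indicator)
    ends = np.arange(wlen - 1, T)
    tau = trend_tau(values, np.arange(len(values)))
    return RollingTrace(
        window_ends=ends, values=values, tau=tau, window_length=wlen
    )


def trend_tau(values, times) -> float:
    """Tie-corrected Kendall tau-b between indicator values and time."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    if ok.sum() < 3:
        return np.nan
    if np.all(v[ok] == v[ok][0]):
        return np.nan
    tau = kendalltau(t[ok], v[ok]).statistic
    return float(tau) if np.isfinite(tau) else np.nan


def permutation_warning(
    data, indicator: str, config: AssessmentConfig
) -> tuple[bool, RollingTrace]:
    """Rolling-window warning from a permutation surrogate test.

    The series (all genus columns together, preserving the cross-sectional
    structure) is time-shuffled ``n_permutations`` times, the rolling tau is
    recomputed for each surrogate, and a warning fires iff the observed tau is
    positive and at or above the ``permutation_quantile`` of the null taus.
    """
    arr = _as_array(data)
    trace = rolling_assessment(arr, indicator, config)
    rng = np.random.default_rng(config.seed)
    T = arr.shape[0]
    null = np.empty(config.n_permutations)
    wlen = trace.window_length
    for b in range(config.n_permutations):
        perm = rng.permutation(T)
        values = _rolling_values(arr[perm], wlen, indicator)
        null[b] = trend_tau(values, np.arange(len(values)))
    finite_null = null[np.isfinite(null)]
    if np.isnan(trace.tau) or len(finite_null) == 0:
        warning = False
    else:
        crit = float(np.quantile(finite_null, config.permutation_quantile))
        warning = bool(trace.tau > 0 and trace.tau >= crit)
    trace = replace(trace, warning=warning, null_taus=null)
    return warning, trace


@dataclass
class ExpandingTrace:
    times: np.ndarray  # 1-based time positions
    raw: np.ndarray  # indicator on data[1:t]; NaN before computable
    standardized: np.ndarray  # Eq-style running standardization; NaN pre burn-in
    exceedances: np.ndarray  # standardized > threshold_sigma
    burn_in_end: int  # last 1-based position inside the burn-in


def expanding_assessment(
    data, indicator: str | list[str], config: AssessmentConfig
) -> ExpandingTrace:
    """Expanding-window indicator with running standardization.

    For a composite (list of members or a registered composite name), each
    member's raw sequence is standardized separately and the standardized
    values are summed per time point.
    """
    arr = _as_array(data)
    T = arr.shape[0]
    burn_end = int(np.floor(config.burn_in_fraction * T))
    if T - burn_end < 2 or burn_end < 4:
        raise ValueError(f"series too short for expanding assessment (T={T})")

    if isinstance(indicator, str) and indicator in ind.COMPOSITE_MEMBERS:
        members = list(ind.COMPOSITE_MEMBERS[indicator])
    elif isinstance(indicator, (list, tuple)):
        members = list(indicator)
    else:
        members = [indicator]

    min_rows = 4 if arr.ndim == 1 else max(4, arr.shape[1] + 2)
    std_members = []
    raw_members = []
    for name in members:
        raw = np.full(T, np.nan)
        for t in range(min_rows - 1, T):
            window = arr[: t + 1]
            if arr.ndim == 1:
                w = window[np.isfinite(window)]
                if len(w) >= 4:
                    raw[t] = ind.univariate_indicator(w, name)
            else:
                raw[t] = ind.multivariate_indicator(window, name)
        std = _running_standardize(raw)
        raw_members.append(raw)
        std_members.append(std)

    if len(members) == 1:
        standardized = std_members[0]
        raw_out = raw_members[0]
    else:
        stacked = np.vstack(std_members)
        standardized = np.where(
            np.isfinite(stacked).all(axis=0), stacked.sum(axis=0), np.nan
        )
        raw_out = np.vstack(raw_members).sum(axis=0)

    # warnings are only evaluated past the burn-in
    masked = standardized.copy()
    masked[:burn_end] = np.nan
    exceed = np.zeros(T, dtype=bool)
    finite = np.isfinite(masked)
    exceed[finite] = masked[finite] > config.threshold_sigma
    return ExpandingTrace(
        times=np.arange(1, T + 1),
        raw=raw_out,
        standardized=masked,
        exceedances=exceed,
        burn_in_end=burn_end,
    )


def _running_standardize(raw: np.ndarray) -> np.ndarray:
    """(ews_t − mean(ews_{1:t})) / sd(ews_{1:t}) over the defined prefix."""
    out = np.full_like(raw, np.nan)
    defined = np.where(np.isfinite(raw))[0]
    for j, t in enumerate(defined):
        hist = raw[defined[: j + 1]]
        if len(hist) < 2:
            continue
        s = np.std(hist, ddof=1)
        if s == 0:
            continue
        out[t] = (raw[t] - hist.mean()) / s
    return out


def exceedance_warning(trace: ExpandingTrace, config: AssessmentConfig) -> bool:
    """Two-or-more exceedances of the 2σ threshold after burn-in.

    With ``config.consecutive`` the exceedances must form a run of at least
    ``min_exceedances`` consecutive time points.
    """
    flags = trace.exceedances
    if not config.consecutive:
        return bool(flags.sum() >= config.min_exceedances)
    run = best = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return bool(best >= config.min_exceedances)


# ---------------------------------------------------------------------------
# tidy per-community assessment


def assess_series(series, indicator, method: str, config: AssessmentConfig) -> bool:
    """One binary warning for one series × indicator × computation method."""
    if method == "rolling":
        warning, _ = permutation_warning(series, indicator, config)
        return warning
    if method == "expanding":
        trace = expanding_assessment(series, indicator, config)
        return exceedance_warning(trace, config)
    raise ValueError(f"unknown method {method!r}")


def assess_community(
    matrix: pd.DataFrame,
    lake: str,
    trophic_level: str,
    resolution: str,
    config: AssessmentConfig,
    uni_indicators=("ar1", "SD", "skew"),
    multi_indicators=("meanAR", "pcaSD", "eigenMAF"),
    composites=("ar1+SD",),
    preprocess_label: str = "none+none",
) -> pd.DataFrame:
    """Tidy warnings table for one lake × trophic level community matrix.

    Univariate methods contribute one warning per genus series; multivariate
    methods concatenate the community into a single assessment per indicator.
    """
    rows = []

    def add(method, indicator, series_name, warning):
        rows.append(
            {
                "lake": lake,
                "trophic_level": trophic_level,
                "series": series_name,
                "resolution": resolution,
                "preprocess": preprocess_label,
                "method": method,
                "indicator": indicator,
                "warning": int(warning),
            }
        )

    for col in matrix.columns:
        series = matrix[col].to_numpy(dtype=float)
        if np.nanstd(series) == 0:
            continue
        for name in uni_indicators:
            add("uni_rolling", name, col, assess_series(series, name, "rolling", config))
            add(
                "uni_expanding",
                name,
                col,
                assess_series(series, name, "expanding", config),
            )
        for name in composites:
            trace = expanding_assessment(series, name, config)
            add("uni_expanding", name, col, exceedance_warning(trace, config))

    import warnings as _warnings

    X = matrix.to_numpy(dtype=float)
    if X.shape[1] >= 2:
        for name in multi_indicators:
            try:
                add(
                    "multi_rolling",
                    name,
                    "community",
                    assess_series(X, name, "rolling", config),
                )
                trace = expanding_assessment(X, name, config)
                add(
                    "multi_expanding", name, "community",
                    exceedance_warning(trace, config),
                )
            except ValueError as err:  # e.g. window shorter than p+2 columns
                _warnings.warn(f"skipping {name}: {err}")
    return pd.DataFrame(rows)
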