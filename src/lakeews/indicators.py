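"""Registry of univariate and multivariate early-warning indicators.

Univariate indicators quantify critical slowing down in a single series:
lag-1 autocorrelation (``ar1``), standard deviation (``SD``) and skewness
(``skew``).  Composites (``ar1+SD`` etc.) sum standardized member values and
exist only for expanding-window assessment.  Multivariate indicators pool a
community matrix, either by summarising per-column univariate statistics
(``meanAR``, ``maxSD``, ...) or through a dimension reduction: principal
components (``pcaAR``, ``pcaSD``), the covariance spectrum (``eigenCOV``,
``maxCOV``), maximum-autocorrelation factors (``eigenMAF``, ``mafAR``,
``mafSD``) and mean pairwise mutual information (``mutINFO``).

MAF convention: the generalized eigenproblem Σ_Δ w = λ Σ w (difference
covariance against raw covariance); the smallest eigenvalue λ corresponds to
the smoothest, most autocorrelated factor (lag-1 autocorrelation ≈ 1 − λ/2),
so ``eigenMAF`` reports the smallest generalized eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import eigh

__all__ = [
    "IndicatorDef",
    "REGISTRY",
    "UNIVARIATE",
    "COMPOSITES",
    "MULTIVARIATE",
    "univariate_indicator",
    "multivariate_indicator",
    "maf_decomposition",
    "composite_sum",
    "get_indicator",
]


@dataclass(frozen=True)
class IndicatorDef:
    name: str
    arity: str  # "univariate" | "multivariate"
    computable_by: tuple[str, ...]  # subset of ("rolling", "expanding")
    members: tuple[str, ...] = ()  # for composites


def ar1(x: np.ndarray) -> float:
    """Lag-1 autocorrelation as the Pearson correlation of (x_t, x_{t+1})."""
    x = np.asarray(x, dtype=float)
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def sd(x: np.ndarray) -> float:
    """Sample standard deviation (n−1 denominator)."""
    return float(np.std(x, ddof=1))


def skewness(x: np.ndarray) -> float:
    """Bias-corrected sample skewness g1; NaN for zero variance."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return np.nan
    return float(stats.skew(x, bias=False))


_UNI_FUNCS = {"ar1": ar1, "SD": sd, "skew": skewness}


def univariate_indicator(window, name: str) -> float:
    """Evaluate a univariate indicator on one data window (length >= 4)."""
    if name not in _UNI_FUNCS:
        raise KeyError(f"unknown univariate indicator {name!r}")
    w = np.asarray(window, dtype=float)
    if len(w) < 4:
        raise ValueError(f"window too short for {name}: {len(w)} < 4")
    return _UNI_FUNCS[name](w)


def maf_decomposition(window: np.ndarray):
    """Maximum-autocorrelation-factor decomposition of a T×p window.

    Solves Σ_Δ w = λ Σ w with Σ the column covariance and Σ_Δ the covariance
    of first differences.  Eigenvalues are returned ascending (the smallest
    belongs to the maximum-autocorrelation factor); weight vectors are
    Σ-orthonormal.  A singular Σ triggers one ridge-regularized retry
    (ε = 1e−8 on the diagonal) with a warning.
    """
    X = np.asarray(window, dtype=float)
    T, p = X.shape
    if T < p + 2:
        raise ValueError(f"need T >= p + 2 rows (T={T}, p={p})")
    S = np.cov(X, rowvar=False).reshape(p, p)
    Sd = np.cov(np.diff(X, axis=0), rowvar=False).reshape(p, p)
    try:
        vals, vecs = eigh(Sd, S)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in MAF; retrying with ridge 1e-8")
        ridge = 1e-8 * np.eye(p) * max(np.trace(S) / p, 1.0)
        try:
            vals, vecs = eigh(Sd, S + ridge)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance matrix singular even after ridge regularization"
            ) from err
    return vals, vecs


def _pc1_scores(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return U[:, 0] * s[0]


def _maf1_scores(X: np.ndarray) -> np.ndarray:
    _, vecs = maf_decomposition(X)
    Xc = X - X.mean(axis=0)
    return Xc @ vecs[:, 0]


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Histogram mutual information in nats, Miller–Madow bias corrected.

    Equal-width 2-D histogram with ⌈T^(1/3)⌉ bins per axis (keeps the joint
    histogram well populated); the positive plug-in bias ≈ (Bx−1)(By−1)/(2T)
    is subtracted and the result floored at 0, so independent series score
    ≈ 0.
    """
    bins = max(int(np.ceil(len(a) ** (1 / 3))), 2)
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    bx = int((px > 0).sum())
    by = int((py > 0).sum())
    return max(mi - (bx - 1) * (by - 1) / (2 * len(a)), 0.0)


def _per_column(X, func):
    return np.array([func(X[:, j]) for j in range(X.shape[1])])


_MULTI_FUNCS = {
    "meanAR": lambda X: float(np.nanmean(_per_column(X, ar1))),
    "maxAR": lambda X: float(np.nanmax(_per_column(X, ar1))),
    "meanSD": lambda X: float(np.mean(_per_column(X, sd))),
    "maxSD": lambda X: float(np.max(_per_column(X, sd))),
    "eigenCOV": lambda X: float(
        np.linalg.eigvalsh(np.cov(X, rowvar=False).reshape(X.shape[1], -1))[-1]
    ),
    "maxCOV": lambda X: _max_offdiag_cov(X),
    "pcaAR": lambda X: ar1(_pc1_scores(X)),
    "pcaSD": lambda X: sd(_pc1_scores(X)),
    "pcaVE": lambda X: _pca_variance_explained(X),
    "eigenMAF": lambda X: float(maf_decomposition(X)[0][0]),
    "mafAR": lambda X: ar1(_maf1_scores(X)),
    "mafSD": lambda X: sd(_maf1_scores(X)),
    "mutINFO": lambda X: _mean_pairwise_mi(X),
}


def _max_offdiag_cov(X):
    C = np.cov(X, rowvar=False).reshape(X.shape[1], -1)
    mask = ~np.eye(C.shape[0], dtype=bool)
    return float(C[mask].max())


def _pca_variance_explained(X):
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    return float(s[0] ** 2 / np.sum(s**2))


def _mean_pairwise_mi(X):
    p = X.shape[1]
    vals = [
        _mutual_information(X[:, i], X[:, j])
        for i in range(p)
        for j in range(i + 1, p)
    ]
    return float(np.mean(vals))


_PAIRWISE = {"maxCOV", "mutINFO"}


def multivariate_indicator(window, name: str) -> float:
    """Evaluate a multivariate indicator on a T×p window matrix."""
    if name not in _MULTI_FUNCS:
        raise KeyError(f"unknown multivariate indicator {name!r}")
    X = np.asarray(window, dtype=float)
    if X.ndim != 2:
        raise ValueError("multivariate indicators need a 2-D window")
    if X.shape[1] < 2 and name in _PAIRWISE:
        raise ValueError(f"{name} needs at least 2 columns")
    if X.shape[0] < 4:
        raise ValueError("window too short (need >= 4 rows)")
    return _MULTI_FUNCS[name](X)


def composite_sum(standardized_values) -> float:
    """Sum of member indicators' standardized values at one time point.

    Any missing member makes the composite missing.
    """
    v = np.asarray(standardized_values, dtype=float)
    if np.any(~np.isfinite(v)):
        return np.nan
    return float(v.sum())


COMPOSITE_MEMBERS = {
    "ar1+SD": ("ar1", "SD"),
    "ar1+skew": ("ar1", "skew"),
    "SD+skew": ("SD", "skew"),
    "ar1+SD+skew": ("ar1", "SD", "skew"),
}

UNIVARIATE = tuple(_UNI_FUNCS)
COMPOSITES = tuple(COMPOSITE_MEMBERS)
MULTIVARIATE = tuple(_MULTI_FUNCS)

REGISTRY: dict[str, IndicatorDef] = {}
for _name in UNIVARIATE:
    REGISTRY[_name] = IndicatorDef(_name, "univariate", ("rolling", "expanding"))
for _name, _members in COMPOSITE_MEMBERS.items():
    REGISTRY[_name] = IndicatorDef(_name, "univariate", ("expanding",), _members)
for _name in MULTIVARIATE:
    REGISTRY[_name] = IndicatorDef(_name, "multivariate", ("rolling", "expanding"))


def get_indicator(name: str) -> IndicatorDef:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown indicator {name!r}; available: {sorted(REGISTRY)}"
        ) from None


def evaluate(window, name: str) -> float:
    """Evaluate any non-composite registry indicator on a window."""
    d = get_indicator(name)
    if d.members:
        raise ValueError(f"{name} is a composite; use expanding assessment")
    if d.arity == "univariate":
        return univariate_indicator(window, name)
    return multivariate_indicator(window, name)
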