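"""Breakpoint pre-classification of lake fates via (threshold) penalized smooths.

A continuous penalized smooth (GAM) and a two-segment threshold smooth (TGAM)
are fitted to yearly total plankton density against time and against the
leading principal component of the abiotic drivers ("state space").  The
smoothing parameter is chosen by Gaussian REML, model choice (GAM vs TGAM,
and the breakpoint location) by generalized cross-validation
GCV = n·RSS/(n−edf)².  Basis dimension is capped at six knots for the
continuous smooth and three per segment of the threshold smooth; a threshold
model is only attempted when the continuous smooth's effective degrees of
freedom reach three (an approximately cubic shape that can contain a step).
Breaks are only permitted between adjacent time points, in the time-series
and the state-space model alike.

The fate decision combines (i) a breakpoint in time, (ii) a coherent
breakpoint in state space, (iii) bimodality of the density distribution
(bimodality coefficient > 0.5), and (iv) hysteresis — an overlap of the two
state-space segments' driver ranges on which their fitted confidence bands
are disjoint, i.e. two distinct states for a single stressor value.  Only a
series satisfying all four is labelled a critical transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from lakeews.standardise import LakeDataset

__all__ = [
    "InsufficientDataError",
    "SmoothFit",
    "ThresholdFit",
    "BimodalityResult",
    "StateSpaceSeries",
    "FateLabel",
    "fit_penalized_smooth",
    "fit_threshold_smooth",
    "select_smooth_model",
    "driver_principal_component",
    "bimodality_coefficient",
    "detect_hysteresis",
    "classify_fate",
    "classify_dataset",
    "trim_for_assessment",
]

EDF_GATE = 3.0  # continuous-smooth edf required before a threshold model is tried
MIN_SEGMENT = 4  # observations per threshold segment


class InsufficientDataError(ValueError):
    """Raised when a smooth is requested on too few observations."""


# ---------------------------------------------------------------------------
# penalized spline machinery


class TPSBasis:
    """Rank-reduced 1-D thin-plate regression spline basis of dimension k.

    The full thin-plate spline on all data points (radial basis |x−x_i|³,
    null space {1, x}, penalty δᵀEδ) is truncated to the k−2 leading
    eigenvectors of the radial matrix E, and the null-space constraint
    Tᵀδ = 0 is absorbed, yielding a k-dimensional penalized basis whose last
    two columns span the unpenalized linear part.  The covariate is rescaled
    to [0, 1] for conditioning.
    """

    def __init__(self, x: np.ndarray, k: int):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise InsufficientDataError("covariate has zero range")
        self.shift, self.scale = lo, hi - lo
        x0 = np.unique((np.asarray(x, dtype=float) - lo) / self.scale)
        if len(x0) < k:
            raise InsufficientDataError(
                f"need >= {k} distinct covariate values, got {len(x0)}"
            )
        self.knots = x0
        E = np.abs(x0[:, None] - x0[None, :]) ** 3
        vals, vecs = np.linalg.eigh(E)
        order = np.argsort(-np.abs(vals))[:k]
        U = vecs[:, order]
        D = vals[order]
        T = np.column_stack([np.ones_like(x0), x0])
        # absorb the null-space constraint Tᵀ U z = 0 (2 conditions)
        C = T.T @ U  # 2 × k
        _, _, Vt = np.linalg.svd(C, full_matrices=True)
        Z = Vt[2:].T  # k × (k−2)
        self.M = U @ Z  # maps reduced spline coefs to δ
        n_spline = Z.shape[1]
        self.k = n_spline + 2
        S_spline = Z.T @ (D[:, None] * Z)
        S_spline = (S_spline + S_spline.T) / 2
        # the r³ kernel is only conditionally positive definite; project the
        # constrained penalty onto its PSD part for numerical safety
        w, Q = np.linalg.eigh(S_spline)
        S_spline = (Q * np.maximum(w, 0.0)) @ Q.T
        S = np.zeros((self.k, self.k))
        S[:n_spline, :n_spline] = S_spline
        self.S = S

    def design(self, x) -> np.ndarray:
        x0 = (np.asarray(x, dtype=float) - self.shift) / self.scale
        E = np.abs(x0[:, None] - self.knots[None, :]) ** 3
        T = np.column_stack([np.ones_like(x0), x0])
        return np.column_stack([E @ self.M, T])


@dataclass
class SmoothFit:
    """A fitted penalized smooth of y on x."""

    x: np.ndarray
    y: np.ndarray
    basis: TPSBasis
    coef: np.ndarray
    lam: float
    edf: float  # smooth edf (model dof minus intercept)
    model_dof: float  # total effective parameters incl. intercept
    gcv: float
    rss: float
    fitted: np.ndarray
    se: np.ndarray
    scale: float  # residual variance estimate RSS/(n - model_dof)
    _cov: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.y)

    def predict(self, xnew, ci: bool = False):
        """Fitted values (and pointwise 95% CI half-width) at new covariates."""
        xnew = np.asarray(xnew, dtype=float)
        B = self.basis.design(xnew)
        mu = B @ self.coef
        if not ci:
            return mu
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, self._cov, B), 0.0))
        return mu, 1.96 * se

    def ci_band(self, xnew):
        mu, hw = self.predict(xnew, ci=True)
        return mu - hw, mu + hw


def _fit_at_lambda(y, B, S, lam, ridge):
    k = B.shape[1]
    A = B.T @ B + lam * S + ridge * np.eye(k)
    c, low = cho_factor(A)
    coef = cho_solve((c, low), B.T @ y)
    fitted = B @ coef
    rss = float(np.sum((y - fitted) ** 2))
    pen = float(lam * coef @ S @ coef)
    Ainv_S = cho_solve((c, low), S)
    model_dof = k - lam * float(np.trace(Ainv_S))
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    return coef, fitted, rss, pen, model_dof, logdet_A, (c, low)


def fit_penalized_smooth(
    y, x, max_knots: int = 6, min_n: int = 8
) -> SmoothFit:
    """Fit a penalized regression spline with REML-selected smoothing.

    ``max_knots`` caps the basis dimension (3–6).  Reports the smooth's
    effective degrees of freedom (excluding the intercept) and
    GCV = n·RSS/(n − model_dof)².
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < min_n:
        raise InsufficientDataError(f"need >= {min_n} observations, got {n}")
    if not 3 <= max_knots <= 6:
        raise ValueError("max_knots must be in 3..6")
    k = min(max_knots, n - 1, len(np.unique(x)))
    if k < 3:
        raise InsufficientDataError("need >= 3 distinct covariate values")
    basis = TPSBasis(x, k)
    B = basis.design(x)
    S = basis.S
    ridge = 1e-9 * float(np.trace(B.T @ B)) / k

    s_eig = np.linalg.eigvalsh(S)
    pos = s_eig[s_eig > 1e-10 * max(s_eig[-1], 1e-300)]
    r = len(pos)
    null_dim = k - r
    logdet_S_pos = float(np.sum(np.log(pos)))
    var_y = float(np.var(y)) + 1e-300

    def neg2_reml(log_lam):
        lam = np.exp(log_lam)
        _, _, rss, pen, _, logdet_A, _ = _fit_at_lambda(y, B, S, lam, ridge)
        phi = max((rss + pen) / max(n - null_dim, 1), 1e-12 * var_y)
        return (
            (n - null_dim) * (np.log(2 * np.pi * phi) + 1.0)
            + logdet_A
            - (r * log_lam + logdet_S_pos)
        )

    res = minimize_scalar(neg2_reml, bounds=(-12.0, 18.0), method="bounded")
    lam = float(np.exp(res.x))
    coef, fitted, rss, _, model_dof, _, cho = _fit_at_lambda(y, B, S, lam, ridge)
    scale = rss / max(n - model_dof, 1e-8)
    cov = cho_solve(cho, np.eye(k)) * scale
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, cov, B), 0.0))
    gcv = n * rss / (n - model_dof) ** 2
    return SmoothFit(
        x=x,
        y=y,
        basis=basis,
        coef=coef,
        lam=lam,
        edf=model_dof - 1.0,
        model_dof=model_dof,
        gcv=gcv,
        rss=rss,
        fitted=fitted,
        se=se,
        scale=scale,
        _cov=cov,
    )


@dataclass
class ThresholdFit:
    """Two penalized smooths joined at a breakpoint of the threshold variable."""

    breakpoint: float  # midpoint between two adjacent threshold values
    left: SmoothFit
    right: SmoothFit
    gcv: float
    n: int
    threshold_values: np.ndarray = field(repr=False, default=None)

    @property
    def model_dof(self) -> float:
        return self.left.model_dof + self.right.model_dof

    @property
    def rss(self) -> float:
        return self.left.rss + self.right.rss


def fit_threshold_smooth(
    y,
    x,
    threshold=None,
    gam: SmoothFit | None = None,
    gate_edf: float | None = None,
    max_knots: int = 3,
    min_segment: int = MIN_SEGMENT,
) -> ThresholdFit | None:
    """Exhaustive GCV search for a breakpoint splitting the series in two smooths.

    ``threshold`` is the variable the break is defined on (default: the smooth
    covariate ``x`` itself; for a state-space model pass the time axis, since
    breaks are only permitted between adjacent time points).  Candidates are
    midpoints between adjacent sorted threshold values with at least
    ``min_segment`` observations per side; each segment gets a ≤``max_knots``
    smooth of y on x.  Returns ``None`` when the continuous smooth's edf is
    below three (the gate) or when no candidate is feasible.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    thr = x if threshold is None else np.asarray(threshold, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x) & np.isfinite(thr)
    y, x, thr = y[ok], x[ok], thr[ok]
    n = len(y)
    if gam is None:
        gam = fit_penalized_smooth(y, x)
    if (gam.edf if gate_edf is None else gate_edf) < EDF_GATE:
        return None
    order = np.argsort(thr, kind="stable")
    ys, xs, ts = y[order], x[order], thr[order]

    best: ThresholdFit | None = None
    for i in range(min_segment - 1, n - min_segment):
        if ts[i + 1] <= ts[i]:  # no break within tied threshold values
            continue
        try:
            left = fit_penalized_smooth(
                ys[: i + 1], xs[: i + 1], max_knots=max_knots, min_n=min_segment
            )
            right = fit_penalized_smooth(
                ys[i + 1 :], xs[i + 1 :], max_knots=max_knots, min_n=min_segment
            )
        except InsufficientDataError:
            continue
        dof = left.model_dof + right.model_dof
        if n - dof <= 0:
            continue
        gcv = n * (left.rss + right.rss) / (n - dof) ** 2
        if best is None or gcv < best.gcv:  # strict: ties keep the earlier break
            best = ThresholdFit(
                breakpoint=float((ts[i] + ts[i + 1]) / 2),
                left=left,
                right=right,
                gcv=gcv,
                n=n,
                threshold_values=ts,
            )
    return best


def select_smooth_model(gam: SmoothFit, tgam: ThresholdFit | None):
    """GCV model choice; the continuous smooth wins exact ties (parsimony)."""
    if tgam is None or not np.isfinite(tgam.gcv):
        return gam
    return tgam if tgam.gcv < gam.gcv else gam


# ---------------------------------------------------------------------------
# state space, bimodality, hysteresis


@dataclass
class StateSpaceSeries:
    """PC1 of the standardized abiotic drivers, paired with yearly density."""

    scores: pd.Series  # PC1 per year
    loadings: pd.Series
    variance_explained: float
    dropped: tuple[str, ...] = ()


def driver_principal_component(drivers: pd.DataFrame) -> StateSpaceSeries:
    """First principal component of standardized drivers.

    Columns are z-scored before the PCA; constant columns are dropped with a
    warning.  Sign convention: the total-phosphorus loading is nonnegative
    (falling back to the first retained column when phosphorus is absent).
    """
    df = drivers.dropna()
    if len(df) < 3:
        raise InsufficientDataError("need >= 3 time points for the driver PCA")
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant driver column(s): {constant}")
        df = df.drop(columns=constant)
        sd = sd.drop(index=constant)
    if df.shape[1] == 0:
        raise ValueError("all driver columns constant")
    Z = (df - df.mean()) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = pd.Series(Vt[0], index=df.columns)
    anchor = "phosphorus" if "phosphorus" in loadings.index else loadings.index[0]
    if loadings[anchor] < 0:
        loadings = -loadings
        U = -U
    scores = pd.Series(U[:, 0] * s[0], index=df.index, name="PC1")
    ve = float(s[0] ** 2 / np.sum(s**2))
    return StateSpaceSeries(
        scores=scores,
        loadings=loadings,
        variance_explained=ve,
        dropped=tuple(constant),
    )


@dataclass(frozen=True)
class BimodalityResult:
    n: int
    skewness: float
    excess_kurtosis: float
    bc: float

    @property
    def is_bimodal(self) -> bool:
        return self.bc > 0.5


def bimodality_coefficient(values) -> BimodalityResult:
    """Sample bimodality coefficient BC = (g1²+1)/(g2 + 3(n−1)²/((n−2)(n−3))).

    Uses sample skewness g1 and sample excess kurtosis g2 (bias-corrected,
    SAS convention).  BC > 5/9 ≈ 0.556 is the value of a uniform distribution;
    BC > 0.5 is read as evidence of bimodality.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n < 4:
        raise ValueError(f"bimodality coefficient needs n >= 4, got {n}")
    if np.var(v) == 0:
        raise ValueError("bimodality coefficient undefined for zero variance")
    g1 = float(stats.skew(v, bias=False))
    g2 = float(stats.kurtosis(v, fisher=True, bias=False))
    bc = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return BimodalityResult(n=n, skewness=g1, excess_kurtosis=g2, bc=bc)


def detect_hysteresis(
    state_fit, n_eval: int = 100, min_overlap_frac: float = 0.1
) -> bool:
    """Dual states for a single stressor value.

    True iff the state-space model is a threshold fit whose two segments span
    overlapping driver (PC1) ranges, and somewhere on that shared interval the
    segments' pointwise 95% confidence bands are disjoint in the density
    dimension.  The overlap must cover at least ``min_overlap_frac`` of the
    combined driver range and contain at least two observations from each
    segment: a single-valued threshold response produces at most a
    noise-width, data-poor overlap at the segment boundary, which is not
    evidence of dual states.
    """
    if not isinstance(state_fit, ThresholdFit):
        return False
    lo = max(state_fit.left.x.min(), state_fit.right.x.min())
    hi = min(state_fit.left.x.max(), state_fit.right.x.max())
    full = max(state_fit.left.x.max(), state_fit.right.x.max()) - min(
        state_fit.left.x.min(), state_fit.right.x.min()
    )
    if hi <= lo or (full > 0 and (hi - lo) / full < min_overlap_frac):
        return False
    n_left = int(np.sum((state_fit.left.x >= lo) & (state_fit.left.x <= hi)))
    n_right = int(np.sum((state_fit.right.x >= lo) & (state_fit.right.x <= hi)))
    if min(n_left, n_right) < 2:
        return False
    grid = np.linspace(lo, hi, n_eval)
    l_lo, l_hi = state_fit.left.ci_band(grid)
    r_lo, r_hi = state_fit.right.ci_band(grid)
    disjoint = (l_hi < r_lo) | (r_hi < l_lo)
    return bool(disjoint.any())


# ---------------------------------------------------------------------------
# fate decision


@dataclass
class FateLabel:
    """Mechanism classification of one lake × trophic level."""

    mechanism: str  # critical_transition / abrupt_nonbifurcation /
    # nonlinear_continuous / no_shift
    transition_time: float | None
    evidence: dict

    @property
    def is_critical(self) -> bool:
        return self.mechanism == "critical_transition"


def _break_year(tgam: ThresholdFit) -> float:
    """First time point of the post-break regime (break at a midpoint)."""
    return float(np.ceil(tgam.breakpoint))


def classify_fate(
    time_model,
    state_model,
    bimodality: BimodalityResult,
    hysteresis: bool,
    coherence_tol_years: float = 2.0,
) -> FateLabel:
    """Decision tree combining breakpoints, bimodality and hysteresis.

    ``time_model`` and ``state_model`` are the GCV-selected models (a
    :class:`SmoothFit` or :class:`ThresholdFit`); the state-space threshold is
    defined on time, so breakpoint coherence is the distance in years between
    the two breakpoints.
    """
    time_break = isinstance(time_model, ThresholdFit)
    state_break = isinstance(state_model, ThresholdFit)
    t_b = _break_year(time_model) if time_break else None
    s_b = _break_year(state_model) if state_break else None
    coherent = (
        time_break and state_break and abs(time_model.breakpoint - state_model.breakpoint)
        <= coherence_tol_years
    )
    bimodal = bimodality.is_bimodal
    evidence = {
        "time_break": t_b,
        "state_break": s_b,
        "coherent": bool(coherent),
        "bc": bimodality.bc,
        "hysteresis": bool(hysteresis),
    }
    if time_break and coherent and bimodal and hysteresis:
        mech = "critical_transition"
    elif time_break and bimodal:
        mech = "abrupt_nonbifurcation"
    elif time_break:
        mech = "abrupt_nonbifurcation"
        evidence["note"] = "unimodal"
    else:
        smooth = time_model  # a SmoothFit when no break was selected
        mech = "nonlinear_continuous" if smooth.edf >= EDF_GATE else "no_shift"
    return FateLabel(
        mechanism=mech,
        transition_time=t_b if time_break else None,
        evidence=evidence,
    )


def classify_dataset(
    ds: LakeDataset, coherence_tol_years: float = 2.0
) -> FateLabel:
    """Full pre-classification of one yearly lake × trophic-level dataset.

    Fits the time-series and state-space (T)GAMs on yearly total density,
    computes the bimodality coefficient of the density distribution and the
    hysteresis criterion, and returns the fate label.
    """
    if ds.resolution != "yearly":
        raise ValueError("classification operates on yearly datasets")
    total = ds.total_density.dropna()
    years = np.asarray(total.index, dtype=float)
    dens = total.to_numpy(dtype=float)

    time_gam = fit_penalized_smooth(dens, years)
    time_tgam = fit_threshold_smooth(dens, years, gam=time_gam)
    time_model = select_smooth_model(time_gam, time_tgam)

    pca = driver_principal_component(ds.drivers.loc[total.index])
    pc1 = pca.scores.to_numpy(dtype=float)
    state_gam = fit_penalized_smooth(dens, pc1)
    # the step-shape gate is a property of the series, assessed on the time
    # smooth; a hysteresis loop is not a smooth function of the driver, so the
    # state-space continuous smooth's own edf would wrongly veto it
    state_tgam = fit_threshold_smooth(
        dens, pc1, threshold=years, gam=state_gam, gate_edf=time_gam.edf
    )
    state_model = select_smooth_model(state_gam, state_tgam)

    bim = bimodality_coefficient(dens)
    hyst = detect_hysteresis(state_model)
    fate = classify_fate(
        time_model, state_model, bim, hyst, coherence_tol_years=coherence_tol_years
    )
    fate.evidence.update(
        {
            "gcv_gam_time": time_gam.gcv,
            "gcv_tgam_time": None if time_tgam is None else time_tgam.gcv,
            "edf_time": time_gam.edf,
            "pc1_variance_explained": pca.variance_explained,
        }
    )
    return fate


@dataclass
class TrimResult:
    matrix: pd.DataFrame
    too_short: bool


def trim_for_assessment(
    matrix: pd.DataFrame,
    lake_fates: dict[str, FateLabel],
    no_shift_fraction: float = 0.85,
    min_length: int = 10,
) -> TrimResult:
    """Restrict a community matrix to the pre-transition assessment window.

    If any trophic level of the lake has a transition time, all series of the
    lake are truncated strictly before the earliest one; otherwise the first
    ``floor(0.85·T)`` points are kept.  A trimmed length below ``min_length``
    flags the result as too short (it is not dropped).
    """
    times = [
        f.transition_time for f in lake_fates.values() if f.transition_time is not None
    ]
    if times:
        cut = min(times)
        idx = matrix.index
        years = idx.year if hasattr(idx, "year") else np.asarray(idx, dtype=float)
        trimmed = matrix.loc[np.asarray(years) < cut]
    else:
        keep = int(np.floor(no_shift_fraction * len(matrix)))
        trimmed = matrix.iloc[:keep]
    too_short = len(trimmed) < min_length
    if too_short:
        warnings.warn(
            f"trimmed series has {len(trimmed)} points (< {min_length}); flagged"
        )
    return TrimResult(matrix=trimmed, too_short=too_short)
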