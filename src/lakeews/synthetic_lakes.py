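"""Labelled synthetic lake plankton communities.

Each generated lake follows one of six transition mechanisms for its latent
trophic-level biomass:

``fold_bifurcation``
    The grazing-type consumer model ``dX/dt = r·X(1−X/K) − c·X²/(X²+h²)``
    (May 1977) integrated by Euler–Maruyama with multiplicative noise, with
    the grazing pressure ``c`` following the driver schedule.  Ramping ``c``
    past the upper saddle-node collapses the population; relaxing ``c`` back
    into the bistable band leaves the system on the low branch, so hysteresis
    is present by construction.
``step_change``
    Fast equilibrium tracking of a driver with a discontinuous jump
    (an abrupt but non-bifurcation regime shift).
``noise_induced``
    A bistable potential under a constant driver with large noise; the shift
    is triggered by the noise, not the driver.
``threshold_like``
    A steep sigmoid steady-state response to a smoothly ramped driver; the
    state–driver relation is single valued (no hysteresis).
``smooth_trend``
    Monotone drift of the equilibrium (nonlinear-continuous change).
``stationary``
    An Ornstein–Uhlenbeck process around a fixed mean.

The latent trophic state is disaggregated into genus-level series with
autocorrelated Dirichlet shares, given a multiplicative seasonal cycle,
and observed through zero-inflated lognormal noise — emulating the structure
of long-term plankton monitoring data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MECHANISMS",
    "MechanismSpec",
    "FateTruth",
    "LatentTrajectory",
    "SyntheticLake",
    "IntegrationError",
    "grazing_equilibria",
    "grazing_folds",
    "simulate_mechanism",
    "generate_drivers",
    "disaggregate_to_genera",
    "sample_observations",
    "make_lake",
    "generate_benchmark_suite",
    "write_suite_csv",
]

MECHANISMS = (
    "fold_bifurcation",
    "step_change",
    "noise_induced",
    "threshold_like",
    "smooth_trend",
    "stationary",
)

#: mechanisms with no true shift time
_NO_SHIFT = {"smooth_trend", "stationary"}

# grazing-model defaults (May 1977 scaling)
GRAZING_R = 1.0
GRAZING_K = 10.0
GRAZING_H = 1.0

EULER_DT = 1.0 / 120.0  # years; 10 sub-steps per month


class IntegrationError(RuntimeError):
    """Raised when the stochastic integration produces a non-finite state."""


@dataclass(frozen=True)
class PiecewiseLinear:
    """Piecewise-linear control-parameter path over time (years)."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __call__(self, t):
        return np.interp(t, self.times, self.values)


def _default_schedule(mechanism: str, duration: float) -> PiecewiseLinear:
    T = float(duration)
    if mechanism == "fold_bifurcation":
        # ramp well past the upper fold (~2.604) and hold, so the collapse
        # completes despite the saddle-node ghost, then relax into the
        # bistable band (hysteresis: the state stays on the low branch)
        # slow approach toward the fold (critical slowing down develops),
        # then a fast, deep overshoot so the collapse completes within ~1-2
        # years, a short hold, and relaxation back into the bistable band
        return PiecewiseLinear(
            (0.0, 0.5 * T, 0.55 * T, 0.7 * T, T), (2.0, 2.5, 4.5, 4.5, 2.2)
        )
    if mechanism == "step_change":
        eps = 1.0 / 1200.0
        return PiecewiseLinear((0.0, T / 2, T / 2 + eps, T), (0.0, 0.0, 1.0, 1.0))
    if mechanism == "threshold_like":
        return PiecewiseLinear((0.0, T), (0.0, 1.0))
    if mechanism == "smooth_trend":
        return PiecewiseLinear((0.0, T), (0.0, 1.0))
    # noise_induced, stationary: constant driver
    return PiecewiseLinear((0.0, T), (0.0, 0.0))


# noise_induced needs large noise by construction; others default to modest
# multiplicative environmental noise
_DEFAULT_NOISE = {"noise_induced": 0.6}


@dataclass
class MechanismSpec:
    """Specification of one synthetic transition mechanism."""

    mechanism: str
    duration_years: int = 30
    noise_sd: float | None = None
    seed: int = 0
    driver_schedule: PiecewiseLinear | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.duration_years < 10:
            raise ValueError(
                "duration_years must be >= 10 (breakpoint models need "
                f"~10 yearly points); got {self.duration_years}"
            )
        if self.noise_sd is None:
            self.noise_sd = _DEFAULT_NOISE.get(self.mechanism, 0.05)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.driver_schedule is None:
            self.driver_schedule = _default_schedule(
                self.mechanism, self.duration_years
            )
        sched = np.asarray(
            self.driver_schedule(np.linspace(0, self.duration_years, 256))
        )
        if not np.all(np.isfinite(sched)):
            raise ValueError("driver_schedule must be finite on [0, duration]")


@dataclass(frozen=True)
class FateTruth:
    """Ground-truth label for a latent trajectory."""

    mechanism: str
    shift_time: float | None

    @property
    def is_critical(self) -> bool:
        return self.mechanism == "fold_bifurcation"


@dataclass
class LatentTrajectory:
    """Monthly latent trophic state with its forcing path and truth label."""

    time: np.ndarray  # years, monthly midpoints
    state: np.ndarray  # latent biomass, >= 0
    control: np.ndarray  # control-parameter value per month
    truth: FateTruth


def grazing_equilibria(c: float, r=GRAZING_R, K=GRAZING_K, h=GRAZING_H):
    """All nonnegative equilibria of the grazing model at grazing pressure c.

    Solves r(1−X/K)(X²+h²) − cX = 0 (cubic in X) and returns the real
    positive roots sorted ascending.
    """
    # expand: -r/K X^3 + r X^2 - (c + r h^2/K) X + r h^2 = 0
    coeffs = [-r / K, r, -(c + r * h * h / K), r * h * h]
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real
    return np.sort(real[real > 0])


def grazing_folds(r=GRAZING_R, K=GRAZING_K, h=GRAZING_H, n_grid: int = 20000):
    """Locate the two saddle-node (fold) values of c by numerical continuation.

    Scans the equilibrium curve c(X) = r(1−X/K)(X²+h²)/X for turning points
    and polishes each with a root find on dc/dX.  Returns (c_lower, c_upper).
    """

    def c_of_x(x):
        return r * (1 - x / K) * (x * x + h * h) / x

    def dc_dx(x):
        e = 1e-6
        return (c_of_x(x + e) - c_of_x(x - e)) / (2 * e)

    xs = np.linspace(0.05, K * 0.999, n_grid)
    d = dc_dx(xs)
    sign_change = np.where(np.diff(np.sign(d)) != 0)[0]
    folds = []
    for i in sign_change:
        x_star = brentq(dc_dx, xs[i], xs[i + 1])
        folds.append(c_of_x(x_star))
    folds = sorted(folds)
    if len(folds) != 2:
        raise RuntimeError("expected exactly two folds in the grazing model")
    return folds[0], folds[1]


def _monthly_grid(duration_years: int) -> np.ndarray:
    n = 12 * duration_years
    return (np.arange(n) + 0.5) / 12.0


def _integrate_sde(drift, x0, times, noise_sd, rng, multiplicative=True):
    """Euler–Maruyama from t=0, sampled at the monthly grid points."""
    x = float(x0)
    out = np.empty(len(times))
    prev_t = 0.0
    step = 0
    for i, ti in enumerate(times):
        n_sub = max(1, int(round((ti - prev_t) / EULER_DT)))
        dt = (ti - prev_t) / n_sub
        sqrt_dt = np.sqrt(dt)
        t = prev_t
        for _ in range(n_sub):
            amp = x if multiplicative else 1.0
            x = x + drift(x, t) * dt + noise_sd * amp * sqrt_dt * rng.standard_normal()
            x = max(x, 1e-12)
            t += dt
            step += 1
            if not np.isfinite(x):
                raise IntegrationError(
                    f"non-finite state at integration step {step} (t≈{t:.3f} yr)"
                )
        out[i] = x
        prev_t = ti
    return out


def _sustained_crossing(time, state, threshold, below=True, hold_months=6):
    """First time the state crosses a threshold and stays there."""
    flag = state < threshold if below else state > threshold
    for i in range(len(flag)):
        j = min(len(flag), i + hold_months)
        if flag[i] and flag[i:j].all():
            return float(time[i])
    return None


def simulate_mechanism(spec: MechanismSpec) -> LatentTrajectory:
    """Simulate the latent trophic-level state for one mechanism.

    Returns a monthly :class:`LatentTrajectory` whose truth tag equals the
    spec's mechanism.  ``shift_time`` is ``None`` exactly for the smooth-trend
    and stationary mechanisms.
    """
    times = _monthly_grid(spec.duration_years)
    rng = np.random.default_rng(spec.seed)
    sched = spec.driver_schedule
    control = np.asarray(sched(times), dtype=float)
    mech = spec.mechanism
    shift: float | None = None

    if mech == "fold_bifurcation":
        eq0 = grazing_equilibria(float(sched(0.0)))
        x0 = eq0[-1]  # upper branch

        def drift(x, t):
            c = sched(t)
            return (
                GRAZING_R * x * (1 - x / GRAZING_K)
                - c * x * x / (x * x + GRAZING_H**2)
            )

        state = _integrate_sde(drift, x0, times, spec.noise_sd, rng)
        shift = _sustained_crossing(times, state, 2.5, below=True)
        if shift is None:  # noise-free runs collapse when c crosses the fold
            _, c_up = grazing_folds()
            above = np.asarray(sched(times)) >= c_up
            shift = float(times[np.argmax(above)]) if above.any() else float(times[-1])

    elif mech == "step_change":
        theta = 12.0  # fast relaxation (1-month time scale)

        def mu(t):
            return 8.0 - 5.0 * sched(t)

        state = _integrate_sde(
            lambda x, t: theta * (mu(t) - x), mu(0.0), times, spec.noise_sd, rng
        )
        dv = np.asarray(sched(times))
        shift = float(times[np.argmax(dv > 0.5)])

    elif mech == "noise_induced":
        m1, m2, m3, a = 2.0, 5.0, 8.0, 0.1

        def drift(x, t):
            return -a * (x - m1) * (x - m2) * (x - m3)

        state = _integrate_sde(drift, m3, times, spec.noise_sd, rng)
        shift = _sustained_crossing(times, state, m2, below=True, hold_months=12)
        if shift is None:
            shift = float(times[int(np.argmax(np.abs(np.diff(state)))) + 1])

    elif mech == "threshold_like":
        theta, hi, lo, k = 12.0, 8.0, 1.0, 30.0

        def mu(t):
            return lo + (hi - lo) / (1 + np.exp(k * (sched(t) - 0.5)))

        state = _integrate_sde(
            lambda x, t: theta * (mu(t) - x), mu(0.0), times, spec.noise_sd, rng
        )
        dv = np.asarray(sched(times))
        shift = float(times[np.argmax(dv > 0.5)])

    elif mech == "smooth_trend":
        theta = 12.0

        def mu(t):
            return 8.0 - 5.0 * sched(t)

        state = _integrate_sde(
            lambda x, t: theta * (mu(t) - x), mu(0.0), times, spec.noise_sd, rng
        )

    else:  # stationary
        theta, mean = 4.0, 5.0
        state = _integrate_sde(
            lambda x, t: theta * (mean - x), mean, times, spec.noise_sd, rng
        )

    if mech in _NO_SHIFT:
        shift = None
    return LatentTrajectory(
        time=times,
        state=state,
        control=control,
        truth=FateTruth(mechanism=mech, shift_time=shift),
    )


def generate_drivers(spec: MechanismSpec, seed: int) -> pd.DataFrame:
    """Monthly abiotic driver table for one lake.

    Total phosphorus is the designated forcing driver: it follows the control
    schedule (linearly rescaled to realistic μg/L).  Nitrate and temperature
    co-trend weakly with the forcing — monitored eutrophication drivers are
    correlated in practice — so the leading principal component of the
    standardized drivers tracks the control parameter.  Temperature carries an
    annual sinusoid (amplitude 8 °C).  All driver noise scales with the spec's
    ``noise_sd`` (zero noise gives noise-free drivers).
    """
    rng = np.random.default_rng(seed)
    t = _monthly_grid(spec.duration_years)
    control = np.asarray(spec.driver_schedule(t), dtype=float)
    span = control.max() - control.min()
    z = (control - control.mean()) / span if span > 0 else np.zeros_like(control)

    s = spec.noise_sd
    temperature = (
        15.0
        + 8.0 * np.sin(2 * np.pi * t)
        + 1.5 * z
        + 10.0 * s * rng.standard_normal(len(t))
    )
    nitrate = 250.0 + 120.0 * z + 300.0 * s * rng.standard_normal(len(t))
    phosphorus = 20.0 + 20.0 * control + 80.0 * s * rng.standard_normal(len(t))
    return pd.DataFrame(
        {
            "time": t,
            "temperature": temperature,
            "nitrate": nitrate,
            "phosphorus": phosphorus,
        }
    )


def disaggregate_to_genera(
    state: np.ndarray,
    n_genera: int,
    dirichlet_conc: float = 5.0,
    seed: int = 0,
    share_sd: float = 0.2,
    share_ar: float = 0.8,
) -> np.ndarray:
    """Split a trophic-level state into genus series that sum to it exactly.

    Each genus receives a Dirichlet base share; log-share fluctuations follow
    an AR(1) process (coefficient ``share_ar``, innovation scale ``share_sd``)
    and shares are renormalized at every time step, so column sums equal the
    latent state to machine precision.
    """
    if n_genera < 2:
        raise ValueError("n_genera must be >= 2")
    state = np.asarray(state, dtype=float)
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_genera, dirichlet_conc))
    T = len(state)
    innov_sd = share_sd * np.sqrt(1 - share_ar**2) if share_sd > 0 else 0.0
    e = np.zeros((T, n_genera))
    if share_sd > 0:
        e[0] = share_sd * rng.standard_normal(n_genera)
        for i in range(1, T):
            e[i] = share_ar * e[i - 1] + innov_sd * rng.standard_normal(n_genera)
    shares = base[None, :] * np.exp(e)
    shares /= shares.sum(axis=1, keepdims=True)
    return shares * state[:, None]


def sample_observations(
    latent: pd.DataFrame,
    obs_noise_cv: float = 0.2,
    detection_limit: float = 0.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Apply lognormal observation noise and a detection limit.

    ``latent`` is a monthly genus matrix with a DatetimeIndex.  Multiplicative
    lognormal noise with coefficient of variation ``obs_noise_cv`` (unit mean)
    is applied per cell; values below ``detection_limit`` are recorded as 0.
    Returns ``{"monthly": ..., "yearly": ...}`` where the yearly matrix is the
    arithmetic mean of the monthly observations within each calendar year.
    """
    if obs_noise_cv < 0:
        raise ValueError("obs_noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    values = latent.to_numpy(dtype=float)
    if obs_noise_cv > 0:
        sigma2 = np.log1p(obs_noise_cv**2)
        factor = np.exp(
            np.sqrt(sigma2) * rng.standard_normal(values.shape) - sigma2 / 2
        )
        values = values * factor
    values = np.where(values < detection_limit, 0.0, values)
    monthly = pd.DataFrame(values, index=latent.index, columns=latent.columns)
    yearly = monthly.groupby(monthly.index.year).mean()
    yearly.index.name = "year"
    return {"monthly": monthly, "yearly": yearly}


@dataclass
class SyntheticLake:
    """One labelled synthetic lake: observed communities, drivers, truth."""

    name: str
    monthly: dict[str, pd.DataFrame]  # trophic level -> genus matrix
    yearly: dict[str, pd.DataFrame]
    drivers_monthly: pd.DataFrame  # DatetimeIndex; temperature/nitrate/phosphorus
    drivers_yearly: pd.DataFrame
    truth: dict[str, FateTruth]
    latent_monthly: dict[str, pd.DataFrame] = field(default_factory=dict)


TROPHIC_LEVELS = ("phytoplankton", "zooplankton")
_LEVEL_SCALE = {"phytoplankton": 1000.0, "zooplankton": 50.0}
_LEVEL_GENERA = {"phytoplankton": 8, "zooplankton": 4}


def _month_index(duration_years: int, start_year: int = 1980) -> pd.DatetimeIndex:
    return pd.date_range(f"{start_year}-01-01", periods=12 * duration_years, freq="MS")


def make_lake(
    name: str,
    spec: MechanismSpec,
    n_genera: dict[str, int] | None = None,
    seasonal_amplitude: float = 0.3,
    obs_noise_cv: float = 0.2,
    detection_limit_frac: float = 1e-3,
    start_year: int = 1980,
) -> SyntheticLake:
    """Assemble a full synthetic lake from a mechanism spec.

    Both trophic levels follow the same mechanism and driver schedule with
    independent noise realisations (shared forcing, no explicit food-web
    coupling).  A multiplicative seasonal sinusoid (relative amplitude
    ``seasonal_amplitude``) is applied to the monthly latent state; it cancels
    to first order in the yearly means.
    """
    n_genera = dict(_LEVEL_GENERA if n_genera is None else n_genera)
    idx = _month_index(spec.duration_years, start_year)
    ss = np.random.SeedSequence(spec.seed)
    child = ss.generate_state(8) % (2**31)

    monthly, yearly, latent_m, truth = {}, {}, {}, {}
    for li, level in enumerate(TROPHIC_LEVELS):
        lspec = MechanismSpec(
            mechanism=spec.mechanism,
            duration_years=spec.duration_years,
            noise_sd=spec.noise_sd,
            seed=int(child[li]),
            driver_schedule=spec.driver_schedule,
        )
        traj = simulate_mechanism(lspec)
        scale = _LEVEL_SCALE[level]
        seasonal = 1.0 + seasonal_amplitude * np.sin(2 * np.pi * traj.time)
        state_m = traj.state * seasonal * scale
        genus_mat = disaggregate_to_genera(
            state_m, n_genera[level], seed=int(child[2 + li])
        )
        cols = [f"{level[:4]}_genus_{g+1:02d}" for g in range(n_genera[level])]
        latent = pd.DataFrame(genus_mat, index=idx, columns=cols)
        obs = sample_observations(
            latent,
            obs_noise_cv=obs_noise_cv,
            detection_limit=detection_limit_frac * float(state_m.mean()),
            seed=int(child[4 + li]),
        )
        monthly[level] = obs["monthly"]
        yearly[level] = obs["yearly"]
        latent_m[level] = latent
        shift = traj.truth.shift_time
        truth[level] = FateTruth(
            mechanism=spec.mechanism,
            shift_time=None if shift is None else start_year + shift,
        )

    drivers = generate_drivers(spec, seed=int(child[6]))
    drivers_m = drivers.drop(columns="time").set_index(idx)
    drivers_y = drivers_m.groupby(drivers_m.index.year).mean()
    drivers_y.index.name = "year"
    return SyntheticLake(
        name=name,
        monthly=monthly,
        yearly=yearly,
        drivers_monthly=drivers_m,
        drivers_yearly=drivers_y,
        truth=truth,
        latent_monthly=latent_m,
    )


def generate_benchmark_suite(
    config: dict[str, int],
    seed: int = 0,
    duration_years: int = 30,
    outdir: str | Path | None = None,
    **lake_kwargs,
) -> tuple[list[SyntheticLake], list[dict]]:
    """Generate a reproducible labelled suite of synthetic lakes.

    ``config`` maps mechanism name to replicate count.  Returns the lakes and
    a manifest (one record per lake × trophic level with the truth labels).
    If ``outdir`` is given, long-format CSVs and a JSON manifest are written.
    """
    lakes: list[SyntheticLake] = []
    manifest: list[dict] = []
    ss = np.random.SeedSequence(seed)
    n_total = sum(config.values())
    child_seeds = ss.generate_state(max(n_total, 1)) % (2**31)
    i = 0
    for mechanism, count in sorted(config.items()):
        for rep in range(count):
            name = f"{mechanism}_{rep+1:02d}"
            spec = MechanismSpec(
                mechanism=mechanism,
                duration_years=duration_years,
                seed=int(child_seeds[i]),
            )
            lake = make_lake(name, spec, **lake_kwargs)
            lakes.append(lake)
            for level in TROPHIC_LEVELS:
                tr = lake.truth[level]
                manifest.append(
                    {
                        "lake": name,
                        "trophic_level": level,
                        "mechanism": tr.mechanism,
                        "is_critical": tr.is_critical,
                        "shift_time": tr.shift_time,
                    }
                )
            i += 1
    if outdir is not None:
        write_suite_csv(lakes, manifest, outdir)
    return lakes, manifest


def write_suite_csv(lakes, manifest, outdir) -> None:
    """Write the suite as long-format plankton/driver CSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plankton_rows = []
    driver_frames = []
    for lake in lakes:
        for level in TROPHIC_LEVELS:
            df = lake.monthly[level].copy()
            long = df.reset_index(names="date").melt(
                id_vars="date", var_name="genus", value_name="density"
            )
            long.insert(0, "lake", lake.name)
            long.insert(2, "trophic_level", level)
            plankton_rows.append(long)
        d = lake.drivers_monthly.reset_index(names="date")
        d.insert(0, "lake", lake.name)
        driver_frames.append(d)
    plankton = pd.concat(plankton_rows, ignore_index=True)
    plankton["date"] = plankton["date"].dt.strftime("%Y-%m-%d")
    drivers = pd.concat(driver_frames, ignore_index=True)
    drivers["date"] = drivers["date"].dt.strftime("%Y-%m-%d")
    plankton.to_csv(outdir / "plankton.csv", index=False, float_format="%.10g")
    drivers.to_csv(outdir / "drivers.csv", index=False, float_format="%.10g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
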