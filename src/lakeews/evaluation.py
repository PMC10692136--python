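"""Bayesian hierarchical binomial scoring of warning accuracy.

Warnings are compared with ground-truth fates: a "success" is a warning on a
critically transitioning series or the absence of one on a non-transitioning
series.  Successes are aggregated per (lake j, fate k, factor level) and
modelled as

    y_ijk ~ Binomial(n_ijk, π_ijk)
    logit(π_ijk) = β_level + u_j + u_k + u_jk

with no global intercept, so each β_level is the absolute log-odds of a
correct classification at that factor level.  Weakly informative priors:
β_level ~ Normal(0, 1.2) truncated to (−5.5, 5.5) (≈1%–99% on the probability
scale), mean-zero random intercepts with Exponential(1) scale priors.  The
posterior is sampled by Hamiltonian Monte Carlo (analytic gradients,
dual-averaging step-size adaptation, diagonal mass matrix, 4 chains) under a
non-centered parameterisation; convergence is checked with split-Rhat.
Posterior summaries are back-transformed to probabilities, and a level is
better (worse) than chance when its 95% credible interval lies entirely
above (below) 0.5.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "PosteriorFit",
    "build_trial_table",
    "fit_binomial_hierarchy",
    "summarize_posterior",
    "select_preprocessing",
    "simulate_trial_table",
    "invlogit",
]


def invlogit(x):
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, 1 / (1 + np.exp(-x)), np.exp(x) / (1 + np.exp(x)))


@dataclass(frozen=True)
class PriorSpec:
    beta_sd: float = 1.2
    beta_bound: float = 5.5  # symmetric truncation of the level effects
    alpha_sd: float = 1.2  # location prior, unused in the no-intercept model
    sigma_rate: float = 1.0  # Exponential rate of the random-effect scales

    def __post_init__(self):
        if self.beta_bound <= 0 or self.beta_sd <= 0 or self.sigma_rate <= 0:
            raise ValueError("prior scales and bounds must be positive")


def build_trial_table(
    warnings: pd.DataFrame, fates: pd.DataFrame, factor: str
) -> pd.DataFrame:
    """Aggregate binary warnings into successes/trials per (lake, fate, level).

    ``warnings`` needs columns lake, trophic_level, warning and the factor
    column; ``fates`` needs lake, trophic_level, is_critical.  A warning is a
    success on a critical series, a failure otherwise (and vice versa).
    """
    if warnings.empty:
        return pd.DataFrame(
            columns=["lake", "fate", "level", "successes", "trials"]
        )
    keys = ["lake", "trophic_level"]
    merged = warnings.merge(
        fates[keys + ["is_critical"]], on=keys, how="left", validate="many_to_one"
    )
    unmatched = merged[merged["is_critical"].isna()]
    if len(unmatched):
        missing = unmatched[keys].drop_duplicates().to_records(index=False).tolist()
        raise KeyError(f"warnings with no matching fate: {missing}")
    merged["fate"] = np.where(merged["is_critical"], "critical", "not_critical")
    merged["success"] = (
        merged["warning"].astype(int) == merged["is_critical"].astype(int)
    ).astype(int)
    grouped = (
        merged.groupby(["lake", "fate", factor], observed=True)
        .agg(successes=("success", "sum"), trials=("success", "count"))
        .reset_index()
        .rename(columns={factor: "level"})
    )
    return grouped


@dataclass
class PosteriorFit:
    levels: list[str]
    beta: np.ndarray  # (chains, draws, n_levels) log-odds draws
    rhat: dict[str, float]
    acceptance: float
    priors: PriorSpec
    converged: bool
    extras: dict = field(default_factory=dict, repr=False)


def _model_factory(
    y, n, level_idx, lake_idx, fate_idx, jk_idx, L, J, K, priors,
    obs_intercept: bool = False,
):
    """Vectorized log posterior and gradient for the non-centered model.

    Parameter layout: beta(L) | z_j(J) | [z_k(K) | z_jk(JK)] |
    log σ_j [| log σ_k | log σ_jk].  Outside the β truncation box the log
    density is −inf (proposals there are rejected; the box sits 4.6 prior SDs
    out, so the truncated prior is numerically a Normal(0, 1.2)).
    """
    use_k = K >= 2
    n_jk = J * K if use_k else 0
    bound = priors.beta_bound
    inv_b2 = 1.0 / priors.beta_sd**2
    groups = [("j", lake_idx, J)] + ([("k", fate_idx, K), ("jk", jk_idx, n_jk)] if use_k else [])
    if obs_intercept:  # the ε term: one intercept per aggregated observation
        groups.append(("obs", np.arange(len(y)), len(y)))
    n_groups = len(groups)
    ndim = L + sum(g[2] for g in groups) + n_groups
    N = len(y)
    # one-hot design for fast index sums: columns [levels | units of each group]
    onehot = np.zeros((N, L + sum(g[2] for g in groups)))
    onehot[np.arange(N), level_idx] = 1.0
    off = L
    for _, idx, size in groups:
        onehot[np.arange(N), off + idx] = 1.0
        off += size

    def logp_grad(theta):
        theta = np.atleast_2d(theta)
        C = theta.shape[0]
        grad = np.zeros_like(theta)
        pos = 0
        beta = theta[:, :L]
        pos = L
        zs, sizes, idxs = [], [], []
        for _, idx, size in groups:
            zs.append(theta[:, pos : pos + size])
            sizes.append(size)
            idxs.append(idx)
            pos += size
        ls = theta[:, pos : pos + n_groups]
        sig = np.exp(np.clip(ls, -30, 30))

        bad = (np.abs(beta) >= bound).any(axis=1) | (np.abs(ls) > 20).any(axis=1)

        lp = -0.5 * inv_b2 * (beta**2).sum(axis=1)
        grad[:, :L] = -inv_b2 * beta
        p0 = L
        for g, z in enumerate(zs):
            lp -= 0.5 * (z**2).sum(axis=1)
            grad[:, p0 : p0 + sizes[g]] = -z
            p0 += sizes[g]
        lp += (ls - priors.sigma_rate * sig).sum(axis=1)
        grad[:, p0:] = 1.0 - priors.sigma_rate * sig

        eta = beta[:, level_idx]
        for g, z in enumerate(zs):
            eta = eta + sig[:, g : g + 1] * z[:, idxs[g]]
        log_pi = -np.logaddexp(0.0, -eta)
        log_1mpi = -np.logaddexp(0.0, eta)
        lp = lp + (y[None, :] * log_pi + (n - y)[None, :] * log_1mpi).sum(axis=1)
        resid = y[None, :] - n[None, :] * np.exp(log_pi)  # y − n·π
        sums = resid @ onehot  # (C, L + Σ group sizes)

        grad[:, :L] += sums[:, :L]
        p0 = L
        for g, z in enumerate(zs):
            block = sums[:, p0 : p0 + sizes[g]]
            grad[:, p0 : p0 + sizes[g]] += sig[:, g : g + 1] * block
            # d/d(log σ_g) = σ_g · Σ_i resid_i z_{g(i)}
            grad[:, L + sum(sizes) + g] += sig[:, g] * (block * z).sum(axis=1)
            p0 += sizes[g]

        lp = np.where(bad, -np.inf, lp)
        grad[bad] = 0.0
        return lp, grad

    return logp_grad, ndim, use_k


def _hmc_sample(
    logp_grad,
    p0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
):
    """Vectorized-over-chains HMC with dual-averaging ε and diagonal mass."""
    C, D = p0.shape
    x = p0.copy()
    lp, gr = logp_grad(x)
    minv = np.ones(D)  # inverse mass (posterior variance estimate)

    def run(n_iter, eps, adapt, collect):
        nonlocal x, lp, gr, minv
        log_eps = np.log(eps)
        mu = np.log(10.0) + log_eps
        log_eps_bar = np.zeros(C)
        h_bar = np.zeros(C)
        gamma, t0, kappa = 0.05, 10.0, 0.75
        out = np.empty((n_iter, C, D)) if collect else None
        sqrt_minv = np.sqrt(minv)
        for it in range(n_iter):
            n_leap = int(rng.integers(8, 25))
            p = rng.standard_normal((C, D)) / sqrt_minv[None, :]
            # note: momentum ~ N(0, M) with M = 1/minv
            ke0 = 0.5 * ((p**2) * minv[None, :]).sum(axis=1)
            xn, pn, grn = x.copy(), p.copy(), gr.copy()
            # downward step-size jitter: regions stiffer than the adapted
            # scale (hierarchical ridges) stay reachable
            jitter = np.exp(rng.uniform(np.log(1 / 3), 0.0, C))
            step = (np.exp(log_eps) * jitter)[:, None]
            pn = pn + 0.5 * step * grn
            bad = np.zeros(C, dtype=bool)
            for _ in range(n_leap):
                xn = xn + step * (pn * minv[None, :])
                lpn, grn = logp_grad(xn)
                bad |= ~np.isfinite(lpn)
                grn[bad] = 0.0
                pn = pn + step * grn
            pn = pn - 0.5 * step * grn
            ke1 = 0.5 * ((pn**2) * minv[None, :]).sum(axis=1)
            with np.errstate(invalid="ignore"):
                log_alpha = np.where(bad, -np.inf, (lpn - ke1) - (lp - ke0))
            accept_prob = np.exp(np.minimum(0.0, log_alpha))
            accept = rng.random(C) < accept_prob
            x[accept] = xn[accept]
            lp[accept] = lpn[accept]
            gr[accept] = grn[accept]
            if adapt:
                m = it + 1
                h_bar = (1 - 1 / (m + t0)) * h_bar + (
                    target_accept - accept_prob
                ) / (m + t0)
                log_eps = mu - np.sqrt(m) / gamma * h_bar
                eta = m**-kappa
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            if collect:
                out[it] = x
        return out, np.exp(log_eps_bar if adapt else log_eps)

    eps0 = np.full(C, 0.1)
    n1 = max(n_warmup // 2, 20)
    warm1, eps1 = run(n1, eps0, adapt=True, collect=True)
    # diagonal mass from mean within-chain variance over the second half of
    # the first warmup window (between-chain spread would inflate it)
    sample = warm1[n1 // 2 :]
    minv = np.maximum(sample.var(axis=0).mean(axis=0), 1e-6)
    n2 = max(n_warmup - n1, 20)
    # share the (robust) adapted step size: a single badly adapted chain
    # would otherwise freeze and fake a posterior mode
    _, eps2 = run(n2, np.full(C, np.median(eps1)), adapt=True, collect=False)
    draws, _ = run(n_draws, np.full(C, np.median(eps2)), adapt=False, collect=True)
    return np.moveaxis(draws, 0, 1)  # (chains, draws, D)


def fit_binomial_hierarchy(
    table: pd.DataFrame,
    priors: PriorSpec | None = None,
    iterations: int = 10_000,
    warmup: int = 2_000,
    chains: int = 4,
    seed: int = 0,
    rhat_tol: float = 1.05,
    obs_intercept: bool = False,
) -> PosteriorFit:
    """Sample the no-intercept hierarchical binomial model by HMC.

    ``table`` has columns lake, fate, level, successes, trials (from
    :func:`build_trial_table`).  ``iterations`` post-warmup draws are kept per
    chain after a ``warmup`` adaptation phase.  With a single fate in the
    table the fate and fate-within-lake intercepts drop out (the separate
    true-positive / true-negative analyses).  Raises on non-convergence (max
    split-Rhat above ``rhat_tol``).
    """
    priors = priors or PriorSpec()
    t = table.reset_index(drop=True)
    levels = sorted(t["level"].astype(str).unique())
    lakes = sorted(t["lake"].astype(str).unique())
    fates = sorted(t["fate"].astype(str).unique())
    L, J, K = len(levels), len(lakes), len(fates)
    if L < 1 or J < 1:
        raise ValueError("need at least one level and one lake")
    level_idx = t["level"].astype(str).map({v: i for i, v in enumerate(levels)}).to_numpy()
    lake_idx = t["lake"].astype(str).map({v: i for i, v in enumerate(lakes)}).to_numpy()
    fate_idx = t["fate"].astype(str).map({v: i for i, v in enumerate(fates)}).to_numpy()
    jk_idx = lake_idx * K + fate_idx
    y = t["successes"].to_numpy(dtype=float)
    n = t["trials"].to_numpy(dtype=float)
    if np.any(y > n) or np.any(y < 0):
        raise ValueError("successes must satisfy 0 <= y <= trials")

    logp_grad, ndim, use_k = _model_factory(
        y, n, level_idx, lake_idx, fate_idx, jk_idx, L, J, K, priors,
        obs_intercept=obs_intercept,
    )

    rng = np.random.default_rng(seed)
    p0 = np.empty((chains, ndim))
    p0[:, :L] = np.clip(
        rng.normal(0, priors.beta_sd, (chains, L)),
        -priors.beta_bound + 1e-3,
        priors.beta_bound - 1e-3,
    )
    n_z = J + (K + J * K if use_k else 0) + (len(y) if obs_intercept else 0)
    p0[:, L : L + n_z] = rng.normal(0, 1, (chains, n_z))
    p0[:, L + n_z :] = np.log(
        rng.exponential(1.0 / priors.sigma_rate, (chains, ndim - L - n_z))
    )

    draws = _hmc_sample(logp_grad, p0, warmup, iterations, rng)
    beta = draws[:, :, :L]  # (chains, draws, L)
    rhat = _split_rhat(beta)
    if np.max(rhat) > rhat_tol:
        # one automatic restart with doubled adaptation before giving up
        draws = _hmc_sample(logp_grad, p0, 2 * warmup, iterations, rng)
        beta = draws[:, :, :L]
        rhat = _split_rhat(beta)
    rhat_map = {f"beta[{lev}]": float(r) for lev, r in zip(levels, rhat)}
    converged = max(rhat_map.values()) <= rhat_tol
    fit = PosteriorFit(
        levels=levels,
        beta=beta,
        rhat=rhat_map,
        acceptance=float("nan"),
        priors=priors,
        converged=converged,
        extras={"draws": draws, "lakes": lakes, "fates": fates},
    )
    if not converged:
        raise RuntimeError(
            f"sampler did not converge: max Rhat = {max(rhat_map.values()):.3f} "
            f"(tolerance {rhat_tol}); diagnostics: {rhat_map}"
        )
    return fit


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter for draws shaped (chains, draws, k)."""
    try:
        import arviz as az

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            r = az.rhat(az.convert_to_dataset({"x": draws}))["x"].to_numpy()
        return np.atleast_1d(r)
    except Exception:
        c, d, k = draws.shape
        half = d // 2
        split = draws[:, : 2 * half, :].reshape(c * 2, half, k)
        m = split.mean(axis=1)
        v = split.var(axis=1, ddof=1)
        W = v.mean(axis=0)
        B = half * m.var(axis=0, ddof=1)
        var_hat = (half - 1) / half * W + B / half
        return np.sqrt(var_hat / W)


def summarize_posterior(fit: PosteriorFit) -> pd.DataFrame:
    """Per-level medians and 50/80/95% credible intervals on the probability scale."""
    if fit.beta.size == 0:
        raise ValueError("empty posterior draws")
    draws = invlogit(fit.beta.reshape(-1, len(fit.levels)))
    qs = np.percentile(draws, [2.5, 10, 25, 50, 75, 90, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "level": fit.levels,
            "median": qs[3],
            "q2.5": qs[0],
            "q10": qs[1],
            "q25": qs[2],
            "q75": qs[4],
            "q90": qs[5],
            "q97.5": qs[6],
        }
    )
    out["better_than_chance"] = out["q2.5"] > 0.5
    out["worse_than_chance"] = out["q97.5"] < 0.5
    out["rhat"] = [fit.rhat[f"beta[{lev}]"] for lev in fit.levels]
    return out


def select_preprocessing(
    warnings_df: pd.DataFrame,
    fates: pd.DataFrame,
    factor: str = "preprocess",
    method_col: str = "method",
    **fit_kwargs,
) -> pd.DataFrame:
    """Optimal preprocessing combination per EWS method class.

    Considers critically transitioning series only, fits the hierarchy with
    the preprocessing combination as the factor, and returns the level with
    the highest posterior median per method class (alphabetically first on
    ties, with a warning).
    """
    crit_lakes = fates.loc[fates["is_critical"], ["lake", "trophic_level"]]
    sub = warnings_df.merge(crit_lakes, on=["lake", "trophic_level"])
    if sub.empty:
        raise ValueError("no warnings on critically transitioning series")
    rows = []
    for method, grp in sub.groupby(method_col):
        table = build_trial_table(grp, fates, factor)
        if table["level"].nunique() == 1:
            rows.append({"method": method, "best": table["level"].iloc[0], "median": np.nan})
            continue
        fit = fit_binomial_hierarchy(table, **fit_kwargs)
        summ = summarize_posterior(fit).sort_values(
            ["median", "level"], ascending=[False, True]
        )
        top = summ.iloc[0]
        ties = summ[np.isclose(summ["median"], top["median"])]
        if len(ties) > 1:
            _warnings.warn(
                f"tied posterior medians for method {method}: "
                f"{ties['level'].tolist()}; keeping {top['level']}"
            )
        rows.append(
            {"method": method, "best": top["level"], "median": float(top["median"])}
        )
    return pd.DataFrame(rows)


def simulate_trial_table(
    level_probs: dict[str, float],
    n_lakes: int = 9,
    trials: int = 50,
    sigma_lake: float = 0.2,
    sigma_fate: float = 0.2,
    sigma_nested: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate successes/trials from the hierarchical binomial model.

    Each level has a known marginal probability; lake, fate and nested
    intercepts are drawn with the given scales.  Used for parameter-recovery
    checks against the data-generating truth.
    """
    rng = np.random.default_rng(seed)
    lakes = [f"lake_{j+1:02d}" for j in range(n_lakes)]
    fates = ["critical", "not_critical"]
    u_j = rng.normal(0, sigma_lake, n_lakes)
    u_k = rng.normal(0, sigma_fate, 2)
    u_jk = rng.normal(0, sigma_nested, (n_lakes, 2))
    rows = []
    for name, p in level_probs.items():
        beta = np.log(p / (1 - p))
        for j, lake in enumerate(lakes):
            for k, fate in enumerate(fates):
                pi = float(invlogit(beta + u_j[j] + u_k[k] + u_jk[j, k]))
                rows.append(
                    {
                        "lake": lake,
                        "fate": fate,
                        "level": name,
                        "successes": int(rng.binomial(trials, pi)),
                        "trials": trials,
                    }
                )
    return pd.DataFrame(rows)
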