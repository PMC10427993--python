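"""Bayesian Gaussian models: fixed-effects regressions, group means, and the
hierarchical varying-intercept/varying-slope footprint model.

All three models share a Gaussian likelihood with weakly informative priors:
Normal(0, 2.5·sd(y)/sd(x)) on slopes, Normal(mean(y), 2.5·sd(y)) on
intercepts/cell means, and half-Student-t(3, sd(y)) on every scale. Scales
use the inverse-gamma auxiliary-variable representation of the half-t, so
every full conditional is conjugate and posteriors are drawn by Gibbs
sampling (multiple chains, fixed seed, bit-stable). Convergence is checked
post hoc with split-R-hat and bulk ESS (via arviz); "statistical clarity"
of an effect means its equal-tailed 95% credible interval excludes zero.

For the non-hierarchical Gaussian model the exact Normal-inverse-gamma /
Student-t posterior under a flat prior is available as an independent
analytic cross-check (:func:`ols_t_intervals`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DiagnosticsError, DomainError

_HALF_T_DF = 3.0  # degrees of freedom of every half-t scale prior

RHAT_MAX = 1.01
ESS_MIN = 400.0


# ---------------------------------------------------------------------------
# Result containers


def _quantiles(draws: np.ndarray) -> dict:
    q = np.percentile(draws, [2.5, 17, 50, 83, 97.5])
    return {
        "ci95": (float(q[0]), float(q[4])),
        "ci66": (float(q[1]), float(q[3])),
        "median": float(q[2]),
    }


@dataclass
class PosteriorSummary:
    """Draws plus equal-tailed interval summaries for one parameter."""

    parameter: str
    draws: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)
    ci66: tuple[float, float] = field(init=False)
    ci95: tuple[float, float] = field(init=False)
    clarity: bool = field(init=False)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, float).ravel()
        self.mean = float(self.draws.mean())
        self.sd = float(self.draws.std(ddof=1))
        q = _quantiles(self.draws)
        self.median, self.ci66, self.ci95 = q["median"], q["ci66"], q["ci95"]
        self.clarity = not (self.ci95[0] <= 0.0 <= self.ci95[1])

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "ci66": list(self.ci66),
            "ci95": list(self.ci95),
            "clarity": self.clarity,
        }


@dataclass
class Contrast:
    """Posterior difference of two group means, optionally back-transformed.

    When the response was modelled on the log10 scale the ratio draws
    ``10^difference`` express the contrast as a multiplicative ratio on the
    original scale.
    """

    pair: tuple[str, str]
    difference_draws: np.ndarray
    ratio_draws: np.ndarray | None = None

    def summary(self) -> dict:
        d = PosteriorSummary("-".join(self.pair), self.difference_draws)
        out = {"pair": list(self.pair), "difference": d.to_dict()}
        if self.ratio_draws is not None:
            out["ratio"] = PosteriorSummary("ratio", self.ratio_draws).to_dict()
        return out


@dataclass
class Diagnostics:
    max_rhat: float
    min_ess: float

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_MAX and self.min_ess >= ESS_MIN

    def to_dict(self) -> dict:
        return {
            "max_rhat": self.max_rhat,
            "min_ess": self.min_ess,
            "converged": self.converged,
        }


@dataclass
class FitResult:
    summaries: dict[str, PosteriorSummary]
    contrasts: list[Contrast]
    diagnostics: Diagnostics
    draws: dict[str, np.ndarray]  # (chains, draws) per parameter
    report: dict = field(default_factory=dict)

    def contrast(self, a: str, b: str, log10_response: bool = False) -> Contrast:
        """Contrast of two named parameters from the same posterior draws."""
        diff = self.summaries[a].draws - self.summaries[b].draws
        return Contrast(
            pair=(a, b),
            difference_draws=diff,
            ratio_draws=np.power(10.0, diff) if log10_response else None,
        )

    def to_dict(self) -> dict:
        return {
            "parameters": {k: v.to_dict() for k, v in self.summaries.items()},
            "contrasts": [c.summary() for c in self.contrasts],
            "diagnostics": self.diagnostics.to_dict(),
            "report": self.report,
        }


@dataclass
class LinearModelSpec:
    """What to regress on what, and on which scale.

    ``transforms`` maps a variable name to "log10" or "identity" (default
    identity). ``zero_policy`` governs zeros under log10: "drop" removes the
    rows (counted in the report), "offset1" adds 1 before the log. Negative
    values under log10 are always a data error.
    """

    response_name: str
    predictor_names: Sequence[str]
    transforms: dict = field(default_factory=dict)
    zero_policy: str = "drop"


# ---------------------------------------------------------------------------
# Shared sampling machinery


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _diagnostics(draws: dict[str, np.ndarray]) -> Diagnostics:
    ds = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    max_rhat = float(max(rhat[v].values.max() for v in rhat.data_vars))
    min_ess = float(min(ess[v].values.min() for v in ess.data_vars))
    return Diagnostics(max_rhat=max_rhat, min_ess=min_ess)


def _check(diag: Diagnostics, strict: bool) -> None:
    if strict and not diag.converged:
        raise DiagnosticsError(
            f"convergence failure: max R-hat {diag.max_rhat:.4f}, min ESS {diag.min_ess:.0f}"
        )


def _apply_transforms(data: pd.DataFrame, spec: LinearModelSpec) -> tuple[pd.DataFrame, dict]:
    cols = [spec.response_name, *spec.predictor_names]
    df = data[cols].copy()
    report = {"n_rows_in": len(df), "n_dropped_zero": 0}
    for col in cols:
        if spec.transforms.get(col, "identity") != "log10":
            df[col] = pd.to_numeric(df[col], errors="raise")
            continue
        v = pd.to_numeric(df[col], errors="raise")
        if (v < 0).any():
            bad = df.index[v < 0].tolist()
            raise DataError(f"negative values under log10 in {col!r}, rows {bad[:10]}")
        if spec.zero_policy == "offset1":
            df[col] = np.log10(v + 1.0)
        elif spec.zero_policy == "drop":
            zero = v == 0
            if zero.any():
                report["n_dropped_zero"] += int(zero.sum())
                df = df[~zero]
                v = v[~zero]
            df[col] = np.log10(v)
        else:
            if (v <= 0).any():
                bad = df.index[v <= 0].tolist()
                raise DataError(f"nonpositive values under log10 in {col!r}, rows {bad[:10]}")
            df[col] = np.log10(v)
    if df.isna().any().any():
        raise DataError("missing values after transform")
    report["n_rows_used"] = len(df)
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Fixed-effects Gaussian linear model


def fit_gaussian_lm(
    data: pd.DataFrame,
    spec: LinearModelSpec,
    draws: int = 1000,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    strict: bool = False,
) -> FitResult:
    """Gibbs-sampled Bayesian Gaussian regression ``y ~ 1 + X``.

    Returns posteriors for the intercept ``alpha``, one slope ``b_<name>``
    per predictor, and the residual scale ``sigma``, each with a clarity
    flag (95% interval excludes zero). With ``strict`` the post-hoc
    convergence thresholds (R-hat < 1.01, ESS >= 400) become hard errors.
    """
    df, report = _apply_transforms(data, spec)
    y = df[spec.response_name].to_numpy(float)
    Xp = df[list(spec.predictor_names)].to_numpy(float)
    n, p = Xp.shape
    if n <= p + 2:
        raise DataError(f"need more than {p + 2} rows, got {n}")
    sds = Xp.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [spec.predictor_names[i] for i in np.flatnonzero(sds == 0)]
        raise DataError(f"constant predictor column(s): {bad}")
    X = np.column_stack([np.ones(n), Xp])
    sd_y = max(y.std(ddof=1), 1e-8)
    prior_mean = np.concatenate([[y.mean()], np.zeros(p)])
    prior_sd = np.concatenate([[2.5 * sd_y], 2.5 * sd_y / sds])

    XtX = X.T @ X
    Xty = X.T @ y
    P = np.diag(1.0 / prior_sd**2)
    Pm = prior_mean / prior_sd**2
    A2 = sd_y**2  # half-t scale squared
    nu = _HALF_T_DF

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    names = ["alpha"] + [f"b_{nm}" for nm in spec.predictor_names] + ["sigma"]
    store = np.empty((chains, draws, p + 2))
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ beta_ols
    s2_ols = max(float(resid0 @ resid0) / max(n - p - 1, 1), 1e-12)

    for c in range(chains):
        rng = np.random.default_rng(child[c])
        beta = beta_ols + rng.normal(0, 0.1 * np.abs(beta_ols) + 1e-3)
        s2 = s2_ols * np.exp(rng.normal(0, 0.3))
        a = A2
        for it in range(warmup + draws):
            prec = XtX / s2 + P
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xty / s2 + Pm)
            beta = mean + np.linalg.solve(L.T, rng.standard_normal(p + 1))
            a = _inv_gamma(rng, (nu + 1) / 2, nu / s2 + 1.0 / A2)
            resid = y - X @ beta
            s2 = _inv_gamma(rng, (n + nu) / 2, (resid @ resid) / 2 + nu / a)
            if it >= warmup:
                store[c, it - warmup, :p + 1] = beta
                store[c, it - warmup, p + 1] = np.sqrt(s2)

    draws_by_name = {nm: store[:, :, i] for i, nm in enumerate(names)}
    diag = _diagnostics(draws_by_name)
    _check(diag, strict)
    summaries = {nm: PosteriorSummary(nm, d) for nm, d in draws_by_name.items()}
    return FitResult(
        summaries=summaries, contrasts=[], diagnostics=diag, draws=draws_by_name, report=report
    )


def ols_t_intervals(data: pd.DataFrame, spec: LinearModelSpec, level: float = 0.95) -> dict:
    """Exact marginal posterior intervals under a flat prior (analytic oracle).

    With p(beta, sigma^2) ∝ 1/sigma^2, the marginal posterior of each
    coefficient is a scaled Student-t around the OLS estimate. Used in tests
    as the independent cross-check of the Gibbs sampler; not part of the
    pipeline fit path.
    """
    df, _ = _apply_transforms(data, spec)
    y = df[spec.response_name].to_numpy(float)
    Xp = df[list(spec.predictor_names)].to_numpy(float)
    n = len(y)
    X = np.column_stack([np.ones(n), Xp])
    p = X.shape[1]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    tcrit = stats.t.ppf(0.5 + level / 2, dof)
    names = ["alpha"] + [f"b_{nm}" for nm in spec.predictor_names]
    return {
        nm: {
            "estimate": float(beta[i]),
            "ci": (
                float(beta[i] - tcrit * np.sqrt(cov[i, i])),
                float(beta[i] + tcrit * np.sqrt(cov[i, i])),
            ),
        }
        for i, nm in enumerate(names)
    }


# ---------------------------------------------------------------------------
# Group means on log10 diversification rates


def fit_group_means(
    rate_table: pd.DataFrame,
    draws: int = 1000,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    exclude_monotypic: bool = True,
    exclude_extreme: bool = False,
    strict: bool = False,
) -> FitResult:
    """Posterior mean log10 diversification rate per group + pairwise ratios.

    Cell-means Gaussian model ``d_i ~ Normal(mu_{group_i}, sigma)`` on the
    log10 rate. All six pairwise contrasts are reported with back-
    transformed ratio draws ``10^difference`` (a ratio of rates on the
    original scale).
    """
    from .diversification import GROUP_LABELS

    df = rate_table.copy()
    if exclude_monotypic:
        df = df[~df["monotypic"].astype(bool)]
    if exclude_extreme:
        df = df[~df["extreme"].astype(bool)]
    df = df[np.isfinite(df["log10_rate"])]
    y = df["log10_rate"].to_numpy(float)
    g = df["group"].astype(int).to_numpy()
    for gid, lab in GROUP_LABELS.items():
        if not np.any(g == gid):
            raise DataError(f"empty group {gid} ({lab}) after exclusions")
    n = len(y)
    sd_y = max(y.std(ddof=1), 1e-8)
    prior_mean, prior_sd = y.mean(), 2.5 * sd_y
    A2, nu = sd_y**2, _HALF_T_DF
    idx = g - 1
    counts = np.bincount(idx, minlength=4).astype(float)

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    store = np.empty((chains, draws, 5))
    for c in range(chains):
        rng = np.random.default_rng(child[c])
        mu = np.array([y[idx == k].mean() for k in range(4)])
        s2 = max(float(np.var(y - mu[idx])), 1e-12)
        for it in range(warmup + draws):
            sums = np.bincount(idx, weights=y, minlength=4)
            prec = counts / s2 + 1.0 / prior_sd**2
            mean = (sums / s2 + prior_mean / prior_sd**2) / prec
            mu = mean + rng.standard_normal(4) / np.sqrt(prec)
            a = _inv_gamma(rng, (nu + 1) / 2, nu / s2 + 1.0 / A2)
            resid = y - mu[idx]
            s2 = _inv_gamma(rng, (n + nu) / 2, (resid @ resid) / 2 + nu / a)
            if it >= warmup:
                store[c, it - warmup, :4] = mu
                store[c, it - warmup, 4] = np.sqrt(s2)

    names = [f"mu_{GROUP_LABELS[k]}" for k in (1, 2, 3, 4)] + ["sigma"]
    draws_by_name = {nm: store[:, :, i] for i, nm in enumerate(names)}
    diag = _diagnostics(draws_by_name)
    _check(diag, strict)
    summaries = {nm: PosteriorSummary(nm, d) for nm, d in draws_by_name.items()}
    contrasts = []
    labels = [GROUP_LABELS[k] for k in (1, 2, 3, 4)]
    for i in range(4):
        for j in range(i + 1, 4):
            a_lab, b_lab = labels[j], labels[i]  # later group minus earlier
            diff = summaries[f"mu_{a_lab}"].draws - summaries[f"mu_{b_lab}"].draws
            contrasts.append(
                Contrast(pair=(a_lab, b_lab), difference_draws=diff, ratio_draws=10.0**diff)
            )
    return FitResult(
        summaries=summaries,
        contrasts=contrasts,
        diagnostics=diag,
        draws=draws_by_name,
        report={"n_rows_used": n, "group_sizes": counts.astype(int).tolist()},
    )


# ---------------------------------------------------------------------------
# Hierarchical varying-intercept / varying-slope footprint model


def fit_varying_slopes(
    observations: pd.DataFrame,
    draws: int = 1000,
    warmup: int = 1000,
    chains: int = 4,
    seed: int = 0,
    strict: bool = False,
) -> FitResult:
    """Footprint-by-type model with triplet-level intercepts and slopes.

    ``f_i ~ Normal(theta_{type_i} + alpha_{triplet_i} + b_{type_i, triplet_i},
    sigma)`` where the triplet intercepts and the per-triplet type effects
    are exchangeable with their own scales (tau_alpha, tau_b). The reported
    type means are the population-level ``theta``; pairwise type contrasts
    (hybrid-native, hybrid-neophyte, native-neophyte) come from the same
    draws, so antisymmetry is exact.
    """
    from .footprint import TAXON_TYPES

    df = observations[["triplet_id", "taxon_type", "hfi"]].dropna()
    trip_ids = sorted(df["triplet_id"].unique())
    if len(trip_ids) < 2:
        raise DataError("need at least 2 triplets to identify grouping variance")
    types_per_trip = df.groupby("triplet_id")["taxon_type"].nunique()
    if (types_per_trip < 2).any():
        bad = types_per_trip[types_per_trip < 2].index.tolist()
        raise DataError(f"triplets with fewer than 2 types: {bad[:5]}")
    type_index = {t: k for k, t in enumerate(TAXON_TYPES)}
    unknown = set(df["taxon_type"]) - set(TAXON_TYPES)
    if unknown:
        raise DataError(f"unknown taxon types {sorted(unknown)}")
    y = df["hfi"].to_numpy(float)
    k_idx = df["taxon_type"].map(type_index).to_numpy()
    t_idx = df["triplet_id"].map({t: i for i, t in enumerate(trip_ids)}).to_numpy()
    K, T, n = 3, len(trip_ids), len(y)
    cell_idx = k_idx * T + t_idx
    n_k = np.bincount(k_idx, minlength=K).astype(float)
    n_t = np.bincount(t_idx, minlength=T).astype(float)
    n_cell = np.bincount(cell_idx, minlength=K * T).astype(float)

    sd_y = max(y.std(ddof=1), 1e-8)
    theta_prior_mean, theta_prior_sd = y.mean(), 2.5 * sd_y
    A2, nu = sd_y**2, _HALF_T_DF

    # joint design over all location parameters [theta(3) | alpha(T) | b(KT)];
    # given the scales their full conditional is one multivariate normal, so a
    # single blocked draw sidesteps the heavy theta/alpha/b cross-correlation
    # that cripples coordinate-wise updates in this weakly identified model
    p_loc = K + T + K * T
    rows = np.arange(n)
    Z = np.zeros((n, p_loc))
    Z[rows, k_idx] = 1.0
    Z[rows, K + t_idx] = 1.0
    Z[rows, K + T + cell_idx] = 1.0
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    prior_mean_vec = np.concatenate([np.full(K, theta_prior_mean), np.zeros(T + K * T)])

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(chains)
    store = np.empty((chains, draws, K + 3))  # theta x3, sigma, tau_alpha, tau_b
    for c in range(chains):
        rng = np.random.default_rng(child[c])
        theta = np.array([y[k_idx == k].mean() for k in range(K)])
        s2 = max(float(np.var(y - theta[k_idx])), 1e-12)
        ta2 = tb2 = max(s2, 1e-6)
        loc = np.concatenate([theta, np.zeros(T + K * T)])
        a_ta = a_tb = a_s = A2
        for it in range(warmup + draws):
            prior_prec = np.concatenate(
                [
                    np.full(K, 1.0 / theta_prior_sd**2),
                    np.full(T, 1.0 / ta2),
                    np.full(K * T, 1.0 / tb2),
                ]
            )
            prec = ZtZ / s2 + np.diag(prior_prec)
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Zty / s2 + prior_prec * prior_mean_vec)
            loc = mean + np.linalg.solve(L.T, rng.standard_normal(p_loc))
            theta = loc[:K]
            alpha = loc[K : K + T]
            b = loc[K + T :]
            # scales (half-t via inverse-gamma auxiliaries)
            a_ta = _inv_gamma(rng, (nu + 1) / 2, nu / ta2 + 1.0 / A2)
            ta2 = _inv_gamma(rng, (T + nu) / 2, (alpha @ alpha) / 2 + nu / a_ta)
            a_tb = _inv_gamma(rng, (nu + 1) / 2, nu / tb2 + 1.0 / A2)
            tb2 = _inv_gamma(rng, (K * T + nu) / 2, (b @ b) / 2 + nu / a_tb)
            resid = y - theta[k_idx] - alpha[t_idx] - b[cell_idx]
            a_s = _inv_gamma(rng, (nu + 1) / 2, nu / s2 + 1.0 / A2)
            s2 = _inv_gamma(rng, (n + nu) / 2, (resid @ resid) / 2 + nu / a_s)
            if it >= warmup:
                store[c, it - warmup, :K] = theta
                store[c, it - warmup, K] = np.sqrt(s2)
                store[c, it - warmup, K + 1] = np.sqrt(ta2)
                store[c, it - warmup, K + 2] = np.sqrt(tb2)

    names = [f"mu_{t}" for t in TAXON_TYPES] + ["sigma", "tau_alpha", "tau_b"]
    draws_by_name = {nm: store[:, :, i] for i, nm in enumerate(names)}
    diag = _diagnostics(draws_by_name)
    _check(diag, strict)
    summaries = {nm: PosteriorSummary(nm, d) for nm, d in draws_by_name.items()}
    contrasts = [
        Contrast(
            pair=(a, bb),
            difference_draws=summaries[f"mu_{a}"].draws - summaries[f"mu_{bb}"].draws,
        )
        for a, bb in (("hybrid", "native"), ("hybrid", "neophyte"), ("native", "neophyte"))
    ]
    return FitResult(
        summaries=summaries,
        contrasts=contrasts,
        diagnostics=diag,
        draws=draws_by_name,
        report={"n_observations": n, "n_triplets": T},
    )


# ---------------------------------------------------------------------------


def slope_percent_change(b: float, predictor_factor: float) -> float:
    """Percent change in the response for a multiplicative predictor change.

    For a log10-response-on-log10-predictor slope ``b``, scaling the
    predictor by ``predictor_factor`` scales the response by
    ``predictor_factor ** b``; returned as a percentage.
    """
    if predictor_factor <= 0:
        raise DomainError(f"predictor_factor must be positive, got {predictor_factor}")
    return 100.0 * (predictor_factor**b - 1.0)
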