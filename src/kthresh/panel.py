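"""First-difference panel model of log mortality on log spending.

The model, on the differenced scale, is

    dlog_m[i] ~ Normal(mu + alpha*dlog_c[i] + beta*dlog_c_lag[i]
                       + gamma[t[i]] + tau[a[i]], sigma_m)
    gamma[t]  ~ Normal(0, sigma_gamma)
    tau[a]    ~ Normal(0, sigma_tau)

with normal priors on (mu, alpha, beta) and uniform priors on the three
standard deviations.  Estimation is blocked Gibbs: the linear-Gaussian blocks
have conjugate conditionals, and each standard deviation is updated by slice
sampling within its (bounded) uniform support.  A degenerate uniform prior
(lo == hi) fixes the corresponding standard deviation; fixing one at zero
removes its random-intercept block entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z975 = 1.959964  # standard-normal 0.975 quantile used for interval -> sd


class RankDeficiencyError(ValueError):
    """Raised when the dummy-coded design matrix is not full rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix rank deficient; collinear columns: {self.columns}")


# --------------------------------------------------------------------------
# model frame
# --------------------------------------------------------------------------

def build_model_frame(
    panel: pd.DataFrame,
    year_min: int | None = None,
    year_max: int | None = None,
) -> pd.DataFrame:
    """Differenced log-scale design rows from a raw panel.

    Per stratum, a row exists for each year ``y`` whose two predecessors fall
    inside the (optional) window::

        dlog_m     = log m[y]   - log m[y-1]
        dlog_c     = log c[y]   - log c[y-1]
        dlog_c_lag = log c[y-1] - log c[y-2]

    Year and stratum ids are assigned densely over the rows that survive.
    """
    from .synthetic import validate_panel

    validate_panel(panel)
    sub = panel
    if year_min is not None:
        sub = sub[sub["year"] >= year_min]
    if year_max is not None:
        sub = sub[sub["year"] <= year_max]
    if sub.empty:
        raise ValueError(
            f"no panel rows in year window [{year_min}, {year_max}]"
        )

    rows = []
    for (age_group, gender), grp in sub.groupby(["age_group", "gender"], sort=True):
        grp = grp.sort_values("year")
        if len(grp) < 3:
            raise ValueError(
                f"stratum ({age_group}, {gender}) has fewer than 3 consecutive "
                f"years in window [{year_min}, {year_max}]"
            )
        log_m = np.log(grp["mortality_rate"].to_numpy(float))
        log_c = np.log(grp["spending"].to_numpy(float))
        years = grp["year"].to_numpy(int)
        for k in range(2, len(grp)):
            rows.append(
                (
                    age_group,
                    gender,
                    int(years[k]),
                    log_m[k] - log_m[k - 1],
                    log_c[k] - log_c[k - 1],
                    log_c[k - 1] - log_c[k - 2],
                )
            )
    frame = pd.DataFrame(
        rows, columns=["age_group", "gender", "year", "dlog_m", "dlog_c", "dlog_c_lag"]
    )
    if not np.all(np.isfinite(frame[["dlog_m", "dlog_c", "dlog_c_lag"]].to_numpy())):
        raise ValueError("non-finite differenced values in model frame")
    frame["year_id"] = pd.factorize(frame["year"], sort=True)[0]
    stratum_key = frame["age_group"].astype(str) + "|" + frame["gender"].astype(str)
    frame["stratum_id"] = pd.factorize(stratum_key, sort=True)[0]
    return frame


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalPrior:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("normal prior sd must be > 0")


@dataclass(frozen=True)
class UniformPrior:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo < 0 or self.hi < self.lo:
            raise ValueError("uniform prior needs 0 <= lo <= hi")

    @property
    def fixed(self) -> bool:
        return self.lo == self.hi


@dataclass(frozen=True)
class PriorSpec:
    mu_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, np.sqrt(10.0)))
    alpha_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, np.sqrt(10.0)))
    beta_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, np.sqrt(10.0)))
    sigma_m_prior: UniformPrior = field(default_factory=lambda: UniformPrior(0.0, 1.0))
    sigma_gamma_prior: UniformPrior = field(default_factory=lambda: UniformPrior(0.0, 1.0))
    sigma_tau_prior: UniformPrior = field(default_factory=lambda: UniformPrior(0.0, 1.0))


def make_prior(
    style: str,
    mean: float | None = None,
    ci95: tuple[float, float] | None = None,
) -> PriorSpec:
    """Vague priors, or an informative normal prior on the instantaneous
    elasticity derived from a published point estimate and 95% interval."""
    if style == "vague":
        return PriorSpec()
    if style == "elasticity_interval":
        if mean is None or ci95 is None:
            raise ValueError("elasticity_interval style needs mean and ci95")
        lo, hi = ci95
        if not lo < hi:
            raise ValueError(f"malformed interval ({lo}, {hi}): need lo < hi")
        sd = (hi - lo) / (2.0 * Z975)
        return PriorSpec(alpha_prior=NormalPrior(float(mean), sd))
    raise ValueError(f"unknown prior style {style!r}")


# --------------------------------------------------------------------------
# MCMC configuration and draws container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 3
    n_iter: int = 75_000
    burn_in: int = 25_000
    thin: int = 4
    seed: int = 0
    init_dispersion: float = 0.25

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_keep_per_chain(self) -> int:
        # iterations burn_in, burn_in+thin, ... below n_iter
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin

    @property
    def n_retained(self) -> int:
        return self.n_chains * self.n_keep_per_chain


@dataclass
class PosteriorDraws:
    """Retained chain-labelled draws; arrays are shaped (n_chains, n_keep)."""

    params: dict[str, np.ndarray]
    config: McmcConfig
    notes: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def n_retained(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.flat(name).mean())

    def sd(self, name: str) -> float:
        return float(self.flat(name).std(ddof=1))

    def quantile(self, name: str, q) -> np.ndarray:
        return np.quantile(self.flat(name), q)

    def ci95(self, name: str) -> tuple[float, float]:
        lo, hi = self.quantile(name, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def elasticity_name(self) -> str:
        return "alpha_plus_beta" if "alpha_plus_beta" in self.params else "alpha"

    def elasticity_draws(self) -> np.ndarray:
        return self.flat(self.elasticity_name)

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_keep = next(iter(self.params.values())).shape
        data = {
            "chain": np.repeat(np.arange(n_chains), n_keep),
            "draw": np.tile(np.arange(n_keep), n_chains),
        }
        for name, arr in self.params.items():
            data[name] = arr.reshape(-1)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: McmcConfig) -> "PosteriorDraws":
        n_chains = int(df["chain"].max()) + 1
        n_keep = int(df["draw"].max()) + 1
        params = {}
        for name in df.columns:
            if name in ("chain", "draw"):
                continue
            params[name] = df[name].to_numpy(float).reshape(n_chains, n_keep)
        return cls(params=params, config=config)


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------

def _slice_bounded(logp, x0: float, lo: float, hi: float, rng) -> float:
    """Shrinkage slice sampling on a bounded interval."""
    height = logp(x0) - rng.exponential()
    left, right = lo, hi
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logp(x1) >= height:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def fit_mcmc(
    frame: pd.DataFrame,
    priors: PriorSpec,
    config: McmcConfig,
    include_lag: bool = True,
    compute_diagnostics: bool = True,
):
    """Blocked-Gibbs posterior sampling of the differenced panel model.

    Returns ``(PosteriorDraws, FitDiagnostics)``; diagnostics are ``None``
    when ``compute_diagnostics`` is false.
    """
    y = frame["dlog_m"].to_numpy(float)
    x1 = frame["dlog_c"].to_numpy(float)
    cols = [np.ones_like(y), x1]
    coef_names = ["mu", "alpha"]
    coef_priors = [priors.mu_prior, priors.alpha_prior]
    if include_lag:
        cols.append(frame["dlog_c_lag"].to_numpy(float))
        coef_names.append("beta")
        coef_priors.append(priors.beta_prior)
    X = np.column_stack(cols)
    n, p = X.shape
    t_idx = frame["year_id"].to_numpy(int)
    a_idx = frame["stratum_id"].to_numpy(int)
    T = int(t_idx.max()) + 1
    A = int(a_idx.max()) + 1
    n_t = np.bincount(t_idx, minlength=T).astype(float)
    n_a = np.bincount(a_idx, minlength=A).astype(float)

    notes: list[str] = []
    spend_cols = X[:, 1:]
    if np.allclose(spend_cols, 0.0):
        msg = "data carry no information on elasticity (all spending covariates zero)"
        notes.append(msg)
        warnings.warn(msg)

    prior_mean = np.array([q.mean for q in coef_priors])
    prior_var = np.array([q.sd**2 for q in coef_priors])
    XtX = X.T @ X

    sm_pr, sg_pr, st_pr = (
        priors.sigma_m_prior,
        priors.sigma_gamma_prior,
        priors.sigma_tau_prior,
    )
    if sm_pr.fixed and sm_pr.hi == 0.0:
        raise ValueError("sigma_m cannot be fixed at zero")

    n_keep = config.n_keep_per_chain
    scalar_names = coef_names + ["sigma_m", "sigma_gamma", "sigma_tau"]
    store = {
        name: np.empty((config.n_chains, n_keep)) for name in scalar_names
    }
    for t in range(T):
        store[f"gamma[{t}]"] = np.empty((config.n_chains, n_keep))
    for a in range(A):
        store[f"tau[{a}]"] = np.empty((config.n_chains, n_keep))

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains)

    def _sd_logpost(count: float, ss: float):
        def logp(s: float) -> float:
            if s <= 0:
                return -np.inf
            return -count * np.log(s) - ss / (2.0 * s * s)
        return logp

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        offset = config.init_dispersion * (c - (config.n_chains - 1) / 2.0)
        theta = prior_mean + offset
        mid = lambda pr: pr.lo + 0.5 * (pr.hi - pr.lo)  # noqa: E731
        sigma_m = sm_pr.hi if sm_pr.fixed else max(mid(sm_pr), 1e-3)
        sigma_g = sg_pr.hi if sg_pr.fixed else max(mid(sg_pr), 1e-3)
        sigma_t = st_pr.hi if st_pr.fixed else max(mid(st_pr), 1e-3)
        gamma = np.zeros(T)
        tau = np.zeros(A)
        kept = 0
        for it in range(config.n_iter):
            s2m = sigma_m * sigma_m
            # coefficient block (conjugate multivariate normal)
            r = y - gamma[t_idx] - tau[a_idx]
            prec = XtX / s2m + np.diag(1.0 / prior_var)
            b = X.T @ r / s2m + prior_mean / prior_var
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b)
            z = rng.standard_normal(p)
            theta = mean + np.linalg.solve(L.T, z)
            fitted = X @ theta

            # year intercepts
            if sigma_g > 0.0:
                e = y - fitted - tau[a_idx]
                sums = np.bincount(t_idx, weights=e, minlength=T)
                prec_t = n_t / s2m + 1.0 / (sigma_g * sigma_g)
                gamma = sums / s2m / prec_t + rng.standard_normal(T) / np.sqrt(prec_t)
            else:
                gamma = np.zeros(T)

            # stratum intercepts
            if sigma_t > 0.0:
                e = y - fitted - gamma[t_idx]
                sums = np.bincount(a_idx, weights=e, minlength=A)
                prec_a = n_a / s2m + 1.0 / (sigma_t * sigma_t)
                tau = sums / s2m / prec_a + rng.standard_normal(A) / np.sqrt(prec_a)
            else:
                tau = np.zeros(A)

            # scale parameters (slice sampling within uniform support)
            if not sm_pr.fixed:
                resid = y - fitted - gamma[t_idx] - tau[a_idx]
                ss = float(resid @ resid)
                sigma_m = _slice_bounded(
                    _sd_logpost(n, ss), sigma_m, sm_pr.lo, sm_pr.hi, rng
                )
            if not sg_pr.fixed:
                sigma_g = _slice_bounded(
                    _sd_logpost(T, float(gamma @ gamma)), sigma_g, sg_pr.lo, sg_pr.hi, rng
                )
            if not st_pr.fixed:
                sigma_t = _slice_bounded(
                    _sd_logpost(A, float(tau @ tau)), sigma_t, st_pr.lo, st_pr.hi, rng
                )

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                for j, name in enumerate(coef_names):
                    store[name][c, kept] = theta[j]
                store["sigma_m"][c, kept] = sigma_m
                store["sigma_gamma"][c, kept] = sigma_g
                store["sigma_tau"][c, kept] = sigma_t
                for t in range(T):
                    store[f"gamma[{t}]"][c, kept] = gamma[t]
                for a in range(A):
                    store[f"tau[{a}]"][c, kept] = tau[a]
                kept += 1
        assert kept == n_keep

    if include_lag:
        store["alpha_plus_beta"] = store["alpha"] + store["beta"]

    for name, pr in (
        ("sigma_m", sm_pr), ("sigma_gamma", sg_pr), ("sigma_tau", st_pr)
    ):
        if not pr.fixed and pr.hi > pr.lo:
            pile = np.mean(store[name] > pr.hi - 0.01 * (pr.hi - pr.lo))
            if pile > 0.10:
                msg = (
                    f"{name} posterior piles up at the upper prior bound {pr.hi}; "
                    "the uniform prior truncation is binding"
                )
                notes.append(msg)
                warnings.warn(msg)

    draws = PosteriorDraws(params=store, config=config, notes=notes)
    diagnostics = diagnose(draws) if compute_diagnostics else None
    return draws, diagnostics


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

@dataclass
class FitDiagnostics:
    summary: pd.DataFrame          # columns: param, rhat, ess
    autocorr: pd.DataFrame         # columns: param, lag, autocorr
    notes: list[str] = field(default_factory=list)


def diagnose(
    draws: PosteriorDraws,
    lags: tuple[int, ...] = (1, 5, 10, 20),
) -> FitDiagnostics:
    """Split-chain potential scale reduction, ESS and lag-k autocorrelation.

    With a single chain, scale reduction is reported as NaN (unavailable);
    ESS is still computed.
    """
    import arviz as az

    notes = []
    single_chain = next(iter(draws.params.values())).shape[0] < 2
    if single_chain:
        notes.append("single chain: potential scale reduction unavailable")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dataset = az.from_dict(posterior=draws.params).posterior
        ess_ds = az.ess(dataset)
        rhat_ds = None if single_chain else az.rhat(dataset)

    records = []
    ac_records = []
    for name, arr in draws.params.items():
        ess = float(ess_ds[name].values)
        rhat = float("nan") if single_chain else float(rhat_ds[name].values)
        if arr.std() == 0.0:
            ess = 1.0  # a constant chain carries a single piece of information
            notes.append(f"{name}: degenerate (constant) chain")
        records.append((name, rhat, ess))
        flat = arr.reshape(-1)
        centered = flat - flat.mean()
        denom = float(centered @ centered)
        for lag in lags:
            if lag < len(flat) and denom > 0:
                ac = float(centered[:-lag] @ centered[lag:]) / denom
            else:
                ac = float("nan")
            ac_records.append((name, lag, ac))

    summary = pd.DataFrame(records, columns=["param", "rhat", "ess"])
    autocorr = pd.DataFrame(ac_records, columns=["param", "lag", "autocorr"])
    return FitDiagnostics(summary=summary, autocorr=autocorr, notes=notes)


# --------------------------------------------------------------------------
# frequentist fit
# --------------------------------------------------------------------------

@dataclass
class FrequentistFit:
    params: pd.Series
    cov: pd.DataFrame
    resid_sd: float
    nobs: int

    def coef_ci95(self, name: str) -> tuple[float, float]:
        se = float(np.sqrt(self.cov.loc[name, name]))
        est = float(self.params[name])
        return est - Z975 * se, est + Z975 * se


def design_matrix(frame: pd.DataFrame, include_lag: bool = True):
    """Dummy-coded OLS design: intercept, spending terms, year and stratum
    dummies (first level of each block is the reference)."""
    names = ["const", "dlog_c"]
    cols = [np.ones(len(frame)), frame["dlog_c"].to_numpy(float)]
    if include_lag:
        names.append("dlog_c_lag")
        cols.append(frame["dlog_c_lag"].to_numpy(float))
    t_idx = frame["year_id"].to_numpy(int)
    a_idx = frame["stratum_id"].to_numpy(int)
    for t in np.unique(t_idx)[1:]:
        names.append(f"year[{t}]")
        cols.append((t_idx == t).astype(float))
    for a in np.unique(a_idx)[1:]:
        names.append(f"stratum[{a}]")
        cols.append((a_idx == a).astype(float))
    return np.column_stack(cols), names


def fit_frequentist(frame: pd.DataFrame, include_lag: bool = True) -> FrequentistFit:
    """OLS of dlog_m on spending terms plus year and stratum dummies."""
    import statsmodels.api as sm

    X, names = design_matrix(frame, include_lag)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[k]] for k in range(len(diag)) if diag[k] < tol]
        bad += [names[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(bad or names)
    y = frame["dlog_m"].to_numpy(float)
    res = sm.OLS(y, X).fit()
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    resid_sd = float(np.sqrt(res.scale)) if res.df_resid > 0 else 0.0
    return FrequentistFit(params=params, cov=cov, resid_sd=resid_sd, nobs=int(res.nobs))


def rename_frequentist_coefs(fit: FrequentistFit) -> dict[str, float]:
    """Map OLS coefficient names onto the Bayesian parameter names."""
    out = {"mu": float(fit.params["const"]), "alpha": float(fit.params["dlog_c"])}
    if "dlog_c_lag" in fit.params.index:
        out["beta"] = float(fit.params["dlog_c_lag"])
    return out
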