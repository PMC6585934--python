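"""Synthetic panel and life-table input generation with known ground truth.

The panel generator draws year and stratum intercepts once, builds exogenous
log-spending paths, and accumulates log mortality according to the
first-difference model that the fitting module estimates.  The realized latent
effects are returned in a sidecar so parameter-recovery tests can compare
against truth; the fitting code never sees them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lifetable import LifeTableInputs

DEFAULT_AGE_GROUPS: tuple[str, ...] = (
    "60-64", "65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95+",
)
DEFAULT_GENDERS: tuple[str, str] = ("male", "female")


def age_group_start(label: str) -> int:
    """Lowest single-year age of a 5-year group label such as '60-64' or '95+'."""
    return int(label.rstrip("+").split("-")[0])


@dataclass(frozen=True)
class SpendGrowth:
    """Per-year log-spending increment: deterministic trend plus optional noise."""

    trend: float = 0.04
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruePanelParams:
    """Generative truth for a spending/mortality panel.

    ``m0`` and ``c0`` may be scalars (same baseline everywhere) or mappings
    keyed by ``(age_group, gender)``.
    """

    mu: float = -0.02
    alpha: float = -0.065
    beta: float = -0.124
    sigma_m: float = 0.04
    sigma_gamma: float = 0.02
    sigma_tau: float = 0.01
    years: tuple[int, int] = (1994, 2010)
    age_groups: Sequence[str] = DEFAULT_AGE_GROUPS
    genders: Sequence[str] = DEFAULT_GENDERS
    m0: float | Mapping[tuple[str, str], float] = 0.01
    c0: float | Mapping[tuple[str, str], float] = 100.0
    spend_growth: SpendGrowth = field(default_factory=SpendGrowth)
    population: float | Mapping[tuple[str, str], float] = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        for name in ("sigma_m", "sigma_gamma", "sigma_tau"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        lo, hi = self.years
        if hi - lo + 1 < 3:
            errors.append("need at least 3 years (differencing plus lag consumes two)")
        for key, val in self._stratum_values(self.m0).items():
            if not 0 < val < 1:
                errors.append(f"m0 for {key} must be in (0, 1), got {val}")
        for key, val in self._stratum_values(self.c0).items():
            if val <= 0:
                errors.append(f"c0 for {key} must be > 0, got {val}")
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def strata(self) -> list[tuple[str, str]]:
        return [(a, g) for a in self.age_groups for g in self.genders]

    def _stratum_values(self, spec: float | Mapping) -> dict[tuple[str, str], float]:
        if isinstance(spec, Mapping):
            missing = [s for s in self.strata if s not in spec]
            if missing:
                raise ValueError(f"missing baseline values for strata: {missing}")
            return {s: float(spec[s]) for s in self.strata}
        return {s: float(spec) for s in self.strata}


def gompertz_profile(
    age_groups: Sequence[str], rate_at_60: float, log_slope: float
) -> dict[str, float]:
    """Exponential-in-age profile evaluated at each group's start age."""
    return {
        a: rate_at_60 * float(np.exp(log_slope * (age_group_start(a) - 60)))
        for a in age_groups
    }


@dataclass
class PanelSimulation:
    """A generated panel plus the realized latent effects (truth sidecar)."""

    panel: pd.DataFrame
    year_effects: pd.DataFrame      # columns: year, gamma
    stratum_effects: pd.DataFrame   # columns: age_group, gender, tau
    params: TruePanelParams

    def write(self, panel_path, truth_path) -> None:
        self.panel.to_csv(panel_path, index=False)
        truth = self.year_effects.assign(kind="gamma").rename(columns={"gamma": "value"})
        tau = self.stratum_effects.assign(kind="tau").rename(columns={"tau": "value"})
        pd.concat([truth, tau], ignore_index=True).to_csv(truth_path, index=False)


def generate_panel(params: TruePanelParams) -> PanelSimulation:
    """Simulate a stratified mortality/spending panel from known truth.

    Log spending follows an exogenous path (one hidden pre-period year supplies
    the first lagged difference); log mortality accumulates
    ``mu + alpha*dlog_c[t] + beta*dlog_c[t-1] + gamma[t] + tau[a] + noise``
    from the baseline onward.
    """
    rng = np.random.default_rng(params.seed)
    y0, y1 = params.years
    years = np.arange(y0, y1 + 1)
    n_years = len(years)
    strata = params.strata
    m0 = params._stratum_values(params.m0)
    c0 = params._stratum_values(params.c0)
    pop = params._stratum_values(params.population)

    # one intercept per year with a defined mortality difference (y0+1 .. y1)
    gamma = rng.normal(0.0, params.sigma_gamma, size=n_years - 1)
    tau = rng.normal(0.0, params.sigma_tau, size=len(strata))

    records = []
    for s_i, stratum in enumerate(strata):
        age_group, gender = stratum
        # spending increments for years y0 .. y1, with a pre-period increment
        # so the lagged difference exists in the first modelled year
        incr = params.spend_growth.trend + rng.normal(
            0.0, params.spend_growth.noise_sd, size=n_years
        ) * (1.0 if params.spend_growth.noise_sd > 0 else 0.0)
        log_c = np.log(c0[stratum]) + np.cumsum(np.concatenate([[0.0], incr[1:]]))
        dlog_c = incr  # dlog_c[k] = log c[k] - log c[k-1] (k=0 uses pre-period)

        log_m = np.empty(n_years)
        log_m[0] = np.log(m0[stratum])
        eps = rng.normal(0.0, params.sigma_m, size=n_years - 1)
        for k in range(1, n_years):
            log_m[k] = (
                log_m[k - 1]
                + params.mu
                + params.alpha * dlog_c[k]
                + params.beta * dlog_c[k - 1]
                + gamma[k - 1]
                + tau[s_i]
                + eps[k - 1]
            )
        if not np.all(np.isfinite(log_m)):
            raise ValueError(
                f"non-finite log mortality accumulated in stratum {stratum}"
            )
        mort = np.exp(log_m)
        spend = np.exp(log_c)
        if not (np.all(np.isfinite(mort)) and np.all(np.isfinite(spend))):
            raise ValueError(f"non-finite rates generated in stratum {stratum}")
        for k, year in enumerate(years):
            records.append(
                (age_group, gender, int(year), mort[k], spend[k], pop[stratum])
            )

    panel = pd.DataFrame.from_records(
        records,
        columns=["age_group", "gender", "year", "mortality_rate", "spending", "population"],
    )
    validate_panel(panel)
    year_effects = pd.DataFrame({"year": years[1:], "gamma": gamma})
    stratum_effects = pd.DataFrame(
        {
            "age_group": [s[0] for s in strata],
            "gender": [s[1] for s in strata],
            "tau": tau,
        }
    )
    return PanelSimulation(panel, year_effects, stratum_effects, params)


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the PanelDataset contract; raise ValueError naming the offence."""
    required = {"age_group", "gender", "year", "mortality_rate", "spending", "population"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel missing columns: {sorted(missing)}")
    bad_m = panel[panel["mortality_rate"] <= 0]
    if len(bad_m):
        row = bad_m.iloc[0]
        raise ValueError(
            f"nonpositive mortality_rate at ({row.age_group}, {row.gender}, {row.year})"
        )
    bad_c = panel[panel["spending"] <= 0]
    if len(bad_c):
        row = bad_c.iloc[0]
        raise ValueError(
            f"nonpositive spending at ({row.age_group}, {row.gender}, {row.year})"
        )
    for (age_group, gender), grp in panel.groupby(["age_group", "gender"], sort=False):
        yrs = grp["year"].to_numpy()
        if len(np.unique(yrs)) != len(yrs):
            raise ValueError(f"duplicate year rows in stratum ({age_group}, {gender})")
        yrs = np.sort(yrs)
        if np.any(np.diff(yrs) != 1):
            raise ValueError(f"gap in years for stratum ({age_group}, {gender})")


@dataclass(frozen=True)
class LifeSurfaceParams:
    """Parameters for synthetic life-table input surfaces.

    Other-cause and cardiovascular mortality follow ``a * exp(b * (age-60))``;
    quality of life declines linearly with age and takes additive decrements in
    the final years before death; unrelated hospital cost grows with age and is
    scaled up in the last year of life; cardiovascular spending follows a bell
    curve peaking in old age.
    """

    gompertz_a: float = 0.012
    gompertz_b: float = 0.085
    cvd_gompertz_a: float = 0.003
    cvd_gompertz_b: float = 0.10
    qol_age_slope: float = 0.004
    qol_ttd_decrements: Sequence[float] = (0.30, 0.15, 0.08, 0.04, 0.02)
    unrelated_cost_base: float = 1_500.0
    unrelated_cost_age_rate: float = 0.02
    unrelated_cost_terminal: float = 8.0
    cvd_spending_base: float = 400.0
    cvd_spending_peak_age: float = 80.0
    cvd_spending_width: float = 18.0
    gender_mortality_ratio: float = 1.3    # male / female rate multiplier
    population_by_stratum: Mapping[tuple[str, str], float] | float = 1_000.0
    age_groups: Sequence[str] = DEFAULT_AGE_GROUPS
    genders: Sequence[str] = DEFAULT_GENDERS
    closure_age: int = 105
    ttd_horizon: int = 5

    def __post_init__(self) -> None:
        errors = []
        for name in (
            "gompertz_a", "cvd_gompertz_a", "unrelated_cost_base",
            "unrelated_cost_terminal", "cvd_spending_base",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        if self.closure_age < max(age_group_start(a) for a in self.age_groups):
            errors.append("closure_age must cover all start ages")
        if errors:
            raise ValueError("; ".join(errors))


def generate_life_inputs(params: LifeSurfaceParams) -> LifeTableInputs:
    """Tabulate mortality, quality-of-life, cost and population surfaces."""
    start = min(age_group_start(a) for a in params.age_groups)
    ages = np.arange(start, params.closure_age + 1)
    rel = ages - 60.0
    horizon = params.ttd_horizon
    n_cols = horizon + 1  # last column = background (ttd >= horizon)

    decr = np.zeros(n_cols)
    for k, d in enumerate(params.qol_ttd_decrements):
        if k < horizon:
            decr[k] = d

    cvd_mortality, other_mortality, cvd_spending = {}, {}, {}
    qol, unrelated = {}, {}
    for gender in params.genders:
        mult = params.gender_mortality_ratio if gender == params.genders[0] else 1.0
        other_mortality[gender] = params.gompertz_a * np.exp(params.gompertz_b * rel) * mult
        cvd_mortality[gender] = (
            params.cvd_gompertz_a * np.exp(params.cvd_gompertz_b * rel) * mult
        )
        cvd_spending[gender] = params.cvd_spending_base * np.exp(
            -0.5 * ((ages - params.cvd_spending_peak_age) / params.cvd_spending_width) ** 2
        )
        base_q = 1.0 - params.qol_age_slope * rel
        qol[gender] = np.clip(base_q[:, None] - decr[None, :], 0.0, 1.0)
        cost_age = params.unrelated_cost_base * np.exp(params.unrelated_cost_age_rate * rel)
        surf = np.tile(cost_age[:, None], (1, n_cols))
        surf[:, 0] *= params.unrelated_cost_terminal
        unrelated[gender] = np.maximum(surf, 0.0)

    pop_spec = params.population_by_stratum
    population = {}
    for a in params.age_groups:
        for g in params.genders:
            v = pop_spec[(a, g)] if isinstance(pop_spec, Mapping) else float(pop_spec)
            population[(a, g)] = v

    inputs = LifeTableInputs(
        ages=ages,
        genders=tuple(params.genders),
        cvd_mortality=cvd_mortality,
        other_mortality=other_mortality,
        cvd_spending=cvd_spending,
        qol=qol,
        unrelated_cost=unrelated,
        population=population,
        ttd_horizon=horizon,
    )
    inputs.validate()
    return inputs


def params_from_dict(block: Mapping) -> TruePanelParams:
    """Build TruePanelParams from a configuration mapping."""
    kwargs = dict(block)
    if "years" in kwargs:
        kwargs["years"] = tuple(kwargs["years"])
    if "spend_growth" in kwargs and isinstance(kwargs["spend_growth"], Mapping):
        kwargs["spend_growth"] = SpendGrowth(**kwargs["spend_growth"])
    valid = {f.name for f in dataclasses.fields(TruePanelParams)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown panel parameters: {sorted(unknown)}")
    return TruePanelParams(**kwargs)


def life_params_from_dict(block: Mapping) -> LifeSurfaceParams:
    """Build LifeSurfaceParams from a configuration mapping."""
    kwargs = dict(block)
    valid = {f.name for f in dataclasses.fields(LifeSurfaceParams)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown life-surface parameters: {sorted(unknown)}")
    return LifeSurfaceParams(**kwargs)
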