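"""Cohort life-table projection with time-to-death quality of life and costs.

Conventions (each isolated here, configurable where noted):

* annual cycle; the probability of dying within a year with total hazard ``h``
  is ``1 - exp(-h)`` (additive cause-specific hazards);
* a person lives the whole calendar year in which they die;
* at the closure age everyone remaining dies;
* quality-of-life and unrelated-cost surfaces are indexed by (age, time to
  death); times to death at or beyond the horizon use the background column;
* effects are discounted at ``effect_rate``, costs at ``cost_rate``; year 0 is
  undiscounted.

The projection is expressed through death-year weight vectors: for a cohort
starting at a given age, ``w[d]`` is the present value accrued by a person who
dies in projection year ``d``.  Totals are then inner products with the death
year distribution, which makes evaluation over many posterior elasticity draws
a single matrix product (see :mod:`kthresh.threshold`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

ADJUST_MODES = ("constant_elasticity", "linear")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rates for costs and health effects."""

    cost_rate: float = 0.04
    effect_rate: float = 0.015

    def __post_init__(self) -> None:
        if self.cost_rate < 0 or self.effect_rate < 0:
            raise ValueError("discount rates must be >= 0")


def _parse_group_start(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label)
    m = re.match(r"^(\d+)", str(label))
    if not m:
        raise ValueError(f"cannot parse age group label {label!r}")
    return int(m.group(1))


@dataclass
class LifeTableInputs:
    """Mortality, quality-of-life, cost and population surfaces.

    Per gender: 1-D arrays over ``ages`` for CVD mortality, other-cause
    mortality and CVD spending; 2-D arrays ``(n_ages, ttd_horizon + 1)`` for
    quality of life and unrelated cost, whose last column is the background
    used for any time to death >= ``ttd_horizon``.
    """

    ages: np.ndarray
    genders: tuple[str, ...]
    cvd_mortality: dict[str, np.ndarray]
    other_mortality: dict[str, np.ndarray]
    cvd_spending: dict[str, np.ndarray]
    qol: dict[str, np.ndarray]
    unrelated_cost: dict[str, np.ndarray]
    population: dict[tuple[str, str], float] = field(default_factory=dict)
    ttd_horizon: int = 5

    @property
    def closure_age(self) -> int:
        return int(self.ages[-1])

    def validate(self) -> None:
        ages = np.asarray(self.ages)
        if len(ages) < 1 or np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive single years")
        n = len(ages)
        n_cols = self.ttd_horizon + 1
        for g in self.genders:
            for name, arr in (
                ("cvd_mortality", self.cvd_mortality[g]),
                ("other_mortality", self.other_mortality[g]),
                ("cvd_spending", self.cvd_spending[g]),
            ):
                if arr.shape != (n,):
                    raise ValueError(f"{name}[{g}] must have shape ({n},)")
                if np.any(arr < 0):
                    raise ValueError(f"{name}[{g}] has negative values")
            for name, arr in (("qol", self.qol[g]), ("unrelated_cost", self.unrelated_cost[g])):
                if arr.shape != (n, n_cols):
                    raise ValueError(f"{name}[{g}] must have shape ({n}, {n_cols})")
            if np.any(self.qol[g] < 0) or np.any(self.qol[g] > 1):
                raise ValueError(f"qol[{g}] outside [0, 1]")
            if np.any(self.unrelated_cost[g] < 0):
                raise ValueError(f"unrelated_cost[{g}] has negative values")
        for (group, gender), pop in self.population.items():
            if pop < 0:
                raise ValueError(f"population for ({group}, {gender}) is negative")
            if _parse_group_start(group) > self.closure_age:
                raise ValueError(f"start group {group} beyond closure age")

    def age_index(self, age: int) -> int:
        i = int(age) - int(self.ages[0])
        if not 0 <= i < len(self.ages):
            raise ValueError(f"age {age} outside table range {self.ages[0]}..{self.ages[-1]}")
        return i

    def same_grid(self, other: "LifeTableInputs") -> bool:
        return (
            np.array_equal(self.ages, other.ages)
            and self.genders == other.genders
            and self.ttd_horizon == other.ttd_horizon
        )

    # ---- delimited text round-trip -------------------------------------
    def to_tables(self) -> dict[str, pd.DataFrame]:
        rate_rows, surf_rows, pop_rows = [], [], []
        for g in self.genders:
            for i, age in enumerate(self.ages):
                rate_rows.append(
                    (int(age), g, self.cvd_mortality[g][i], self.other_mortality[g][i],
                     self.cvd_spending[g][i])
                )
                for ttd in range(self.ttd_horizon + 1):
                    surf_rows.append(
                        (int(age), g, ttd, self.qol[g][i, ttd], self.unrelated_cost[g][i, ttd])
                    )
        for (group, gender), pop in self.population.items():
            pop_rows.append((group, gender, pop))
        return {
            "rates": pd.DataFrame(
                rate_rows,
                columns=["age", "gender", "cvd_mortality", "other_mortality", "cvd_spending"],
            ),
            "surfaces": pd.DataFrame(
                surf_rows, columns=["age", "gender", "time_to_death", "qol", "unrelated_cost"]
            ),
            "population": pd.DataFrame(
                pop_rows, columns=["age_group", "gender", "population"]
            ),
        }

    @classmethod
    def from_tables(
        cls,
        rates: pd.DataFrame,
        surfaces: pd.DataFrame,
        population: pd.DataFrame,
    ) -> "LifeTableInputs":
        genders = tuple(pd.unique(rates["gender"]))
        ages = np.sort(pd.unique(rates["age"]).astype(int))
        horizon = int(surfaces["time_to_death"].max())
        n = len(ages)
        cvd_m, oth_m, cvd_s, qol, unrel = {}, {}, {}, {}, {}
        for g in genders:
            sub = rates[rates["gender"] == g].sort_values("age")
            if len(sub) != n:
                raise ValueError(f"rates table incomplete for gender {g}")
            cvd_m[g] = sub["cvd_mortality"].to_numpy(float)
            oth_m[g] = sub["other_mortality"].to_numpy(float)
            cvd_s[g] = sub["cvd_spending"].to_numpy(float)
            ssub = surfaces[surfaces["gender"] == g]
            q = np.full((n, horizon + 1), np.nan)
            u = np.full((n, horizon + 1), np.nan)
            ai = ssub["age"].to_numpy(int) - int(ages[0])
            ti = ssub["time_to_death"].to_numpy(int)
            q[ai, ti] = ssub["qol"].to_numpy(float)
            u[ai, ti] = ssub["unrelated_cost"].to_numpy(float)
            if np.any(np.isnan(q)) or np.any(np.isnan(u)):
                miss = np.argwhere(np.isnan(q))
                age, ttd = int(ages[miss[0, 0]]), int(miss[0, 1])
                raise ValueError(f"missing surface cell at (age={age}, ttd={ttd})")
            qol[g], unrel[g] = q, u
        pop = {
            (row.age_group, row.gender): float(row.population)
            for row in population.itertuples()
        }
        obj = cls(
            ages=ages, genders=genders, cvd_mortality=cvd_m, other_mortality=oth_m,
            cvd_spending=cvd_s, qol=qol, unrelated_cost=unrel, population=pop,
            ttd_horizon=horizon,
        )
        obj.validate()
        return obj

    def write_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        for name, df in self.to_tables().items():
            df.to_csv(p / f"{name}.csv", index=False)

    @classmethod
    def read_dir(cls, path) -> "LifeTableInputs":
        from pathlib import Path

        p = Path(path)
        return cls.from_tables(
            pd.read_csv(p / "rates.csv"),
            pd.read_csv(p / "surfaces.csv"),
            pd.read_csv(p / "population.csv"),
        )


@dataclass
class CohortProjection:
    """Per-year survivorship and discounted lifetime totals for one cohort."""

    start_age: int
    gender: str
    survival: np.ndarray       # P(alive at start of projection year y)
    death_prob: np.ndarray     # P(death occurs in projection year y)
    qalys: float
    life_years: float
    cvd_cost: float
    unrelated_cost: float

    @property
    def total_cost(self) -> float:
        return self.cvd_cost + self.unrelated_cost

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": np.arange(len(self.survival)),
                "age": self.start_age + np.arange(len(self.survival)),
                "survival": self.survival,
                "death_prob": self.death_prob,
            }
        )


@dataclass
class ScenarioDelta:
    """Population-weighted incremental discounted totals between two scenarios."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    elasticity_used: float


def adjust_mortality(
    cvd_mortality,
    spend_multiplier: float,
    elasticity: float,
    mode: str = "constant_elasticity",
):
    """Adjust a CVD mortality rate for a proportional spending change.

    Default is the constant-elasticity reading ``rate * multiplier**elasticity``;
    the ``linear`` mode applies ``rate * (1 + 0.9*elasticity*(multiplier-1))``.
    """
    rate = np.asarray(cvd_mortality, dtype=float)
    if np.any(rate < 0):
        raise ValueError("cvd_mortality must be >= 0")
    if spend_multiplier <= 0:
        raise ValueError("spend_multiplier must be > 0")
    if mode == "constant_elasticity":
        out = rate * spend_multiplier ** elasticity
    elif mode == "linear":
        factor = 1.0 + 0.9 * elasticity * (spend_multiplier - 1.0)
        if factor < 0:
            raise ValueError(
                f"linear adjustment factor {factor:.4f} < 0 yields a negative rate"
            )
        out = rate * factor
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}; choose from {ADJUST_MODES}")
    return out if out.ndim else float(out)


def _discount_factors(n: int, rate: float) -> np.ndarray:
    return (1.0 + rate) ** -np.arange(n)


def _path_arrays(inputs: LifeTableInputs, gender: str, start_age: int):
    i0 = inputs.age_index(start_age)
    sl = slice(i0, len(inputs.ages))
    return (
        inputs.cvd_mortality[gender][sl],
        inputs.other_mortality[gender][sl],
        inputs.cvd_spending[gender][sl],
        inputs.qol[gender][sl],
        inputs.unrelated_cost[gender][sl],
    )


def death_year_weights(
    inputs: LifeTableInputs,
    gender: str,
    start_age: int,
    discounts: DiscountSpec,
    cvd_spending_override: np.ndarray | None = None,
):
    """Present value accrued per death year d, for QALYs / LYs / costs.

    Returns ``(w_qaly, w_ly, w_cvd_cost, w_unrelated_cost)``, each of length
    ``n = closure_age - start_age + 1``; ``w[d]`` is the total discounted value
    for a person who dies in projection year ``d`` (living years 0..d).
    """
    cvd_m, _, cvd_s, qol, unrel = _path_arrays(inputs, gender, start_age)
    if cvd_spending_override is not None:
        cvd_s = np.asarray(cvd_spending_override, dtype=float)
        if cvd_s.shape != cvd_m.shape:
            raise ValueError("cvd_spending_override has wrong length")
    n = len(cvd_m)
    disc_e = _discount_factors(n, discounts.effect_rate)
    disc_c = _discount_factors(n, discounts.cost_rate)

    y = np.arange(n)[:, None]
    d = np.arange(n)[None, :]
    lived = d >= y
    ttd = np.clip(d - y, 0, inputs.ttd_horizon)
    rows = np.broadcast_to(y, (n, n))

    q_mat = qol[rows, ttd] * disc_e[:, None] * lived
    u_mat = unrel[rows, ttd] * disc_c[:, None] * lived
    c_mat = (cvd_s[:, None] * disc_c[:, None]) * lived
    ly_mat = disc_e[:, None] * lived

    return q_mat.sum(axis=0), ly_mat.sum(axis=0), c_mat.sum(axis=0), u_mat.sum(axis=0)


def death_year_distribution(cvd_rates, other_rates):
    """Survival, in-year death probability and death-year distribution.

    Accepts 1-D arrays ``(n,)`` or batched 2-D arrays ``(k, n)`` of rates over
    the projection years; the closure year forces death.  Returns
    ``(survival, q, p_death)`` with the same leading shape.
    """
    hazard = np.asarray(cvd_rates, dtype=float) + np.asarray(other_rates, dtype=float)
    q = 1.0 - np.exp(-hazard)
    q = np.array(q, copy=True)
    q[..., -1] = 1.0
    one_minus = 1.0 - q
    surv = np.ones_like(q)
    surv[..., 1:] = np.cumprod(one_minus[..., :-1], axis=-1)
    p_death = surv * q
    return surv, q, p_death


def project_cohort(
    inputs: LifeTableInputs,
    start_age_group,
    gender: str,
    discounts: DiscountSpec,
    cvd_mortality_override: np.ndarray | None = None,
    cvd_spending_override: np.ndarray | None = None,
) -> CohortProjection:
    """Project one cohort from its start age to closure, accumulating
    discounted QALYs, life years, CVD spending and unrelated costs."""
    start_age = _parse_group_start(start_age_group)
    cvd_m, oth_m, _, _, _ = _path_arrays(inputs, gender, start_age)
    if cvd_mortality_override is not None:
        cvd_m = np.asarray(cvd_mortality_override, dtype=float)
        if cvd_m.shape != oth_m.shape:
            raise ValueError("cvd_mortality_override has wrong length")
    w_q, w_ly, w_c, w_u = death_year_weights(
        inputs, gender, start_age, discounts, cvd_spending_override
    )
    surv, _, p_death = death_year_distribution(cvd_m, oth_m)
    return CohortProjection(
        start_age=start_age,
        gender=gender,
        survival=surv,
        death_prob=p_death,
        qalys=float(p_death @ w_q),
        life_years=float(p_death @ w_ly),
        cvd_cost=float(p_death @ w_c),
        unrelated_cost=float(p_death @ w_u),
    )


def scenario_delta(
    inputs: LifeTableInputs,
    elasticity: float,
    spend_increase: float = 0.10,
    discounts: DiscountSpec = DiscountSpec(),
    mode: str = "constant_elasticity",
) -> ScenarioDelta:
    """Incremental discounted totals of a proportional CVD spending increase.

    Baseline cohorts are projected per start age group and gender; the
    alternative scales CVD spending by ``1 + spend_increase`` and adjusts CVD
    mortality via :func:`adjust_mortality`.  Deltas are aggregated with
    population weights; unrelated costs in added years are included.
    """
    mult = 1.0 + spend_increase
    d_cost = d_qaly = d_ly = 0.0
    if not inputs.population:
        raise ValueError("inputs carry no population weights")
    for (group, gender), pop in inputs.population.items():
        if pop == 0:
            continue
        start_age = _parse_group_start(group)
        cvd_m, _, cvd_s, _, _ = _path_arrays(inputs, gender, start_age)
        base = project_cohort(inputs, start_age, gender, discounts)
        alt = project_cohort(
            inputs,
            start_age,
            gender,
            discounts,
            cvd_mortality_override=adjust_mortality(cvd_m, mult, elasticity, mode),
            cvd_spending_override=cvd_s * mult,
        )
        d_cost += pop * (alt.total_cost - base.total_cost)
        d_qaly += pop * (alt.qalys - base.qalys)
        d_ly += pop * (alt.life_years - base.life_years)
    return ScenarioDelta(d_cost, d_qaly, d_ly, elasticity)


def compare_states(
    inputs_baseline: LifeTableInputs,
    inputs_alternative: LifeTableInputs,
    discounts: DiscountSpec = DiscountSpec(),
) -> ScenarioDelta:
    """Incremental totals between two observed states (same grid required).

    Population weights are taken from the baseline inputs.  The elasticity
    field of the result is NaN: no elasticity is involved.
    """
    if not inputs_baseline.same_grid(inputs_alternative):
        raise ValueError("life-table inputs are on different age/gender grids")
    d_cost = d_qaly = d_ly = 0.0
    for (group, gender), pop in inputs_baseline.population.items():
        if pop == 0:
            continue
        base = project_cohort(inputs_baseline, group, gender, discounts)
        alt = project_cohort(inputs_alternative, group, gender, discounts)
        d_cost += pop * (alt.total_cost - base.total_cost)
        d_qaly += pop * (alt.qalys - base.qalys)
        d_ly += pop * (alt.life_years - base.life_years)
    return ScenarioDelta(d_cost, d_qaly, d_ly, float("nan"))
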