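"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results with naive enumeration or
closed forms so the streamlined implementations are checked against an
independent computation path.
"""

from __future__ import annotations

import numpy as np
import pytest

from kthresh import DiscountSpec, LifeTableInputs, TruePanelParams, generate_panel
from kthresh.synthetic import SpendGrowth


@pytest.fixture(scope="session")
def paper_dims_panel():
    """One fixed synthetic panel at the reference dimensions (16 strata x 17 y)."""
    params = TruePanelParams(seed=20240901)
    return generate_panel(params)


def make_toy_inputs(
    n_ages: int = 3,
    start_age: int = 60,
    cvd=0.05,
    other=0.10,
    spending=100.0,
    qol_flat: bool = True,
    horizon: int = 2,
    unrelated=50.0,
    terminal_mult: float = 1.0,
    genders=("female",),
    population=None,
) -> LifeTableInputs:
    """Small hand-sized life-table inputs for enumeration oracles."""
    ages = np.arange(start_age, start_age + n_ages)
    n = n_ages
    cvd_m, oth_m, cvd_s, qol, unrel = {}, {}, {}, {}, {}
    rng = np.random.default_rng(123)
    for g in genders:
        cvd_m[g] = np.full(n, float(cvd))
        oth_m[g] = np.full(n, float(other))
        cvd_s[g] = np.full(n, float(spending))
        if qol_flat:
            qol[g] = np.ones((n, horizon + 1))
        else:
            qol[g] = np.clip(
                0.9 - 0.05 * np.arange(n)[:, None] - 0.1 * (horizon - np.arange(horizon + 1))[None, :] / horizon,
                0.0, 1.0,
            )
        u = np.full((n, horizon + 1), float(unrelated))
        u[:, 0] *= terminal_mult
        unrel[g] = u
    if population is None:
        population = {(str(start_age), g): 1.0 for g in genders}
    inputs = LifeTableInputs(
        ages=ages, genders=tuple(genders), cvd_mortality=cvd_m, other_mortality=oth_m,
        cvd_spending=cvd_s, qol=qol, unrelated_cost=unrel, population=population,
        ttd_horizon=horizon,
    )
    inputs.validate()
    return inputs


def brute_force_projection(
    inputs: LifeTableInputs,
    gender: str,
    start_age: int,
    discounts: DiscountSpec,
    cvd_override=None,
    spending_override=None,
):
    """Exhaustive enumeration over death years, in plain Python loops.

    Returns dict with qalys, life_years, cvd_cost, unrelated_cost.
    """
    i0 = int(start_age) - int(inputs.ages[0])
    n = len(inputs.ages) - i0
    cvd = list(inputs.cvd_mortality[gender][i0:])
    if cvd_override is not None:
        cvd = list(cvd_override)
    oth = list(inputs.other_mortality[gender][i0:])
    spend = list(inputs.cvd_spending[gender][i0:])
    if spending_override is not None:
        spend = list(spending_override)
    qol = inputs.qol[gender][i0:]
    unrel = inputs.unrelated_cost[gender][i0:]
    H = inputs.ttd_horizon

    q = [1.0 - np.exp(-(cvd[y] + oth[y])) for y in range(n)]
    q[n - 1] = 1.0

    totals = {"qalys": 0.0, "life_years": 0.0, "cvd_cost": 0.0, "unrelated_cost": 0.0}
    for d in range(n):
        p = 1.0
        for y in range(d):
            p *= 1.0 - q[y]
        p *= q[d]
        for y in range(d + 1):  # full year lived in year of death
            de = (1.0 + discounts.effect_rate) ** (-y)
            dc = (1.0 + discounts.cost_rate) ** (-y)
            ttd = min(d - y, H)
            totals["qalys"] += p * de * qol[y, ttd]
            totals["life_years"] += p * de
            totals["cvd_cost"] += p * dc * spend[y]
            totals["unrelated_cost"] += p * dc * unrel[y, ttd]
    return totals


def conjugate_posterior(X, y, sigma, prior_mean, prior_sd):
    """Closed-form normal posterior for a linear model with known noise sd."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    v0inv = np.diag(1.0 / np.asarray(prior_sd, float) ** 2)
    prec = v0inv + X.T @ X / sigma**2
    cov = np.linalg.inv(prec)
    mean = cov @ (v0inv @ np.asarray(prior_mean, float) + X.T @ y / sigma**2)
    return mean, cov


def quiet_panel_params(**overrides) -> TruePanelParams:
    """Panel params with strong random effects and spending variation, for
    tests that need well-identified, nearly-unshrunk estimates."""
    defaults = dict(
        seed=42,
        sigma_gamma=0.10,
        sigma_tau=0.05,
        spend_growth=SpendGrowth(0.04, 0.10),
    )
    defaults.update(overrides)
    return TruePanelParams(**defaults)
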