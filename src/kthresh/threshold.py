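"""Translate posterior elasticity draws into a cost-per-QALY threshold.

Point estimates and intervals follow the mean-costs-over-mean-effects
convention: the headline ratio divides the mean incremental cost by the mean
incremental QALYs across draws, and the 95% interval evaluates the ratio at
the 0.025 and 0.975 quantiles of the elasticity draws (not at quantiles of
the per-draw ratio).  Percentile intervals of the per-draw ICER are computed
alongside for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lifetable import (
    DiscountSpec,
    LifeTableInputs,
    _parse_group_start,
    adjust_mortality,
    death_year_distribution,
    death_year_weights,
    _path_arrays,
    scenario_delta,
)
from .panel import (
    McmcConfig,
    PriorSpec,
    build_model_frame,
    fit_frequentist,
    fit_mcmc,
    make_prior,
)

SCENARIO_LABELS = (
    "base",
    "prior_gallet",
    "prior_claxton",
    "years_2001_2010",
    "frequentist",
    "no_lag",
)

GALLET_PRIOR = dict(mean=-0.13, ci95=(-0.20, -0.06))
CLAXTON_PRIOR = dict(mean=-1.43, ci95=(-1.86, -1.00))


@dataclass
class DeltaDraws:
    """Per-draw incremental totals for a vector of elasticity draws."""

    elasticities: np.ndarray
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_ly: np.ndarray

    def icers(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.delta_qaly != 0, self.delta_cost / self.delta_qaly, np.nan)


def batched_deltas(
    inputs: LifeTableInputs,
    elasticities,
    spend_increase: float = 0.10,
    discounts: DiscountSpec = DiscountSpec(),
    mode: str = "constant_elasticity",
) -> DeltaDraws:
    """Vectorized scenario deltas: one spending-increase experiment per draw.

    Equivalent to calling :func:`kthresh.lifetable.scenario_delta` per draw;
    the death-year weight vectors per cohort are shared across draws so the
    whole batch reduces to a few matrix products.
    """
    e = np.asarray(elasticities, dtype=float).reshape(-1)
    if e.size == 0:
        raise ValueError("need at least one elasticity draw")
    mult = 1.0 + spend_increase
    if mode == "constant_elasticity":
        factors = mult ** e
    elif mode == "linear":
        factors = 1.0 + 0.9 * e * (mult - 1.0)
        if np.any(factors < 0):
            raise ValueError("linear adjustment yields a negative mortality rate")
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")

    d_cost = np.zeros_like(e)
    d_qaly = np.zeros_like(e)
    d_ly = np.zeros_like(e)
    if not inputs.population:
        raise ValueError("inputs carry no population weights")
    for (group, gender), pop in inputs.population.items():
        if pop == 0:
            continue
        start_age = _parse_group_start(group)
        cvd_m, oth_m, cvd_s, _, _ = _path_arrays(inputs, gender, start_age)
        w_q, w_ly, w_c, w_u = death_year_weights(inputs, gender, start_age, discounts)
        w_qb, w_lyb, w_cb, w_ub = w_q, w_ly, w_c * mult, w_u  # alt CVD cost scales
        _, _, p_base = death_year_distribution(cvd_m, oth_m)
        base_q = p_base @ w_q
        base_ly = p_base @ w_ly
        base_cost = p_base @ (w_c + w_u)
        alt_rates = cvd_m[None, :] * factors[:, None]
        _, _, p_alt = death_year_distribution(alt_rates, oth_m[None, :])
        d_qaly += pop * (p_alt @ w_qb - base_q)
        d_ly += pop * (p_alt @ w_lyb - base_ly)
        d_cost += pop * (p_alt @ (w_cb + w_ub) - base_cost)
    return DeltaDraws(e, d_cost, d_qaly, d_ly)


@dataclass
class ThresholdSummary:
    cost_per_qaly: float
    cost_per_ly: float
    ci95_qaly: tuple[float, float]
    ci95_ly: tuple[float, float]
    n_draws: int
    share_nonpositive_dqaly: float
    undefined: bool = False
    icer_percentile_ci: tuple[float, float] = (float("nan"), float("nan"))
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cost_per_qaly": self.cost_per_qaly,
            "cost_per_ly": self.cost_per_ly,
            "ci95_qaly": list(self.ci95_qaly),
            "ci95_ly": list(self.ci95_ly),
            "n_draws": self.n_draws,
            "share_nonpositive_dqaly": self.share_nonpositive_dqaly,
            "undefined": self.undefined,
            "icer_percentile_ci": list(self.icer_percentile_ci),
            "notes": self.notes,
        }


def _ratio_at_quantile(
    inputs, q_elast, spend_increase, discounts, mode
) -> tuple[float, float]:
    d = scenario_delta(inputs, float(q_elast), spend_increase, discounts, mode)
    cq = d.delta_cost / d.delta_qaly if d.delta_qaly != 0 else float("nan")
    cl = d.delta_cost / d.delta_ly if d.delta_ly != 0 else float("nan")
    return cq, cl


def summarize_threshold(
    draw_elasticities,
    inputs: LifeTableInputs,
    spend_increase: float = 0.10,
    discounts: DiscountSpec = DiscountSpec(),
    mode: str = "constant_elasticity",
) -> ThresholdSummary:
    """Point estimate and 95% interval of euros per QALY (and per life year).

    Point estimate: mean incremental cost over mean incremental QALYs across
    draws.  Interval: the ratio evaluated at the 0.025/0.975 quantiles of the
    elasticity draws, reported in ascending order when both are defined.
    """
    deltas = batched_deltas(inputs, draw_elasticities, spend_increase, discounts, mode)
    n = deltas.elasticities.size
    share_np = float(np.mean(deltas.delta_qaly <= 0))
    notes: list[str] = []

    mean_dc = float(deltas.delta_cost.mean())
    mean_dq = float(deltas.delta_qaly.mean())
    mean_dly = float(deltas.delta_ly.mean())
    undefined = mean_dq <= 0
    if undefined:
        notes.append("mean incremental QALYs <= 0: cost per QALY undefined")
        warnings.warn(notes[-1])
        cpq = float("nan")
    else:
        cpq = mean_dc / mean_dq
    cpl = mean_dc / mean_dly if mean_dly > 0 else float("nan")

    q_lo, q_hi = np.quantile(deltas.elasticities, [0.025, 0.975])
    cq_lo, cl_lo = _ratio_at_quantile(inputs, q_lo, spend_increase, discounts, mode)
    cq_hi, cl_hi = _ratio_at_quantile(inputs, q_hi, spend_increase, discounts, mode)
    ci_q = (cq_lo, cq_hi)
    ci_l = (cl_lo, cl_hi)
    if np.isfinite(ci_q).all() and cq_lo > 0 and cq_hi > 0:
        ci_q = tuple(sorted(ci_q))
    if np.isfinite(ci_l).all() and cl_lo > 0 and cl_hi > 0:
        ci_l = tuple(sorted(ci_l))

    pos = deltas.delta_qaly > 0
    if pos.any():
        icer_ci = tuple(np.quantile(deltas.icers()[pos], [0.025, 0.975]))
    else:
        icer_ci = (float("nan"), float("nan"))

    return ThresholdSummary(
        cost_per_qaly=cpq,
        cost_per_ly=cpl,
        ci95_qaly=ci_q,
        ci95_ly=ci_l,
        n_draws=n,
        share_nonpositive_dqaly=share_np,
        undefined=undefined,
        icer_percentile_ci=icer_ci,
        notes=notes,
    )


@dataclass
class ProbabilityCurve:
    values: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "probability": self.probability})


def probability_below(
    draw_elasticities,
    inputs: LifeTableInputs,
    spend_increase: float = 0.10,
    discounts: DiscountSpec = DiscountSpec(),
    grid=None,
    mode: str = "constant_elasticity",
) -> ProbabilityCurve:
    """P(threshold <= x) for each x in a sorted monetary grid.

    Per draw, ICER = delta cost / delta QALYs; draws whose incremental QALYs
    are non-positive never count as below any finite value.
    """
    if grid is None or len(grid) == 0:
        raise ValueError("grid must be a non-empty ascending sequence")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    deltas = batched_deltas(inputs, draw_elasticities, spend_increase, discounts, mode)
    n = deltas.elasticities.size
    pos = deltas.delta_qaly > 0
    icers = np.sort(deltas.icers()[pos])
    prob = np.searchsorted(icers, grid, side="right") / n
    return ProbabilityCurve(values=grid, probability=prob)


# --------------------------------------------------------------------------
# scenario battery
# --------------------------------------------------------------------------

def run_scenarios(
    panel: pd.DataFrame,
    inputs: LifeTableInputs,
    battery,
    config: McmcConfig,
    discounts: DiscountSpec = DiscountSpec(),
    spend_increase: float = 0.10,
    mode: str = "constant_elasticity",
    base_priors: PriorSpec | None = None,
    year_min: int | None = None,
    year_max: int | None = None,
    subset_years: tuple[int, int] = (2001, 2010),
    n_freq_draws: int = 10_000,
    return_details: bool = False,
):
    """Fit each scenario in ``battery`` and translate it to threshold rows.

    Returns a report DataFrame (one row per scenario with posterior summaries
    of alpha, beta, their sum, and costs per QALY / life year), and optionally
    a per-scenario details dict with draws, diagnostics, summaries and deltas.
    """
    unknown = [s for s in battery if s not in SCENARIO_LABELS]
    if unknown:
        raise ValueError(f"unknown scenario labels {unknown}; choose from {SCENARIO_LABELS}")
    base_priors = base_priors or make_prior("vague")
    frame_full = build_model_frame(panel, year_min, year_max)

    rows = []
    details: dict[str, dict] = {}
    for label in battery:
        frame = frame_full
        priors = base_priors
        include_lag = True
        if label == "prior_gallet":
            priors = make_prior("elasticity_interval", **GALLET_PRIOR)
        elif label == "prior_claxton":
            priors = make_prior("elasticity_interval", **CLAXTON_PRIOR)
        elif label == "years_2001_2010":
            frame = build_model_frame(panel, subset_years[0], subset_years[1])
        elif label == "no_lag":
            include_lag = False

        if label == "frequentist":
            fit = fit_frequentist(frame_full, include_lag=True)
            idx = ["dlog_c", "dlog_c_lag"]
            mean_ab = fit.params[idx].to_numpy()
            cov_ab = fit.cov.loc[idx, idx].to_numpy()
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
            samples = rng.multivariate_normal(mean_ab, cov_ab, size=n_freq_draws)
            alpha_d, beta_d = samples[:, 0], samples[:, 1]
            elast_d = alpha_d + beta_d
            stats = {
                "alpha": _stat_triplet(alpha_d),
                "beta": _stat_triplet(beta_d),
                "elasticity": _stat_triplet(elast_d),
            }
            detail: dict = {"fit": fit, "elasticity_draws": elast_d}
        else:
            draws, diag = fit_mcmc(frame, priors, config, include_lag=include_lag)
            elast_d = draws.elasticity_draws()
            stats = {
                "alpha": _stat_triplet(draws.flat("alpha")),
                "elasticity": _stat_triplet(elast_d),
            }
            if include_lag:
                stats["beta"] = _stat_triplet(draws.flat("beta"))
            else:
                stats["beta"] = (float("nan"), float("nan"), float("nan"))
            detail = {"draws": draws, "diagnostics": diag, "elasticity_draws": elast_d}

        summary = summarize_threshold(elast_d, inputs, spend_increase, discounts, mode)
        detail["summary"] = summary
        details[label] = detail
        a = stats["alpha"]
        b = stats["beta"]
        s = stats["elasticity"]
        rows.append(
            {
                "scenario": label,
                "alpha_mean": a[0], "alpha_lo": a[1], "alpha_hi": a[2],
                "beta_mean": b[0], "beta_lo": b[1], "beta_hi": b[2],
                "elasticity_mean": s[0], "elasticity_lo": s[1], "elasticity_hi": s[2],
                "cost_per_qaly": summary.cost_per_qaly,
                "cost_per_qaly_lo": summary.ci95_qaly[0],
                "cost_per_qaly_hi": summary.ci95_qaly[1],
                "cost_per_ly": summary.cost_per_ly,
                "cost_per_ly_lo": summary.ci95_ly[0],
                "cost_per_ly_hi": summary.ci95_ly[1],
            }
        )
    report = pd.DataFrame(rows)
    return (report, details) if return_details else report


def _stat_triplet(x: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.quantile(x, [0.025, 0.975])
    return float(np.mean(x)), float(lo), float(hi)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Formatted view: currency rounded to the nearest 100, coefficients to 3 dp."""
    out = report.copy()
    for col in out.columns:
        if col.startswith("cost_per"):
            out[col] = (out[col] / 100.0).round() * 100.0
        elif col != "scenario":
            out[col] = out[col].round(3)
    return out


# --------------------------------------------------------------------------
# life-expectancy attribution
# --------------------------------------------------------------------------

def _expand_group_rates(panel_sub: pd.DataFrame, inputs, gender, value_col):
    """Per-age values over the input grid from group-level panel values."""
    groups = panel_sub[panel_sub["gender"] == gender]
    starts = sorted(
        (_parse_group_start(g), g) for g in groups["age_group"].unique()
    )
    values = dict(zip(groups["age_group"], groups[value_col]))
    out = np.empty(len(inputs.ages))
    for i, age in enumerate(inputs.ages):
        label = None
        for s, g in starts:
            if age >= s:
                label = g
        if label is None:
            out[i] = np.nan
        else:
            out[i] = values[label]
    return out


def attribute_le_gain(
    panel: pd.DataFrame,
    inputs: LifeTableInputs,
    elasticity: float,
    reference_age: int = 65,
    mode: str = "constant_elasticity",
) -> float:
    """Share of the observed life-expectancy gain attributable to spending.

    Numerator: undiscounted life-expectancy gain at ``reference_age`` when the
    first-year CVD mortality is reduced only by the spending-attributable part
    (elasticity applied to the observed spending change per stratum);
    denominator: gain under the full observed CVD mortality change.
    Other-cause mortality comes from ``inputs`` and is held fixed.
    """
    years = sorted(panel["year"].unique())
    if len(years) < 2:
        raise ValueError("panel must span at least 2 years")
    first = panel[panel["year"] == years[0]]
    last = panel[panel["year"] == years[-1]]

    i0 = inputs.age_index(reference_age)
    num = den = 0.0
    weight_total = 0.0
    for gender in inputs.genders:
        m_first = _expand_group_rates(first, inputs, gender, "mortality_rate")
        m_last = _expand_group_rates(last, inputs, gender, "mortality_rate")
        c_first = _expand_group_rates(first, inputs, gender, "spending")
        c_last = _expand_group_rates(last, inputs, gender, "spending")
        if np.any(np.isnan(m_first[i0:])):
            raise ValueError(f"panel does not cover ages from {reference_age} for {gender}")
        mult = c_last / c_first
        m_attr = np.array(
            [
                adjust_mortality(m, mu_, elasticity, mode)
                for m, mu_ in zip(m_first[i0:], mult[i0:])
            ]
        )
        oth = inputs.other_mortality[gender][i0:]

        def le(cvd):
            surv, _, _ = death_year_distribution(cvd, oth)
            return float(surv.sum())

        le_base = le(m_first[i0:])
        le_full = le(m_last[i0:])
        le_attr = le(m_attr)
        w = sum(
            pop for (g, gen), pop in inputs.population.items() if gen == gender
        ) or 1.0
        num += w * (le_attr - le_base)
        den += w * (le_full - le_base)
        weight_total += w
    if den == 0:
        raise ValueError("observed life-expectancy gain is zero: attribution undefined")
    return num / den
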