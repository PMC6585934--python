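"""Run configuration: loading, validation, defaults and the pipeline driver.

Defaults: 3 chains of 75,000 MCMC iterations with 25,000 burn-in and thinning
by 4; 4% / 1.5% discounting of costs / effects; a 10% spending increase.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lifetable, synthetic, threshold as threshold_mod
from .lifetable import DiscountSpec, LifeTableInputs
from .panel import McmcConfig, PosteriorDraws, build_model_frame, fit_mcmc, make_prior

log = logging.getLogger("kthresh")

ALL_STAGES = ("simulate", "fit", "translate", "report")

_TOP_KEYS = {
    "seed", "output_dir", "panel", "life_inputs", "prior", "mcmc", "discounts",
    "spend_increase", "mortality_adjustment", "scenarios", "year_min",
    "year_max", "verbosity", "curve_grid",
}


class ConfigError(ValueError):
    """Carries every validation violation found in a config file."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in self.violations))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("kthresh_out")
    panel_path: Path | None = None
    panel_synthetic: dict | None = None
    life_path: Path | None = None
    life_synthetic: dict | None = None
    prior_style: str = "vague"
    prior_mean: float | None = None
    prior_ci95: tuple[float, float] | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    discounts: DiscountSpec = field(default_factory=DiscountSpec)
    spend_increase: float = 0.10
    mortality_adjustment: str = "constant_elasticity"
    scenarios: tuple[str, ...] = ("base",)
    year_min: int | None = None
    year_max: int | None = None
    verbosity: str = "info"
    curve_grid: tuple[float, float, int] = (0.0, 200_000.0, 201)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "panel": (
                {"path": str(self.panel_path)}
                if self.panel_path is not None
                else {"synthetic": self.panel_synthetic or {}}
            ),
            "life_inputs": (
                {"path": str(self.life_path)}
                if self.life_path is not None
                else {"synthetic": self.life_synthetic or {}}
            ),
            "prior": {
                "style": self.prior_style,
                "mean": self.prior_mean,
                "ci95": list(self.prior_ci95) if self.prior_ci95 else None,
            },
            "mcmc": {
                "n_chains": self.mcmc.n_chains,
                "n_iter": self.mcmc.n_iter,
                "burn_in": self.mcmc.burn_in,
                "thin": self.mcmc.thin,
                "init_dispersion": self.mcmc.init_dispersion,
            },
            "discounts": {
                "cost_rate": self.discounts.cost_rate,
                "effect_rate": self.discounts.effect_rate,
            },
            "spend_increase": self.spend_increase,
            "mortality_adjustment": self.mortality_adjustment,
            "scenarios": list(self.scenarios),
            "year_min": self.year_min,
            "year_max": self.year_max,
            "verbosity": self.verbosity,
            "curve_grid": list(self.curve_grid),
        }

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def prior_spec(self):
        if self.prior_style == "vague":
            return make_prior("vague")
        return make_prior(self.prior_style, self.prior_mean, self.prior_ci95)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults.

    All violations are collected and reported together in a single
    :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    violations: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        violations.append(f"unknown keys: {sorted(unknown)}")

    def _input_block(name):
        block = raw.get(name)
        if block is None:
            violations.append(f"missing required block {name!r}")
            return None, None
        if not isinstance(block, dict):
            violations.append(f"{name} must be a mapping with 'path' or 'synthetic'")
            return None, None
        has_path = "path" in block and block["path"] is not None
        has_syn = "synthetic" in block and block["synthetic"] is not None
        extra = set(block) - {"path", "synthetic"}
        if extra:
            violations.append(f"{name}: unknown keys {sorted(extra)}")
        if has_path == has_syn:
            violations.append(
                f"{name}: exactly one of 'path' or 'synthetic' must be given"
            )
            return None, None
        if has_path:
            return Path(block["path"]), None
        syn = dict(block["synthetic"]) if isinstance(block["synthetic"], dict) else {}
        if not isinstance(block["synthetic"], dict):
            violations.append(f"{name}.synthetic must be a mapping")
        return None, syn

    panel_path, panel_syn = _input_block("panel")
    life_path, life_syn = _input_block("life_inputs")

    seed = raw.get("seed")
    if seed is None:
        violations.append("seed is required (stochastic stages must be reproducible)")
        seed = 0
    elif not isinstance(seed, int):
        violations.append(f"seed must be an integer, got {seed!r}")
        seed = 0

    mcmc_raw = raw.get("mcmc") or {}
    mcmc = McmcConfig(seed=seed)
    try:
        mcmc = McmcConfig(
            n_chains=int(mcmc_raw.get("n_chains", 3)),
            n_iter=int(mcmc_raw.get("n_iter", 75_000)),
            burn_in=int(mcmc_raw.get("burn_in", 25_000)),
            thin=int(mcmc_raw.get("thin", 4)),
            seed=seed,
            init_dispersion=float(mcmc_raw.get("init_dispersion", 0.25)),
        )
    except (ValueError, TypeError) as exc:
        violations.append(f"mcmc: {exc}")

    disc_raw = raw.get("discounts") or {}
    discounts = DiscountSpec()
    try:
        discounts = DiscountSpec(
            cost_rate=float(disc_raw.get("cost_rate", 0.04)),
            effect_rate=float(disc_raw.get("effect_rate", 0.015)),
        )
    except (ValueError, TypeError) as exc:
        violations.append(f"discounts: {exc}")

    prior_raw = raw.get("prior") or {}
    prior_style = prior_raw.get("style", "vague")
    prior_mean = prior_raw.get("mean")
    prior_ci95 = prior_raw.get("ci95")
    if prior_ci95 is not None:
        prior_ci95 = tuple(float(v) for v in prior_ci95)
    if prior_style not in ("vague", "elasticity_interval"):
        violations.append(f"prior.style must be vague|elasticity_interval, got {prior_style!r}")
    elif prior_style == "elasticity_interval":
        if prior_mean is None or prior_ci95 is None:
            violations.append("prior style elasticity_interval needs mean and ci95")
        elif not prior_ci95[0] < prior_ci95[1]:
            violations.append(f"prior.ci95 must satisfy lo < hi, got {prior_ci95}")

    scenarios = tuple(raw.get("scenarios") or ("base",))
    bad = [s for s in scenarios if s not in threshold_mod.SCENARIO_LABELS]
    if bad:
        violations.append(
            f"unknown scenarios {bad}; choose from {list(threshold_mod.SCENARIO_LABELS)}"
        )

    spend_increase = raw.get("spend_increase", 0.10)
    if not isinstance(spend_increase, (int, float)) or spend_increase <= -1:
        violations.append(f"spend_increase must be a number > -1, got {spend_increase!r}")

    adj = raw.get("mortality_adjustment", "constant_elasticity")
    if adj not in lifetable.ADJUST_MODES:
        violations.append(
            f"mortality_adjustment must be one of {lifetable.ADJUST_MODES}, got {adj!r}"
        )

    curve_grid = raw.get("curve_grid") or [0.0, 200_000.0, 201]
    if not (isinstance(curve_grid, (list, tuple)) and len(curve_grid) == 3):
        violations.append("curve_grid must be [start, stop, num]")
        curve_grid = [0.0, 200_000.0, 201]

    verbosity = raw.get("verbosity", "info")
    if verbosity not in ("debug", "info", "warning", "error"):
        violations.append(f"verbosity must be debug|info|warning|error, got {verbosity!r}")

    if panel_syn is not None:
        try:
            synthetic.params_from_dict({**panel_syn, "seed": seed})
        except (ValueError, TypeError) as exc:
            violations.append(f"panel.synthetic: {exc}")
    if life_syn is not None:
        try:
            synthetic.life_params_from_dict(life_syn)
        except (ValueError, TypeError) as exc:
            violations.append(f"life_inputs.synthetic: {exc}")

    if violations:
        raise ConfigError(violations)

    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "kthresh_out")),
        panel_path=panel_path,
        panel_synthetic=panel_syn,
        life_path=life_path,
        life_synthetic=life_syn,
        prior_style=prior_style,
        prior_mean=prior_mean,
        prior_ci95=prior_ci95,
        mcmc=mcmc,
        discounts=discounts,
        spend_increase=float(spend_increase),
        mortality_adjustment=adj,
        scenarios=scenarios,
        year_min=raw.get("year_min"),
        year_max=raw.get("year_max"),
        verbosity=verbosity,
        curve_grid=tuple(curve_grid),
    )


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    panel: pd.DataFrame
    inputs: LifeTableInputs
    frame: pd.DataFrame | None = None
    draws: PosteriorDraws | None = None
    diagnostics: object = None
    summary: object = None
    curve: object = None
    report: pd.DataFrame | None = None
    files: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> PipelineResult:
    """Execute simulate -> fit -> translate -> report, writing artifacts.

    Each requested stage writes its outputs under ``config.output_dir``;
    earlier stages are recomputed in memory (deterministically, from the seed)
    when their artifacts are needed but not on disk.
    """
    logging.basicConfig(level=config.verbosity.upper(), format="%(levelname)s %(message)s")
    stages = tuple(stages)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                timings[name] = dt
                if exc is None:
                    log.info("stage %s: done in %.2fs", name, dt)
                else:
                    log.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, exc) from exc
        return _Ctx()

    # ---- simulate / load inputs ---------------------------------------
    with _stage("simulate"):
        if config.panel_path is not None:
            panel = pd.read_csv(config.panel_path)
            synthetic.validate_panel(panel)
        else:
            params = synthetic.params_from_dict(
                {**config.panel_synthetic, "seed": config.seed}
            )
            sim = synthetic.generate_panel(params)
            panel = sim.panel
            if "simulate" in stages:
                sim.write(outdir / "panel.csv", outdir / "panel_truth.csv")
                files["panel"] = outdir / "panel.csv"
                files["panel_truth"] = outdir / "panel_truth.csv"
        if config.life_path is not None:
            inputs = LifeTableInputs.read_dir(config.life_path)
        else:
            lparams = synthetic.life_params_from_dict(config.life_synthetic)
            inputs = synthetic.generate_life_inputs(lparams)
            if "simulate" in stages:
                inputs.write_dir(outdir / "life_inputs")
                for name in ("rates", "surfaces", "population"):
                    files[f"life_{name}"] = outdir / "life_inputs" / f"{name}.csv"

    result = PipelineResult(panel=panel, inputs=inputs, files=files)
    needs_fit = any(s in stages for s in ("fit", "translate"))
    if not (needs_fit or "report" in stages):
        _write_manifest(config, files, outdir)
        return result

    # ---- fit -----------------------------------------------------------
    with _stage("fit"):
        frame = build_model_frame(panel, config.year_min, config.year_max)
        result.frame = frame
        draws, diag = fit_mcmc(frame, config.prior_spec(), config.mcmc)
        result.draws, result.diagnostics = draws, diag
        if "fit" in stages:
            frame.to_csv(outdir / "model_frame.csv", index=False)
            draws.to_frame().to_csv(outdir / "draws.csv", index=False)
            diag.summary.to_csv(outdir / "diagnostics.csv", index=False)
            diag.autocorr.to_csv(outdir / "autocorrelation.csv", index=False)
            meta = outdir / "run_metadata.txt"
            meta.write_text(
                "".join(
                    f"{k} = {v}\n"
                    for k, v in sorted(_flatten(config.to_dict()).items())
                )
            )
            files.update(
                model_frame=outdir / "model_frame.csv",
                draws=outdir / "draws.csv",
                diagnostics=outdir / "diagnostics.csv",
                autocorrelation=outdir / "autocorrelation.csv",
                run_metadata=meta,
            )

    # ---- translate ------------------------------------------------------
    if any(s in stages for s in ("translate", "report")):
        with _stage("translate"):
            elast = result.draws.elasticity_draws()
            summary = threshold_mod.summarize_threshold(
                elast, inputs, config.spend_increase, config.discounts,
                config.mortality_adjustment,
            )
            result.summary = summary
            deltas = threshold_mod.batched_deltas(
                inputs, elast, config.spend_increase, config.discounts,
                config.mortality_adjustment,
            )
            start, stop, num = config.curve_grid
            grid = np.linspace(float(start), float(stop), int(num))
            curve = threshold_mod.probability_below(
                elast, inputs, config.spend_increase, config.discounts, grid,
                config.mortality_adjustment,
            )
            result.curve = curve
            if "translate" in stages:
                (outdir / "summary.json").write_text(
                    json.dumps(summary.to_dict(), indent=2, sort_keys=True)
                )
                pd.DataFrame(
                    {
                        "elasticity": deltas.elasticities,
                        "delta_cost": deltas.delta_cost,
                        "delta_qaly": deltas.delta_qaly,
                        "delta_ly": deltas.delta_ly,
                        "icer": deltas.icers(),
                    }
                ).to_csv(outdir / "deltas.csv", index=False)
                curve.to_frame().to_csv(outdir / "curve.csv", index=False)
                files.update(
                    summary=outdir / "summary.json",
                    deltas=outdir / "deltas.csv",
                    curve=outdir / "curve.csv",
                )

    # ---- report ---------------------------------------------------------
    if "report" in stages:
        with _stage("report"):
            report = threshold_mod.run_scenarios(
                panel,
                inputs,
                config.scenarios,
                config.mcmc,
                config.discounts,
                config.spend_increase,
                config.mortality_adjustment,
                base_priors=config.prior_spec(),
                year_min=config.year_min,
                year_max=config.year_max,
            )
            result.report = report
            report.to_csv(outdir / "report.csv", index=False)
            threshold_mod.format_report(report).to_csv(
                outdir / "report_formatted.csv", index=False
            )
            files["report"] = outdir / "report.csv"
            files["report_formatted"] = outdir / "report_formatted.csv"

    _write_manifest(config, files, outdir)
    result.files = files
    for name, dt in timings.items():
        log.debug("timing %s: %.2fs", name, dt)
    return result


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def _write_manifest(config: RunConfig, files: dict[str, Path], outdir: Path) -> None:
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "digests": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
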