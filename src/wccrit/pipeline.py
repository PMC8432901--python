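"""Run configuration and the analytic -> simulate -> analyse pipeline.

A :class:`RunConfig` (YAML on disk, strict keys) fixes the model
parameters, engine settings and analysis settings of one reproducible
run.  All randomness flows from the single config seed through a
``numpy.random.SeedSequence`` split, one child stream per stochastic
stage, so stages never share a stream and a fixed seed reproduces the
report bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .avalanches import detect_binned, detect_threshold, fit_power_law, size_duration_scaling
from .correlation import empirical_autocorrelation, fit_correlation_time
from .linear_noise import build_linear_solution, rate_statistics
from .model import MS_TO_HZ, ModelParams, critical_coupling, stable_fixed_point
from .simulate import default_burn_in, gillespie, langevin

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_STAGES = ("analytic", "simulate", "avalanches", "correlate")


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    # model
    w0: float = 0.1
    w_sum: float = 13.8
    alpha: float = 0.1
    beta: float = 1.0
    h: float = 1e-6
    n: int = 10**5
    # engine
    engine: str = "gillespie"  # or "langevin"
    t_max: float = 1e5  # ms
    dt: float = 1e-3  # Langevin step, ms
    dt_sample: float = 1.0  # ms
    seed: int = 0
    burn_in: float | None = None  # ms; None -> 20 * max(tau1, tau2)
    # analysis
    stages: tuple = _STAGES
    deltas: tuple = (1.0, 2.0, 4.0, 8.0, 16.0)  # binned delta sweep, ms
    theta_rule: str = "zero"  # zero | mean | absolute
    theta_value: float = 0.0  # used by the "absolute" rule, ms^-1
    size_def: int = 3
    s_min: float = 10.0
    t_min: float = 10.0  # ms
    gamma_window: tuple = (80.0, 200.0)  # ms
    max_lag: float | None = None  # ms; None -> 10 * tau1
    corr_window: tuple = (0.01, 0.2)
    # output
    out_dir: str | None = None

    def params(self) -> ModelParams:
        return ModelParams.from_balance(
            self.w0, self.w_sum, alpha=self.alpha, beta=self.beta, h=self.h, n=self.n
        )


def load_config(path) -> RunConfig:
    """Read a YAML config; unknown keys are an error, not a silent skip."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("stages", "deltas", "gamma_window", "corr_window"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return a machine-readable report.

    The report embeds the resolved config, the package version, the
    per-stage seeds and wall times.  Any stage failure raises a
    RuntimeError tagged with the stage name; results of stages that
    completed before the failure are not returned.
    """
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    params = config.params()
    children = np.random.SeedSequence(config.seed).spawn(len(_STAGES))
    stage_seed = {
        s: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for s, c in zip(_STAGES, children)
    }
    report: dict = {
        "config": asdict(config),
        "version": __version__,
        "stage_seeds": {s: stage_seed[s] for s in config.stages},
        "timings_s": {},
    }

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        return out

    series = None
    if "analytic" in config.stages:
        def _analytic():
            fp = stable_fixed_point(params)
            block = {
                "w0c": critical_coupling(params),
                "sigma0": fp.sigma0,
                "r0_hz": fp.r0_hz,
                "tau1_ms": fp.tau1,
                "tau2_ms": fp.tau2,
            }
            if fp.tau1 > 0:
                sol = build_linear_solution(params, fp)
                st = rate_statistics(sol)
                block.update(
                    w_ff=sol.w_ff, sigma_rr=st.sigma_rr, fano=st.fano, cv2=st.cv2
                )
            return block
        report["analytic"] = timed("analytic", _analytic)

    if "simulate" in config.stages:
        def _simulate():
            nonlocal series
            burn = config.burn_in if config.burn_in is not None else default_burn_in(params)
            if config.engine == "gillespie":
                series = gillespie(
                    params, config.t_max, stage_seed["simulate"],
                    dt_sample=config.dt_sample, burn_in=burn,
                )
            elif config.engine == "langevin":
                series = langevin(
                    params, config.t_max, stage_seed["simulate"],
                    dt=config.dt, dt_sample=config.dt_sample, burn_in=burn,
                )
            else:
                raise ValueError(f"unknown engine {config.engine!r}")
            return {
                "engine": config.engine,
                "t_max_ms": config.t_max,
                "burn_in_ms": burn,
                "mean_rate_hz": float(series.rate.mean()) * MS_TO_HZ,
            }
        report["simulate"] = timed("simulate", _simulate)

    if "avalanches" in config.stages:
        if series is None:
            raise RuntimeError("stage 'avalanches' needs stage 'simulate'")
        def _avalanches():
            if config.theta_rule == "zero":
                theta = 0.0
            elif config.theta_rule == "mean":
                theta = float(series.rate.mean())
            elif config.theta_rule == "absolute":
                theta = config.theta_value
            else:
                raise ValueError(f"unknown theta rule {config.theta_rule!r}")
            cat = detect_threshold(series, theta, config.size_def)
            out = {"theta_per_ms": theta, "n_avalanches": len(cat)}
            if len(cat) >= 2:
                sfit = fit_power_law(cat.sizes, config.s_min)
                tfit = fit_power_law(cat.durations, config.t_min)
                out["tau_s"] = sfit.exponent
                out["tau_s_stderr"] = sfit.stderr
                out["tau_t"] = tfit.exponent
                out["tau_t_stderr"] = tfit.stderr
            if series.spike_counts is not None:
                binned = detect_binned(series, config.deltas[0], keep_profiles=False)
                try:
                    scal = size_duration_scaling(binned, config.gamma_window)
                    out["gamma"] = scal.gamma
                except ValueError:
                    out["gamma"] = None
            return out
        report["avalanches"] = timed("avalanches", _avalanches)

    if "correlate" in config.stages:
        if series is None:
            raise RuntimeError("stage 'correlate' needs stage 'simulate'")
        def _correlate():
            fp = stable_fixed_point(params)
            max_lag = config.max_lag if config.max_lag is not None else 10.0 * max(fp.tau1, fp.tau2)
            max_lag = min(max_lag, series.duration / 10.0)
            corr = empirical_autocorrelation(series, max_lag)
            out = {"max_lag_ms": max_lag}
            try:
                out["tau_max_ms"] = fit_correlation_time(corr, config.corr_window)
            except ValueError as exc:
                out["tau_max_ms"] = None
                out["fit_note"] = str(exc)
            return out
        report["correlate"] = timed("correlate", _correlate)

    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
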