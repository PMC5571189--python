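"""End-to-end orchestration: generator -> pipelines -> model comparisons.

Each stage is an ordinary function (used directly by the numbered analysis
drivers) and :func:`run_all` chains them under a single seeded
configuration, emitting a machine-readable JSON report.  A stage failure is
recorded and its dependents are skipped; the report is deterministic under
a fixed config + seed apart from the isolated ``timestamps`` block.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import model as M
from . import psp as P
from . import synth as S
from . import upstate as U
from .kuiper import kuiper_test
from .protocols import ProtocolSpec

__all__ = [
    "RunConfig",
    "run_all",
    "protocol_conditions",
    "EXPECTED_SIGNS",
    "stage_generate",
    "stage_psp",
    "stage_upstate",
    "stage_model_protocols",
    "stage_model_surface",
    "stage_discovery",
]

log = logging.getLogger("rstdp")

REPORT_SCHEMA_VERSION = 1

KNOWN_STAGES = ("generate", "psp", "upstate", "model_surface",
                "model_protocols", "discovery")

#: stage -> context keys it needs from earlier stages
_REQUIRES = {"upstate": ("recording",)}


@dataclass
class RunConfig:
    """Configuration for a full orchestrated run."""

    stages: List[str] = field(default_factory=lambda: list(KNOWN_STAGES))
    params: Dict[str, dict] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        unknown = [s for s in self.stages if s not in KNOWN_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# canonical protocol conditions (positive-pairing variants)
# ---------------------------------------------------------------------------

def protocol_conditions(n_events: int = 60) -> Dict[str, ProtocolSpec]:
    """The six positive-pairing protocol conditions the model reproduces."""
    base = dict(n_events=n_events, pairing_dt_ms=10.0)
    return {
        "pairings_alone": ProtocolSpec(light_on=False, bsr_on=False, **base),
        "reinforced": ProtocolSpec(light_on=True, bsr_on=True, **base),
        "bsr_only": ProtocolSpec(light_on=False, bsr_on=True, **base),
        "light_only": ProtocolSpec(light_on=True, bsr_on=False, **base),
        "delayed_2s": ProtocolSpec(light_on=True, bsr_on=True,
                                   reinforcement_delay_shift_s=1.0, **base),
        "thalamus_lesioned": ProtocolSpec(light_on=True, bsr_on=True,
                                          thalamus_lesioned=True, **base),
    }


#: expected final weight-change sign per condition; light_only additionally
#: rises above baseline before ending below it ("rise-then-fall")
EXPECTED_SIGNS = {
    "pairings_alone": -1,
    "reinforced": +1,
    "bsr_only": -1,
    "light_only": -1,
    "delayed_2s": -1,
    "thalamus_lesioned": -1,
}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_generate(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """Generate a synthetic recording for the downstream pipelines."""
    from .io import write_recording

    proto = ProtocolSpec(**params.get("protocol", {"n_events": 30, "pairing_dt_ms": 0.0}))
    sp = S.SynthParams(**{"seed": seed, **params.get("synth", {})})
    rec = S.generate_recording(sp, proto)
    context["recording"] = rec
    out = None
    if params.get("write", True):
        out = str(write_recording(rec, out_dir / "recording.h5"))
    return {"n_samples": len(rec.vm_mv), "duration_s": rec.duration_s,
            "n_events": len(rec.events), "file": out}


def stage_psp(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """PSP trial set -> exclusion -> slopes -> binned percent change."""
    import pandas as pd

    n_base = params.get("n_baseline", 30)
    n_test = params.get("n_test", 60)
    drift_factor = params.get("drift_factor", 1.25)
    artifact_fraction = params.get("artifact_fraction", 0.10)
    sp = S.SynthParams(**{"seed": seed, "noise_sd_mv": 0.3, **params.get("synth", {})})

    drift = np.concatenate([np.ones(n_base), np.full(n_test, drift_factor)])
    ts = S.generate_psp_trial_set(sp, n_base + n_test, drift,
                                  artifact_fraction=artifact_fraction)
    included, frac = P.exclude_outlier_traces(
        ts.traces, ts.time_s, ts.stim_time_s - 0.005, ts.stim_time_s + 0.200)
    slopes = P.measure_trial_slopes(ts)
    period = params.get("trial_period_s", 10.0)
    series = pd.DataFrame({
        "trial_time_s": np.arange(ts.n_trials) * period,
        "slope_mv_per_ms": slopes,
        "included": included & np.isfinite(slopes),
        "phase": ["baseline"] * n_base + ["test"] * n_test,
    })
    binned = P.normalize_and_bin(series, bin_width_s=params.get("bin_width_s", 300.0))
    binned.to_csv(out_dir / "psp_binned.csv", index=False)
    series.to_csv(out_dir / "psp_trials.csv", index=False)
    return {
        "fraction_excluded": frac,
        "injected_artifact_fraction": float(ts.artifact.mean()),
        "mean_percent_change": float(binned["mean"].mean()),
        "configured_percent_change": 100.0 * (drift_factor - 1.0),
        "n_bins": int(len(binned)),
    }


def stage_upstate(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """Latency extraction, distribution fits, Kuiper test, excess probability."""
    rec = context["recording"]
    ds = U.extract_latencies(rec, seed=seed,
                             max_latency_s=params.get("max_latency_s", 1.0))
    report = {"n_light": ds.n_light, "n_random": ds.n_random,
              "empty": bool(ds.empty)}
    if ds.n_light >= 5:
        light_fit = U.fit_distribution(ds.light_latencies_s, "loglogistic")
        rand_fit = U.fit_distribution(ds.random_latencies_s, "weibull")
        kt = kuiper_test(ds.light_latencies_s, rand_fit.cdf, seed=seed)
        report.update({
            "light_fit": {"family": light_fit.family, **light_fit.params,
                          "bic": light_fit.bic},
            "random_fit": {"family": rand_fit.family, **rand_fit.params,
                           "bic": rand_fit.bic},
            "kuiper": {"V": kt.statistic, "p": kt.p_value, "n": kt.n},
            "excess_probability_60_140ms": U.excess_probability(light_fit, rand_fit),
        })
        pd_grid = np.linspace(0.005, 1.0, 200)
        np.savetxt(out_dir / "latency_cdfs.csv",
                   np.column_stack([pd_grid, light_fit.cdf(pd_grid),
                                    rand_fit.cdf(pd_grid)]),
                   delimiter=",", header="latency_s,cdf_light,cdf_random",
                   comments="")
    return report


def stage_model_surface(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """Weight-change surface and its diagonal half-max window."""
    rule = M.reference_rule(**params.get("rule", {}))
    step = params.get("step_s", 0.025)
    grid = np.arange(0.0, 3.0 + step / 2, step)
    surface = M.weight_change_surface(grid, grid, rule)
    np.savetxt(out_dir / "weight_change_surface.csv", surface, delimiter=",")
    lo, hi = M.diagonal_half_max(rule, step=min(step, 0.01))
    return {"half_max_lower_s": lo, "half_max_upper_s": hi,
            "grid_step_s": step, "n_grid": int(len(grid))}


def stage_model_protocols(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """The six protocol conditions and their weight-change signs."""
    rule = M.reference_rule(**params.get("rule", {}))
    n_events = params.get("n_events", 60)
    out = {}
    for name, proto in protocol_conditions(n_events).items():
        res = M.run_protocol(proto, rule)
        out[name] = {
            "percent_change": res.percent_change,
            "peak_percent_change": res.peak_percent_change,
            "sign": int(np.sign(res.percent_change)),
        }
    (out_dir / "protocol_conditions.json").write_text(json.dumps(out, indent=1))
    return out


def stage_discovery(params: dict, seed: int, out_dir: Path, context: dict) -> dict:
    """Action-discovery switching experiment."""
    import pandas as pd

    rule = M.reference_rule(**params.get("rule", {}))
    traj = M.run_action_discovery(
        duration_s=params.get("duration_s", 600.0), rule=rule,
        switch_time_s=params.get("switch_time_s", 300.0), seed=seed)
    df = pd.DataFrame({k: traj[k] for k in
                       ("time_s", "program", "mean_w_spn1", "mean_w_spn2")})
    df.to_csv(out_dir / "action_discovery.csv", index=False)
    pre = traj["time_s"] < traj["switch_time_s"]
    w0 = rule.params.w_init
    return {
        "w1_at_switch": float(traj["mean_w_spn1"][pre][-1]) if pre.any() else w0,
        "w1_at_end": float(traj["mean_w_spn1"][-1]),
        "w2_at_switch": float(traj["mean_w_spn2"][pre][-1]) if pre.any() else w0,
        "w2_at_end": float(traj["mean_w_spn2"][-1]),
        "n_events": int(len(traj["time_s"])),
    }


_STAGE_FUNCS = {
    "generate": stage_generate,
    "psp": stage_psp,
    "upstate": stage_upstate,
    "model_surface": stage_model_surface,
    "model_protocols": stage_model_protocols,
    "discovery": stage_discovery,
}


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in order and write the JSON report.

    Returns the report dict; ``report["ok"]`` is False if any stage failed
    (stages whose prerequisites failed are recorded as skipped).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    context: dict = {}
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
              "stages": {}, "ok": True}
    timestamps = {"started": _time.strftime("%Y-%m-%dT%H:%M:%S")}
    failed = set()
    for name in config.stages:
        missing = [k for k in _REQUIRES.get(name, ()) if k not in context]
        if missing:
            report["stages"][name] = {"status": "skipped",
                                      "reason": f"missing prerequisites {missing}"}
            continue
        try:
            log.info("running stage %s", name)
            result = _STAGE_FUNCS[name](config.params.get(name, {}),
                                        config.seed, out_dir, context)
            report["stages"][name] = {"status": "ok", "result": result}
        except Exception as exc:
            log.exception("stage %s failed", name)
            failed.add(name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            report["ok"] = False
    timestamps["finished"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
    full = dict(report)
    full["timestamps"] = timestamps
    (out_dir / "report.json").write_text(json.dumps(full, indent=1, sort_keys=True))
    return full
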