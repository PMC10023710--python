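"""Campaign orchestration: configure, simulate, evaluate, report.

A campaign is specimens x protocols x repeats.  Seeding is hierarchical:
the root seed spawns one child sequence per specimen (used to generate the
virtual specimen) and one per trial (used for that trial's sensor-noise
stream), so any subset of the campaign is reproducible from the root seed
and the run is deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .evaluation import MetricsReport, evaluate_campaign
from .motions import PROTOCOLS, build_profile
from .simulate import TrialTrace, run_trial
from .specimen import (
    DislocationError,
    InstabilityError,
    VirtualSpecimen,
    generate_specimen,
    reference_specimen,
)

__all__ = ["RunConfig", "run_simulation", "run_evaluation", "campaign_traces"]

log = logging.getLogger("shouldersim")

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of a simulation run."""

    specimen_source: str = "generated"  # "reference" | "generated"
    n_specimens: int = 3
    specimen_file: str | None = None
    protocols: tuple[str, ...] = PROTOCOLS
    repeats: int = 3
    noise: bool = True
    variability: float = 0.10
    seed: int = 0
    out_dir: str = "runs"
    record_clean: bool = False
    gains_file: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocols"] = list(self.protocols)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["protocols"] = tuple(d.get("protocols", PROTOCOLS))
        return cls(**d)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0] % _SEED_MOD) for s in ss.spawn(n)]


def campaign_specimens(config: RunConfig) -> list[VirtualSpecimen]:
    if config.specimen_file:
        return [VirtualSpecimen.from_yaml(config.specimen_file)]
    if config.specimen_source == "reference":
        return [reference_specimen()]
    seeds = _spawn_seeds(config.seed, config.n_specimens)
    return [generate_specimen(s, config.variability) for s in seeds]


def campaign_traces(
    config: RunConfig,
    specimens: Sequence[VirtualSpecimen] | None = None,
) -> tuple[list[TrialTrace], list[dict]]:
    """Run every trial of the campaign in memory.

    Returns the successful traces and a list of per-trial records
    (including failures, which abort only their own trial).
    """
    specimens = list(specimens) if specimens is not None else campaign_specimens(config)
    controller = None
    if config.gains_file:
        from .controller import ThreeLoopController, load_gain_table

        controller = ThreeLoopController(gains=load_gain_table(config.gains_file))
    n_trials = len(specimens) * len(config.protocols) * config.repeats
    trial_seeds = _spawn_seeds(config.seed + 1, max(n_trials, 1))
    traces: list[TrialTrace] = []
    records: list[dict] = []
    i = 0
    for spec in specimens:
        for protocol in config.protocols:
            profile = build_profile(protocol)
            for rep in range(config.repeats):
                seed = trial_seeds[i]
                i += 1
                rec = dict(
                    specimen_id=spec.specimen_id, protocol=protocol,
                    repeat=rep, seed=seed,
                )
                try:
                    tr = run_trial(
                        spec, profile, repeat=rep, seed=seed,
                        noise=config.noise, record_clean=config.record_clean,
                        controller=controller,
                    )
                except (DislocationError, InstabilityError) as exc:
                    rec["status"] = "failed"
                    rec["error"] = f"{type(exc).__name__}: {exc}"
                    log.warning("trial failed: %s", rec["error"])
                else:
                    rec["status"] = "ok"
                    traces.append(tr)
                records.append(rec)
    return traces, records


def run_simulation(config: RunConfig) -> dict:
    """Execute the campaign and write one trace CSV per trial plus a JSON
    manifest (seeds, config hash, software version, failures)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.protocols:
        warnings.warn("no protocols requested: writing an empty manifest")
        manifest = {
            "version": __version__, "config": config.to_dict(),
            "config_hash": config.config_hash(), "trials": [],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    specimens = campaign_specimens(config)
    for spec in specimens:
        spec.to_yaml(out / f"specimen_{spec.specimen_id}.yaml")
    traces, records = campaign_traces(config, specimens)
    for tr, rec in zip(traces, (r for r in records if r["status"] == "ok")):
        fname = f"trace_{tr.specimen_id}_{tr.protocol}_r{tr.repeat}.csv"
        tr.to_csv(out / fname)
        rec["file"] = fname
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "specimens": [s.specimen_id for s in specimens],
        "trials": records,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_evaluation(
    trace_dir,
    *,
    pooling: str = "pooled",
    thresholds: dict | None = None,
) -> tuple[MetricsReport, bool]:
    """Evaluate all traces in a directory and write the metrics report.

    Returns the report and whether the (optional) thresholds are met.
    Protocols with fewer than 2 repeats are skipped for ICC with a
    warning.  ``thresholds`` may bound ``max_mean_deviation_deg``,
    ``max_rmse_deg``, ``max_sd_deg`` and ``max_avg_sd_deg``.
    """
    trace_dir = Path(trace_dir)
    files = sorted(trace_dir.glob("trace_*.csv"))
    if not files:
        raise FileNotFoundError(f"no trace files in {trace_dir}")
    traces = [TrialTrace.from_csv(f) for f in files]
    report = evaluate_campaign(traces, pooling=pooling)
    report.to_json(trace_dir / "metrics.json")
    report.to_csv(trace_dir / "metrics.csv")
    ok = True
    if thresholds:
        summary = report.summary()
        for key, bound in thresholds.items():
            if key not in summary:
                raise KeyError(f"unknown threshold {key!r}")
            if summary[key] > bound:
                log.error("threshold violated: %s = %.3f > %.3f", key, summary[key], bound)
                ok = False
    return report, ok
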