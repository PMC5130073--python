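"""Structured run configurations and experiment orchestration.

A run is fully described by ``(experiment, parameters, seed)`` and is exactly
reproducible from that triple: every stochastic component draws from a single
``numpy`` Generator seeded from the config.  ``run_experiment`` executes the
configured experiment and writes a per-generation CSV trajectory plus a JSON
metadata sidecar (config echo, seed, convergence generation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .capacity import capacity_table, estimate_capacity
from .evolution import (
    PopulationConfig,
    generations_to_fitness,
    run_changing_environment,
    run_elitist,
    run_selectionist,
)
from .landscapes import EnvironmentSchedule, make_test_landscape
from .metapopulation import MetapopConfig, run_metapopulation
from .patterns import VariationParams

__all__ = ["RunConfig", "load_config", "run_experiment", "EXPERIMENT_DEFAULTS"]

#: Per-experiment parameter defaults (the headline study configurations).
EXPERIMENT_DEFAULTS: dict[str, dict[str, Any]] = {
    "select": {
        "N": 200, "N_A": 20, "mu_I": 0.005, "pretrain_count": 30,
        "max_generations": 200,
    },
    "evolve": {
        "N": 200, "N_A": 20, "N_T": 1, "mu_I": 0.005, "mu_T": 0.01,
        "pretrain_count": 30, "max_generations": 5000,
        "abstract": False, "C_fix": 30, "mu_O": 0.001,
    },
    "cycle": {
        "N": 100, "N_A": 100, "N_T": 40, "T_E": 2000, "T_nolearn": 12000,
        "mu_R": None, "pretrain_count": 20, "n_generations": 20000,
        "wipe_memory_at_nolearn": False,
    },
    "gbbf": {
        "N": 100, "P": 10, "side": 10, "N_A": 10, "N_T": 5,
        "p_rec": 0.1, "p_migr": 0.004, "mu_R": None, "pretrain_count": 20,
        "w1": 10.0, "w2": 9.0, "max_generations": 50000, "record_every": 10,
    },
    "capacity": {
        "rule": "both", "N": 200, "replicates": 20, "table": False,
    },
}


@dataclass
class RunConfig:
    """A validated, fully defaulted experiment configuration."""

    experiment: str
    seed: int = 0
    out_dir: str | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_DEFAULTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"expected one of {sorted(EXPERIMENT_DEFAULTS)}"
            )
        defaults = EXPERIMENT_DEFAULTS[self.experiment]
        unknown = set(self.params) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown parameter(s) for experiment {self.experiment!r}: "
                f"{sorted(unknown)}"
            )
        self.params = {**defaults, **self.params}

    def to_dict(self) -> dict[str, Any]:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "params": self.params,
        }


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults and rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    if "experiment" not in raw:
        raise ValueError("config is missing the required key 'experiment'")
    top = {"experiment", "seed", "out_dir"}
    experiment = raw["experiment"]
    params = {k: v for k, v in raw.items() if k not in top}
    return RunConfig(
        experiment=experiment,
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir"),
        params=params,
    )


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "generation": r.generation,
                "best_fitness": r.best_fitness,
                "mean_fitness": r.mean_fitness,
                "best_producer": r.best_producer,
                "memory_distance": r.memory_distance,
                "environment": r.environment,
            }
        )
    return pd.DataFrame(rows)


def _execute(config: RunConfig) -> tuple[pd.DataFrame, dict[str, Any]]:
    p = config.params
    rng = np.random.default_rng(config.seed)
    extra: dict[str, Any] = {}
    if config.experiment == "select":
        pc = PopulationConfig(
            N_A=p["N_A"], N=p["N"], N_T=1,
            variation=VariationParams(mu_I=p["mu_I"]),
            pretrain_count=p["pretrain_count"], learning_enabled=False,
        )
        records = run_selectionist(pc, rng, max_generations=p["max_generations"])
        df = _records_frame(records)
        extra["converged_at"] = generations_to_fitness(records)
        extra["producer_sequence"] = [int(r.best_producer) for r in records]
    elif config.experiment == "evolve":
        pc = PopulationConfig(
            N_A=p["N_A"], N=p["N"], N_T=p["N_T"],
            variation=VariationParams(mu_I=p["mu_I"], mu_T=p["mu_T"], mu_O=p["mu_O"]),
            pretrain_count=p["pretrain_count"],
        )
        records = run_elitist(
            pc, rng, max_generations=p["max_generations"],
            abstract=p["abstract"], C_fix=p["C_fix"],
        )
        df = _records_frame(records)
        extra["converged_at"] = generations_to_fitness(records)
    elif config.experiment == "cycle":
        mu_R = p["mu_R"] if p["mu_R"] is not None else 1.0 / p["N"]
        pc = PopulationConfig(
            N_A=p["N_A"], N=p["N"], N_T=p["N_T"],
            variation=VariationParams(mu_R=mu_R),
            pretrain_count=p["pretrain_count"],
        )
        sched = EnvironmentSchedule(N=p["N"], T_E=p["T_E"], T_nolearn=p["T_nolearn"])
        records = run_changing_environment(
            pc, sched, rng, n_generations=p["n_generations"],
            wipe_memory_at_nolearn=p["wipe_memory_at_nolearn"],
        )
        df = _records_frame(records)
    elif config.experiment == "gbbf":
        mc = MetapopConfig(
            side=p["side"], N_A=p["N_A"], N=p["N"], N_T=p["N_T"],
            p_rec=p["p_rec"], p_migr=p["p_migr"], mu_R=p["mu_R"],
            pretrain_count=p["pretrain_count"],
        )
        land = make_test_landscape(p["N"], p["P"], w1=p["w1"], w2=p["w2"])
        traj, converged = run_metapopulation(
            mc, land, rng, max_generations=p["max_generations"],
            record_every=p["record_every"],
        )
        df = pd.DataFrame(traj, columns=["generation", "best_fitness"])
        extra["converged_at"] = converged
    elif config.experiment == "capacity":
        rules = ["covariance", "storkey"] if p["rule"] == "both" else [p["rule"]]
        if p["table"]:
            rows = []
            for rule in rules:
                rows.extend(capacity_table(rule, N=p["N"],
                                           replicates=p["replicates"], rng=rng))
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame()
        for rule in rules:
            est = estimate_capacity(rule, N=p["N"], replicates=p["replicates"],
                                    rng=rng)
            extra[f"capacity_ratio_{rule}"] = est.ratio
    else:  # pragma: no cover - guarded by RunConfig
        raise AssertionError(config.experiment)
    return df, extra


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute a configured experiment; optionally write trajectory + metadata.

    Returns a result dict with the trajectory DataFrame under ``"trajectory"``
    and experiment summaries (convergence generation, capacity ratios, ...).
    When an output directory is given (argument or config), writes
    ``trajectory.csv`` and ``metadata.json`` there.
    """
    df, extra = _execute(config)
    meta = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        **{k: v for k, v in extra.items() if k != "trajectory"},
    }
    out = out_dir or config.out_dir
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "trajectory.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=_json_default))
        meta["trajectory_path"] = str(out / "trajectory.csv")
    return {"trajectory": df, **meta}


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
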