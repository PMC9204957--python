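"""Run configuration: a flat, YAML-serialisable schema covering the life
history, pool, inheritance and run settings, with strict validation
(unknown keys are rejected) and lossless round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .inheritance import InheritanceSpec
from .model_core import ColonizerPool, LifeHistory
from .population import PopulationConfig

__all__ = ["RunConfig", "parse_config", "config_from_dict"]

_TOP_KEYS = {
    "m", "tau", "alpha0", "N", "H", "p", "inheritance",
    "engine", "t_max", "record_times", "seed", "init_counts",
}
_INH_KEYS = {"mode", "a", "b"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one simulation run."""

    lh: LifeHistory
    pool: ColonizerPool
    inheritance: InheritanceSpec
    engine: str = "discrete"
    t_max: int = 1000
    record_times: tuple = ()
    seed: int = 0
    init_counts: tuple | None = None

    def population_config(self, log_births: bool = False) -> PopulationConfig:
        return PopulationConfig(
            t_max=self.t_max,
            record_times=self.record_times,
            engine=self.engine,
            inheritance=self.inheritance,
            log_births=log_births,
        )

    def to_dict(self) -> dict:
        d = {
            "m": float(self.lh.m),
            "tau": float(self.lh.tau),
            "alpha0": float(self.lh.alpha0),
            "N": int(self.lh.N),
            "H": int(self.lh.H),
            "p": [float(v) for v in self.pool.p],
            "engine": self.engine,
            "t_max": int(self.t_max),
            "record_times": [float(t) for t in self.record_times],
            "seed": int(self.seed),
        }
        if self.inheritance.mode == "none":
            d["inheritance"] = {"mode": "none"}
        else:
            d["inheritance"] = {
                "mode": "beta",
                "a": [float(v) for v in self.inheritance.a],
                "b": [float(v) for v in self.inheritance.b],
            }
        if self.init_counts is not None:
            d["init_counts"] = [list(map(int, row)) for row in self.init_counts]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def config_from_dict(raw: dict) -> RunConfig:
    """Build a validated RunConfig from a plain dict, filling defaults."""
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("m", "tau", "alpha0", "N"):
        if key not in raw:
            raise ValueError(f"missing required config key: {key}")
    lh = LifeHistory(
        m=float(raw["m"]),
        tau=float(raw["tau"]),
        alpha0=float(raw["alpha0"]),
        N=int(raw["N"]),
        H=int(raw.get("H", 2)),
    )
    pool = ColonizerPool(p=np.asarray(raw.get("p", [1.0]), dtype=float))
    inh_raw = raw.get("inheritance", {"mode": "none"})
    unknown = set(inh_raw) - _INH_KEYS
    if unknown:
        raise ValueError(f"unknown inheritance keys: {sorted(unknown)}")
    mode = inh_raw.get("mode", "none")
    if mode == "beta":
        a = np.asarray(inh_raw["a"], dtype=float)
        b = np.asarray(inh_raw["b"], dtype=float)
        if a.size != pool.n_taxa or b.size != pool.n_taxa:
            raise ValueError(
                f"inheritance shapes must have length {pool.n_taxa} "
                f"(one per taxon), got {a.size} and {b.size}"
            )
        inheritance = InheritanceSpec(mode="beta", a=a, b=b)
    else:
        inheritance = InheritanceSpec(mode="none")
    t_max = int(raw.get("t_max", 1000))
    record_times = tuple(float(t) for t in raw.get("record_times", [t_max]))
    init_counts = raw.get("init_counts")
    if init_counts is not None:
        init_counts = tuple(tuple(int(v) for v in row) for row in init_counts)
    return RunConfig(
        lh=lh,
        pool=pool,
        inheritance=inheritance,
        engine=str(raw.get("engine", "discrete")),
        t_max=t_max,
        record_times=record_times,
        seed=int(raw.get("seed", 0)),
        init_counts=init_counts,
    )


def parse_config(path: str) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw if raw is not None else {})
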