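"""Run configuration: one YAML file describing a reproducible run.

A persisted configuration plus its seed reproduces a run bit for bit on the
same platform.  Sections:

* ``model``      -- overrides of the node parameters (Table-style names)
                    and the global coupling K_gl
* ``simulation`` -- duration_s, dt_ms, transient_s, rec_dt_ms, seed
* ``evolution``  -- mode, n_init, n_pop, n_gen, stage-2 duration
* ``data``       -- paths to connectome / FC / BOLD / spectrum files
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .params import NodeParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    model: dict = field(default_factory=dict)        # NodeParams overrides + K_gl
    simulation: dict = field(default_factory=dict)
    evolution: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "run"

    # simulation defaults
    _SIM_DEFAULTS = {
        "duration_s": 60.0,
        "dt_ms": 0.1,
        "transient_s": 1.0,
        "rec_dt_ms": 1.0,
    }

    def node_params(self) -> NodeParams:
        kw = {k: v for k, v in self.model.items() if k != "K_gl"}
        return NodeParams(**kw)

    @property
    def K_gl(self) -> float:
        return float(self.model.get("K_gl", 0.0))

    def sim(self, key: str):
        return self.simulation.get(key, self._SIM_DEFAULTS[key])

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def save(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
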