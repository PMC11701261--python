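"""Run configuration: one structured YAML, flat keys namespaced by module.

Unknown keys are rejected; every run's outputs embed the resolved config
hash so any artifact can be traced back to the exact parameter set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import yaml

from .dynamics import ProtocolSchedule, TFPopulation
from .extrusion import ExtrusionParams
from .forcefield import AffinityTable, ForceFieldParams, SimulationUnits


def _defaults() -> dict:
    return {
        "forcefield": asdict(ForceFieldParams()),
        "affinities": {f"{s}:{m}": e for (s, m), e in AffinityTable().table.items()},
        "extrusion": asdict(ExtrusionParams()),
        "schedule": asdict(ProtocolSchedule()),
        "tf": {"fraction": 0.10, "ksw": 1e-3},
        "units": {"timestep": 0.01, "physical_sigma_nm": 25.0,
                  "density_mbp_um3": 6.5},
        "analysis": {
            "contact_threshold": 3.5,
            "partner_threshold": 0.10,
            "influential_threshold": 0.50,
            "rt_hic": 3.5,
            "rt_microc": 1.5,
            "d_lower_kb": 20,
            "d_upper_kb": 500,
        },
        "desk_scale": 1.0,
        "seed": 1,
    }


def _merge(base: dict, user: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in user.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


class RunConfig:
    """Resolved configuration (defaults overlaid with a user YAML)."""

    def __init__(self, overrides: Optional[dict] = None) -> None:
        self.data = _merge(_defaults(), overrides or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(user)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.data, sort_keys=True, default=float)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    # typed views ----------------------------------------------------------

    def forcefield(self) -> ForceFieldParams:
        return ForceFieldParams(**self.data["forcefield"])

    def affinity_table(self) -> AffinityTable:
        table = {}
        for key, eps in self.data["affinities"].items():
            species, _, mark = key.partition(":")
            table[(species, mark)] = float(eps)
        return AffinityTable(table)

    def extrusion(self) -> ExtrusionParams:
        return ExtrusionParams(**self.data["extrusion"])

    def schedule(self) -> ProtocolSchedule:
        return ProtocolSchedule(**self.data["schedule"])

    def units(self) -> SimulationUnits:
        u = self.data["units"]
        return SimulationUnits(timestep=u["timestep"],
                               physical_sigma_nm=u["physical_sigma_nm"])

    def tf_population(self, n_beads: int) -> TFPopulation:
        tf = self.data["tf"]
        return TFPopulation.from_chain(n_beads, tf["fraction"], tf["ksw"])
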