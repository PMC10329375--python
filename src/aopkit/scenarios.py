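"""Named bench scenarios and scenario-file loading.

Three scenarios ship with the package, mirroring the mechanical test-lung
models used to establish the method: ``aop10`` (airway closure with opening
pressure 10 cmH2O), ``control1`` (linear compliance, no closure) and
``control2`` (bilinear compliance with a lower inflection point at 10 cmH2O,
no closure).  All use an airway resistance of 10 cmH2O/(L/s) and a circuit
compliance of 2 mL/cmH2O.  Arbitrary scenarios can be loaded from YAML/JSON
files with the same schema.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Tuple, Union

import yaml

from .mechanics import (
    BilinearCompliance,
    LinearCompliance,
    RespiratorySystem,
    VentCircuit,
)

__all__ = ["BENCH_SCENARIOS", "load_scenario"]

BENCH_SCENARIOS = ("aop10", "control1", "control2")


def _compliance_from_dict(d: dict):
    if "linear" in d:
        return LinearCompliance(crs=float(d["linear"]["crs"]))
    if "bilinear" in d:
        b = d["bilinear"]
        return BilinearCompliance(c_below=float(b["c_below"]),
                                  c_above=float(b["c_above"]),
                                  lip=float(b["lip"]))
    raise ValueError("compliance must contain a 'linear' or 'bilinear' entry")


def _from_dict(cfg: dict) -> Tuple[RespiratorySystem, VentCircuit]:
    sysd = cfg["system"]
    aop = sysd.get("aop")
    system = RespiratorySystem(
        rrs=float(sysd["rrs"]),
        compliance=_compliance_from_dict(sysd["compliance"]),
        aop=float(aop) if aop is not None else None,
        relax_volume=float(sysd.get("relax_volume", 0.0)),
    )
    circd = cfg.get("circuit", {})
    circuit = VentCircuit(ccirc=float(circd.get("ccirc", 2.0)),
                          rcirc=float(circd.get("rcirc", 0.0)))
    return system, circuit


def load_scenario(name_or_path: Union[str, Path]) -> Tuple[RespiratorySystem, VentCircuit]:
    """Load a scenario by built-in name or from a YAML/JSON file path."""
    name = str(name_or_path)
    if name in BENCH_SCENARIOS:
        text = resources.files("aopkit").joinpath(f"data/scenarios/{name}.yaml").read_text()
        return _from_dict(yaml.safe_load(text))
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown scenario {name!r}: not one of {BENCH_SCENARIOS} and no such file"
        )
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_dict(cfg)
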