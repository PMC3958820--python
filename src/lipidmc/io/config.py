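"""YAML run configuration.

A run file has two sections: ``system`` (what to simulate) and ``run``
(sampling parameters, mapping 1:1 onto :class:`~lipidmc.sampler.RunConfig`).
Every default is stated explicitly in the shipped example configs.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from ..forcefield.dielectric import DielectricParams
from ..sampler.driver import RunConfig


def run_config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    diel = d.pop("dielectric", None)
    rc = RunConfig(**d)
    if diel is not None:
        rc.dielectric = DielectricParams(**diel)
    return rc


def load_run_file(path: str | Path) -> tuple[dict, RunConfig]:
    """Returns (system section, RunConfig)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    system = data.get("system", {})
    rc = run_config_from_dict(data.get("run", {}))
    return system, rc


def dump_run_file(system: dict, rc: RunConfig, path: str | Path):
    d = asdict(rc)
    d["dielectric"] = {
        "plateau_d": rc.dielectric.plateau_d,
        "slope_s": rc.dielectric.slope_s,
    }
    Path(path).write_text(
        yaml.safe_dump({"system": system, "run": d}, sort_keys=False)
    )
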