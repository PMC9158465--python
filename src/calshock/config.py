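"""YAML configuration: one section per parameter table.

Sections (all optional; missing keys fall back to the built-in defaults):
``biophysics``, ``kinetics``, ``protocol``, ``strain``, ``solver``.  Strain
overrides are sparse patches — only changed keys appear.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import NamedTuple

import yaml

from .biophysics import BiophysicalParameters, StimulusProtocol
from .signaling import KineticParameters
from .simulator import SolverSettings, StrainConfig

__all__ = ["RunRecords", "default_config", "load_config", "save_config",
           "records_from_config"]


class RunRecords(NamedTuple):
    kinetic: KineticParameters
    biophys: BiophysicalParameters
    protocol: StimulusProtocol
    strain: StrainConfig
    solver: SolverSettings


def default_config() -> dict:
    """The full default configuration as a plain dict."""
    return {
        "biophysics": asdict(BiophysicalParameters()),
        "kinetics": asdict(KineticParameters()),
        "protocol": asdict(StimulusProtocol()),
        "strain": {
            "name": "wild-type",
            "overrides": {},
            "resting_camb": "calibrate-to-baseline",
            "target_baseline": None,
        },
        "solver": {
            "rtol": SolverSettings().rtol,
            "atol": list(SolverSettings().atol),
            "output_dt": SolverSettings().output_dt,
        },
    }


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config and merge it over the defaults (section-wise)."""
    cfg = default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    unknown = set(raw) - set(cfg)
    if unknown:
        raise ValueError(f"{path}: unknown config section(s): {sorted(unknown)}")
    for section, values in raw.items():
        if values is None:
            continue
        if not isinstance(values, dict):
            raise ValueError(f"{path}: section {section!r} must be a mapping")
        bad = set(values) - set(cfg[section])
        if bad:
            raise ValueError(
                f"{path}: unknown key(s) in [{section}]: {sorted(bad)}"
            )
        cfg[section].update(values)
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def records_from_config(cfg: dict) -> RunRecords:
    """Instantiate parameter records from a (merged) config dict."""
    solver = dict(cfg["solver"])
    atol = solver.pop("atol", None)
    settings = SolverSettings(
        **({"atol": tuple(atol)} if atol is not None else {}), **solver
    )
    return RunRecords(
        kinetic=KineticParameters(**cfg["kinetics"]),
        biophys=BiophysicalParameters(**cfg["biophysics"]),
        protocol=StimulusProtocol(**cfg["protocol"]),
        strain=StrainConfig(**cfg["strain"]),
        solver=settings,
    )
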