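"""Experiment-like synthetic calcium traces.

Generates noisy replicate time courses emulating luminescence-derived
cytosolic-calcium recordings: a pre-stimulus baseline of one-to-few hundred
nM, a transient peak within about two minutes of a hypotonic dilution, and
strain- and dilution-dependent baselines and peaks.  The noise model is
additive-plus-multiplicative Gaussian applied to the clean simulation
(photon-counting statistics of the real reporter are not modelled); all
generating parameters and seeds are recorded in a manifest so the traces
double as ground truth for parameter-recovery experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .biophysics import BiophysicalParameters, StimulusProtocol
from .signaling import KineticParameters
from .simulator import (
    SolverSettings,
    StrainConfig,
    Trace,
    simulate,
)

__all__ = [
    "SyntheticCondition",
    "SyntheticDesign",
    "synth_trace",
    "synth_dataset",
    "read_traces",
    "default_design",
]


@dataclass(frozen=True)
class SyntheticCondition:
    """One experimental condition to emulate.

    ``overrides`` patch the generating kinetic parameters (and are recorded
    as ground truth); ``target_baseline`` feeds the resting calibration.
    """

    label: str
    strain: str = "wild-type"
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    overrides: dict = field(default_factory=dict)
    replicates: int = 3
    sampling_interval: float = 1.0
    target_baseline: float | None = None
    resting_camb: float | str = "calibrate-to-baseline"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")

    def strain_config(self) -> StrainConfig:
        return StrainConfig(
            name=self.strain,
            overrides=dict(self.overrides),
            resting_camb=self.resting_camb,
            target_baseline=self.target_baseline,
        )


@dataclass(frozen=True)
class SyntheticDesign:
    """A set of conditions plus the noise model and master seed.

    ``noise_sd`` is the additive Gaussian standard deviation (nM);
    ``noise_mult`` the multiplicative one (fraction of the clean signal).
    Per-trace seeds derive deterministically from the master seed.
    """

    conditions: tuple[SyntheticCondition, ...]
    noise_sd: float = 10.0
    noise_mult: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate condition labels")
        if self.noise_sd < 0 or self.noise_mult < 0:
            raise ValueError("noise magnitudes must be non-negative")


def default_design(master_seed: int = 0, noise_sd: float = 10.0) -> SyntheticDesign:
    """Four-strain replicate design mirroring the published experiment set:
    one hypotonic dilution (d = 5, ~29.5 uM initial external calcium) per
    strain, three replicates each."""
    proto = StimulusProtocol(d=5.0, t_off=30.0, t_m=9.1, Ca_ex0=29_500.0, t_end=160.0)
    return SyntheticDesign(
        conditions=tuple(
            SyntheticCondition(label=s, strain=s, protocol=proto)
            for s in ("wild-type", "cnb1", "cch1", "flc2")
        ),
        noise_sd=noise_sd,
        master_seed=master_seed,
    )


def _trace_seed(design: SyntheticDesign, cond_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(design.master_seed,
                                spawn_key=(cond_index, replicate))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def synth_trace(
    condition: SyntheticCondition,
    seed: int,
    noise_sd: float = 0.0,
    noise_mult: float = 0.0,
    base_kinetic: KineticParameters | None = None,
    biophys: BiophysicalParameters | None = None,
    settings: SolverSettings | None = None,
) -> Trace:
    """Simulate one condition and add observation noise to the calcium.

    y = clean * (1 + noise_mult * e1) + noise_sd * e2, e i.i.d. standard
    normal, clamped at zero.  With both noise magnitudes zero the output is
    exactly the sampled clean simulation.  Same seed, same output.
    """
    base_kinetic = base_kinetic or KineticParameters()
    biophys = biophys or BiophysicalParameters()
    proto = condition.protocol
    dt = condition.sampling_interval
    n = int(round(proto.t_end / dt))
    t_eval = np.linspace(0.0, n * dt, n + 1)
    settings = settings or SolverSettings()
    trace = simulate(
        base_kinetic, biophys, proto,
        strain=condition.strain_config(), settings=settings, t_eval=t_eval,
    )
    rng = np.random.default_rng(seed)
    if noise_mult > 0 or noise_sd > 0:
        e1 = rng.standard_normal(trace.Ca_cyt.shape)
        e2 = rng.standard_normal(trace.Ca_cyt.shape)
        noisy = trace.Ca_cyt * (1.0 + noise_mult * e1) + noise_sd * e2
        trace.Ca_cyt = np.maximum(noisy, 0.0)
    trace.metadata.update(
        {
            "condition": condition.label,
            "seed": int(seed),
            "noise_sd": float(noise_sd),
            "noise_mult": float(noise_mult),
            "sampling_interval": float(dt),
        }
    )
    return trace


def synth_dataset(
    design: SyntheticDesign,
    outdir: str | Path | None = None,
    base_kinetic: KineticParameters | None = None,
    biophys: BiophysicalParameters | None = None,
    settings: SolverSettings | None = None,
) -> tuple[list[dict], dict]:
    """Generate all condition x replicate traces (optionally written out).

    Returns ``(records, manifest)`` where each record is
    ``{"condition", "replicate", "seed", "trace"}`` and the manifest holds
    the design, generating parameters and per-trace seeds — the ground
    truth for recovery tests.  Regenerating from the same design reproduces
    the files byte-identically.
    """
    base_kinetic = base_kinetic or KineticParameters()
    biophys = biophys or BiophysicalParameters()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    records: list[dict] = []
    manifest: dict = {
        "master_seed": design.master_seed,
        "noise_sd": design.noise_sd,
        "noise_mult": design.noise_mult,
        "base_kinetic": base_kinetic.to_dict(),
        "biophysics": biophys.to_dict(),
        "conditions": [],
    }
    for ci, cond in enumerate(design.conditions):
        cond_entry = {
            "label": cond.label,
            "strain": cond.strain,
            "protocol": cond.protocol.to_dict(),
            "overrides": dict(cond.overrides),
            "replicates": cond.replicates,
            "sampling_interval": cond.sampling_interval,
            "traces": [],
        }
        for ri in range(cond.replicates):
            seed = _trace_seed(design, ci, ri)
            trace = synth_trace(
                cond, seed, design.noise_sd, design.noise_mult,
                base_kinetic, biophys, settings,
            )
            trace.metadata["replicate"] = ri
            fname = f"{cond.label.replace(' ', '_')}_rep{ri}.csv"
            if outdir is not None:
                trace.to_csv(outdir / fname)
            cond_entry["traces"].append(
                {
                    "file": fname,
                    "seed": seed,
                    "resting_state": trace.metadata.get("resting_state"),
                }
            )
            records.append(
                {"condition": cond.label, "replicate": ri, "seed": seed,
                 "trace": trace}
            )
        cond_entry["generating_parameters"] = records[-1]["trace"].metadata[
            "kinetic_parameters"
        ]
        manifest["conditions"].append(cond_entry)
    if outdir is not None:
        (Path(outdir) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    return records, manifest


def read_traces(paths) -> list[Trace]:
    """Load and validate trace CSVs (with their metadata sidecars).

    Validates a mandatory header, strictly increasing time and non-negative
    concentrations; a missing sidecar loads with a warning and the strain
    marked unknown.
    """
    traces = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            trace = Trace.from_csv(path)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
        dt = np.diff(trace.time)
        if np.any(dt <= 0):
            line = int(np.argmax(dt <= 0)) + 2  # header is line 1
            raise ValueError(f"{path}, line {line}: time must be strictly increasing")
        if np.any(trace.Ca_cyt < 0):
            line = int(np.argmax(trace.Ca_cyt < 0)) + 2
            raise ValueError(f"{path}, line {line}: negative calcium concentration")
        if not trace.metadata:
            warnings.warn(f"{path}: metadata sidecar missing; strain unknown")
            trace.metadata = {"strain": "unknown"}
        traces.append(trace)
    return traces
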