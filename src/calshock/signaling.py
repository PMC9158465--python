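"""Biochemical half of the hypotonic-shock model.

Cytosolic calcium is fed by gradient-driven influx through the HACS channel
(Cch1/Mid1) and through a stretch-activated (mechanosensitive, MS) channel
whose open probability is a Boltzmann function of turgor, and is cleared by
three Michaelis-Menten transporters (vacuolar Pmc1 and Vcx1, Golgi Pmr1).
Calmodulin binds calcium cooperatively and inhibits the MS channel; the
calcium/calmodulin-activated phosphatase calcineurin inhibits Vcx1.

Two components of the original, pre-simplification model are retained in
code but disabled by default: the unidentified Michaelis-Menten influx
("IN", v_IN = 0) and the calcineurin feedback on the HACS channel
(kI_Cch1 = 0).

Signaling concentrations are in nM, fluxes in nM/s, turgor in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np

from .biophysics import (
    BiophysicalDerived,
    BiophysicalParameters,
    StimulusProtocol,
    turgor_pressure,
    osmotic_volume_rate,
)

__all__ = [
    "KineticParameters",
    "SignalingState",
    "FluxBreakdown",
    "open_probability",
    "extracellular_calcium",
    "michaelis_flux",
    "gradient_flux",
    "inhibition_factor",
    "calmodulin_rate",
    "calcineurin_rate",
    "calcium_rate",
    "system_rhs",
]

# km_minus is tied to km_plus by the calmodulin dissociation constant
# (km_minus / km_plus = 9000 in nM^3 with the printed rate forms).
CAM_EQUILIBRIUM_RATIO = 9000.0


@dataclass(frozen=True)
class KineticParameters:
    """Rate, affinity, feedback and abundance constants of the wild type.

    All concentrations in nM, maximal rates in nM/s, channel rate constants
    in 1/s, inhibition constants in 1/nM.  ``km_minus`` is constrained to
    ``km_plus * 9000`` unless explicitly overridden.  ``v_IN`` and
    ``kI_Cch1`` default to zero: the corresponding influx and feedback were
    removed from the simplified model.
    """

    Ca_cyt0: float = 100.0
    Ca_ex0: float = 29_500.0
    v_Vcx1: float = 2_820_420.0
    v_Pmc1: float = 280_870.0
    v_Pmr1: float = 813.0
    k_Vcx1: float = 100_000.0
    k_Pmc1: float = 4_300.0
    k_Pmr1: float = 70.0
    k_MS: float = 132_184.0
    k_Cch1: float = 0.37
    P_MS: float = 0.76
    g_MS: float = 0.039
    km_plus: float = 1.8e-14
    km_minus: float | None = None  # defaults to km_plus * 9000
    kn_plus: float = 0.1
    kn_minus: float = 1_000.0
    CaM_t: float = 2_600.0
    CaN_t: float = 310.0
    kI_MS: float = 26_395.0
    kI_Vcx1: float = 9_348_540.0
    kI_Cch1: float = 0.0
    v_IN: float = 0.0
    k_IN: float = 1.0

    def __post_init__(self) -> None:
        if self.km_minus is None:
            object.__setattr__(self, "km_minus", self.km_plus * CAM_EQUILIBRIUM_RATIO)
        if self.g_MS <= 0:
            raise ValueError("gating slope g_MS must be positive")
        for name in (
            "v_Vcx1", "v_Pmc1", "v_Pmr1", "k_Vcx1", "k_Pmc1", "k_Pmr1",
            "k_MS", "k_Cch1", "km_plus", "km_minus", "kn_plus", "kn_minus",
            "CaM_t", "CaN_t", "kI_MS", "kI_Vcx1", "kI_Cch1", "v_IN", "k_IN",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_overrides(self, **overrides: float) -> "KineticParameters":
        """Return a copy with the given fields replaced (sparse patch)."""
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown kinetic parameter(s): {sorted(unknown)}")
        # re-tie km_minus unless the patch pins it explicitly
        if "km_plus" in overrides and "km_minus" not in overrides:
            overrides["km_minus"] = None
        return replace(self, **overrides)


@dataclass
class SignalingState:
    """Instantaneous biochemical state: cytosolic Ca, bound CaM, bound CaN."""

    Ca_cyt: float
    CaMb: float
    CaNb: float


@dataclass(frozen=True)
class FluxBreakdown:
    """Per-transporter calcium fluxes (nM/s) and the MS open probability.

    Influx terms (j_IN, j_Cch1, j_MS) enter the calcium balance with a plus
    sign, efflux terms (j_Pmr1, j_Vcx1, j_Pmc1) with a minus sign.
    ``j_MS0`` and ``j_Vcx10`` are the uninhibited counterparts of the two
    feedback-regulated fluxes.
    """

    j_Cch1: float
    j_MS: float
    j_Pmc1: float
    j_Vcx1: float
    j_Pmr1: float
    j_IN: float
    P_open: float
    j_MS0: float
    j_Vcx10: float

    @property
    def net(self) -> float:
        return (
            self.j_IN + self.j_Cch1 + self.j_MS
            - self.j_Pmr1 - self.j_Vcx1 - self.j_Pmc1
        )


def open_probability(P: float, params: KineticParameters) -> float:
    """Boltzmann open probability of the MS channel at turgor ``P`` (MPa).

    1 - 1/(1 + exp((P - P_MS)/g_MS)): equals 0.5 at P = P_MS, strictly
    increasing in P, saturating to 0/1 for large negative/positive
    arguments (overflow-guarded).
    """
    x = (P - params.P_MS) / params.g_MS
    if x > 500.0:
        return 1.0
    if x < -500.0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + math.exp(x))


def extracellular_calcium(
    t: float, params: KineticParameters, protocol: StimulusProtocol
) -> float:
    """Extracellular calcium (nM) under the dilution stimulus.

    Mirrors the external-osmolarity relaxation: constant at Ca_ex(0) before
    onset, then exponential decay with time constant t_m toward Ca_ex(0)/d.
    """
    ca0 = protocol.Ca_ex0 if protocol.Ca_ex0 is not None else params.Ca_ex0
    if t < protocol.t_off:
        return ca0
    target = ca0 / protocol.d
    return (ca0 - target) * math.exp((protocol.t_off - t) / protocol.t_m) + target


def michaelis_flux(v_max: float, k_m: float, s: float) -> float:
    """Michaelis-Menten transport rate v_max * s / (k_m + s), nM/s."""
    denom = k_m + s
    if denom == 0.0:
        return 0.0
    return v_max * s / denom


def gradient_flux(rate: float, ca_ex: float, ca_cyt: float, gate: float = 1.0) -> float:
    """Gradient-driven channel flux gate * rate * (ca_ex - ca_cyt), nM/s.

    The HACS channel uses gate = 1; the MS channel gates the flux by its
    open probability.  The sign follows the concentration gradient.
    """
    return gate * rate * (ca_ex - ca_cyt)


def inhibition_factor(k_I: float, modifier: float) -> float:
    """Multiplicative feedback inhibition 1 / (1 + k_I * modifier)."""
    return 1.0 / (1.0 + k_I * modifier)


def calmodulin_rate(ca_cyt: float, camb: float, params: KineticParameters) -> float:
    """Rate of calcium-bound calmodulin formation, nM/s.

    Cooperative binding of three calcium ions in a single mass-action step:
    km_plus * (CaM_t - CaMb) * Ca^3 - km_minus * CaMb.
    """
    return (
        params.km_plus * (params.CaM_t - camb) * ca_cyt**3
        - params.km_minus * camb
    )


def calcineurin_rate(camb: float, canb: float, params: KineticParameters) -> float:
    """Rate of calmodulin-bound calcineurin formation, nM/s.

    kn_plus * (CaN_t - CaNb) * CaMb - kn_minus * CaNb.  With kn_minus of
    order 10^3 /s this species relaxes on millisecond timescales and is the
    stiff direction of the system.
    """
    return params.kn_plus * (params.CaN_t - canb) * camb - params.kn_minus * canb


def quasi_steady_canb(camb: float, params: KineticParameters) -> float:
    """Quasi-steady bound calcineurin at a given bound-calmodulin level."""
    if params.kn_plus == 0.0 or params.CaN_t == 0.0:
        return 0.0
    kd = params.kn_minus / params.kn_plus
    return params.CaN_t * camb / (camb + kd)


def calcium_rate(
    state: SignalingState,
    t: float,
    P: float,
    params: KineticParameters,
    protocol: StimulusProtocol,
) -> tuple[float, FluxBreakdown]:
    """Net cytosolic-calcium rate (nM/s) and its per-transporter breakdown.

    Applies the calmodulin feedback on the MS channel and the calcineurin
    feedback on Vcx1; the HACS feedback and the IN influx are inert at their
    default-zero parameters.  Calmodulin binding does not consume cytosolic
    calcium in this balance (the calcium equation is a pure transport sum).
    """
    ca = state.Ca_cyt
    ca_ex = extracellular_calcium(t, params, protocol)
    p_open = open_probability(P, params)

    j_in = michaelis_flux(params.v_IN, params.k_IN, ca_ex)
    j_pmr1 = michaelis_flux(params.v_Pmr1, params.k_Pmr1, ca)
    j_pmc1 = michaelis_flux(params.v_Pmc1, params.k_Pmc1, ca)
    j_vcx1_0 = michaelis_flux(params.v_Vcx1, params.k_Vcx1, ca)
    j_ms_0 = gradient_flux(params.k_MS, ca_ex, ca, gate=p_open)
    j_cch1_0 = gradient_flux(params.k_Cch1, ca_ex, ca)

    j_ms = j_ms_0 * inhibition_factor(params.kI_MS, state.CaMb)
    j_vcx1 = j_vcx1_0 * inhibition_factor(params.kI_Vcx1, state.CaNb)
    j_cch1 = j_cch1_0 * inhibition_factor(params.kI_Cch1, state.CaNb)

    breakdown = FluxBreakdown(
        j_Cch1=j_cch1, j_MS=j_ms, j_Pmc1=j_pmc1, j_Vcx1=j_vcx1,
        j_Pmr1=j_pmr1, j_IN=j_in, P_open=p_open,
        j_MS0=j_ms_0, j_Vcx10=j_vcx1_0,
    )
    return breakdown.net, breakdown


def system_rhs(
    t: float,
    full_state,
    params: KineticParameters,
    biophys: BiophysicalParameters,
    derived: BiophysicalDerived,
    protocol: StimulusProtocol,
    buffered: bool = False,
):
    """Right-hand side of the coupled 4-state ODE system.

    State ordering: [V_os (L), Ca_cyt (nM), CaMb (nM), CaNb (nM)].  Turgor
    is computed from the instantaneous volume and feeds the MS gate.  Bound
    fractions are clamped into [0, total] for evaluation (solvers may probe
    slightly out-of-bound states); ``buffered=True`` additionally subtracts
    the 3:1 stoichiometric calcium consumption of calmodulin binding from
    the calcium balance (off by default: the balance is a pure transport
    sum).

    Deterministic and side-effect free; use :func:`state_violations` to
    diagnose out-of-bound states.
    """
    v_os, ca, camb, canb = float(full_state[0]), float(full_state[1]), \
        float(full_state[2]), float(full_state[3])
    ca = max(ca, 0.0)
    camb = min(max(camb, 0.0), params.CaM_t)
    canb = min(max(canb, 0.0), params.CaN_t)

    dv = osmotic_volume_rate(v_os, t, biophys, derived, protocol)
    P = turgor_pressure(v_os + biophys.V_b, derived, biophys)
    state = SignalingState(Ca_cyt=ca, CaMb=camb, CaNb=canb)
    dca, _ = calcium_rate(state, t, P, params, protocol)
    dcamb = calmodulin_rate(ca, camb, params)
    dcanb = calcineurin_rate(camb, canb, params)
    if buffered:
        dca -= 3.0 * dcamb
    return np.array([dv, dca, dcamb, dcanb])


def state_violations(full_state, params: KineticParameters) -> list[str]:
    """Names of state-invariant violations in a raw state vector."""
    v_os, ca, camb, canb = full_state
    out = []
    if v_os <= 0:
        out.append("V_os <= 0")
    if ca < 0:
        out.append("Ca_cyt < 0")
    if not (0 <= camb <= params.CaM_t):
        out.append("CaMb outside [0, CaM_t]")
    if not (0 <= canb <= params.CaN_t):
        out.append("CaNb outside [0, CaN_t]")
    return out
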