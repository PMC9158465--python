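"""Biophysical half of the hypotonic-shock model.

A walled yeast cell is treated as a sphere whose osmotically active (water)
volume responds to the imbalance between turgor pressure and the van't Hoff
osmotic pressure difference across the plasma membrane.  Turgor follows an
elastic law in the relative volume; the hypotonic stimulus is an exponential
relaxation of the external osmolarity toward its diluted value.

Canonical internal units: seconds, litres (= dm^3), MPa, and umol/L for
osmolytes.  All unit conversions happen at the parameter boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "BiophysicalParameters",
    "BiophysicalDerived",
    "StimulusProtocol",
    "surface_area",
    "zero_turgor_volume",
    "turgor_pressure",
    "initial_internal_osmolarity",
    "internal_osmolarity",
    "external_osmolarity",
    "osmotic_volume_rate",
]

_SPHERE_COEF = (36.0 * math.pi) ** (1.0 / 3.0)


@dataclass(frozen=True)
class BiophysicalParameters:
    """Physical constants of the cell and its environment.

    Defaults describe a yeast cell grown in rich (YPD) medium at 30 °C.

    Attributes
    ----------
    V_b : float
        Osmotically inactive (solid) volume, L.
    V_total0 : float
        Initial total cell volume V(0), L.
    V_ex : float
        Extracellular volume, L.  Stored for completeness; the external
        medium is treated as an infinite reservoir and V_ex plays no
        dynamical role.
    L_p : float
        Hydraulic conductivity of the membrane, dm·MPa^-1·s^-1.
    P_0 : float
        Initial turgor pressure, MPa.
    c_PC : float
        Concentration-to-pressure conversion factor (relates M to MPa in
        the van't Hoff law), dimensionless.
    R : float
        Gas constant, J·mol^-1·K^-1.
    T : float
        Temperature, K.
    c_n_e0 : float
        Initial extracellular osmolarity, umol/L.
    Gly_i : float
        Intracellular glycerol concentration, umol/L (held constant on the
        160-s horizon).
    epsilon : float
        Volumetric elastic modulus of the wall, MPa.
    sigma : float
        Reflection coefficient; fixed at 1 (glycerol is the only permeable
        solute considered and its reflection coefficient is ~1).
    """

    V_b: float = 20.5e-15
    V_total0: float = 50e-15
    V_ex: float = field(default=50e-12)  # 1000 * V(0)
    L_p: float = 1.3e-7
    P_0: float = 0.61
    c_PC: float = 1e-9
    R: float = 8.314
    T: float = 303.15
    c_n_e0: float = 260_000.0
    Gly_i: float = 180_000.0
    epsilon: float = 14.3
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.V_b <= 0 or self.V_total0 <= 0 or self.V_ex <= 0:
            raise ValueError("all volumes must be positive")
        if self.V_b >= self.V_total0:
            raise ValueError("solid volume V_b must be smaller than V(0)")
        if self.epsilon <= 0:
            raise ValueError("elastic modulus must be positive")
        if self.sigma != 1.0:
            raise ValueError("reflection coefficient is fixed at 1")
        if self.c_PC * self.R * self.T <= 0:
            raise ValueError("van't Hoff factor c_PC*R*T must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BiophysicalDerived:
    """Quantities derived once from :class:`BiophysicalParameters`.

    V_os0 : initial osmotic volume (L); Osm_i0 : initial internal osmolarity
    (umol/L); c_n_i : internal non-permeable solute concentration (umol/L);
    Gly_e0 : initial extracellular glycerol (umol/L); V_zero : volume at
    which turgor vanishes (L).
    """

    V_os0: float
    Osm_i0: float
    c_n_i: float
    Gly_e0: float
    V_zero: float

    @classmethod
    def from_parameters(cls, params: BiophysicalParameters) -> "BiophysicalDerived":
        V_os0 = params.V_total0 - params.V_b
        Osm_i0 = initial_internal_osmolarity(params)
        c_n_i = Osm_i0 - params.Gly_i
        if V_os0 <= 0:
            raise ValueError("initial osmotic volume must be positive")
        if c_n_i <= 0:
            raise ValueError("non-permeable internal solutes must be positive")
        return cls(
            V_os0=V_os0,
            Osm_i0=Osm_i0,
            c_n_i=c_n_i,
            Gly_e0=params.Gly_i / 1000.0,
            V_zero=zero_turgor_volume(params),
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Hypotonic-dilution stimulus.

    d : dilution factor (>= 1; adding four volumes of water to one of medium
    gives d = 5).  t_off : onset time of the dilution, s.  t_m : mixing time
    constant governing the speed of dilution, s.  Ca_ex0 : initial
    extracellular calcium, nM.  t_end : simulation horizon, s.
    """

    d: float = 5.0
    t_off: float = 30.0
    t_m: float = 9.1
    Ca_ex0: float = 29_500.0
    t_end: float = 160.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.t_m <= 0:
            raise ValueError("mixing time must be positive")
        if not (0 <= self.t_off < self.t_end):
            raise ValueError("need 0 <= t_off < t_end")

    def to_dict(self) -> dict:
        return asdict(self)


def surface_area(V_total: float) -> float:
    """Surface area (dm^2) of a sphere of volume ``V_total`` (L = dm^3)."""
    if V_total <= 0:
        raise ValueError("volume must be positive")
    return _SPHERE_COEF * V_total ** (2.0 / 3.0)


def zero_turgor_volume(params: BiophysicalParameters) -> float:
    """Volume V0 at which turgor vanishes, from the elastic turgor law.

    Constructed so that the turgor evaluated at V(0) equals P_0 exactly:
    V0 = V(0) * exp(-P_0 / epsilon).
    """
    return params.V_total0 * math.exp(-params.P_0 / params.epsilon)


def turgor_pressure(
    V_total: float,
    derived: BiophysicalDerived,
    params: BiophysicalParameters,
) -> float:
    """Turgor pressure (MPa) as a function of total cell volume.

    P = epsilon * ln(V / V0) for V >= V0, and 0 below V0 (a flaccid wall
    exerts no pressure).  Continuous and non-decreasing in V.
    """
    if V_total <= 0:
        raise ValueError("volume must be positive")
    if V_total < derived.V_zero:
        return 0.0
    return params.epsilon * math.log(V_total / derived.V_zero)


def initial_internal_osmolarity(params: BiophysicalParameters) -> float:
    """Internal osmolarity (umol/L) consistent with rest at turgor P_0.

    At steady state the turgor exactly balances the van't Hoff osmotic
    pressure difference, so Osm_i(0) = c_e(0) + P_0 / (c_PC * R * T).
    """
    return params.c_n_e0 + params.P_0 / (params.c_PC * params.R * params.T)


def internal_osmolarity(V_os: float, derived: BiophysicalDerived) -> float:
    """Internal osmolarity (umol/L) at osmotic volume ``V_os`` (L).

    Non-permeable solutes dilute with the water volume; glycerol is held
    constant: Osm_i = Gly_i + c_n_i * V_os(0) / V_os.
    """
    if V_os <= 0:
        raise ValueError("osmotic volume must be positive")
    return (derived.Osm_i0 - derived.c_n_i) + derived.c_n_i * derived.V_os0 / V_os


def external_osmolarity(
    t: float,
    params: BiophysicalParameters,
    protocol: StimulusProtocol,
) -> float:
    """External osmolarity (umol/L) under the dilution stimulus.

    Constant at c_e(0) before onset; afterwards relaxes exponentially with
    time constant t_m toward c_e(0)/d.  Extracellular glycerol is held at
    its initial value, so it contributes no net osmotic term.
    """
    c0 = params.c_n_e0
    if t < protocol.t_off:
        return c0
    target = c0 / protocol.d
    return (c0 - target) * math.exp((protocol.t_off - t) / protocol.t_m) + target


def osmotic_volume_rate(
    V_os: float,
    t: float,
    params: BiophysicalParameters,
    derived: BiophysicalDerived,
    protocol: StimulusProtocol,
) -> float:
    """Rate of change of the osmotic volume, L/s.

    dV_os/dt = -L_p * A(V) * (P(V) + c_PC*R*T*(Osm_e - Osm_i)).
    Zero at rest by construction of Osm_i(0); positive (swelling) right
    after a sufficiently large hypotonic dilution.
    """
    if V_os <= 0:
        raise ValueError("osmotic volume must be positive")
    V = V_os + params.V_b
    P = turgor_pressure(V, derived, params)
    osm_term = params.c_PC * params.R * params.T * (
        external_osmolarity(t, params, protocol) - internal_osmolarity(V_os, derived)
    )
    return -params.L_p * surface_area(V) * (P + osm_term)
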