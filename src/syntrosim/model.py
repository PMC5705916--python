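"""State space and right-hand sides of the coculture ODE system.

Two model variants share one state vector:

``DEFAULT``
    Partial privatization: the N2 fixer grows on N2 directly (route 1,
    bypassing the dissolved NH4+ pool) and additionally takes up
    extracellular NH4+ through a small boost route (route 2).  NH4+
    excretion is tied to route-1 growth flux.

``COMMUNAL``
    All fixed nitrogen passes through the extracellular NH4+ pool before
    either species can assimilate it; fixation is decoupled from growth.

State variables (units): Ec, Rp cells/ml; G, A, C, F, E, H mM.  H is a
cumulative liquid-equivalent bookkeeping of evolved H2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Iterator

import numpy as np

from .params import ParameterSet, ParameterError, UNIT_CONV

__all__ = [
    "STATE_FIELDS",
    "CultureState",
    "Derivs",
    "ModelVariant",
    "monod",
    "acid_inhibition",
    "rhs_default",
    "rhs_communal",
    "rhs_array",
]

STATE_FIELDS = ("Ec", "Rp", "G", "A", "C", "F", "E", "H")

STATE_UNITS = {
    "Ec": "cells/ml",
    "Rp": "cells/ml",
    "G": "mM",
    "A": "mM",
    "C": "mM",
    "F": "mM",
    "E": "mM",
    "H": "mM",
}


class DomainError(ValueError):
    """Raised when a state violates its domain (e.g. negative density)."""


@dataclass(frozen=True)
class CultureState:
    """Instantaneous culture composition.

    Ec: fermenter density; Rp: fixer density; G: glucose; A: extracellular
    NH4+; C: lumped consumable organic acids (acetate + lactate + succinate);
    F: formate; E: ethanol; H: cumulative H2.
    """

    Ec: float
    Rp: float
    G: float
    A: float = 0.0
    C: float = 0.0
    F: float = 0.0
    E: float = 0.0
    H: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise DomainError(f"state component {f.name} must be >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CultureState":
        return cls(**{n: float(v) for n, v in zip(STATE_FIELDS, y)})

    def __iter__(self) -> Iterator[float]:
        return iter(self.to_array())


@dataclass(frozen=True)
class Derivs:
    """Time derivative of each state variable (same units per hour)."""

    Ec: float
    Rp: float
    G: float
    A: float
    C: float
    F: float
    E: float
    H: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_FIELDS], dtype=float)


class ModelVariant(enum.Enum):
    """Which nitrogen topology to simulate."""

    DEFAULT = "default"    # partial privatization: direct N2 route exists
    COMMUNAL = "communal"  # all fixed N routed through the shared NH4+ pool

    @classmethod
    def coerce(cls, value: "ModelVariant | str") -> "ModelVariant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown model variant {value!r}; expected one of "
                f"{[v.value for v in cls]}"
            ) from None


def monod(s: float, K: float):
    """Monod saturation fraction s / (K + s), in [0, 1].

    Accepts scalars or arrays in ``s``.  K must be strictly positive.
    """
    if K <= 0:
        raise ParameterError(f"half-saturation constant must be > 0, got {K}")
    s = np.maximum(s, 0.0)
    return s / (K + s)


def acid_inhibition(C: float, F: float, params: ParameterSet):
    """Growth/metabolism attenuation from medium acidification.

    Decreasing Hill function of the total acid pool (consumable acids plus
    formate): 1 / (1 + ((C+F)/K_I)^n_I).  Equals 1 with no acids, 0.5 at
    C+F = K_I.  Applied multiplicatively to every growth and consumption
    rate of both species.  Ethanol is not an acid and does not contribute.
    """
    total = np.maximum(C, 0.0) + np.maximum(F, 0.0)
    return 1.0 / (1.0 + (total / params.K_I) ** params.n_I)


def _fluxes_default(y: np.ndarray, p: ParameterSet):
    """Specific rates shared by the default-variant RHS and diagnostics."""
    Ec, Rp, G, A, C, F = y[0], y[1], y[2], y[3], y[4], y[5]
    inhib = acid_inhibition(C, F, p)
    mG = monod(G, p.K_G)
    mC = monod(C, p.K_C)
    mu_E = p.mu_E_max * mG * monod(A, p.K_A) * inhib
    # maintenance fermentation is nitrogen-independent: stationary fermenter
    # cells keep turning glucose into acids, which feeds the fixer
    q_G = mu_E / p.Y_EG + (p.m_G * UNIT_CONV) * mG * inhib
    mu_R1 = p.mu_R_max1 * mC * inhib                      # N2 route
    mu_R2 = p.mu_R_max2 * mC * monod(A, p.K_AR) * inhib   # NH4+ uptake route
    return mu_E, q_G, mu_R1, mu_R2


def rhs_array(t: float, y: np.ndarray, params: ParameterSet,
              variant: ModelVariant) -> np.ndarray:
    """Raw ndarray right-hand side used by the integrator."""
    p = params
    Ec, Rp = y[0], y[1]
    if variant is ModelVariant.DEFAULT:
        mu_E, q_G, mu_R1, mu_R2 = _fluxes_default(y, p)
        mu_R = mu_R1 + mu_R2
        dEc = mu_E * Ec
        dRp = mu_R * Rp
        dG = -q_G * Ec
        dC = p.f_C * q_G * Ec - (mu_R / p.Y_RC) * Rp
        dF = p.f_F * q_G * Ec
        dE = p.f_E * q_G * Ec
        dA = (p.R_A * UNIT_CONV * mu_R1 * Rp
              - (mu_E / p.Y_EA) * Ec
              - (mu_R2 / p.Y_RA) * Rp)
        dH = p.phi_H * UNIT_CONV * mu_R1 * Rp
    elif variant is ModelVariant.COMMUNAL:
        G, A, C, F = y[2], y[3], y[4], y[5]
        inhib = acid_inhibition(C, F, p)
        mG = monod(G, p.K_G)
        mC = monod(C, p.K_C)
        mu_E = p.mu_E_max * mG * monod(A, p.K_A) * inhib
        q_G = mu_E / p.Y_EG + (p.m_G * UNIT_CONV) * mG * inhib
        # all growth of the fixer now requires extracellular NH4+
        mu_R = (p.mu_R_max1 + p.mu_R_max2) * mC * monod(A, p.K_AR) * inhib
        fix = p.v_fix * UNIT_CONV * mC * inhib * Rp  # mM/h of new NH4+
        dEc = mu_E * Ec
        dRp = mu_R * Rp
        dG = -q_G * Ec
        dC = p.f_C * q_G * Ec - (mu_R / p.Y_RC) * Rp
        dF = p.f_F * q_G * Ec
        dE = p.f_E * q_G * Ec
        dA = fix - (mu_E / p.Y_EA) * Ec - (mu_R / p.Y_RA) * Rp
        dH = p.phi_H * UNIT_CONV * mC * inhib * Rp
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unhandled variant {variant}")
    return np.array([dEc, dRp, dG, dA, dC, dF, dE, dH])


def _rhs(state: CultureState, params: ParameterSet,
         variant: ModelVariant) -> Derivs:
    y = state.to_array()
    if np.any(y < 0):
        raise DomainError("negative state component")
    d = rhs_array(0.0, y, params, variant)
    return Derivs(*map(float, d))


def rhs_default(state: CultureState, params: ParameterSet) -> Derivs:
    """Derivatives under the partial-privatization (default) topology.

    The fixer grows on N2 directly (mu_R1, bypassing the dissolved pool) and
    through a boost route on extracellular NH4+ (mu_R2).  NH4+ excretion is
    proportional to route-1 growth flux (R_A per new cell), so excretion
    stops when nitrogenase-fueled growth stops.
    """
    return _rhs(state, params, ModelVariant.DEFAULT)


def rhs_communal(state: CultureState, params: ParameterSet) -> Derivs:
    """Derivatives when every fixed nitrogen atom transits the shared pool.

    Fixation proceeds at v_fix per cell (scaled by acid saturation and
    inhibition) regardless of growth; both species then draw on the same
    extracellular NH4+, and no nitrogen enters biomass except through it.
    """
    return _rhs(state, params, ModelVariant.COMMUNAL)
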