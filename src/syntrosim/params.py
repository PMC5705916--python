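"""Kinetic, stoichiometric and inhibition parameters for the coculture model.

Units throughout the package: cell densities in cells/ml, dissolved species in
mM, time in h.  The single unit-bridging constant ``UNIT_CONV`` converts a
per-cell molar quantity (fmol/cell) times a cell density (cells/ml) into mM:
1 fmol/cell x 1 cell/ml = 1e-9 mM.  It is hard-coded and not user-settable.

Every field carries a provenance flag: ``"paper"`` for values printed in the
source literature, ``"calibrated"`` for values chosen so that the default
simulation reproduces the documented macroscopic behaviour (maximum growth
rate ratio of 4.6 between the two species, glucose exhaustion by ~100 h,
stationary cocultures dominated ~10:1 by the phototroph).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import ClassVar, Dict


class ParameterError(ValueError):
    """Raised when a parameter value violates its domain."""


#: mM per (fmol/cell x cells/ml); fixed unit bridge, never user-settable.
UNIT_CONV: float = 1e-9

# provenance of each default value: printed in the paper vs. calibrated here
_PROVENANCE: Dict[str, str] = {
    "mu_E_max": "calibrated",
    "K_G": "calibrated",
    "K_A": "paper",
    "K_AR": "paper",
    "mu_R_max1": "calibrated",
    "mu_R_max2": "paper",
    "K_C": "calibrated",
    "R_A": "paper",
    "Y_EG": "calibrated",
    "Y_EA": "calibrated",
    "Y_RC": "calibrated",
    "Y_RA": "calibrated",
    "m_G": "calibrated",
    "f_C": "calibrated",
    "f_F": "calibrated",
    "f_E": "calibrated",
    "phi_H": "calibrated",
    "K_I": "calibrated",
    "n_I": "calibrated",
    "v_fix": "calibrated",
}

# units of each field, used for config documentation and CSV headers
_UNITS: Dict[str, str] = {
    "mu_E_max": "1/h",
    "K_G": "mM",
    "K_A": "mM",
    "K_AR": "mM",
    "mu_R_max1": "1/h",
    "mu_R_max2": "1/h",
    "K_C": "mM",
    "R_A": "fmol/cell",
    "Y_EG": "cells/ml/mM",
    "Y_EA": "cells/ml/mM",
    "Y_RC": "cells/ml/mM",
    "Y_RA": "cells/ml/mM",
    "m_G": "fmol/cell/h",
    "f_C": "mol/mol",
    "f_F": "mol/mol",
    "f_E": "mol/mol",
    "phi_H": "fmol/cell",
    "K_I": "mM",
    "n_I": "dimensionless",
    "v_fix": "fmol/cell/h",
}

# half-saturation constants that must be strictly positive
_STRICTLY_POSITIVE = ("K_G", "K_A", "K_AR", "K_C", "K_I")


@dataclass(frozen=True)
class ParameterSet:
    """All constants of the two-species cross-feeding model.

    ``E`` refers to the fermenter (glucose consumer, NH4+ recipient), ``R`` to
    the phototrophic N2 fixer (organic-acid consumer, NH4+ producer).
    """

    # fermenter growth kinetics
    mu_E_max: float = 0.23     # maximal fermenter growth rate, 1/h
    K_G: float = 0.05           # glucose half-saturation, mM
    K_A: float = 0.01           # fermenter NH4+ half-saturation, mM
    # N2 fixer growth kinetics
    mu_R_max1: float = 0.05     # maximal growth rate on N2-derived nitrogen, 1/h
    mu_R_max2: float = 0.0152   # additive boost when assimilating NH4+, 1/h
    K_AR: float = 0.01          # fixer NH4+ half-saturation, mM
    K_C: float = 0.3            # consumable-acid half-saturation, mM
    # cross-feeding stoichiometry
    R_A: float = 0.15           # NH4+ excreted per new fixer cell, fmol/cell
    Y_EG: float = 1.0e7         # fermenter yield on glucose, cells/ml/mM
    Y_EA: float = 3.7e9         # fermenter yield on NH4+, cells/ml/mM
    Y_RC: float = 4.0e7         # fixer yield on consumable acids, cells/ml/mM
    Y_RA: float = 2.7e8         # fixer yield on NH4+ (boost route), cells/ml/mM
    m_G: float = 10.0            # maintenance glucose turnover, fmol/cell/h
    f_C: float = 0.9            # consumable acids per glucose, mol/mol
    f_F: float = 0.5            # formate per glucose, mol/mol
    f_E: float = 0.6            # ethanol per glucose, mol/mol
    phi_H: float = 1.1          # H2 per unit N2-route growth flux, fmol/cell
    # acid (pH) inhibition
    K_I: float = 20.0           # total acid at half-maximal inhibition, mM
    n_I: float = 10.0           # Hill steepness of acid inhibition
    # communal-pool variant only
    v_fix: float = 0.13         # N2->NH4+ fixation per cell at saturating acids, fmol/cell/h

    #: fixed constant, mM per (fmol/cell x cells/ml); not a dataclass field.
    unit_conv: ClassVar[float] = UNIT_CONV

    #: provenance flag per field ("paper" or "calibrated")
    provenance: ClassVar[Dict[str, str]] = _PROVENANCE
    #: unit string per field
    units: ClassVar[Dict[str, str]] = _UNITS

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ParameterError(f"{f.name} must be a number, got {v!r}")
            if v < 0:
                raise ParameterError(f"{f.name} must be >= 0, got {v}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        fsum = self.f_C + self.f_F + self.f_E
        if not 0 < fsum <= 3:
            raise ParameterError(
                "fermentation stoichiometry f_C+f_F+f_E must lie in (0, 3], "
                f"got {fsum}"
            )
        if self.n_I <= 0:
            raise ParameterError(f"n_I must be > 0, got {self.n_I}")

    # -- convenience -------------------------------------------------------

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields replaced (validated)."""
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def with_affinity_ratio(self, ratio: float) -> "ParameterSet":
        """Set NH4+ half-saturations for a producer:recipient affinity ratio.

        Affinity is the inverse of the half-saturation constant, so the ratio
        is K_A / K_AR.  Ratios > 1 raise the fermenter K_A from the shared
        default; ratios < 1 raise the fixer K_AR.  Half-saturations are only
        ever raised from the default (higher-than-default affinities are
        considered physiologically implausible).
        """
        if ratio <= 0:
            raise ParameterError(f"affinity ratio must be > 0, got {ratio}")
        base = type(self)().K_A  # shared default half-saturation
        if ratio >= 1.0:
            return self.with_overrides(K_A=base * ratio, K_AR=base)
        return self.with_overrides(K_A=base, K_AR=base / ratio)

    @property
    def affinity_ratio(self) -> float:
        """Producer:recipient relative NH4+ affinity, K_A / K_AR."""
        return self.K_A / self.K_AR

    def to_dict(self) -> Dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def describe(self) -> Dict[str, Dict[str, object]]:
        """Full metadata dump: value, unit and provenance per field."""
        return {
            name: {
                "value": val,
                "unit": _UNITS[name],
                "provenance": _PROVENANCE[name],
            }
            for name, val in self.to_dict().items()
        }


def default_parameters(**overrides: float) -> ParameterSet:
    """The shipped default parameter set, optionally with overrides."""
    return ParameterSet().with_overrides(**overrides)
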