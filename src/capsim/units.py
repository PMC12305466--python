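"""Reduced DPD units and the two scalar bridges to physical chemistry.

DPD works in reduced units: the cutoff radius ``r_c`` is the unit of length
(mapped here to roughly 1 nm), the thermal energy ``k_B T`` is the unit of
energy, and bead masses are 1.  Two conventional bridges connect the
dimensionless simulation parameters to laboratory quantities:

* the linear Groot–Warren relation between the conservative repulsion
  parameter ``a_ij`` and the Flory–Huggins interaction parameter
  ``chi = c * (a_ij - a_ii)`` (c ≈ 0.306 at bead density rho = 3), and
* an Arrhenius-type reading of the per-attempt reaction probability,
  ``P_r = A exp(-E_a / (k_B T))``, which converts a simulated bonding
  probability into an activation energy for a real polymerization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidMappingError, InvalidParameterError

#: molar gas constant in kJ mol^-1 K^-1 (pinned so tests are bit-stable)
MOLAR_GAS_KJ = 8.314e-3


@dataclass(frozen=True)
class ReducedUnitSystem:
    """Scale factors from reduced DPD units to physical units."""

    length_rc_nm: float = 1.0
    energy_kBT: float = 1.0
    time_tau: float = 1.0
    bead_mass: float = 1.0

    def __post_init__(self) -> None:
        for name in ("length_rc_nm", "energy_kBT", "time_tau", "bead_mass"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ChiMapping:
    """Linear repulsion-to-chi conversion chi = coefficient * (a_ij - a_ii)."""

    a_ii: float = 25.0
    chi_coefficient: float = 0.306
    rho: float = 3.0

    def __post_init__(self) -> None:
        if self.a_ii <= 0:
            raise InvalidParameterError("a_ii must be positive")
        if self.chi_coefficient <= 0:
            raise InvalidMappingError("chi_coefficient must be positive")


@dataclass(frozen=True)
class ArrheniusModel:
    """Arrhenius bridge P_r = A exp(-E_a/(k_B T)) with molar constants.

    ``boltzmann_kB`` is expressed per mole (kJ mol^-1 K^-1) so that
    activation energies come out in kJ mol^-1, the unit used for real
    radical polymerizations.
    """

    prefactor_A: float = 2.2e5
    temperature_T: float = 298.0
    boltzmann_kB: float = MOLAR_GAS_KJ

    def __post_init__(self) -> None:
        if self.prefactor_A <= 0:
            raise InvalidParameterError("prefactor_A must be positive")
        if self.temperature_T <= 0:
            raise InvalidParameterError("temperature_T must be positive")


DEFAULT_CHI = ChiMapping()
DEFAULT_ARRHENIUS = ArrheniusModel()


def alpha_to_chi(alpha_ij: float, mapping: ChiMapping = DEFAULT_CHI) -> float:
    """Flory–Huggins chi for a given DPD repulsion parameter.

    Linear and sign-preserving about the like-bead repulsion: beads that
    repel each other less than like beads (alpha < a_ii) have negative chi,
    i.e. an effective affinity.
    """
    if alpha_ij < 0:
        raise InvalidParameterError("repulsion parameter must be non-negative")
    return mapping.chi_coefficient * (alpha_ij - mapping.a_ii)


def chi_to_alpha(chi: float, mapping: ChiMapping = DEFAULT_CHI) -> float:
    """Exact inverse of :func:`alpha_to_chi`."""
    if mapping.chi_coefficient == 0:
        raise InvalidMappingError("chi_coefficient must be non-zero")
    return mapping.a_ii + chi / mapping.chi_coefficient


def pr_to_activation_energy(
    reaction_probability: float, model: ArrheniusModel = DEFAULT_ARRHENIUS
) -> float:
    """Activation energy (kJ mol^-1) implied by a reaction probability.

    E_a = k_B T ln(A / P_r); requires 0 < P_r <= A so the energy is
    non-negative.
    """
    if reaction_probability <= 0:
        raise InvalidParameterError("reaction probability must be positive")
    if reaction_probability > model.prefactor_A:
        raise InvalidParameterError(
            "P_r > A implies a negative activation energy"
        )
    return (
        model.boltzmann_kB
        * model.temperature_T
        * math.log(model.prefactor_A / reaction_probability)
    )


def activation_energy_to_pr(
    activation_energy: float, model: ArrheniusModel = DEFAULT_ARRHENIUS
) -> float:
    """Reaction probability implied by an activation energy (kJ mol^-1)."""
    if activation_energy < 0:
        raise InvalidParameterError("activation energy must be non-negative")
    pr = model.prefactor_A * math.exp(
        -activation_energy / (model.boltzmann_kB * model.temperature_T)
    )
    if pr > 1.0 + 1e-12:
        raise InvalidParameterError(
            "prefactor/temperature combination yields P_r > 1; "
            "not a valid per-attempt probability"
        )
    return min(pr, 1.0)
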