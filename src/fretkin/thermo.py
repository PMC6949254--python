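"""Thermodynamic conversions for binding kinetics.

Equilibrium free energy from the dissociation constant, transition-state
barrier from the association rate (Eyring form with transmission
coefficient kappa), two-site Mg2+ occupancy from NMR-derived association
constants, and the pseudo-first-order rate bookkeeping.

Note on units: the barrier formula is applied to the numeric value of the
second-order rate coefficient in 1/(M s), as is customary in this kind of
analysis even though the argument of the logarithm is then not strictly
dimensionless; with kappa = 1 the result is a lower bound on the barrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermoConstants",
    "BindingConstants",
    "kon_from_pseudo_first_order",
    "delta_g_bind",
    "delta_g_barrier",
    "kd_from_delta_g",
    "mg_occupancy",
    "kd_from_rates",
]

R_GAS = 8.314  # J / (mol K)
K_BOLTZMANN = 1.380649e-23  # J / K
H_PLANCK = 6.62607015e-34  # J s


@dataclass(frozen=True)
class ThermoConstants:
    T: float = 298.0  # K
    kappa: float = 1.0  # transmission coefficient
    R: float = R_GAS
    k_B: float = K_BOLTZMANN
    h: float = H_PLANCK

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")


@dataclass(frozen=True)
class BindingConstants:
    """Association constants (1/M) for the two Mg2+ sites.

    Use :meth:`from_dissociation_mid` to build from dissociation midpoints
    in mM (K = 1 / K_d).
    """

    K1: float
    K2: float

    def __post_init__(self):
        if self.K1 <= 0 or self.K2 <= 0:
            raise ValueError("association constants must be positive")

    @classmethod
    def from_dissociation_mid(cls, kd1_mM: float, kd2_mM: float) -> "BindingConstants":
        return cls(K1=1.0 / (kd1_mM * 1e-3), K2=1.0 / (kd2_mM * 1e-3))


def kon_from_pseudo_first_order(k_on_pseudo: float, ligand_conc: float) -> float:
    """Second-order k_on (1/(M s)) = pseudo-first-order k'_on (1/s) / c (M)."""
    if ligand_conc <= 0:
        raise ValueError("ligand concentration must be positive")
    return k_on_pseudo / ligand_conc


def delta_g_bind(kd: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy dG = R T ln(K_d), K_d in M, result in kJ/mol."""
    if kd <= 0:
        raise ValueError("K_d must be positive")
    return constants.R * constants.T * np.log(kd) / 1000.0


def kd_from_delta_g(dg_kj: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Inverse of :func:`delta_g_bind` (round-trip exact)."""
    return float(np.exp(dg_kj * 1000.0 / (constants.R * constants.T)))


def delta_g_barrier(k_on: float, constants: ThermoConstants = ThermoConstants()) -> float:
    """Transition-state barrier dG‡ = -R T ln(k_on h / (kappa k_B T)) in kJ/mol."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    arg = k_on * constants.h / (constants.kappa * constants.k_B * constants.T)
    return -constants.R * constants.T * np.log(arg) / 1000.0


def mg_occupancy(mg_conc, binding: BindingConstants):
    """Fraction of Mg2+-bound RNA for a two-site scheme.

    Theta = (K1 c + K2 c + K1 K2 c^2) / (1 + K1 c + K2 c + K1 K2 c^2),
    the ratio of the occupied-site partition function to the full one.
    Vectorized over concentrations (in M).
    """
    c = np.asarray(mg_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("Mg2+ concentration must be non-negative")
    num = binding.K1 * c + binding.K2 * c + binding.K1 * binding.K2 * c**2
    theta = num / (1.0 + num)
    return float(theta) if theta.ndim == 0 else theta


def kd_from_rates(k_on: float, k_off: float) -> float:
    """K_d (M) = k_off / k_on; consistency check against population-based K_d."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    return k_off / k_on
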