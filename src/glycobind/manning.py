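"""Counterion-condensation theory for charged glycan chains.

A glycosaminoglycan such as heparan sulphate is treated as a linear
polyelectrolyte with ``P`` charged groups distributed over a contour length
``L``, giving a mean inter-charge spacing ``b = L / P``.  The dimensionless
line charge density

    xi = l_B / b,      l_B = e^2 / (4 pi eps0 eps k T)

compares ``b`` to the Bjerrum length ``l_B`` (the separation at which the
Coulomb energy of two elementary charges equals thermal energy, ~0.71 nm in
water at 25 degC).  Manning's theory predicts that mobile counterions condense
onto the chain whenever ``xi > 1``; for monovalent counterions, condensation
renormalizes the effective line charge down to the critical density, leaving
an effective charge fraction of ``1/xi`` and a condensed fraction ``1 - 1/xi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ELEMENTARY_CHARGE",
    "VACUUM_PERMITTIVITY",
    "BOLTZMANN_CONSTANT",
    "PolyelectrolyteChain",
    "SolventConditions",
    "CondensationState",
    "charge_spacing",
    "bjerrum_length",
    "line_charge_density",
    "condensation_fraction",
]

# CODATA 2018 / SI-2019 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F m^-1
BOLTZMANN_CONSTANT = 1.380649e-23  # J K^-1

_M_TO_NM = 1e9


@dataclass(frozen=True)
class PolyelectrolyteChain:
    """A linear polyelectrolyte: contour length [nm] and number of charges.

    Parameters
    ----------
    contour_length_nm
        Contour length of the chain in nanometres; must be positive.
    n_charges
        Number of charged groups along the chain; at least 1.
    label
        Free-text identifier (e.g. ``"heparan sulphate"``).
    """

    contour_length_nm: float
    n_charges: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.contour_length_nm > 0:
            raise ValueError("contour_length_nm must be > 0, got "
                             f"{self.contour_length_nm!r}")
        if self.n_charges < 1:
            raise ValueError(f"n_charges must be >= 1, got {self.n_charges!r}")


@dataclass(frozen=True)
class SolventConditions:
    """Temperature and relative permittivity of the solvent.

    Defaults are water at 25 degC (eps = 78.5, T = 298.15 K).
    """

    temperature_k: float = 298.15
    dielectric_constant: float = 78.5

    def __post_init__(self) -> None:
        if not self.temperature_k > 0:
            raise ValueError("temperature_k must be > 0")
        if not self.dielectric_constant > 1:
            raise ValueError("dielectric_constant must be > 1")

    @classmethod
    def from_celsius(cls, temperature_c: float,
                     dielectric_constant: float = 78.5) -> "SolventConditions":
        return cls(temperature_k=temperature_c + 273.15,
                   dielectric_constant=dielectric_constant)


@dataclass(frozen=True)
class CondensationState:
    """Line charge density with its condensation consequences.

    ``condensed_fraction + effective_charge_fraction == 1`` above threshold;
    below threshold (xi <= 1) no counterions condense and the effective charge
    fraction is 1.
    """

    xi: float
    is_condensed: bool
    condensed_fraction: float
    effective_charge_fraction: float

    @classmethod
    def from_xi(cls, xi: float) -> "CondensationState":
        if not xi > 0:
            raise ValueError(f"xi must be > 0, got {xi!r}")
        condensed = condensation_fraction(xi)
        return cls(
            xi=xi,
            is_condensed=xi > 1.0,
            condensed_fraction=condensed,
            effective_charge_fraction=1.0 - condensed,
        )


def charge_spacing(chain: PolyelectrolyteChain) -> float:
    """Mean distance between charges along the chain, b = L/P [nm]."""
    return chain.contour_length_nm / chain.n_charges


def bjerrum_length(conditions: SolventConditions | None = None) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps k T) in nanometres."""
    if conditions is None:
        conditions = SolventConditions()
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY * conditions.dielectric_constant
        * BOLTZMANN_CONSTANT * conditions.temperature_k
    )
    return lb_m * _M_TO_NM


def line_charge_density(b_nm: float,
                        conditions: SolventConditions | None = None
                        ) -> CondensationState:
    """Dimensionless line charge density xi = l_B / b and condensation state.

    Parameters
    ----------
    b_nm
        Mean inter-charge spacing in nanometres; must be positive.
    conditions
        Solvent temperature and permittivity; defaults to water at 25 degC.
    """
    if not b_nm > 0:
        raise ValueError(f"charge spacing b must be > 0, got {b_nm!r}")
    xi = bjerrum_length(conditions) / b_nm
    return CondensationState.from_xi(xi)


def condensation_fraction(xi: float) -> float:
    """Fraction of chain charge neutralized by condensed monovalent counterions.

    Manning's limiting law: max(0, 1 - 1/xi).  Zero at or below the
    condensation threshold xi = 1, approaching 1 as xi grows.
    """
    if not xi > 0:
        raise ValueError(f"xi must be > 0, got {xi!r}")
    return max(0.0, 1.0 - 1.0 / xi)
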