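"""Physical-unit mapping between simulation units and nm / kbp / ms / pN.

The simulation works in reduced Lennard-Jones-style units: bead diameter
``sigma``, thermal energy ``kBT`` and bead mass ``m`` are all 1.  One bead
maps to a 20-nm chromatin segment holding 2 kbp.  Times are mapped through
the Brownian time, the time a free bead needs to diffuse its own diameter,

    tau_B = 3 pi sigma^3 eta_sol / kBT,

which evaluates to ~2.7 ms for sigma = 20 nm, T = 300 K and a nucleoplasm
viscosity of 150 cP (commonly quoted rounded to ~3 ms).  Forces are mapped
through the simulation force unit kBT/sigma (~0.2 pN at the same mapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

KB_J_PER_K = 1.380649e-23  # Boltzmann constant, J/K


class ConfigurationError(ValueError):
    """Raised for physically invalid configuration parameters."""


@dataclass(frozen=True)
class UnitSystem:
    """Mapping of reduced simulation units onto physical units.

    Parameters
    ----------
    sigma_nm : float
        Bead diameter in nanometres (default 20).
    bp_per_bead : float
        Genomic content of one bead in base pairs (default 2000).
    temperature_K : float
        Absolute temperature (default 300).
    viscosity_cP : float
        Solvent (nucleoplasm) viscosity in centipoise (default 150).

    Derived fields ``kBT_J``, ``tau_B_s`` and ``force_pN`` are computed in
    ``__post_init__`` and must not be supplied.
    """

    sigma_nm: float = 20.0
    bp_per_bead: float = 2000.0
    temperature_K: float = 300.0
    viscosity_cP: float = 150.0
    kBT_J: float = field(init=False)
    tau_B_s: float = field(init=False)
    force_pN: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("sigma_nm", "bp_per_bead", "temperature_K", "viscosity_cP"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        kbt = KB_J_PER_K * self.temperature_K
        sigma_m = self.sigma_nm * 1e-9
        eta = self.viscosity_cP * 1e-3  # cP -> Pa s
        object.__setattr__(self, "kBT_J", kbt)
        object.__setattr__(self, "tau_B_s", 3.0 * math.pi * sigma_m**3 * eta / kbt)
        object.__setattr__(self, "force_pN", kbt / sigma_m * 1e12)


def map_brownian_time(units: UnitSystem) -> float:
    """Physical duration of one Brownian time, in milliseconds.

    tau_B = 3 pi sigma^3 eta / kBT.  The default mapping gives ~2.7 ms;
    the value is returned unrounded.
    """
    return units.tau_B_s * 1e3


def map_force_unit(units: UnitSystem) -> float:
    """Piconewtons per simulation force unit kBT/sigma (~0.207 pN default)."""
    return units.force_pN


def force_pn_to_sim(force_pN: float, units: UnitSystem) -> float:
    """Convert a physical force in pN to simulation units (kBT/sigma)."""
    return force_pN / units.force_pN


def minutes_to_tau(minutes: float, units: UnitSystem) -> float:
    """Convert wall-clock minutes of mapped biological time to tau_B."""
    return minutes * 60.0 / units.tau_B_s


def bp_to_beads(genomic_length_kbp: float, units: UnitSystem | None = None) -> int:
    """Number of beads holding ``genomic_length_kbp`` kilobases (rounded).

    At the default 2 kbp/bead mapping, 80 kbp -> 40 beads.
    """
    if genomic_length_kbp < 0:
        raise ConfigurationError("genomic length must be non-negative")
    units = units or UnitSystem()
    return round(genomic_length_kbp * 1e3 / units.bp_per_bead)


def beads_to_bp(n_beads: int, units: UnitSystem | None = None) -> float:
    """Genomic length in kbp of ``n_beads`` beads."""
    units = units or UnitSystem()
    return n_beads * units.bp_per_bead / 1e3
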