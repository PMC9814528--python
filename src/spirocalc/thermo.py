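"""Free-energy arithmetic for the spirocyclization model.

Links quantum-chemical Gibbs free energies to the closure constant via
``k_closure = exp(-dG/RT)`` with ``dG = G(closed, acidic) - G(open, acidic)``
in kJ/mol (sign convention fixed throughout the package: a negative dG
favours the closed, dark form).  Also provides hydration-ensemble selection
over candidate microsolvated structures, explicit-water stoichiometry
balancing between open and closed complexes, unit conversion, and the
Eyring rate for an activation free energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp

from .errors import InputError, StoichiometryError

__all__ = [
    "GAS_CONSTANT",
    "BOLTZMANN",
    "PLANCK",
    "HARTREE_TO_KJ_PER_MOL",
    "Form",
    "SpeciesRecord",
    "FreeEnergyDifference",
    "convert_energy",
    "closure_constant_from_delta_g",
    "delta_g_from_closure_constant",
    "ensemble_free_energy",
    "assemble_delta_g",
    "eyring_rate",
]

# Pinned physical constants (CODATA 2018 exact values where defined).
GAS_CONSTANT = 8.314462618  # J mol^-1 K^-1
BOLTZMANN = 1.380649e-23  # J K^-1
PLANCK = 6.62607015e-34  # J s
HARTREE_TO_KJ_PER_MOL = 2625.4996

_UNITS = ("hartree", "kJ/mol")


class Form(str, Enum):
    """Structure role in the thermodynamic cycle."""

    OPEN_ACIDIC = "open_acidic"
    CLOSED_ACIDIC = "closed_acidic"
    TRANSITION_STATE = "transition_state"
    WATER = "water"


@dataclass(frozen=True)
class SpeciesRecord:
    """One optimized structure: a microsolvated open/closed complex, a
    transition state, or a lone water molecule.

    ``free_energy`` is tagged with its unit (``hartree`` straight from a QM
    log, or ``kJ/mol``); ``n_waters`` counts explicit first-shell waters in
    the complex.
    """

    label: str
    form: Form
    n_waters: int
    free_energy: float
    unit: str = "hartree"
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", Form(self.form))
        if self.unit not in _UNITS:
            raise InputError(f"unknown energy unit {self.unit!r}; expected one of {_UNITS}")
        if int(self.n_waters) != self.n_waters or self.n_waters < 0:
            raise InputError(f"n_waters must be a non-negative integer, got {self.n_waters!r}")
        object.__setattr__(self, "n_waters", int(self.n_waters))
        if not math.isfinite(self.free_energy):
            raise InputError(f"free_energy must be finite, got {self.free_energy!r}")
        if self.temperature <= 0:
            raise InputError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def free_energy_kj(self) -> float:
        return convert_energy(self.free_energy, self.unit, "kJ/mol")


@dataclass(frozen=True)
class FreeEnergyDifference:
    """``G(closed acidic) - G(open acidic)`` in kJ/mol at ``temperature`` K.

    ``n_waters`` records the balanced explicit-water count of the two
    complexes the difference was assembled from (``None`` when unknown).
    """

    delta_g: float
    temperature: float = 298.15
    n_waters: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_g):
            raise InputError(f"delta_g must be finite, got {self.delta_g!r}")
        if self.temperature <= 0:
            raise InputError(f"temperature must be > 0 K, got {self.temperature}")


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between hartree and kJ/mol (1 hartree = 2625.4996 kJ/mol)."""
    if from_unit not in _UNITS or to_unit not in _UNITS:
        raise InputError(
            f"unknown unit in conversion {from_unit!r} -> {to_unit!r}; expected {_UNITS}"
        )
    if from_unit == to_unit:
        return value
    if from_unit == "hartree":
        return value * HARTREE_TO_KJ_PER_MOL
    return value / HARTREE_TO_KJ_PER_MOL


def closure_constant_from_delta_g(
    delta_g: Union[FreeEnergyDifference, float], temperature: float = 298.15
) -> float:
    """Closure constant from a free-energy difference:
    ``k_closure = exp(-dG * 1000 / (R*T))`` with dG in kJ/mol.

    Accepts a :class:`FreeEnergyDifference` (its own temperature wins) or a
    bare kJ/mol value with an explicit ``temperature``.
    """
    if isinstance(delta_g, FreeEnergyDifference):
        dg, temperature = delta_g.delta_g, delta_g.temperature
    else:
        dg = float(delta_g)
        if not math.isfinite(dg):
            raise InputError(f"delta_g must be finite, got {delta_g!r}")
    return math.exp(-dg * 1000.0 / (GAS_CONSTANT * temperature))


def delta_g_from_closure_constant(
    k_closure: float, temperature: float = 298.15, n_waters: Optional[int] = None
) -> FreeEnergyDifference:
    """Exact inverse of :func:`closure_constant_from_delta_g`."""
    if k_closure <= 0:
        raise InputError(f"k_closure must be > 0 to define a free energy, got {k_closure}")
    dg = -GAS_CONSTANT * temperature * math.log(k_closure) / 1000.0
    return FreeEnergyDifference(dg, temperature, n_waters)


def eyring_rate(activation_free_energy: float, temperature: float = 298.15) -> float:
    """Unimolecular rate constant (1/s) from an activation free energy
    (kJ/mol) via the Eyring equation ``k = (k_B*T/h) * exp(-dG'/RT)``,
    transmission coefficient 1."""
    if not math.isfinite(activation_free_energy):
        raise InputError("activation free energy must be finite")
    if temperature <= 0:
        raise InputError(f"temperature must be > 0 K, got {temperature}")
    prefactor = BOLTZMANN * temperature / PLANCK
    return prefactor * math.exp(
        -activation_free_energy * 1000.0 / (GAS_CONSTANT * temperature)
    )


class EnsembleMode(str, Enum):
    MIN = "min"
    BOLTZMANN = "boltzmann"


def _homogeneous(records: Sequence[SpeciesRecord]) -> tuple[Form, int]:
    forms = {r.form for r in records}
    waters = {r.n_waters for r in records}
    if len(forms) > 1:
        raise StoichiometryError(f"mixed forms in ensemble: {sorted(f.value for f in forms)}")
    if len(waters) > 1:
        raise StoichiometryError(f"mixed explicit-water counts in ensemble: {sorted(waters)}")
    return next(iter(forms)), next(iter(waters))


def ensemble_free_energy(
    records: Iterable[SpeciesRecord],
    mode: Union[EnsembleMode, str] = EnsembleMode.MIN,
    temperature: float = 298.15,
) -> float:
    """Effective free energy (kJ/mol) of candidate hydration structures.

    ``min`` picks the most stable structure — the usual practice when
    scanning explicit-water arrangements.  ``boltzmann`` returns the
    population-weighted free energy ``-RT ln sum_i exp(-G_i/RT)``, which is
    always <= the minimum (it adds configurational entropy).  All records
    must describe the same form with the same explicit-water count.
    """
    records = list(records)
    if not records:
        raise InputError("ensemble_free_energy requires at least one record")
    _homogeneous(records)
    g = np.array([r.free_energy_kj for r in records])
    if EnsembleMode(mode) is EnsembleMode.MIN:
        return float(g.min())
    rt = GAS_CONSTANT * temperature / 1000.0  # kJ/mol
    return float(-rt * logsumexp(-g / rt))


def assemble_delta_g(
    open_records: Sequence[SpeciesRecord],
    closed_records: Sequence[SpeciesRecord],
    mode: Union[EnsembleMode, str] = EnsembleMode.MIN,
    water_reference: Optional[SpeciesRecord] = None,
    temperature: float = 298.15,
) -> FreeEnergyDifference:
    """dG = G(closed) - G(open) in kJ/mol, balancing explicit waters.

    When the open and closed complexes carry different numbers of explicit
    water molecules, free energies are not directly comparable; the deficit
    side is topped up with ``(count difference) x G(water_reference)`` so
    both sides of the difference describe the same atoms.  Without a water
    reference, unequal counts are a stoichiometry error.
    """
    if not open_records or not closed_records:
        raise InputError("assemble_delta_g requires open and closed records")
    open_form, n_open = _homogeneous(list(open_records))
    closed_form, n_closed = _homogeneous(list(closed_records))
    if open_form is not Form.OPEN_ACIDIC:
        raise StoichiometryError(f"open ensemble has form {open_form.value!r}")
    if closed_form is not Form.CLOSED_ACIDIC:
        raise StoichiometryError(f"closed ensemble has form {closed_form.value!r}")

    g_open = ensemble_free_energy(open_records, mode, temperature)
    g_closed = ensemble_free_energy(closed_records, mode, temperature)

    if n_open != n_closed:
        if water_reference is None:
            raise StoichiometryError(
                f"open complex carries {n_open} explicit waters but closed carries "
                f"{n_closed}; supply a water reference energy to balance"
            )
        if water_reference.form is not Form.WATER:
            raise StoichiometryError(
                f"water reference has form {water_reference.form.value!r}, expected 'water'"
            )
        g_water = water_reference.free_energy_kj
        if n_open < n_closed:
            g_open += (n_closed - n_open) * g_water
        else:
            g_closed += (n_open - n_closed) * g_water

    return FreeEnergyDifference(g_closed - g_open, temperature, max(n_open, n_closed))
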